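"""Shared helpers: independent naive scattering reference and random graphs.

The naive implementation below is the oracle for the scattering transform:
explicit ``np.linalg.matrix_power`` powers, explicit loops over channels,
scales and moments, ordinary BLAS sums.  It shares no code with the
package's implementation.
"""

from __future__ import annotations

import numpy as np
import pytest


def naive_scattering(A, x, J, Q, orders=("zeroth", "first", "second")):
    """Reference scattering features: explicit powers and triple loops."""
    A = np.asarray(A, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = A.shape[0]
    D_inv = np.diag(1.0 / A.sum(axis=0))
    P = 0.5 * (np.eye(n) + A @ D_inv)
    psis = [
        np.linalg.matrix_power(P, 2 ** (j - 1)) - np.linalg.matrix_power(P, 2**j)
        for j in range(1, J + 1)
    ]
    feats = []
    for c in range(x.shape[1]):
        xc = x[:, c]
        if "zeroth" in orders:
            for q in range(1, Q + 1):
                feats.append(np.sum(xc**q))
        if "first" in orders:
            for j in range(J):
                u = np.abs(psis[j] @ xc)
                for q in range(1, Q + 1):
                    feats.append(np.sum(u**q))
        if "second" in orders:
            for j in range(J):
                uj = np.abs(psis[j] @ xc)
                for jp in range(j + 1, J):
                    u2 = np.abs(psis[jp] @ uj)
                    for q in range(1, Q + 1):
                        feats.append(np.sum(u2**q))
    return np.asarray(feats)


def random_connected_adjacency(rng, n, extra_edge_prob=0.3):
    """Random connected simple graph: random tree plus extra edges."""
    A = np.zeros((n, n), dtype=np.int64)
    for i in range(1, n):
        j = int(rng.integers(0, i))
        A[i, j] = A[j, i] = 1
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] == 0 and rng.random() < extra_edge_prob:
                A[i, j] = A[j, i] = 1
    return A


def graph_from_adjacency(A):
    """Wrap a raw adjacency matrix in a MolecularGraph for the transform."""
    from gsgmol.graphs import MolecularGraph

    n = A.shape[0]
    return MolecularGraph(
        n=n,
        adjacency=np.asarray(A, dtype=np.int64),
        node_order=list(range(n)),
        smiles_canonical="",
        mol_weight=1.0,
        element_set=frozenset({"C"}),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
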