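"""Geometric scattering transform on molecular graphs.

Maps a graph with per-node signals to a fixed-length, permutation-invariant
feature vector.  The construction:

* lazy random walk          P  = (I + A D^-1) / 2
* dyadic graph wavelets     Psi_j = P^(2^(j-1)) - P^(2^j),   1 <= j <= J
* scattering moments        S0[q]       = sum_i x_i^q
                            S1[j, q]    = sum_i |Psi_j x|_i^q
                            S2[j,j',q]  = sum_i |Psi_j' |Psi_j x||_i^q,  j < j'

for 1 <= q <= Q, giving N*Q*(1 + J + J(J-1)/2) features for N signal
channels when all three orders are selected.  The filters are designed, not
learned: the only parameters are the maximum scale J, the number of moments
Q, and which orders to include.

Numerical note — exact permutation invariance.  Floating-point addition is
not associative, so the result of an ordinary matrix product depends on the
summation order and relabeling graph nodes can perturb features in the last
bit.  Every contraction here (matrix powers, wavelet application, moment
sums) therefore sorts its product terms before a deterministic pairwise
summation.  The multiset of terms is relabeling-invariant, hence so is the
sorted sequence and its sum: features are *bit-identical* under any node
permutation, not merely close.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graphs import MolecularGraph

ORDER_NAMES = ("zeroth", "first", "second")


class GraphDegeneracyError(ValueError):
    """Raised for graphs on which the lazy walk is undefined."""


@dataclass(frozen=True)
class GSGConfig:
    """Parameters of the scattering transform.

    Parameters
    ----------
    J : int
        Maximum wavelet scale (>= 1); wavelets probe dyadic scales
        2^0 .. 2^J. The reference choice for molecular work is 4.
    Q : int
        Number of statistical moments per signal (>= 1).
    orders : tuple of str
        Non-empty subset of {"zeroth", "first", "second"}.
    """

    J: int = 4
    Q: int = 4
    orders: tuple[str, ...] = ORDER_NAMES

    def __post_init__(self):
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        orders = tuple(self.orders)
        if not orders:
            raise ValueError("orders must be non-empty")
        bad = set(orders) - set(ORDER_NAMES)
        if bad:
            raise ValueError(f"unknown scattering orders: {sorted(bad)}")
        if "second" in orders and self.J < 2:
            raise ValueError("second-order moments need J >= 2 (they pair j < j')")
        object.__setattr__(self, "orders", orders)


@dataclass(frozen=True)
class DiffusionOperator:
    """Lazy random walk matrix P; columns sum to 1, entries >= 0."""

    P: np.ndarray


@dataclass(frozen=True)
class WaveletBank:
    """Dyadic wavelet filters; ``psi[j-1]`` holds Psi_j, columns sum to 0."""

    psi: list[np.ndarray]


@dataclass(frozen=True)
class ScatteringFeatures:
    """Flat invariant feature vector with its named layout."""

    vector: np.ndarray
    layout: list[str]
    length: int = field(init=False)

    def __post_init__(self):
        if self.vector.shape != (len(self.layout),):
            raise ValueError("vector/layout length mismatch")
        object.__setattr__(self, "length", self.vector.shape[0])


def _stable_contract(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """a @ b with summation order independent of row/column labeling.

    Materialises all products a[i,k]*b[k,j], sorts each contraction fiber,
    and reduces with numpy's deterministic pairwise sum.  O(n^2 m log m) —
    molecules are small, so exactness is worth more than BLAS speed here.
    """
    prod = a[:, :, None] * b[None, :, :]
    prod.sort(axis=1)
    return prod.sum(axis=1)


def _stable_colsum(a: np.ndarray) -> np.ndarray:
    """Column sums independent of row ordering."""
    return np.sort(a, axis=0).sum(axis=0)


def lazy_random_walk(graph: MolecularGraph) -> DiffusionOperator:
    """P = (I + A D^-1)/2: half stay put, half step to a uniform neighbor."""
    n = graph.n
    if n == 0:
        raise GraphDegeneracyError("empty graph")
    A = np.asarray(graph.adjacency, dtype=np.float64)
    deg = A.sum(axis=0)
    if n >= 2 and np.any(deg == 0):
        raise GraphDegeneracyError("zero-degree node: D is singular")
    if n == 1:
        return DiffusionOperator(P=np.ones((1, 1)))
    P = 0.5 * (np.eye(n) + A / deg[None, :])
    return DiffusionOperator(P=P)


def build_wavelets(operator: DiffusionOperator, J: int) -> WaveletBank:
    """Psi_j = P^(2^(j-1)) - P^(2^j), computed by repeated squaring."""
    if J < 1:
        raise ValueError("J must be >= 1")
    P = operator.P
    powers = [P]  # powers[k] = P^(2^k)
    for _ in range(J):
        powers.append(_stable_contract(powers[-1], powers[-1]))
    psi = [powers[j - 1] - powers[j] for j in range(1, J + 1)]
    return WaveletBank(psi=psi)


def feature_length(N: int, J: int, Q: int, orders=ORDER_NAMES) -> int:
    """Number of scattering features for N channels: closed-form count."""
    orders = set(orders)
    blocks = (
        ("zeroth" in orders)
        + J * ("first" in orders)
        + (J * (J - 1) // 2) * ("second" in orders)
    )
    return N * Q * blocks


def feature_names(channel_names, config: GSGConfig) -> list[str]:
    """Frozen flat layout: channel outermost, then S0 | S1(j) | S2(j<j'), then q."""
    J, Q = config.J, config.Q
    names = []
    for ch in channel_names:
        if "zeroth" in config.orders:
            names += [f"{ch}|S0|q{q}" for q in range(1, Q + 1)]
        if "first" in config.orders:
            names += [
                f"{ch}|S1|j{j}|q{q}"
                for j in range(1, J + 1)
                for q in range(1, Q + 1)
            ]
        if "second" in config.orders:
            names += [
                f"{ch}|S2|j{j}|j{jp}|q{q}"
                for j in range(1, J + 1)
                for jp in range(j + 1, J + 1)
                for q in range(1, Q + 1)
            ]
    return names


def _moments(values: np.ndarray, Q: int) -> np.ndarray:
    """Raw q-th moment sums over nodes, q = 1..Q; shape (N, Q).

    Plain sums — no normalisation by n and no q-th root.
    """
    out = np.empty((values.shape[1], Q))
    for q in range(1, Q + 1):
        out[:, q - 1] = _stable_colsum(values**q)
    return out


def scattering_moments(
    graph: MolecularGraph,
    signals: np.ndarray,
    config: GSGConfig,
    channel_names=None,
) -> ScatteringFeatures:
    """Scattering feature vector of one (graph, signal) pair.

    Parameters
    ----------
    graph : MolecularGraph
    signals : ndarray of shape (n, N)
        One row per node in ``graph.node_order``; columns are signal channels.
    config : GSGConfig
    channel_names : sequence of str, optional
        Labels for the N channels (defaults to ``ch0..ch{N-1}``).
    """
    x = np.asarray(signals, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] != graph.n:
        raise ValueError(
            f"signals have {x.shape[0]} rows but the graph has {graph.n} nodes"
        )
    N = x.shape[1]
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(N)]
    J, Q = config.J, config.Q

    need_wavelets = "first" in config.orders or "second" in config.orders
    if need_wavelets:
        bank = build_wavelets(lazy_random_walk(graph), J)
        U1 = [np.abs(_stable_contract(psi, x)) for psi in bank.psi]

    blocks = {}
    if "zeroth" in config.orders:
        blocks["S0"] = _moments(x, Q)  # (N, Q)
    if "first" in config.orders:
        blocks["S1"] = np.stack([_moments(u, Q) for u in U1])  # (J, N, Q)
    if "second" in config.orders:
        s2 = [
            _moments(np.abs(_stable_contract(bank.psi[jp], U1[j])), Q)
            for j in range(J)
            for jp in range(j + 1, J)
        ]
        blocks["S2"] = np.stack(s2) if s2 else np.empty((0, N, Q))

    # assemble: channel outermost, then order, then scale(s), then q
    per_channel = []
    for c in range(N):
        parts = []
        if "S0" in blocks:
            parts.append(blocks["S0"][c])
        if "S1" in blocks:
            parts.append(blocks["S1"][:, c, :].ravel())
        if "S2" in blocks:
            parts.append(blocks["S2"][:, c, :].ravel())
        per_channel.append(np.concatenate(parts))
    vector = np.concatenate(per_channel) if per_channel else np.empty(0)

    names = feature_names(channel_names, config)
    assert vector.shape[0] == feature_length(N, J, Q, config.orders)
    return ScatteringFeatures(vector=vector, layout=names)
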