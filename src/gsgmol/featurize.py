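"""SMILES -> invariant feature matrix, as a scikit-learn transformer."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .attributes import (
    MoleculeSkipped,
    TypeVocabulary,
    assign_attributes,
    encode_signals,
    get_provider,
)
from .forcefields import AtomTypingError
from .graphs import SmilesParseError, parse_smiles
from .scattering import GSGConfig, feature_names, scattering_moments


class GSGFeaturizer(BaseEstimator, TransformerMixin):
    """Geometric-scattering featurizer over force-field atom attributes.

    Turns SMILES strings into fixed-length, permutation-invariant feature
    vectors: parse the molecular graph, assign per-atom force-field
    attributes (charge, LJ r and epsilon, one-hot atom type), and apply the
    graph scattering transform.  Stateless in the sklearn sense — ``fit``
    only freezes the vocabulary and feature layout — so it composes with
    :class:`~sklearn.pipeline.Pipeline`.

    Parameters
    ----------
    provider : str or provider object, default "mmff94"
        Atom-attribute provider id (mmff94 / uff / gaff / ghemical /
        fallback) or a provider instance.
    J : int, default 4
        Maximum wavelet scale.
    Q : int, default 4
        Moments per signal channel.
    orders : tuple of str, default ("zeroth", "first", "second")
        Scattering orders to include.
    add_hydrogens : bool, default True
        Include hydrogens as graph nodes.
    grouping : dict or None
        Optional atom-type -> group coarsening applied before one-hot.
    on_error : {"raise", "skip"}, default "raise"
        Whether transform raises on an untypeable/unparseable molecule or
        skips it (skips are reported in ``skipped_``).
    """

    def __init__(self, provider="mmff94", J=4, Q=4,
                 orders=("zeroth", "first", "second"),
                 add_hydrogens=True, grouping=None, on_error="raise"):
        self.provider = provider
        self.J = J
        self.Q = Q
        self.orders = orders
        self.add_hydrogens = add_hydrogens
        self.grouping = grouping
        self.on_error = on_error

    def _config(self) -> GSGConfig:
        return GSGConfig(J=self.J, Q=self.Q, orders=tuple(self.orders))

    def fit(self, X=None, y=None):
        config = self._config()
        prov = get_provider(self.provider)
        vocab = prov.vocabulary()
        if self.grouping is not None:
            vocab = TypeVocabulary(vocab.provider_name, vocab.labels,
                                   dict(self.grouping))
        self.vocabulary_ = vocab
        self.channel_names_ = None  # filled on first molecule
        dummy = ("charge", "lj_r", "lj_eps") + tuple(
            f"type:{l}" for l in vocab.effective_labels
        )
        self.feature_names_ = feature_names(dummy, config)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def featurize_one(self, smiles: str, mol_id=None) -> np.ndarray:
        """Feature vector of a single molecule (raises on failure)."""
        graph = parse_smiles(smiles, add_hydrogens=self.add_hydrogens)
        attrs = assign_attributes(graph, get_provider(self.provider),
                                  mol_id=mol_id)
        signals = encode_signals(attrs, self.vocabulary_)
        feats = scattering_moments(graph, signals.matrix, self._config(),
                                   channel_names=signals.channel_names)
        return feats.vector

    def transform(self, X) -> np.ndarray:
        """Featurize a sequence of SMILES strings.

        With ``on_error="skip"``, failed molecules are dropped from the
        output and recorded in ``skipped_`` (list of
        :class:`MoleculeSkipped`); ``kept_indices_`` maps output rows back
        to input positions.
        """
        if not hasattr(self, "vocabulary_"):
            self.fit()
        rows, skipped, kept = [], [], []
        provider_name = getattr(get_provider(self.provider), "name",
                                str(self.provider))
        for i, smi in enumerate(X):
            try:
                rows.append(self.featurize_one(smi, mol_id=i))
                kept.append(i)
            except (SmilesParseError, AtomTypingError, ValueError) as exc:
                if self.on_error == "raise":
                    raise
                skipped.append(MoleculeSkipped(smi, provider_name, str(exc)))
        self.skipped_ = skipped
        self.kept_indices_ = kept
        if not rows:
            return np.empty((0, self.n_features_out_))
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


def featurize_smiles(smiles_list, provider="mmff94", J=4, Q=4,
                     orders=("zeroth", "first", "second"),
                     add_hydrogens=True, on_error="skip"):
    """Thin functional wrapper: returns (DataFrame of features, skips)."""
    tr = GSGFeaturizer(provider=provider, J=J, Q=Q, orders=orders,
                       add_hydrogens=add_hydrogens, on_error=on_error).fit()
    mat = tr.transform(smiles_list)
    frame = pd.DataFrame(mat, columns=tr.feature_names_,
                         index=[smiles_list[i] for i in tr.kept_indices_])
    return frame, tr.skipped_
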