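"""End-to-end plumbing: curate -> featurize -> train -> predict.

A trained artifact is a bundle of (network weights, standardizer, the
featurizer settings it was trained under, and a vocabulary hash) so that
prediction can refuse inputs featurized under a different layout instead
of silently mispredicting.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .attributes import MoleculeSkipped
from .featurize import GSGFeaturizer
from .predictor import (
    LogPRegressor,
    grid_search_cv,
    load_model,
    save_model,
)


def vocabulary_hash(vocab) -> str:
    joined = "\x1f".join(vocab.effective_labels)
    return hashlib.sha256(joined.encode()).hexdigest()[:16]


@dataclass
class PredictionResult:
    mol_id: str
    smiles: str
    smiles_canonical: str | None
    logp_pred: float | None
    skipped_reason: str | None = None


def featurizer_metadata(featurizer: GSGFeaturizer) -> dict:
    return {
        "provider": getattr(featurizer.provider, "name",
                            str(featurizer.provider)),
        "gsg_config": {"J": featurizer.J, "Q": featurizer.Q,
                       "orders": list(featurizer.orders)},
        "add_hydrogens": featurizer.add_hydrogens,
        "vocabulary_hash": vocabulary_hash(featurizer.vocabulary_),
        "feature_layout": list(featurizer.feature_names_),
    }


def train_on_records(records, provider="mmff94", J=4, Q=4,
                     orders=("zeroth", "first", "second"),
                     grid=None, seed=0, **fit_params):
    """Featurize (smiles, logp) records and train a predictor.

    ``grid=None`` trains a single model with ``fit_params``; otherwise a
    grid-search with 5-fold CV picks the hyperparameters.  Returns
    (model, featurizer, skipped molecules, cv table or None).
    """
    smiles = [s for s, _ in records]
    y_all = np.asarray([v for _, v in records], dtype=float)
    featurizer = GSGFeaturizer(provider=provider, J=J, Q=Q, orders=orders,
                               on_error="skip").fit()
    X = featurizer.transform(smiles)
    y = y_all[featurizer.kept_indices_]
    skipped = featurizer.skipped_
    if grid is None:
        model = LogPRegressor(random_state=seed, **fit_params).fit(X, y)
        table = None
    else:
        model, _, table = grid_search_cv(X, y, param_grid=grid,
                                         random_state=seed, **fit_params)
    return model, featurizer, skipped, table


def predict_molecules(model: LogPRegressor, featurizer: GSGFeaturizer,
                      smiles_list, mol_ids=None) -> list[PredictionResult]:
    """Point predictions per molecule; failures become skip records.

    Order is preserved: one :class:`PredictionResult` per input, with
    either a prediction or a reason.
    """
    if mol_ids is None:
        mol_ids = [f"mol{i}" for i in range(len(smiles_list))]
    if featurizer.n_features_out_ != model.n_features_in_:
        raise ValueError(
            f"feature layout mismatch: featurizer emits "
            f"{featurizer.n_features_out_} features, model expects "
            f"{model.n_features_in_}"
        )
    from .graphs import canonical_smiles

    results = []
    for mol_id, smi in zip(mol_ids, smiles_list):
        try:
            vec = featurizer.featurize_one(smi, mol_id=mol_id)
            pred = float(model.predict(vec[None, :])[0])
            results.append(PredictionResult(
                mol_id, smi, canonical_smiles(smi), pred))
        except Exception as exc:
            results.append(PredictionResult(
                mol_id, smi, None, None, skipped_reason=str(exc)))
    return results


def save_bundle(path, model, featurizer, extra=None) -> None:
    meta = featurizer_metadata(featurizer)
    if extra:
        meta.update(extra)
    save_model(model, path, metadata=meta)


def load_bundle(path):
    """Returns (model, featurizer rebuilt from metadata, metadata)."""
    model, meta = load_model(path)
    featurizer = GSGFeaturizer(
        provider=meta["provider"],
        J=meta["gsg_config"]["J"],
        Q=meta["gsg_config"]["Q"],
        orders=tuple(meta["gsg_config"]["orders"]),
        add_hydrogens=meta["add_hydrogens"],
    ).fit()
    if vocabulary_hash(featurizer.vocabulary_) != meta["vocabulary_hash"]:
        raise ValueError(
            "vocabulary hash mismatch: the provider's type vocabulary "
            "differs from the one the model was trained with"
        )
    return model, featurizer, meta
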