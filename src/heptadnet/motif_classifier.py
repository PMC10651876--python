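"""Motif-grammar classification of cell-type-specific regulatory elements.

Regions are featurized as double-strand consensus-motif counts, min-max
normalized to [0, 1] per motif (normalization constants frozen at training
time and reused, with clipping, when scoring new regions). A gradient-boosted
tree ensemble (one binary model per cell type, target vs background) is
trained on a stratified split; performance is reported as held-out ROC/AUROC.
Per-motif attribution uses the exact tree-path additive decomposition
(TreeSHAP): per region, motif contributions plus the base value reconstruct
the model margin to numerical tolerance.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import train_test_split

from .core_intervals import IntervalSet
from .peak_annotation import ConsensusMotif, count_matches

__all__ = [
    "MotifFeatureTable",
    "TrainedModel",
    "AttributionTable",
    "featurize",
    "featurize_sequences",
    "train",
    "attribute",
    "score_regions",
    "score_cohort",
]

DEFAULT_HYPERPARAMS = {
    "max_depth": 4,
    "n_estimators": 200,
    "learning_rate": 0.1,
    "early_stopping_rounds": 20,
}


@dataclass
class MotifFeatureTable:
    """Regions x motifs table of min-max-normalized counts in [0, 1]."""

    raw_counts: pd.DataFrame
    norm_min: pd.Series
    norm_max: pd.Series
    label: str = ""

    @property
    def motif_names(self) -> list[str]:
        return list(self.raw_counts.columns)

    @property
    def normalized(self) -> pd.DataFrame:
        span = (self.norm_max - self.norm_min).replace(0, np.nan)
        out = (self.raw_counts - self.norm_min) / span
        return out.fillna(0.0).clip(0.0, 1.0)  # constant columns map to 0

    @classmethod
    def from_counts(cls, counts: pd.DataFrame, label: str = "") -> "MotifFeatureTable":
        return cls(counts, counts.min(axis=0), counts.max(axis=0), label)

    def renormalized_like(self, other: "MotifFeatureTable") -> "MotifFeatureTable":
        """Re-express these counts with *other*'s frozen normalization."""
        if list(self.raw_counts.columns) != list(other.raw_counts.columns):
            raise ValueError("feature schema mismatch")
        return MotifFeatureTable(self.raw_counts, other.norm_min, other.norm_max, self.label)


@dataclass
class TrainedModel:
    booster: xgb.Booster
    motif_names: list[str]
    norm_min: pd.Series
    norm_max: pd.Series
    hyperparams: dict
    split_fraction: float
    seed: int
    label: str = ""

    def predict_proba(self, normalized: pd.DataFrame) -> np.ndarray:
        if list(normalized.columns) != self.motif_names:
            raise ValueError("feature schema mismatch")
        dm = xgb.DMatrix(normalized.to_numpy(), feature_names=self.motif_names)
        return self.booster.predict(dm)

    def save(self, path: str | Path) -> None:
        bundle = {
            "format_version": 1,
            "label": self.label,
            "motif_names": self.motif_names,
            "norm_min": self.norm_min.tolist(),
            "norm_max": self.norm_max.tolist(),
            "hyperparams": self.hyperparams,
            "split_fraction": self.split_fraction,
            "seed": self.seed,
            "booster": self.booster.save_raw("json").decode(),
        }
        Path(path).write_text(json.dumps(bundle))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        bundle = json.loads(Path(path).read_text())
        booster = xgb.Booster()
        booster.load_model(bytearray(bundle["booster"].encode()))
        return cls(
            booster,
            bundle["motif_names"],
            pd.Series(bundle["norm_min"], index=bundle["motif_names"]),
            pd.Series(bundle["norm_max"], index=bundle["motif_names"]),
            bundle["hyperparams"],
            bundle["split_fraction"],
            bundle["seed"],
            bundle["label"],
        )


@dataclass
class AttributionTable:
    """Signed per-region, per-motif additive contributions to the margin."""

    contributions: pd.DataFrame  # regions x motifs
    base_value: float
    margins: np.ndarray

    def ranking(self) -> pd.DataFrame:
        mean_abs = self.contributions.abs().mean(axis=0).sort_values(ascending=False)
        return pd.DataFrame(
            {
                "motif": mean_abs.index,
                "mean_abs_contribution": mean_abs.to_numpy(),
                "mean_contribution": self.contributions.mean(axis=0).reindex(mean_abs.index).to_numpy(),
                "rank": np.arange(1, len(mean_abs) + 1),
            }
        ).reset_index(drop=True)

    def top(self, n: int = 12) -> pd.DataFrame:
        return self.ranking().head(n)


def featurize_sequences(
    sequences: list[str], motif_library: list[ConsensusMotif], label: str = ""
) -> MotifFeatureTable:
    if not sequences:
        raise ValueError("empty region set")
    if not motif_library:
        raise ValueError("empty motif library")
    counts = pd.DataFrame(
        {m.name: [count_matches(seq, m) for seq in sequences] for m in motif_library},
        dtype=float,
    )
    return MotifFeatureTable.from_counts(counts, label)


def featurize(
    regions: IntervalSet, genome, motif_library: list[ConsensusMotif], label: str = ""
) -> MotifFeatureTable:
    """Double-strand motif counts per region, min-max normalized per motif."""
    if len(regions) == 0:
        raise ValueError("empty region set")
    seqs = [
        str(genome[regions.chroms[i]][int(regions.starts[i]) : int(regions.ends[i])])
        for i in range(len(regions))
    ]
    return featurize_sequences(seqs, motif_library, label)


def train(
    table: MotifFeatureTable,
    background: MotifFeatureTable,
    split_fraction: float = 0.25,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> tuple[TrainedModel, pd.DataFrame, float]:
    """Train target-vs-background boosted trees; report held-out ROC/AUROC.

    Normalization constants are fitted on the pooled training table and
    frozen into the model. Deterministic given the seed (single-threaded
    histogram trees).
    """
    if len(table.raw_counts) == 0 or len(background.raw_counts) == 0:
        raise ValueError("both classes must be non-empty")
    if list(table.raw_counts.columns) != list(background.raw_counts.columns):
        raise ValueError("feature schema mismatch between classes")
    hp = dict(DEFAULT_HYPERPARAMS, **(hyperparams or {}))

    counts = pd.concat([table.raw_counts, background.raw_counts], ignore_index=True)
    pooled = MotifFeatureTable.from_counts(counts, table.label)
    X = pooled.normalized.to_numpy()
    y = np.concatenate([np.ones(len(table.raw_counts)), np.zeros(len(background.raw_counts))])

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=split_fraction, random_state=seed, stratify=y
    )
    X_fit, X_val, y_fit, y_val = train_test_split(
        X_tr, y_tr, test_size=0.2, random_state=seed, stratify=y_tr
    )
    params = {
        "objective": "binary:logistic",
        "max_depth": hp["max_depth"],
        "eta": hp["learning_rate"],
        "tree_method": "hist",
        "nthread": 1,
        "seed": seed,
        "eval_metric": "logloss",
    }
    names = pooled.motif_names
    dfit = xgb.DMatrix(X_fit, label=y_fit, feature_names=names)
    dval = xgb.DMatrix(X_val, label=y_val, feature_names=names)
    booster = xgb.train(
        params,
        dfit,
        num_boost_round=hp["n_estimators"],
        evals=[(dval, "val")],
        early_stopping_rounds=hp["early_stopping_rounds"],
        verbose_eval=False,
    )
    model = TrainedModel(
        booster, names, pooled.norm_min, pooled.norm_max, hp, split_fraction, seed, table.label
    )
    probs = booster.predict(xgb.DMatrix(X_te, feature_names=names))
    fpr, tpr, thresholds = roc_curve(y_te, probs)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return model, roc, float(auc(fpr, tpr))


def attribute(model: TrainedModel, table: MotifFeatureTable) -> AttributionTable:
    """Exact tree-path additive attribution (TreeSHAP) per region per motif."""
    normalized = table.renormalized_like(
        MotifFeatureTable(table.raw_counts, model.norm_min, model.norm_max)
    ).normalized
    if list(normalized.columns) != model.motif_names:
        raise ValueError("feature schema mismatch")
    dm = xgb.DMatrix(normalized.to_numpy(), feature_names=model.motif_names)
    contribs = model.booster.predict(dm, pred_contribs=True)
    margins = model.booster.predict(dm, output_margin=True)
    base = float(np.mean(contribs[:, -1]))
    return AttributionTable(
        pd.DataFrame(contribs[:, :-1], columns=model.motif_names), base, np.asarray(margins)
    )


def score_regions(
    model: TrainedModel, regions: IntervalSet | list[str], genome=None,
    motif_library: list[ConsensusMotif] | None = None,
) -> np.ndarray:
    """Per-region class probability for new regions under a trained model.

    Counts are normalized with the model's frozen constants and clipped to
    [0, 1]. ``regions`` may be an IntervalSet (with ``genome``) or raw
    sequences.
    """
    if motif_library is None:
        raise ValueError("motif_library required to featurize new regions")
    if isinstance(regions, IntervalSet):
        if genome is None:
            raise ValueError("genome required for IntervalSet input")
        table = featurize(regions, genome, motif_library)
    else:
        if len(regions) == 0:
            raise ValueError("empty cohort")
        table = featurize_sequences(list(regions), motif_library)
    if model.norm_min is None or model.norm_max is None:
        raise ValueError("model missing normalization constants")
    normalized = MotifFeatureTable(
        table.raw_counts, model.norm_min, model.norm_max
    ).normalized
    return model.predict_proba(normalized)


def score_cohort(
    models: dict[str, TrainedModel],
    regions: IntervalSet | list[str],
    genome=None,
    motif_library: list[ConsensusMotif] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Score one cohort under several cell-type models; the cohort call is
    the model with the highest median probability."""
    if not models:
        raise ValueError("no models supplied")
    probs = {
        cell: score_regions(m, regions, genome, motif_library) for cell, m in models.items()
    }
    table = pd.DataFrame(probs)
    call = table.median(axis=0).idxmax()
    return table, str(call)
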