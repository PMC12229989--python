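"""Evaluation metrics and experiment drivers.

AUC (pairwise concordance with half-weight ties), AUPR (step/rectangle
precision-recall area, i.e. average precision) and the Pearson
correlation coefficient, with the degenerate-input contracts the
experiment drivers rely on.  The drivers run five-fold cross-validation
over provided fold assignments (never re-splitting) and
leave-one-molecule-out evaluation over alleles passing the
>40-observations / >=3-binders eligibility filter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .errors import DegenerateInput, DegenerateLabels, NotEnoughAlleles, ShapeError
from .model import HypergraphBindingPredictor, dataset_to_xy
from .seq_io import Dataset, filter_lomo_alleles, split_folds, split_lomo


def _check_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if s.shape != y.shape:
        raise ShapeError(f"scores {s.shape} vs labels {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise DegenerateLabels("labels must be binary")
    return s, y


def auc(scores, labels) -> float:
    """Area under the ROC curve — the fraction of (positive, negative)
    pairs ranked concordantly, ties counting one half."""
    s, y = _check_scores_labels(scores, labels)
    if len(np.unique(y)) < 2:
        raise DegenerateLabels("AUC needs both classes present")
    return float(roc_auc_score(y, s))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve via a descending-score
    sweep with step (rectangle) interpolation."""
    s, y = _check_scores_labels(scores, labels)
    if y.sum() == 0:
        raise DegenerateLabels("AUPR needs at least one positive")
    return float(average_precision_score(y, s))


def pcc(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    a = np.asarray(x, dtype=float).ravel()
    b = np.asarray(y, dtype=float).ravel()
    if a.shape != b.shape:
        raise ShapeError(f"x {a.shape} vs y {b.shape}")
    if a.size < 2:
        raise DegenerateInput("PCC needs n >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInput("PCC undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# experiment drivers


@dataclass
class EvalResult:
    """Aggregate metrics with per-unit (fold or allele) breakdown."""

    auc: float
    aupr: float
    pcc: float
    auc_sd: float = float("nan")
    aupr_sd: float = float("nan")
    pcc_sd: float = float("nan")
    per_unit: dict = field(default_factory=dict)
    pooled: dict = field(default_factory=dict)
    n_used: int = 0
    n_rejected: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "auc": self.auc,
            "aupr": self.aupr,
            "pcc": self.pcc,
            "auc_sd": self.auc_sd,
            "aupr_sd": self.aupr_sd,
            "pcc_sd": self.pcc_sd,
            "per_unit": self.per_unit,
            "pooled": self.pooled,
            "n_used": self.n_used,
            "n_rejected": self.n_rejected,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _evaluate_split(model: HypergraphBindingPredictor, test: Dataset) -> dict:
    X, y = dataset_to_xy(test)
    labels, affinity = y[:, 0], y[:, 1]
    # derive labels where only affinity was recorded
    missing = np.isnan(labels) & ~np.isnan(affinity)
    labels = labels.copy()
    labels[missing] = affinity[missing] > model.threshold
    proba = model.predict_proba(X, on_reject="nan")[:, 1]
    pred_aff = model.predict_affinity(X, on_reject="nan")
    ok = ~np.isnan(proba)
    out = {"n_test": int(len(X)), "n_rejected_test": int((~ok).sum())}
    lab_ok = ok & ~np.isnan(labels)
    aff_ok = ok & ~np.isnan(affinity)
    out["auc"] = auc(proba[lab_ok], labels[lab_ok]) if len(np.unique(labels[lab_ok])) == 2 else float("nan")
    out["aupr"] = aupr(proba[lab_ok], labels[lab_ok]) if labels[lab_ok].sum() > 0 else float("nan")
    if aff_ok.sum() >= 2 and np.ptp(affinity[aff_ok]) > 0 and np.ptp(pred_aff[aff_ok]) > 0:
        out["pcc"] = pcc(pred_aff[aff_ok], affinity[aff_ok])
    else:
        out["pcc"] = float("nan")
    out["_pooled"] = (proba, pred_aff, labels, affinity, ok)
    return out


def _aggregate(per_unit: dict, n_used: int, n_rejected: int) -> EvalResult:
    pooled_parts = [u.pop("_pooled") for u in per_unit.values()]
    proba = np.concatenate([p[0] for p in pooled_parts])
    pred_aff = np.concatenate([p[1] for p in pooled_parts])
    labels = np.concatenate([p[2] for p in pooled_parts])
    affinity = np.concatenate([p[3] for p in pooled_parts])
    ok = np.concatenate([p[4] for p in pooled_parts])
    lab_ok = ok & ~np.isnan(labels)
    aff_ok = ok & ~np.isnan(affinity)
    pooled = {
        "auc": auc(proba[lab_ok], labels[lab_ok]),
        "aupr": aupr(proba[lab_ok], labels[lab_ok]),
        "pcc": pcc(pred_aff[aff_ok], affinity[aff_ok]),
    }

    def mean_sd(key: str) -> tuple[float, float]:
        vals = np.array([u[key] for u in per_unit.values()], dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            return float("nan"), float("nan")
        return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    a, a_sd = mean_sd("auc")
    p, p_sd = mean_sd("aupr")
    c, c_sd = mean_sd("pcc")
    return EvalResult(
        auc=a, aupr=p, pcc=c, auc_sd=a_sd, aupr_sd=p_sd, pcc_sd=c_sd,
        per_unit=per_unit, pooled=pooled, n_used=n_used, n_rejected=n_rejected,
    )


def run_cv(dataset: Dataset, backend=None, **model_params) -> EvalResult:
    """K-fold cross-validation honoring the fold ids carried by the
    records (the redundancy-reduced split is an input, never recomputed
    here).  Metrics are computed per fold and averaged; pooled
    predictions are reported alongside."""
    folds = split_folds(dataset)  # raises MissingFolds
    per_unit: dict = {}
    n_used = n_rejected = 0
    for fold_id, test in folds.items():
        train_recs = [r for f, d in folds.items() if f != fold_id for r in d.records]
        train_ds = dataset.subset(train_recs)
        model = HypergraphBindingPredictor(backend=backend, **model_params)
        Xtr, ytr = dataset_to_xy(train_ds)
        model.fit(Xtr, ytr)
        n_used += model.n_used_
        n_rejected += model.n_rejected_
        res = _evaluate_split(model, test)
        n_rejected += res["n_rejected_test"]
        n_used += res["n_test"] - res["n_rejected_test"]
        per_unit[f"fold{fold_id}"] = res
    return _aggregate(per_unit, n_used, n_rejected)


def run_lomo(
    dataset: Dataset,
    backend=None,
    min_obs: int = 40,
    min_binders: int = 3,
    **model_params,
) -> EvalResult:
    """Leave-one-molecule-out: one train/test cycle per eligible
    allele, reported per allele (sorted names) plus mean +/- sd."""
    eligible = filter_lomo_alleles(dataset, min_obs=min_obs, min_binders=min_binders)
    if len(eligible) < 2:
        raise NotEnoughAlleles(
            f"only {len(eligible)} allele(s) pass the LOMO filter; need >= 2"
        )
    per_unit: dict = {}
    n_used = n_rejected = 0
    for allele in eligible:
        train_ds, test_ds = split_lomo(dataset, allele)
        model = HypergraphBindingPredictor(backend=backend, **model_params)
        Xtr, ytr = dataset_to_xy(train_ds)
        model.fit(Xtr, ytr)
        n_used += model.n_used_
        n_rejected += model.n_rejected_
        res = _evaluate_split(model, test_ds)
        n_rejected += res["n_rejected_test"]
        n_used += res["n_test"] - res["n_rejected_test"]
        per_unit[allele] = res
    return _aggregate(per_unit, n_used, n_rejected)


__all__ = ["auc", "aupr", "pcc", "EvalResult", "run_cv", "run_lomo"]
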