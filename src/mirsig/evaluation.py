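"""Scoring fixed signatures and diagnostic evaluation against CA19-9.

AUC uses the Mann-Whitney identity (ties counted 1/2). Paired AUC
comparison and confidence intervals on fixed sets use DeLong placement
values; cross-validation-based CIs (a different estimator) live in the
signature-search stage. Subgroup AUCs compare each case subgroup against
the full healthy control set. Group differences use the classical
equal-variance unpaired t-test on the linear or log2 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import DataError, NormalizedMatrix

CA199_CUTOFF = 37.0  # U/mL, clinical positivity threshold
CA199_STRATA = ((0.0, 15.0), (15.0, 37.0), (37.0, np.inf))


@dataclass
class FixedSignature:
    """A fixed linear discriminant: score = sum w_i x_i + constant,
    positive (case call) iff score > cutoff."""

    mirnas: list
    weights: list
    constant: float
    cutoff: float = 0.0

    def __post_init__(self) -> None:
        if len(self.mirnas) != len(self.weights):
            raise DataError("weights and miRNAs must have equal length")


def compute_index(signature: FixedSignature, normalized) -> pd.Series:
    """Per-sample signature score from a NormalizedMatrix or a miRNA x
    sample expression frame."""
    values = normalized.values if isinstance(normalized, NormalizedMatrix) else normalized
    missing = [m for m in signature.mirnas if m not in values.index]
    if missing:
        raise DataError(f"signature miRNA(s) absent from the matrix: {missing}")
    X = values.loc[signature.mirnas].to_numpy(dtype=float)
    scores = np.asarray(signature.weights, dtype=float) @ X + signature.constant
    return pd.Series(scores, index=values.columns, name="index_score")


def roc_auc(scores, labels):
    """(AUC, ROC points) with AUC by midrank Mann-Whitney."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("both classes required for ROC analysis")
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    # ROC step points at every distinct threshold, descending
    order = np.argsort(-s, kind="mergesort")
    ys = y[order]
    tps = np.cumsum(ys == 1)
    fps = np.cumsum(ys == 0)
    distinct = np.r_[np.flatnonzero(np.diff(s[order])), len(s) - 1]
    tpr = np.r_[0.0, tps[distinct] / n1]
    fpr = np.r_[0.0, fps[distinct] / n0]
    return float(auc), pd.DataFrame({"fpr": fpr, "tpr": tpr})


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, y: np.ndarray):
    """Placement values (cases, controls) and AUC for one score vector."""
    cases, controls = scores[y == 1], scores[y == 0]
    n1, n0 = len(cases), len(controls)
    tz = _midrank(np.r_[cases, controls])
    tx = _midrank(cases)
    ty = _midrank(controls)
    v10 = (tz[:n1] - tx) / n0  # per-case placement
    v01 = 1.0 - (tz[n1:] - ty) / n1  # per-control placement
    auc = v10.mean()
    return v10, v01, float(auc)


def delong_ci(scores, labels, level: float = 0.95):
    """AUC and DeLong normal-approximation CI, clipped to [0, 1]."""
    y = np.asarray(labels)
    v10, v01, auc = _delong_placements(np.asarray(scores, dtype=float), y)
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return auc, (float(np.clip(auc - half, 0, 1)), float(np.clip(auc + half, 0, 1)))


def compare_auc(scores_a, scores_b, labels) -> dict:
    """Paired DeLong comparison of two score vectors on the same samples."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if a.shape != b.shape or a.shape[0] != y.shape[0]:
        raise DataError("paired comparison requires equal-length score vectors")
    va10, va01, auc_a = _delong_placements(a, y)
    vb10, vb01, auc_b = _delong_placements(b, y)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    S = s10 / len(va10) + s01 / len(va01)
    var_diff = S[0, 0] + S[1, 1] - 2.0 * S[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(2.0 * stats.norm.sf(abs(diff) / np.sqrt(var_diff)))
    z = stats.norm.ppf(0.975)
    ci = lambda auc, v: (float(np.clip(auc - z * np.sqrt(v), 0, 1)), float(np.clip(auc + z * np.sqrt(v), 0, 1)))
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "auc_difference": float(diff),
        "p_value": p,
        "ci_a": ci(auc_a, S[0, 0]),
        "ci_b": ci(auc_b, S[1, 1]),
    }


def classification_table(
    index_scores: pd.Series,
    ca199_linear: pd.Series,
    labels: pd.Series,
    index_cutoff: float = 0.0,
    ca199_cutoff: float = CA199_CUTOFF,
):
    """Sensitivity/specificity for the signature, CA19-9, and the combined
    rule (signature > 0 OR CA19-9 >= 37 U/mL). Samples missing CA19-9 are
    excluded and counted."""
    df = pd.DataFrame({"index": index_scores, "ca199": ca199_linear, "y": labels})
    n_excluded = int(df["ca199"].isna().sum())
    df = df.dropna(subset=["ca199"])
    calls = {
        "index": df["index"] > index_cutoff,
        "ca199": df["ca199"] >= ca199_cutoff,
    }
    calls["combined"] = calls["index"] | calls["ca199"]
    rows = {}
    for name, pos in calls.items():
        y = df["y"] == 1
        tp, fn = int((pos & y).sum()), int((~pos & y).sum())
        fp, tn = int((pos & ~y).sum()), int((~pos & ~y).sum())
        rows[name] = {
            "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
            "specificity": tn / (tn + fp) if tn + fp else np.nan,
            "tp": tp,
            "fn": fn,
            "fp": fp,
            "tn": tn,
        }
    table = pd.DataFrame(rows).T
    table.attrs["n_excluded_missing_ca199"] = n_excluded
    return table


def subgroup_analysis(scores: pd.Series, labels: pd.Series, metadata: pd.DataFrame, grouping: str) -> pd.DataFrame:
    """Per-subgroup AUC + DeLong CI: subgroup cases vs all controls.

    ``grouping`` is a metadata column (e.g. ``ct_score``) or
    ``"ca199_stratum"`` for the CA19-9 strata < 15 / 15-37 / >= 37 U/mL.
    """
    controls = labels.index[labels == 0]
    cases = labels.index[labels == 1]
    if grouping == "ca199_stratum":
        ca = metadata.loc[cases, "ca199_linear"]
        groups = {f"ca199 [{lo:g},{hi:g})": ca.index[(ca >= lo) & (ca < hi)] for lo, hi in CA199_STRATA}
    else:
        col = metadata.loc[cases, grouping]
        groups = {f"{grouping}={v}": col.index[col == v] for v in sorted(col.dropna().unique())}
    rows = []
    for name, members in groups.items():
        if len(members) == 0:
            rows.append({"subgroup": name, "n_cases": 0, "n_controls": len(controls), "auc": np.nan, "ci_low": np.nan, "ci_high": np.nan, "flag": "empty"})
            continue
        ids = list(members) + list(controls)
        y = np.r_[np.ones(len(members)), np.zeros(len(controls))]
        auc, (lo, hi) = delong_ci(scores.loc[ids].to_numpy(), y)
        rows.append({"subgroup": name, "n_cases": len(members), "n_controls": len(controls), "auc": auc, "ci_low": lo, "ci_high": hi, "flag": ""})
    return pd.DataFrame(rows)


def group_difference_test(values, groups, scale: str = "linear"):
    """Unpaired equal-variance two-tailed t-test on the chosen scale."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    uniq = np.unique(g)
    if len(uniq) != 2:
        raise DataError("exactly two groups required")
    a, b = v[g == uniq[0]], v[g == uniq[1]]
    if len(a) < 2 or len(b) < 2:
        raise DataError("both groups need n >= 2")
    if scale == "log2":
        if (v <= 0).any():
            raise DataError("log2 scale requires strictly positive values")
        a, b = np.log2(a), np.log2(b)
    elif scale != "linear":
        raise DataError("scale must be 'linear' or 'log2'")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        raise DataError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class EvaluationReport:
    """Bundle of the evaluation outputs for one signature on one set."""

    scores: pd.Series
    auc: float
    auc_ci: tuple
    classification: pd.DataFrame = field(default=None)
    subgroups: pd.DataFrame = field(default=None)


def evaluate_signature(signature: FixedSignature, normalized: NormalizedMatrix, subgroup_columns=()) -> EvaluationReport:
    """Score a fixed signature on a set and assemble the standard report."""
    scores = compute_index(signature, normalized)
    meta = normalized.metadata
    labels = meta["disease_score"]
    auc, ci = delong_ci(scores.to_numpy(), labels.to_numpy())
    table = None
    if "ca199_linear" in meta.columns:
        table = classification_table(scores, meta["ca199_linear"], labels, index_cutoff=signature.cutoff)
    sub = None
    if subgroup_columns:
        sub = pd.concat([subgroup_analysis(scores, labels, meta, g) for g in subgroup_columns], ignore_index=True)
    return EvaluationReport(scores=scores, auc=auc, auc_ci=ci, classification=table, subgroups=sub)
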