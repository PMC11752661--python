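"""Exhaustive Fisher-discriminant signature search.

Every subset of ``subset_size`` markers (default 5 of 16, 4368 subsets)
yields Fisher LDA weights ``w = S_pooled^-1 (mu_case - mu_control)`` and
three decision constants: the midpoint of the projected class means
(maximum-separation cut), and the nearest-rank constants guaranteeing 80%
training sensitivity or specificity — three discriminants per subset,
13,104 in the 5-of-16 search. Each subset is scored by 5-fold stratified
cross-validation repeated 10 times (50 held-out evaluations): weights and
constants are refit on each training 4/5, and held-out sensitivity,
specificity, and AUC are recorded along with the CA19-9 AUC on the same
fold. A discriminant is selected when mean sensitivity and specificity
exceed 80%, the lower bound of the AUC 95% CI (normal approximation over
the 50 fold AUCs) is at least 0.80, and the mean AUC beats CA19-9.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .dataio import DataError
from .evaluation import FixedSignature

CONSTANT_KINDS = ("max_separation", "sens80", "spec80")


@dataclass
class SearchConfig:
    subset_size: int = 5
    n_folds: int = 5
    n_repeats: int = 10
    seed: int = 0
    sens_threshold: float = 0.80
    spec_threshold: float = 0.80
    auc_ci_low_threshold: float = 0.80
    require_beat_ca199: bool = True
    reg_eps: float = 0.0  # ridge added to the pooled covariance if singular

    def __post_init__(self) -> None:
        if self.subset_size < 1 or self.n_folds < 2 or self.n_repeats < 1:
            raise ValueError("invalid search configuration")


def fisher_lda(X: np.ndarray, y: np.ndarray, reg_eps: float = 0.0) -> np.ndarray:
    """Fisher discriminant direction with unbiased pooled covariance.

    Scores ``w @ x`` have case mean above control mean by construction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    X1, X0 = X[y == 1], X[y == 0]
    d = X.shape[1]
    if len(X1) < d + 1 or len(X0) < d + 1:
        raise DataError("both classes need at least subset_size + 1 samples")
    dmu = X1.mean(axis=0) - X0.mean(axis=0)
    if np.allclose(dmu, 0):
        raise DataError("equal class means: degenerate Fisher discriminant")
    S = ((len(X1) - 1) * np.cov(X1, rowvar=False) + (len(X0) - 1) * np.cov(X0, rowvar=False)) / (
        len(X1) + len(X0) - 2
    )
    S = np.atleast_2d(S) + reg_eps * np.eye(d)
    try:
        w = np.linalg.solve(S, dmu)
    except np.linalg.LinAlgError as exc:
        raise DataError("singular pooled covariance; set reg_eps > 0 to regularize") from exc
    return w


def derive_constants(scores: np.ndarray, y: np.ndarray, sens_threshold: float = 0.80, spec_threshold: float = 0.80) -> dict:
    """Three decision constants; the discriminant is score - constant,
    positive means case.

    ``max_separation``: midpoint of projected class means. ``sens80``: the
    largest constant keeping training sensitivity >= the threshold
    (nearest-rank lower quantile of case scores). ``spec80``: the smallest
    constant reaching training specificity >= the threshold (nearest-rank
    upper quantile of control scores).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    cases, controls = np.sort(scores[y == 1]), np.sort(scores[y == 0])
    n1, n0 = len(cases), len(controls)
    if n1 < 5 or n0 < 5:
        raise DataError("derive_constants needs >= 5 samples per class")
    # sens80: largest observed value v with #(cases > v) >= ceil(0.8 n1);
    # ties at the cutpoint push v down so the training guarantee holds
    m_sens = int(np.ceil(sens_threshold * n1 - 1e-9))
    vals = np.unique(cases)
    n_greater = n1 - np.searchsorted(cases, vals, side="right")
    ok = vals[n_greater >= m_sens]
    c_sens = float(ok.max()) if ok.size else float(cases[0] - 1.0)
    # spec80: smallest value v with #(controls <= v) >= ceil(0.8 n0)
    m_spec = int(np.ceil(spec_threshold * n0 - 1e-9))
    cvals = np.unique(controls)
    n_leq = np.searchsorted(controls, cvals, side="right")
    c_spec = float(cvals[n_leq >= m_spec].min())
    return {
        "max_separation": float((cases.mean() + controls.mean()) / 2.0),
        "sens80": c_sens,
        "spec80": c_spec,
    }


def enumerate_candidates(markers, subset_size: int) -> list:
    """All marker subsets of the given size (each carries 3 discriminants)."""
    markers = list(markers)
    if subset_size > len(markers):
        raise DataError("subset_size exceeds the number of markers")
    return [tuple(c) for c in combinations(markers, subset_size)]


def n_discriminants(n_markers: int, subset_size: int) -> int:
    """Total discriminants: three constants per subset."""
    return 3 * comb(n_markers, subset_size)


def make_folds(y: pd.Series, config: SearchConfig) -> list:
    """The 50 stratified train/test splits (n_folds x n_repeats), a function
    of the seed and the (label, sample-id)-sorted order only."""
    yv = y.to_numpy()
    order = np.lexsort((y.index.to_numpy(), yv))
    rng = np.random.default_rng(config.seed)
    folds = []
    for _ in range(config.n_repeats):
        for _attempt in range(100):
            rs = int(rng.integers(0, 2**31 - 1))
            skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=rs)
            split = [(order[tr], order[te]) for tr, te in skf.split(np.zeros(len(y)), yv[order])]
            if all(len(np.unique(yv[te])) == 2 and len(np.unique(yv[tr])) == 2 for tr, te in split):
                folds.extend(split)
                break
        else:
            raise DataError("could not draw folds containing both classes")
    return folds


def _fold_scores(A, yv, ca, tr, te, idx, reg_eps, sens_t, spec_t):
    """Vectorized per-fold fit/score for a block of subsets (idx: K x m)."""
    Xtr, ytr = A[tr], yv[tr]
    X1, X0 = Xtr[ytr == 1], Xtr[ytr == 0]
    n1, n0 = len(X1), len(X0)
    S = ((n1 - 1) * np.cov(X1, rowvar=False) + (n0 - 1) * np.cov(X0, rowvar=False)) / (n1 + n0 - 2)
    dmu = X1.mean(axis=0) - X0.mean(axis=0)
    S_sub = S[idx[:, :, None], idx[:, None, :]] + reg_eps * np.eye(idx.shape[1])
    try:
        w = np.linalg.solve(S_sub, dmu[idx][..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise DataError("singular pooled covariance in a fold; set reg_eps > 0") from exc

    # nearest-rank constants; projected scores are continuous so the
    # tie-at-cutpoint adjustment of derive_constants cannot trigger here
    s_tr = np.einsum("nkm,km->nk", Xtr[:, idx], w)
    sc, sn = s_tr[ytr == 1], s_tr[ytr == 0]
    k = max(int(np.floor((1.0 - sens_t) * n1 + 1e-9)), 1)
    m = int(np.ceil(spec_t * n0 - 1e-9))
    consts = np.stack(
        [
            (sc.mean(axis=0) + sn.mean(axis=0)) / 2.0,
            np.partition(sc, k - 1, axis=0)[k - 1],
            np.partition(sn, m - 1, axis=0)[m - 1],
        ]
    )  # (3, K)

    s_te = np.einsum("nkm,km->nk", A[te][:, idx], w)
    yte = yv[te]
    case, ctrl = s_te[yte == 1], s_te[yte == 0]
    sens = (case[None, :, :] > consts[:, None, :]).mean(axis=1)  # (3, K)
    spec = (ctrl[None, :, :] <= consts[:, None, :]).mean(axis=1)

    ranks = rankdata(s_te, axis=0)
    nt1, nt0 = len(case), len(ctrl)
    auc = (ranks[yte == 1].sum(axis=0) - nt1 * (nt1 + 1) / 2.0) / (nt1 * nt0)

    ca_te = ca[te]
    ca_ranks = rankdata(ca_te)
    ca_auc = (ca_ranks[yte == 1].sum() - nt1 * (nt1 + 1) / 2.0) / (nt1 * nt0)
    return sens, spec, auc, ca_auc


def search_signatures(
    X: pd.DataFrame,
    y: pd.Series,
    ca199_linear: pd.Series,
    config: SearchConfig,
    markers=None,
    chunk: int = 2048,
) -> pd.DataFrame:
    """Cross-validate every subset x constant-kind discriminant.

    ``X``: sample x marker normalized expression; returns one row per
    discriminant with mean held-out sensitivity/specificity, AUC mean and
    95% CI, the matched CA19-9 AUC, and the selection flag.
    """
    markers = list(X.columns if markers is None else markers)
    subsets = enumerate_candidates(markers, config.subset_size)
    col_pos = {m: i for i, m in enumerate(X.columns)}
    idx_all = np.array([[col_pos[m] for m in s] for s in subsets])
    A = X.to_numpy(dtype=float)
    yv = y.loc[X.index].to_numpy()
    ca = ca199_linear.loc[X.index].to_numpy(dtype=float)
    folds = make_folds(y.loc[X.index], config)

    K = len(subsets)
    sens_sum = np.zeros((3, K))
    spec_sum = np.zeros((3, K))
    aucs = np.zeros((len(folds), K))
    ca_aucs = np.zeros(len(folds))
    for f, (tr, te) in enumerate(folds):
        for start in range(0, K, chunk):
            blk = slice(start, min(start + chunk, K))
            sens, spec, auc, ca_auc = _fold_scores(
                A, yv, ca, tr, te, idx_all[blk], config.reg_eps, config.sens_threshold, config.spec_threshold
            )
            sens_sum[:, blk] += sens
            spec_sum[:, blk] += spec
            aucs[f, blk] = auc
        ca_aucs[f] = ca_auc

    nf = len(folds)
    auc_mean = aucs.mean(axis=0)
    auc_half = 1.96 * aucs.std(axis=0, ddof=1) / np.sqrt(nf)
    ca_mean = float(ca_aucs.mean())

    rows = []
    for j, subset in enumerate(subsets):
        for c, kind in enumerate(CONSTANT_KINDS):
            rows.append(
                {
                    "mirnas": subset,
                    "constant_kind": kind,
                    "mean_sens": sens_sum[c, j] / nf,
                    "mean_spec": spec_sum[c, j] / nf,
                    "auc_mean": auc_mean[j],
                    "auc_ci_low": auc_mean[j] - auc_half[j],
                    "auc_ci_high": auc_mean[j] + auc_half[j],
                    "ca199_auc_mean": ca_mean,
                }
            )
    df = pd.DataFrame(rows)
    df["selected"] = _selection_mask(df, config)
    return df


def _selection_mask(df: pd.DataFrame, config: SearchConfig) -> pd.Series:
    mask = (
        (df["mean_sens"] > config.sens_threshold)
        & (df["mean_spec"] > config.spec_threshold)
        & (df["auc_ci_low"] >= config.auc_ci_low_threshold)
    )
    if config.require_beat_ca199:
        mask &= df["auc_mean"] > df["ca199_auc_mean"]
    return mask


def filter_by_criteria(df: pd.DataFrame, config: SearchConfig) -> pd.DataFrame:
    """Discriminants passing all selection criteria (may be empty)."""
    return df[_selection_mask(df, config)].reset_index(drop=True)


def crossvalidated_metrics(subset, X: pd.DataFrame, y: pd.Series, ca199_linear: pd.Series, config: SearchConfig) -> dict:
    """Reference (single-subset) cross-validation, fold by fold.

    Returns mean sensitivity/specificity per constant kind, AUC mean with
    95% CI over the 50 fold AUCs, and the CA19-9 AUC on the same folds.
    """
    cols = list(subset)
    A = X[cols].to_numpy(dtype=float)
    yv = y.loc[X.index].to_numpy()
    ca = ca199_linear.loc[X.index].to_numpy(dtype=float)
    folds = make_folds(y.loc[X.index], config)
    sens = {k: [] for k in CONSTANT_KINDS}
    spec = {k: [] for k in CONSTANT_KINDS}
    aucs, ca_aucs = [], []
    for tr, te in folds:
        w = fisher_lda(A[tr], yv[tr], reg_eps=config.reg_eps)
        consts = derive_constants(A[tr] @ w, yv[tr], config.sens_threshold, config.spec_threshold)
        s_te = A[te] @ w
        yte = yv[te]
        for kind in CONSTANT_KINDS:
            c = consts[kind]
            sens[kind].append(float((s_te[yte == 1] > c).mean()))
            spec[kind].append(float((s_te[yte == 0] <= c).mean()))
        ranks = rankdata(s_te)
        n1, n0 = int((yte == 1).sum()), int((yte == 0).sum())
        aucs.append(float((ranks[yte == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)))
        car = rankdata(ca[te])
        ca_aucs.append(float((car[yte == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)))
    aucs = np.asarray(aucs)
    half = 1.96 * aucs.std(ddof=1) / np.sqrt(len(aucs))
    return {
        "mean_sens": {k: float(np.mean(v)) for k, v in sens.items()},
        "mean_spec": {k: float(np.mean(v)) for k, v in spec.items()},
        "auc_mean": float(aucs.mean()),
        "auc_ci_low": float(aucs.mean() - half),
        "auc_ci_high": float(aucs.mean() + half),
        "ca199_auc_mean": float(np.mean(ca_aucs)),
        "n_folds_evaluated": len(folds),
    }


def variable_count_sweep(X: pd.DataFrame, y: pd.Series, ca199_linear: pd.Series, sizes, config: SearchConfig) -> pd.DataFrame:
    """Best-candidate metrics per subset size (e.g. 3..6 markers)."""
    rows = []
    for size in sizes:
        cfg = SearchConfig(
            subset_size=size,
            n_folds=config.n_folds,
            n_repeats=config.n_repeats,
            seed=config.seed,
            sens_threshold=config.sens_threshold,
            spec_threshold=config.spec_threshold,
            auc_ci_low_threshold=config.auc_ci_low_threshold,
            require_beat_ca199=config.require_beat_ca199,
            reg_eps=config.reg_eps,
        )
        df = search_signatures(X, y, ca199_linear, cfg)
        best = df.sort_values(["auc_mean", "mean_sens"], ascending=False).iloc[0]
        rows.append(
            {
                "subset_size": size,
                "best_auc_mean": best["auc_mean"],
                "best_auc_ci_low": best["auc_ci_low"],
                "best_mean_sens": best["mean_sens"],
                "best_mean_spec": best["mean_spec"],
                "n_selected": int(df["selected"].sum()),
            }
        )
    return pd.DataFrame(rows)


def fit_signature(X: pd.DataFrame, y: pd.Series, mirnas, constant_kind: str = "max_separation", config: SearchConfig | None = None) -> FixedSignature:
    """Refit weights and the chosen constant on the full set, yielding the
    fixed reporting discriminant (score = sum w_i x_i + constant, positive
    above the 0 cutoff)."""
    config = config or SearchConfig()
    cols = list(mirnas)
    A = X[cols].to_numpy(dtype=float)
    yv = y.loc[X.index].to_numpy()
    w = fisher_lda(A, yv, reg_eps=config.reg_eps)
    consts = derive_constants(A @ w, yv, config.sens_threshold, config.spec_threshold)
    return FixedSignature(mirnas=cols, weights=list(map(float, w)), constant=-consts[constant_kind])
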