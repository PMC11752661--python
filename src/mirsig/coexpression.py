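"""Weighted coexpression modules and module-trait analysis.

Implements the network stage from first principles: unsigned soft-threshold
adjacency ``a_ij = |cor(x_i, x_j)|^power``, topological overlap

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

average-linkage clustering of the TOM dissimilarity, and a dynamic tree cut
in the spirit of the hybrid algorithm: branches are split where the
dendrogram shows a merge-height gap (split sensitivity mapped from
``deep_split``), modules below the minimum size are dissolved, and leftover
miRNAs are assigned to the nearest module by average dissimilarity when
they are closer to it than to the background. Module eigengenes are the
sign-oriented first principal components of the standardized member
profiles; module-trait association uses Pearson correlation with two-sided
t-distribution p-values. A module is rejected as an artifact when it
correlates more strongly with the storage-time disturbance factor than with
any disease trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .dataio import DataError, NormalizedMatrix

#: dendrogram merge-height gap (TOM-dissimilarity units) required to split a
#: branch, by deep_split level; higher deep_split splits more finely
_GAP_BY_DEEPSPLIT = {0: 0.30, 1: 0.225, 2: 0.15, 3: 0.10, 4: 0.05}

#: traits that qualify a module as disease-related
DISEASE_TRAITS = ("disease_score", "log_cea", "log_ca199", "ct_score", "cn_score", "cm_score")
DISTURBANCE_TRAIT = "serum_storage_min"


@dataclass
class NetworkConfig:
    soft_power: int = 5
    min_module_size: int = 10
    deep_split: int = 3
    network_sign: str = "unsigned"

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be a positive integer")
        if self.deep_split not in _GAP_BY_DEEPSPLIT:
            raise ValueError("deep_split must be in 0..4")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValueError("network_sign must be 'unsigned' or 'signed'")


@dataclass
class ModuleSet:
    """Module assignment plus eigengenes and trait statistics."""

    assignment: pd.Series  # miRNA -> module label, 0 = unassigned
    eigengenes: pd.DataFrame = field(default=None)  # module x sample
    module_trait_r: pd.DataFrame = field(default=None)
    module_trait_p: pd.DataFrame = field(default=None)
    disease_flags: pd.Series = field(default=None)
    rejected_flags: pd.Series = field(default=None)

    @property
    def module_labels(self) -> list:
        return sorted(set(self.assignment) - {0})

    def members(self, label) -> list:
        return list(self.assignment.index[self.assignment == label])


def adjacency_tom(values: pd.DataFrame, config: NetworkConfig) -> pd.DataFrame:
    """TOM dissimilarity (1 - TOM) of the miRNA x sample expression block."""
    X = values.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise DataError("network construction requires >= 3 samples")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = values.index[sd == 0].tolist()
        raise DataError(f"constant miRNA row(s): {bad}")
    corr = np.corrcoef(X)
    if config.network_sign == "signed":
        adj = ((1.0 + corr) / 2.0) ** config.soft_power
    else:
        adj = np.abs(corr) ** config.soft_power
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    numerator = adj @ adj + adj
    denominator = np.minimum.outer(k, k) + 1.0 - adj
    tom = numerator / denominator
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(1.0 - tom, index=values.index, columns=values.index)


def _cut_tree(Z: np.ndarray, n: int, min_size: int, gap: float) -> np.ndarray:
    """Gap-based dynamic cut of a linkage matrix.

    A node is a *qualifying split* when the merge height exceeds the larger
    child's core height (0.9-quantile of the child's internal merge heights)
    by more than ``gap`` and at least one child could form a module. Modules
    are the maximal subtrees containing no qualifying split.
    """
    n_nodes = 2 * n - 1
    left = np.full(n_nodes, -1, dtype=int)
    right = np.full(n_nodes, -1, dtype=int)
    height = np.zeros(n_nodes)
    size = np.ones(n_nodes, dtype=int)
    heights_in_subtree: list = [None] * n_nodes
    for i in range(n):
        heights_in_subtree[i] = []
    pure = np.ones(n_nodes, dtype=bool)
    core = np.zeros(n_nodes)
    for i in range(n - 1):
        node = n + i
        a, b = int(Z[i, 0]), int(Z[i, 1])
        left[node], right[node] = a, b
        height[node] = Z[i, 2]
        size[node] = size[a] + size[b]
        heights_in_subtree[node] = heights_in_subtree[a] + heights_in_subtree[b] + [Z[i, 2]]
        hs = heights_in_subtree[node]
        core[node] = float(np.quantile(hs, 0.9)) if hs else 0.0
        child_core = max(core[a], core[b])
        qualifying = (height[node] - child_core > gap) and (max(size[a], size[b]) >= min_size)
        pure[node] = pure[a] and pure[b] and not qualifying
    # maximal pure subtrees of sufficient size become modules
    labels = np.zeros(n, dtype=int)
    root = n_nodes - 1
    stack = [root]
    module_roots = []
    while stack:
        node = stack.pop()
        if pure[node]:
            if size[node] >= min_size:
                module_roots.append(node)
            continue
        stack.extend([left[node], right[node]])
    # stable labels: order modules by decreasing size, ties by smallest leaf
    def _leaves(node):
        out, st = [], [node]
        while st:
            v = st.pop()
            if v < n:
                out.append(v)
            else:
                st.extend([left[v], right[v]])
        return sorted(out)

    roots = sorted(module_roots, key=lambda v: (-size[v], _leaves(v)[0]))
    for label, node in enumerate(roots, start=1):
        labels[_leaves(node)] = label
    return labels


def detect_modules(dissimilarity: pd.DataFrame, config: NetworkConfig) -> pd.Series:
    """Average-linkage dendrogram + dynamic gap cut + nearest-module
    assignment of leftover miRNAs. Label 0 marks unassigned miRNAs."""
    D = dissimilarity.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise DataError("dissimilarity must be square symmetric with zero diagonal")
    n = D.shape[0]
    if n < config.min_module_size:
        warnings.warn("fewer miRNAs than min_module_size; all unassigned", stacklevel=2)
        return pd.Series(0, index=dissimilarity.index, name="module")
    Z = linkage(squareform(D, checks=False), method="average")
    labels = _cut_tree(Z, n, config.min_module_size, _GAP_BY_DEEPSPLIT[config.deep_split])
    if labels.max() == 0:
        warnings.warn("no module satisfied the minimum size; all unassigned", stacklevel=2)
        return pd.Series(labels, index=dissimilarity.index, name="module")
    # nearest-module assignment for leftover points, when closer to the
    # module than to the background average
    background = D[np.triu_indices(n, k=1)].mean()
    for i in np.flatnonzero(labels == 0):
        avg = {m: D[i, labels == m].mean() for m in range(1, labels.max() + 1)}
        best = min(avg, key=lambda m: (avg[m], m))
        if avg[best] < background:
            labels[i] = best
    return pd.Series(labels, index=dissimilarity.index, name="module")


def module_eigengenes(values: pd.DataFrame, assignment: pd.Series) -> pd.DataFrame:
    """First principal component (unit-variance scores) of each module's
    standardized expression, oriented to correlate positively with its
    members on average."""
    sample_ids = values.columns
    rows = {}
    for label in sorted(set(assignment) - {0}):
        members = assignment.index[assignment == label]
        X = values.loc[members].to_numpy(dtype=float)
        sd = X.std(axis=1, ddof=0)
        if (sd == 0).any():
            raise DataError(f"constant member profile in module {label}")
        Xs = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
        # PC1 of samples x members
        _, _, vt = np.linalg.svd(Xs.T - Xs.T.mean(axis=0, keepdims=True), full_matrices=False)
        scores = (Xs.T - Xs.T.mean(axis=0, keepdims=True)) @ vt[0]
        scores = scores / scores.std(ddof=0)
        mean_corr = np.mean([np.corrcoef(scores, row)[0, 1] for row in Xs])
        if mean_corr < 0:
            scores = -scores
        rows[label] = scores
    eig = pd.DataFrame(rows, index=sample_ids).T
    eig.index.name = "module"
    return eig


def module_trait_relationships(eigengenes: pd.DataFrame, traits: pd.DataFrame):
    """Pearson r and two-sided p for each module eigengene against each
    trait, pairwise-dropping missing trait values."""
    r = pd.DataFrame(index=eigengenes.index, columns=traits.columns, dtype=float)
    p = pd.DataFrame(index=eigengenes.index, columns=traits.columns, dtype=float)
    for trait in traits.columns:
        tv = traits[trait].astype(float)
        mask = tv.notna()
        n = int(mask.sum())
        if n < 3:
            raise DataError(f"trait {trait!r} has fewer than 3 complete pairs")
        tvals = tv[mask].to_numpy()
        if np.std(tvals) == 0:
            r[trait] = 0.0
            p[trait] = 1.0
            continue
        for label in eigengenes.index:
            e = eigengenes.loc[label, mask.index[mask]].to_numpy(dtype=float)
            rr = float(np.corrcoef(e, tvals)[0, 1])
            rr = float(np.clip(rr, -1.0, 1.0))
            if abs(rr) == 1.0:
                pp = 0.0
            else:
                tstat = rr * np.sqrt((n - 2) / (1.0 - rr**2))
                pp = 2.0 * t_dist.sf(abs(tstat), df=n - 2)
            r.loc[label, trait] = rr
            p.loc[label, trait] = pp
    return r, p


def build_trait_matrix(metadata: pd.DataFrame) -> pd.DataFrame:
    """Clinical trait columns used for module-trait analysis."""
    cols = list(DISEASE_TRAITS) + [DISTURBANCE_TRAIT, "platelet_count"]
    present = [c for c in cols if c in metadata.columns]
    return metadata[present].astype(float)


def select_disease_mirnas(module_set: ModuleSet, alpha: float = 0.05) -> list:
    """Disease-related miRNAs: members of modules significantly associated
    with at least one disease trait, excluding modules rejected for stronger
    association with the storage-time disturbance factor."""
    r, p = module_set.module_trait_r, module_set.module_trait_p
    disease_cols = [c for c in DISEASE_TRAITS if c in r.columns]
    if not disease_cols or DISTURBANCE_TRAIT not in r.columns:
        raise DataError("trait table must include disease traits and the disturbance trait")
    rejected = (p[DISTURBANCE_TRAIT] < alpha) & (
        r[DISTURBANCE_TRAIT].abs() > r[disease_cols].abs().max(axis=1)
    )
    disease = ~rejected & (p[disease_cols] < alpha).any(axis=1)
    module_set.disease_flags = disease
    module_set.rejected_flags = rejected
    selected = []
    for label in r.index[disease]:
        selected.extend(module_set.members(label))
    if not selected:
        warnings.warn("no disease-related module found", stacklevel=2)
    return selected


def partition_agreement(detected: pd.Series, reference: pd.Series) -> float:
    """Fraction of items whose detected module's majority reference label
    equals their own reference label; detected-unassigned items count as
    disagreement. Label-invariant up to renaming."""
    common = detected.index.intersection(reference.index)
    det, ref = detected.loc[common], reference.loc[common]
    correct = 0
    for label in set(det) - {0}:
        members = det.index[det == label]
        majority = ref.loc[members].mode().iloc[0]
        correct += int((ref.loc[members] == majority).sum())
    return correct / len(common)


def analyze_modules(normalized: NormalizedMatrix, config: NetworkConfig, alpha: float = 0.05):
    """Full module stage: network -> modules -> eigengenes -> trait table ->
    disease-related miRNA list. Returns (ModuleSet, selected miRNAs)."""
    diss = adjacency_tom(normalized.values, config)
    assignment = detect_modules(diss, config)
    if (assignment > 0).sum() == 0:
        ms = ModuleSet(assignment=assignment)
        return ms, []
    eig = module_eigengenes(normalized.values, assignment)
    traits = build_trait_matrix(normalized.metadata)
    r, p = module_trait_relationships(eig, traits)
    ms = ModuleSet(assignment=assignment, eigengenes=eig, module_trait_r=r, module_trait_p=p)
    selected = select_disease_mirnas(ms, alpha=alpha)
    return ms, selected
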