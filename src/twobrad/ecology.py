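"""Community ecology: alpha diversity, beta diversity, ordination, PERMANOVA.

Alpha diversity follows the usual conventions of the vegan/scikit-bio
ecosystem: Chao1 (bias-corrected by default) on integer read counts,
Shannon (natural log) and Simpson (1 - sum p^2) on relative abundances.
Beta diversity supports Bray-Curtis, binary Jaccard and Euclidean
distances; ordination is classical PCoA; group effects are tested with
PERMANOVA (Anderson's pseudo-F, permutation p-value) and alpha-diversity
group contrasts with the two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

__all__ = [
    "AbundanceTable",
    "DistanceMatrix",
    "chao1",
    "shannon",
    "simpson",
    "alpha_diversity",
    "compare_alpha",
    "beta_distance",
    "pcoa",
    "permanova",
    "BETA_METRICS",
]

BETA_METRICS = ("bray_curtis", "binary_jaccard", "euclidean")


@dataclass
class AbundanceTable:
    """Samples x taxa relative abundances plus study metadata.

    ``values`` rows each sum to 1 (or are all zero for an empty sample);
    ``counts`` optionally carries the parallel integer read counts used
    for Chao1; ``groups`` maps samples to group labels; ``taxonomy`` maps
    species to (genus, phylum).
    """

    values: pd.DataFrame
    groups: pd.Series
    counts: pd.DataFrame | None = None
    taxonomy: pd.DataFrame | None = None
    rank: str = "species"

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.index)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()].tolist()
            raise ValueError(f"samples missing group labels: {missing}")
        sums = self.values.sum(axis=1).to_numpy()
        ok = np.isclose(sums, 1.0, atol=1e-9) | (sums == 0)
        if not ok.all():
            bad = self.values.index[~ok].tolist()
            raise ValueError(f"abundance rows must sum to 1 (or 0): {bad}")
        if self.counts is not None:
            if not self.counts.index.equals(self.values.index) or not (
                self.counts.columns.equals(self.values.columns)
            ):
                raise ValueError("counts matrix must align with values")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    def group_names(self) -> list[str]:
        return sorted(self.groups.unique())

    def split_by_group(self) -> dict[str, pd.DataFrame]:
        return {g: self.values.loc[self.groups == g] for g in self.group_names()}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with sample ids and a metric name."""

    ids: Sequence[str]
    data: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))


# ---------------------------------------------------------------------------
# alpha diversity


def chao1(counts: Sequence[int] | np.ndarray, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from a vector of read counts.

    With S observed taxa, F1 singletons and F2 doubletons the
    bias-corrected form is S + F1*(F1-1) / (2*(F2+1)); the classic form
    S + F1^2/(2*F2) is available with ``bias_corrected=False`` (infinite
    when F2 = 0 and F1 > 0).
    """
    c = np.asarray(counts)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    S = int((c > 0).sum())
    if S == 0:
        return 0.0
    F1 = int((c == 1).sum())
    F2 = int((c == 2).sum())
    if bias_corrected:
        return S + F1 * (F1 - 1) / (2 * (F2 + 1))
    if F2 == 0:
        return float("inf") if F1 > 0 else float(S)
    return S + F1 * F1 / (2 * F2)


def _proportions(p: Sequence[float] | np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total == 0:
        return p
    return p / total


def shannon(p: Sequence[float] | np.ndarray, base: float = np.e) -> float:
    """Shannon entropy -sum p ln p (natural log by default; 0 ln 0 := 0)."""
    p = _proportions(p)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(base))


def simpson(p: Sequence[float] | np.ndarray) -> float:
    """Gini-Simpson index 1 - sum p^2."""
    p = _proportions(p)
    return float(1.0 - (p**2).sum())


def alpha_diversity(table: AbundanceTable) -> pd.DataFrame:
    """Per-sample Chao1 / Shannon / Simpson with group labels.

    Chao1 needs integer counts and uses ``table.counts``; Shannon and
    Simpson are computed on the relative abundances.
    """
    rows = {}
    for sample in table.samples:
        p = table.values.loc[sample].to_numpy()
        rows[sample] = {
            "chao1": (
                chao1(table.counts.loc[sample].to_numpy())
                if table.counts is not None
                else np.nan
            ),
            "shannon": shannon(p),
            "simpson": simpson(p),
            "group": table.groups[sample],
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def compare_alpha(values: Sequence[float], groups: Sequence[str]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p for a two-group contrast.

    Uses the exact null distribution when both groups have n <= 20 and the
    pooled values are tie-free, otherwise the tie-corrected normal
    approximation.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    a = values[groups == labels[0]]
    b = values[groups == labels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    no_ties = len(np.unique(values)) == len(values)
    method = "exact" if (no_ties and len(a) <= 20 and len(b) <= 20) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


# ---------------------------------------------------------------------------
# beta diversity


def beta_distance(table: AbundanceTable, metric: str) -> DistanceMatrix:
    """Pairwise sample distances under one of the supported metrics."""
    X = table.values.to_numpy()
    if metric == "bray_curtis":
        condensed = pdist(X, metric="braycurtis")
    elif metric == "binary_jaccard":
        condensed = pdist(X > 0, metric="jaccard")
    elif metric == "euclidean":
        condensed = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {BETA_METRICS}")
    return DistanceMatrix(table.samples, squareform(condensed), metric)


def pcoa(dist: DistanceMatrix, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical principal-coordinate analysis.

    Double-centres -D^2/2, eigendecomposes, and returns the top-k axes
    scaled by the square root of their eigenvalues.  All eigenvalues are
    returned (sorted descending, negatives included for diagnostics) but
    axes are only produced for positive eigenvalues.
    """
    D = dist.data
    n = D.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError("k must be in [1, n-1]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_pos = int((eigvals > 1e-10).sum())
    k_eff = min(k, n_pos)
    coords = eigvecs[:, :k_eff] * np.sqrt(eigvals[:k_eff])
    frame = pd.DataFrame(
        coords,
        index=list(dist.ids),
        columns=[f"PCo{i + 1}" for i in range(k_eff)],
    )
    frame.index.name = "sample_id"
    return frame, eigvals


def _permanova_stat(D2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    """Anderson's pseudo-F from squared distances and integer group codes."""
    n = D2.shape[0]
    a = len(groups)
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ng = len(idx)
        if ng == 0:
            raise ValueError("empty group in PERMANOVA")
        ss_within += D2[np.ix_(idx, idx)].sum() / (2 * ng)
    ss_among = ss_total - ss_within
    denom = ss_within / (n - a)
    if denom == 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (a - 1)) / denom


def permanova(
    dist: DistanceMatrix,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns ``(pseudo_F, p)`` where p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)
    — the observed statistic counts as one of its own permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    # canonicalise sample order so the permutation stream (and hence p)
    # does not depend on how the caller happened to order the matrix
    order = sorted(range(len(dist.ids)), key=lambda i: str(dist.ids[i]))
    ids = [dist.ids[i] for i in order]
    labels = pd.Series(groups).reindex(ids)
    if labels.isna().any():
        raise ValueError("group labels missing for some samples")
    codes, uniques = pd.factorize(labels.to_numpy())
    if len(uniques) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    D2 = dist.data[np.ix_(order, order)] ** 2
    group_ids = np.arange(len(uniques))
    f_obs = _permanova_stat(D2, codes, group_ids)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _permanova_stat(D2, perm, group_ids) >= f_obs:
            hits += 1
    return float(f_obs), (1 + hits) / (1 + n_perm)
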