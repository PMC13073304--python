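"""Correlation, PCA, Ward clustering and outlier flagging on the
sample x element concentration matrix.

Censored cells enter these computations only through an explicit
substitution policy. PCA defaults to the correlation-matrix variant
(columns standardized) because the elements span three orders of
magnitude; clustering likewise z-scores each element by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import chi2_contingency

from .io_datamodel import ELEMENT_ORDER, Element, Policy, SampleRecord, substitute_censored

__all__ = [
    "CorrelationReport",
    "PcaResult",
    "Dendrogram",
    "to_matrix",
    "correlation_report",
    "classify_r",
    "run_pca",
    "ward_cluster",
    "cut_clusters",
    "flag_outliers",
    "region_association",
]


def to_matrix(samples: Sequence[SampleRecord], policy: Policy = Policy.HALF_LOQ) -> pd.DataFrame:
    """Samples x elements concentration matrix with censored cells substituted."""
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in input")
    data = {
        elem.value: [substitute_censored(s[elem], policy) for s in samples]
        for elem in ELEMENT_ORDER
    }
    return pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))


def classify_r(r: float) -> str:
    """Correlation strength band: high (r > 0.5), moderate (0.3 <= r <= 0.5),
    weak otherwise; NaN maps to undefined."""
    if np.isnan(r):
        return "undefined"
    if r > 0.5:
        return "high"
    if 0.3 <= r <= 0.5:
        return "moderate"
    return "weak"


@dataclass(frozen=True)
class CorrelationReport:
    matrix: pd.DataFrame  # element x element Pearson r
    labels: dict[tuple[str, str], str]  # canonical-order pair -> band

    def pair(self, a: Element | str, b: Element | str) -> float:
        return float(self.matrix.loc[str(getattr(a, "value", a)), str(getattr(b, "value", b))])


def correlation_report(
    samples: Sequence[SampleRecord], policy: Policy = Policy.HALF_LOQ
) -> CorrelationReport:
    """Pearson correlations between all element pairs, with strength bands.

    Zero-variance elements yield NaN correlations labeled ``undefined``
    (a warning is emitted).
    """
    df = to_matrix(samples, policy)
    if len(df) < 3:
        raise ValueError("correlation requires at least 3 samples")
    sd = df.std(ddof=1)
    constant = [c for c in df.columns if sd[c] == 0]
    if constant:
        warnings.warn(f"zero-variance elements {constant}: correlations undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = df.corr(method="pearson")
    for c in constant:
        mat.loc[c, :] = np.nan
        mat.loc[:, c] = np.nan
    np.fill_diagonal(mat.values, 1.0)

    labels: dict[tuple[str, str], str] = {}
    cols = list(mat.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            labels[(a, b)] = classify_r(float(mat.loc[a, b]))
    return CorrelationReport(matrix=mat, labels=labels)


@dataclass(frozen=True)
class PcaResult:
    explained_variance_pct: np.ndarray  # per component, sums to 100
    loadings: pd.DataFrame  # element x component, orthonormal columns
    scores: pd.DataFrame  # sample x component


def run_pca(
    samples: Sequence[SampleRecord],
    policy: Policy = Policy.HALF_LOQ,
    standardize: bool = True,
) -> PcaResult:
    """Principal components of the (standardized) concentration matrix.

    Components are ordered by decreasing explained variance. The sign of
    each loading vector is fixed so its largest-magnitude entry is
    positive, making outputs reproducible across linear-algebra backends.
    """
    df = to_matrix(samples, policy)
    n = len(df)
    if n < 3:
        raise ValueError("PCA requires at least 3 samples")
    X = df.to_numpy(dtype=float)
    centered = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        constant = [c for c, s in zip(df.columns, sd) if s == 0]
        if constant:
            raise ValueError(
                f"cannot standardize constant column(s) {constant}; "
                "use standardize=False or drop them"
            )
        centered = centered / sd

    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    variances = S**2 / (n - 1)
    loadings = Vt.T.copy()
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            U[:, j] *= -1.0
    scores = U * S

    comp_names = [f"PC{j + 1}" for j in range(loadings.shape[1])]
    total = variances.sum()
    # all-identical rows carry no variance; report zeros rather than NaN
    explained = 100.0 * variances / total if total > 0 else np.zeros_like(variances)
    return PcaResult(
        explained_variance_pct=explained,
        loadings=pd.DataFrame(loadings, index=df.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=df.index, columns=comp_names),
    )


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history: (cluster_a, cluster_b, height, size) per merge.

    Leaves are numbered 0..n-1 in ``leaves`` order; merge *i* creates
    cluster id ``n + i``. Heights are non-decreasing for Ward linkage on
    Euclidean distances.
    """

    leaves: tuple[str, ...]
    merges: tuple[tuple[int, int, float, int], ...]

    def to_linkage(self) -> np.ndarray:
        return np.array([[a, b, h, c] for a, b, h, c in self.merges], dtype=float)

    def to_merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.merges, columns=["cluster_a", "cluster_b", "height", "size"]
        )

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences to the parent."""
        n = len(self.leaves)
        reprs: dict[int, tuple[str, float]] = {
            i: (name, 0.0) for i, name in enumerate(self.leaves)
        }
        node = ""
        for step, (a, b, h, _count) in enumerate(self.merges):
            (ra, ha), (rb, hb) = reprs.pop(a), reprs.pop(b)
            node = f"({ra}:{h - ha:.10g},{rb}:{h - hb:.10g})"
            reprs[n + step] = (node, h)
        return node + ";"


def ward_cluster(
    samples: Sequence[SampleRecord],
    policy: Policy = Policy.HALF_LOQ,
    normalize: bool = True,
) -> Dendrogram:
    """Ward agglomerative clustering on Euclidean distances between samples.

    With ``normalize=True`` every element is z-scored first (constant
    elements are left centered at zero rather than divided by zero).
    """
    df = to_matrix(samples, policy)
    if len(df) < 2:
        raise ValueError("clustering requires at least 2 samples")
    X = df.to_numpy(dtype=float)
    if normalize:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    merges = tuple(
        (int(a), int(b), float(h), int(c)) for a, b, h, c in Z
    )
    return Dendrogram(leaves=tuple(df.index), merges=merges)


def cut_clusters(dendrogram: Dendrogram, k: int) -> dict[str, int]:
    """Flat cluster labels (1..k) from cutting the tree into ``k`` clusters."""
    labels = hierarchy.fcluster(dendrogram.to_linkage(), t=k, criterion="maxclust")
    return {leaf: int(lab) for leaf, lab in zip(dendrogram.leaves, labels)}


def flag_outliers(pca: PcaResult, k: float = 2.0) -> list[str]:
    """Samples whose PCA-score distance from the score centroid exceeds
    ``k`` times the median distance.

    If every distance is zero (identical rows) nothing is flagged; if the
    median itself is zero, any sample at positive distance is flagged.
    """
    scores = pca.scores.to_numpy(dtype=float)
    centroid = scores.mean(axis=0)
    dist = np.linalg.norm(scores - centroid, axis=1)
    med = float(np.median(dist))
    threshold = k * med
    flagged = dist > threshold if med > 0 else dist > 0
    return [sid for sid, f in zip(pca.scores.index, flagged) if f]


def region_association(
    samples: Sequence[SampleRecord],
    cluster_labels: dict[str, int],
    n_permutations: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation test of association between cluster label and region group.

    The region group is the trailing comma-separated token of the site
    label (the municipality). The statistic is the contingency chi-square
    between group and cluster label; the p-value is the fraction of label
    permutations (plus the observed one) with a statistic at least as
    large. Exploratory: reported, never asserted.
    """
    groups = np.array([s.site.split(",")[-1].strip() for s in samples])
    labels = np.array([cluster_labels[s.sample_id] for s in samples])

    def stat(perm_labels: np.ndarray) -> float:
        table = pd.crosstab(groups, perm_labels).to_numpy()
        if table.shape[0] < 2 or table.shape[1] < 2:
            return 0.0
        return float(chi2_contingency(table, correction=False).statistic)

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_permutations):
        if stat(rng.permutation(labels)) >= observed - 1e-12:
            hits += 1
    return {"statistic": observed, "p_value": hits / (n_permutations + 1)}
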