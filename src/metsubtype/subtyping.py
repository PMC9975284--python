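"""Subtype discovery by resampled consensus Ward clustering.

The discovery procedure follows the Monti-style consensus scheme: many
times, subsample a fraction of the samples, cluster them by Ward-linkage
hierarchical clustering on a 1 - Pearson correlation dissimilarity, and
record for every sample pair how often it co-clusters among the runs in
which both were drawn. The consensus matrix's stability across K (via the
CDF / delta-area diagnostic) guides the choice of cluster number; the
choice itself — including working at a larger K and merging minor
clusters back into the major ones — is explicit user input, not
automated.

Minor-cluster reclassification is one-shot: a binary top-gene centroid
model is built from the kept clusters' current memberships, and every
sample of a non-kept cluster moves to the kept subtype whose centroid it
correlates with best.

Notes on conventions: Ward linkage is applied to the given dissimilarity
via scipy's ``linkage(..., 'ward')`` on the condensed matrix, i.e. the
Ward.D2 convention in which the dissimilarities are treated as Euclidean
distances. Pairwise-complete Pearson handles missing genes; sample pairs
sharing fewer than ``min_shared`` genes get maximal distance 1 with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .stats import welch_t_from_moments

__all__ = [
    "ConsensusResult",
    "SubtypeModel",
    "select_clustering_genes",
    "correlation_distance",
    "consensus_cluster",
    "evaluate_k",
    "select_top_genes",
    "build_subtype_model",
    "reclassify_minor_clusters",
]


@dataclass
class ConsensusResult:
    samples: list[str]
    consensus: dict[int, np.ndarray]  # K -> sample x sample co-clustering rates
    assignments: dict[int, pd.Series]  # K -> integer cluster labels (1..K)
    reps: int
    subsample_fraction: float
    seed: int


@dataclass
class SubtypeModel:
    """Binary nearest-centroid model: per-subtype ordered top-gene lists.

    The centroid matrix M has one {0,1} column per subtype over the union
    of the top lists; M[g, k] = 1 iff gene g is in subtype k's top list.
    """

    labels: list[str]
    top_genes: dict[str, list[str]]
    gene_universe: list[str]
    n_top: int
    centroids: pd.DataFrame = field(init=False)

    def __post_init__(self):
        seen: set[str] = set()
        for lab in self.labels:
            lst = self.top_genes[lab]
            if seen & set(lst):
                raise ValueError("top-gene lists overlap across subtypes")
            seen |= set(lst)
        model_genes = [g for g in self.gene_universe if g in seen]
        M = pd.DataFrame(0, index=model_genes, columns=self.labels, dtype=int)
        for lab in self.labels:
            M.loc[[g for g in self.top_genes[lab] if g in M.index], lab] = 1
        self.centroids = M

    @classmethod
    def from_top_lists(cls, top: dict[str, list[str]], universe, n_top: int):
        return cls(labels=list(top), top_genes=top, gene_universe=list(universe), n_top=n_top)

    @property
    def model_genes(self) -> list[str]:
        return list(self.centroids.index)


def select_clustering_genes(
    values: pd.DataFrame, n: int, min_presence: int, seed: int
) -> list[str]:
    """Uniform random draw of ``n`` genes observed in >= ``min_presence`` samples."""
    presence = values.notna().sum(axis=1)
    pool = sorted(values.index[presence >= min_presence])
    if len(pool) < n:
        raise ValueError(
            f"eligible gene pool ({len(pool)}) smaller than requested n ({n})"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(picked)]


def correlation_distance(values: pd.DataFrame, min_shared: int = 30) -> np.ndarray:
    """Sample x sample 1 - Pearson distance, pairwise-complete over genes."""
    X = values.to_numpy(float)
    if not np.isnan(X).any():
        corr = np.corrcoef(X.T)
    else:
        corr = values.corr(min_periods=min_shared).to_numpy()
        if np.isnan(corr).any():
            warnings.warn(
                f"sample pairs with <{min_shared} shared genes set to distance 1",
                stacklevel=2,
            )
    corr = np.nan_to_num(corr, nan=0.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, None)


def consensus_cluster(
    values: pd.DataFrame,
    k_range=range(2, 16),
    reps: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
    min_shared: int = 30,
) -> ConsensusResult:
    """Monti-style resampled consensus of Ward clusterings.

    ``values`` is gene x sample. Per replicate, ceil(fraction * n) samples
    are drawn without replacement and Ward-clustered on 1 - Pearson
    distance; consensus(i, j) = co-clustered count / co-subsampled count
    (0 when never co-drawn). The final per-K assignment cuts an
    average-linkage tree of 1 - consensus at K.
    """
    samples = list(values.columns)
    n = len(samples)
    k_range = [int(k) for k in k_range]
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    if n < max(k_range) + 1:
        raise ValueError("too few samples for requested k_range")
    if not 0 < subsample_fraction <= 1:
        raise ValueError("subsample_fraction must lie in (0, 1]")

    # pair distance is independent of which other samples are drawn, so the
    # full matrix is computed once and subsampled per replicate
    D = correlation_distance(values, min_shared=min_shared)
    rng = np.random.default_rng(seed)
    m = int(np.ceil(subsample_fraction * n))
    together = {k: np.zeros((n, n)) for k in k_range}
    drawn = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        drawn[np.ix_(idx, idx)] += 1
        sub = D[np.ix_(idx, idx)]
        Z = linkage(squareform(sub, checks=False), method="ward")
        for k in k_range:
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            together[k][np.ix_(idx, idx)] += same

    consensus, assignments = {}, {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for k in k_range:
            C = np.where(drawn > 0, together[k] / np.where(drawn > 0, drawn, 1), 0.0)
            C = (C + C.T) / 2.0
            np.fill_diagonal(C, 1.0)
            consensus[k] = C
            Zc = linkage(squareform(1.0 - C, checks=False), method="average")
            assignments[k] = pd.Series(
                fcluster(Zc, t=k, criterion="maxclust"), index=samples, name=f"k{k}"
            )
    return ConsensusResult(
        samples=samples,
        consensus=consensus,
        assignments=assignments,
        reps=reps,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


def evaluate_k(result: ConsensusResult) -> pd.DataFrame:
    """CDF area and delta-area of off-diagonal consensus values per K.

    The area under the empirical CDF of consensus entries grows as the
    clustering stabilizes; delta-area is the relative increase over the
    previous K (the first K reports its absolute area).
    """
    ks = sorted(result.consensus)
    if len(ks) < 2:
        raise ValueError("need >=2 K values to evaluate")
    rows = []
    prev_area = None
    n = len(result.samples)
    iu = np.triu_indices(n, k=1)
    for k in ks:
        vals = np.sort(result.consensus[k][iu])
        # empirical CDF area over [0, 1] via the step function
        xs = np.concatenate([[0.0], vals, [1.0]])
        cdf = np.concatenate([[0.0], np.arange(1, vals.size + 1) / vals.size, [1.0]])
        area = float(np.sum(np.diff(xs) * cdf[:-1]))
        if prev_area is None:
            delta = area
        else:
            delta = (area - prev_area) / prev_area if prev_area > 0 else 0.0
        rows.append({"k": k, "cdf_area": area, "delta_area": delta})
        prev_area = area
    return pd.DataFrame(rows).set_index("k")


def select_top_genes(
    values: pd.DataFrame, labels: pd.Series, n_top: int = 200
) -> dict[str, list[str]]:
    """Per-subtype ordered marker lists by subtype-vs-rest Welch t.

    A gene is eligible only for the subtype where its t-statistic is
    maximal, which makes the lists disjoint by construction; within a
    subtype genes are ranked by descending t (ties by gene id) and
    truncated at ``n_top``.
    """
    labels = labels.reindex(values.columns)
    groups = sorted(labels.dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 subtypes to rank marker genes")
    X = values.to_numpy(float)
    tmat = np.full((values.shape[0], len(groups)), -np.inf)
    for j, lab in enumerate(groups):
        mask = (labels == lab).to_numpy()
        t, _, _ = _welch_rows(X[:, mask], X[:, ~mask])
        tmat[:, j] = np.where(np.isfinite(t), t, -np.inf)
    best = np.argmax(tmat, axis=1)
    out: dict[str, list[str]] = {}
    genes = np.array(values.index)
    for j, lab in enumerate(groups):
        idx = np.where(best == j)[0]
        order = sorted(idx, key=lambda i: (-tmat[i, j], genes[i]))
        out[str(lab)] = [genes[i] for i in order[:n_top]]
    return out


def _welch_rows(x_in, x_out):
    n1 = np.sum(~np.isnan(x_in), axis=1)
    n2 = np.sum(~np.isnan(x_out), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1, m2 = np.nanmean(x_in, axis=1), np.nanmean(x_out, axis=1)
        v1, v2 = np.nanvar(x_in, axis=1, ddof=1), np.nanvar(x_out, axis=1, ddof=1)
    return welch_t_from_moments(m1, v1, n1, m2, v2, n2)


def build_subtype_model(
    top_lists: dict[str, list[str]], gene_universe, n_top: int | None = None
) -> SubtypeModel:
    if n_top is None:
        n_top = max((len(v) for v in top_lists.values()), default=0)
    return SubtypeModel.from_top_lists(top_lists, gene_universe, n_top=n_top)


def reclassify_minor_clusters(
    values: pd.DataFrame,
    assignments: pd.Series,
    keep: list,
    n_top: int = 200,
    relabel: dict | None = None,
) -> tuple[pd.Series, SubtypeModel]:
    """Fold minor clusters into the kept subtypes by best centroid fit.

    A top-gene model is built once from the kept clusters' members; each
    sample of a non-kept cluster is reassigned to the kept subtype whose
    binary centroid it has the highest Pearson correlation with. Kept
    samples retain their labels. ``relabel`` optionally renames kept
    cluster ids (e.g. {1: "s1"}). Returns (final labels, model).
    """
    from .classify import classify_dataset  # local import avoids a cycle

    assignments = assignments.reindex(values.columns)
    observed = set(assignments.dropna().unique())
    if not set(keep) <= observed:
        raise ValueError(f"keep={keep} not a subset of observed clusters {sorted(observed)}")
    relabel = relabel or {c: f"s{i + 1}" for i, c in enumerate(sorted(keep))}
    kept_mask = assignments.isin(keep)
    for c in keep:
        if (assignments == c).sum() < 3:
            raise ValueError(f"kept cluster {c!r} has <3 samples; t-statistics undefined")
    kept_labels = assignments[kept_mask].map(relabel)
    top = select_top_genes(values.loc[:, kept_mask], kept_labels, n_top=n_top)
    model = build_subtype_model(top, values.index, n_top=n_top)

    final = kept_labels.reindex(values.columns)
    minors = values.columns[~kept_mask]
    if len(minors):
        calls = classify_dataset(values[minors], model)
        final.loc[minors] = calls.set_index("sample_id")["label"]
    return final, model
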