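"""Cross-study compendium assembly and normalization.

Expression tables from independent studies (counts, TPM, or array
intensities) are made comparable by, per study: optional TPM conversion,
optional quantile normalization, collapsing multi-feature genes to the
most variable feature, log2 transform, and finally converting each gene to
unitless "SD-from-median" values within each study x cancer-type stratum:

    x' = (x - median(x)) / SD(x)

with the median taken per gene within the stratum and SD the sample
standard deviation (ddof=1). This erases study- and tissue-level location
and scale effects so a gene's values are comparable across datasets.

Paired metastasis-primary profiles are instead centered on the primary
(the primary's own differential is identically zero) and scaled per study
by the SD across the centered metastasis and primary profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ANNOTATION_COLUMNS

__all__ = [
    "RawStudyTable",
    "ExpressionCompendium",
    "PairedDeltaMatrix",
    "counts_to_tpm",
    "quantile_normalize",
    "collapse_features",
    "assemble_compendium",
    "center_scale_within_strata",
    "paired_normalize",
    "filter_lymphoma_like",
]


@dataclass
class RawStudyTable:
    """One study's feature x sample expression table before harmonization."""

    study_id: str
    values: pd.DataFrame  # feature x sample
    units: str = "tpm"  # counts | tpm | intensity | log2
    feature_to_gene: dict[str, str] | None = None  # many-to-one allowed
    gene_lengths: pd.Series | None = None  # bp, for counts -> TPM
    quantile_normalize: bool = False

    def __post_init__(self):
        if self.units not in {"counts", "tpm", "intensity", "log2"}:
            raise ValueError(f"unknown units {self.units!r}")
        if self.values.columns.duplicated().any():
            raise ValueError(f"duplicate sample ids in study {self.study_id}")
        if self.units in {"counts", "tpm"} and (self.values.values < 0).any():
            raise ValueError(f"negative {self.units} values in study {self.study_id}")


@dataclass
class ExpressionCompendium:
    """Gene x sample matrix in SD-from-median units plus sample annotations."""

    values: pd.DataFrame
    annotations: pd.DataFrame
    gene_universe: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.gene_universe:
            self.gene_universe = list(self.values.index)
        ann_ids = set(self.annotations["sample_id"])
        cols = set(self.values.columns)
        if cols - ann_ids:
            raise ValueError(f"{len(cols - ann_ids)} samples lack annotations")

    def strata(self):
        ann = self.annotations.set_index("sample_id").loc[list(self.values.columns)]
        return ann["study_id"].astype(str) + "||" + ann["cancer_type"].astype(str)


@dataclass
class PairedDeltaMatrix:
    """Gene x metastasis matrix of unitless met-vs-primary differentials."""

    values: pd.DataFrame  # columns = metastasis sample ids
    pairs: pd.DataFrame  # met_sample, primary_sample, patient_id, study_id


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Convert raw read counts to transcripts-per-million.

    rate_f = counts_f / length_f ; TPM_f = 1e6 * rate_f / sum_f rate_f.
    Every column of the result sums to 1e6.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length for feature(s): {list(missing[:5])}")
    L = lengths.reindex(counts.index).astype(float)
    if (L <= 0).any():
        bad = L.index[L <= 0][0]
        raise ValueError(f"non-positive length for feature {bad!r}")
    rate = counts.div(L, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the common per-rank-mean distribution.

    Missing cells stay missing; each column's observed values are ranked and
    mapped onto the reference distribution by quantile interpolation, so for
    complete input every column's sorted vector equals the per-rank means.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    if matrix.isna().all(axis=0).any():
        bad = matrix.columns[matrix.isna().all(axis=0)][0]
        raise ValueError(f"column {bad!r} is entirely missing")
    X = matrix.to_numpy(float)
    if not np.isnan(X).any():
        order = np.argsort(X, axis=0, kind="stable")
        ranks = np.empty_like(order)
        n = X.shape[0]
        rows = np.arange(n)[:, None]
        np.put_along_axis(ranks, order, rows, axis=0)
        ref = np.sort(X, axis=0).mean(axis=1)
        # average reference values over tied ranks within each column
        out = ref[ranks]
        for j in range(X.shape[1]):
            col = X[:, j]
            _, inv, counts = np.unique(col, return_inverse=True, return_counts=True)
            if (counts > 1).any():
                sums = np.bincount(inv, weights=out[:, j])
                out[:, j] = sums[inv] / counts[inv]
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    # NaN-tolerant path: per-column quantile mapping onto the mean quantile curve
    grid = np.linspace(0, 1, 101)
    curves = []
    for j in range(X.shape[1]):
        col = X[:, j]
        curves.append(np.quantile(col[~np.isnan(col)], grid))
    ref_curve = np.mean(curves, axis=0)
    out = np.full_like(X, np.nan)
    for j in range(X.shape[1]):
        col = X[:, j]
        obs = ~np.isnan(col)
        v = col[obs]
        q = (np.argsort(np.argsort(v)) + 0.5) / v.size
        out[obs, j] = np.interp(q, grid, ref_curve)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def collapse_features(table: RawStudyTable) -> pd.DataFrame:
    """Keep, per gene, the feature with the largest SD of log2 values.

    Ties break to the lexicographically smallest feature id. Rows are passed
    through unmodified (selection only).
    """
    if table.feature_to_gene is None:
        raise ValueError("collapse_features requires a feature->gene map")
    vals = table.values
    logged = vals if table.units == "log2" else np.log2(vals + 1.0)
    sd = logged.std(axis=1, ddof=1)
    keep = []
    frame = pd.DataFrame(
        {"gene": [table.feature_to_gene.get(f) for f in vals.index], "sd": sd.values},
        index=vals.index,
    ).dropna(subset=["gene"])
    for _, grp in frame.groupby("gene", sort=True):
        grp = grp.sort_index()  # lexicographic tie-break
        keep.append(grp["sd"].idxmax())
    out = vals.loc[keep]
    out.index = [table.feature_to_gene[f] for f in keep]
    return out.sort_index()


def assemble_compendium(
    tables: list[RawStudyTable],
    annotations: pd.DataFrame,
    universe_rule: str = "intersection",
    anchor_studies: list[str] | None = None,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stack per-study tables on a common gene universe of log2 values.

    The universe is the intersection (or union) of the gene sets of the
    anchor studies (all studies if unset); genes absent from a study become
    missing. Linear-scale inputs get log2(x + pseudocount); log2 inputs pass
    through.
    """
    ids = [t.study_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate study ids")
    all_samples = [s for t in tables for s in t.values.columns]
    if len(set(all_samples)) != len(all_samples):
        raise ValueError("sample ids collide across studies")
    anchors = anchor_studies or ids
    gene_sets = [set(t.values.index) for t in tables if t.study_id in anchors]
    if not gene_sets:
        raise ValueError("no anchor study matched")
    if universe_rule == "intersection":
        universe = set.intersection(*gene_sets)
    elif universe_rule == "union":
        universe = set.union(*gene_sets)
    else:
        raise ValueError(f"unknown universe rule {universe_rule!r}")
    universe = sorted(universe)

    pieces = []
    for t in tables:
        vals = t.values
        logged = vals if t.units == "log2" else np.log2(vals + pseudocount)
        pieces.append(logged.reindex(universe))
    matrix = pd.concat(pieces, axis=1)

    ann_ids = set(annotations["sample_id"])
    unmatched = [s for s in matrix.columns if s not in ann_ids]
    if unmatched:
        raise ValueError(f"{len(unmatched)} samples missing annotations, e.g. {unmatched[:3]}")
    ann = annotations[annotations["sample_id"].isin(matrix.columns)].copy()
    return matrix, ann


def _sd_from_median(block: np.ndarray) -> np.ndarray:
    """Per-row (x - median)/SD with degenerate rows (SD 0 or <2 obs) -> 0."""
    out = np.full_like(block, np.nan, dtype=float)
    n_obs = np.sum(~np.isnan(block), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(block, axis=1)
        sd = np.nanstd(block, axis=1, ddof=1)
    ok = (n_obs >= 2) & (sd > 0)
    out[ok] = (block[ok] - med[ok, None]) / sd[ok, None]
    degenerate = (~ok)[:, None] & ~np.isnan(block)
    out[degenerate] = 0.0
    return out


def center_scale_within_strata(
    matrix: pd.DataFrame, annotations: pd.DataFrame
) -> ExpressionCompendium:
    """Convert log2 values to SD-from-median units per study x cancer-type stratum.

    Strata with a single sample yield all-missing output with a warning;
    genes with fewer than two observations or zero spread map to 0.
    """
    ann = annotations.set_index("sample_id")
    unknown = [s for s in matrix.columns if s not in ann.index]
    if unknown:
        raise ValueError(f"samples without stratum annotation: {unknown[:3]}")
    ann = ann.loc[list(matrix.columns)]
    strata = ann["study_id"].astype(str) + "||" + ann["cancer_type"].astype(str)

    out = np.full(matrix.shape, np.nan)
    X = matrix.to_numpy(float)
    for stratum in strata.unique():
        cols = np.where(strata.values == stratum)[0]
        if cols.size < 2:
            warnings.warn(
                f"stratum {stratum!r} has a single sample; output left missing",
                stacklevel=2,
            )
            continue
        out[:, cols] = _sd_from_median(X[:, cols])
    values = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return ExpressionCompendium(values=values, annotations=annotations)


def paired_normalize(
    met: pd.DataFrame,
    primary: pd.DataFrame,
    pairs: pd.DataFrame,
) -> PairedDeltaMatrix:
    """Center each metastasis on its paired primary and scale per study.

    delta_g = log2(met) - log2(primary) per pair; within each study and gene
    the deltas are divided by the SD computed across the centered metastasis
    AND primary profiles of that study — the primaries contribute all-zero
    columns, which shrink the SD deterministically. Zero SD maps to 0.
    """
    required = {"met_sample", "primary_sample", "study_id"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"pairs table needs columns {sorted(required)}")
    unpaired = [m for m in pairs["met_sample"] if m not in met.columns]
    if unpaired:
        raise ValueError(f"metastasis columns missing from matrix: {unpaired[:3]}")
    missing_primary = [p for p in pairs["primary_sample"] if p not in primary.columns]
    if missing_primary:
        raise ValueError(f"unpaired metastases (no primary): {missing_primary[:3]}")

    genes = met.index.intersection(primary.index)
    deltas = pd.DataFrame(index=genes, columns=list(pairs["met_sample"]), dtype=float)
    for _, row in pairs.iterrows():
        deltas[row["met_sample"]] = (
            met.loc[genes, row["met_sample"]] - primary.loc[genes, row["primary_sample"]]
        )

    out = deltas.copy()
    study_of = pairs.set_index("met_sample")["study_id"]
    for study in study_of.unique():
        cols = [m for m in deltas.columns if study_of[m] == study]
        block = deltas[cols].to_numpy(float)
        n_pairs = len(cols)
        # SD across centered met profiles plus one all-zero column per primary
        padded = np.concatenate([block, np.zeros((block.shape[0], n_pairs))], axis=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(padded, axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(sd[:, None] > 0, block / sd[:, None], 0.0)
        scaled[np.isnan(block)] = np.nan
        out[cols] = scaled
    return PairedDeltaMatrix(values=out, pairs=pairs)


def filter_lymphoma_like(
    dataset: pd.DataFrame,
    marker_gene: str,
    signature_genes: list[str],
    threshold: float = 3.0,
) -> tuple[list[str], list[str]]:
    """Flag graft profiles with lymphocyte-dominated expression.

    ``dataset`` is one study's matrix in SD-from-median units. A sample is
    removed when the B-cell marker gene sits at or above ``threshold`` SD
    from the dataset median, or when the B-cell signature score (mean of
    signature-gene values, re-standardized to SD-from-median across the
    dataset) does. Returns (kept, removed) sample id lists.
    """
    if marker_gene not in dataset.index:
        raise ValueError(f"marker gene {marker_gene!r} absent from dataset")
    present = [g for g in signature_genes if g in dataset.index]
    if not present:
        raise ValueError("no signature gene present in dataset")
    marker = dataset.loc[marker_gene]
    score = dataset.loc[present].mean(axis=0)
    med, sd = score.median(), score.std(ddof=1)
    z = (score - med) / sd if sd > 0 else score * 0.0
    removed = dataset.columns[(marker >= threshold) | (z >= threshold)]
    kept = [s for s in dataset.columns if s not in set(removed)]
    return kept, list(removed)
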