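"""Gene-level copy-number processing and subtype enrichment.

Copy values arrive as non-negative integers per gene and sample. For
datasets not already ploidy-corrected, each sample's values are rescaled
so its median across genes is 2 (v' = 2 v / median), after which a
whole-genome duplication no longer reads as genome-wide gain. Calls are
thresholded on the (possibly non-integer) corrected values:

    loss            v < 2
    neutral         2 <= v < 3
    gain            3 <= v <= 5
    amplification   v > 5

The CNA burden index is the per-sample standard deviation of copy values
across genes, reported raw and centered within each dataset to
SD-from-median units across samples. Gain and mutation enrichment by
subtype use one-sided 2x2 tests (Fisher exact, or signed chi-square for
large tables; see stats.enrichment_test).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import enrichment_test, odds_ratio

__all__ = [
    "ploidy_correct",
    "call_gain_loss",
    "cna_burden",
    "gain_enrichment_by_subtype",
    "mutation_enrichment_by_subtype",
]

CALL_LOSS, CALL_NEUTRAL, CALL_GAIN, CALL_AMP = "loss", "neutral", "gain", "amplification"


def ploidy_correct(copies: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample so its median gene copy value is 2.

    Idempotent (a corrected sample has median exactly 2). A sample whose
    median copy value is 0 cannot be corrected and raises.
    """
    med = copies.median(axis=0)
    if (med <= 0).any():
        bad = med.index[med <= 0][0]
        raise ValueError(f"sample {bad!r} has non-positive median copy value")
    return copies.astype(float).div(med, axis=1) * 2.0


def call_gain_loss(values: pd.DataFrame) -> pd.DataFrame:
    """Categorical calls from copy values (see module docstring thresholds)."""
    if (values.values < 0).any():
        raise ValueError("copy values must be non-negative")
    v = values.to_numpy(float)
    calls = np.full(v.shape, CALL_NEUTRAL, dtype=object)
    calls[v < 2] = CALL_LOSS
    calls[(v >= 3) & (v <= 5)] = CALL_GAIN
    calls[v > 5] = CALL_AMP
    return pd.DataFrame(calls, index=values.index, columns=values.columns)


def cna_burden(copies: pd.DataFrame, dataset: pd.Series | None = None) -> pd.DataFrame:
    """Per-sample copy-number burden: SD of copy values across genes.

    ``dataset`` groups samples for the centered version, (raw - median) /
    SD across the dataset's samples; degenerate spread maps to 0. With no
    grouping, all samples form one dataset.
    """
    if copies.shape[0] < 2:
        raise ValueError("burden needs >=2 genes")
    raw = copies.std(axis=0, ddof=1)
    if dataset is None:
        dataset = pd.Series("all", index=copies.columns)
    dataset = dataset.reindex(copies.columns)
    centered = pd.Series(0.0, index=copies.columns)
    for _, cols in dataset.groupby(dataset).groups.items():
        block = raw.loc[cols]
        sd = block.std(ddof=1)
        if len(block) >= 2 and sd > 0:
            centered.loc[cols] = (block - block.median()) / sd
    return pd.DataFrame({"raw_burden": raw, "centered_burden": centered})


def _binary_enrichment(events: pd.DataFrame, labels: pd.Series, method: str) -> pd.DataFrame:
    labels = labels.reindex(events.columns)
    subtypes = sorted(labels.dropna().unique())
    if len(subtypes) < 2:
        raise ValueError("need >=2 subtypes for enrichment")
    E = events.to_numpy(bool)
    rows = []
    for lab in subtypes:
        mask = (labels == lab).to_numpy()
        n_in, n_out = int(mask.sum()), int((~mask).sum())
        ev_in = E[:, mask].sum(axis=1)
        ev_out = E[:, ~mask].sum(axis=1)
        for i, gene in enumerate(events.index):
            a, b = int(ev_in[i]), int(ev_out[i])
            c, d = n_in - a, n_out - b
            p, used = enrichment_test(a, b, c, d, method=method)
            rows.append(
                {
                    "gene": gene,
                    "subtype": lab,
                    "event_in": a,
                    "event_out": b,
                    "n_in": n_in,
                    "n_out": n_out,
                    "odds": odds_ratio(a, b, c, d),
                    "p_one_sided": p,
                    "method": used,
                }
            )
    return pd.DataFrame(rows)


def gain_enrichment_by_subtype(
    calls: pd.DataFrame, labels: pd.Series, method: str = "auto"
) -> pd.DataFrame:
    """One-sided enrichment of gain-or-amplification calls within each subtype."""
    gains = calls.isin([CALL_GAIN, CALL_AMP])
    return _binary_enrichment(gains, labels, method)


def mutation_enrichment_by_subtype(
    mutations: pd.DataFrame,
    labels: pd.Series,
    gene_panel: list[str] | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """One-sided mutation enrichment within each subtype over a gene panel."""
    table = mutations
    if gene_panel is not None:
        table = mutations.loc[[g for g in gene_panel if g in mutations.index]]
    return _binary_enrichment(table.astype(bool), labels, method)
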