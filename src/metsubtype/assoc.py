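"""Association statistics linking subtypes to expression, gene sets and drugs.

Differential expression is Welch (unequal-variance) two-sample t per
gene, subtype vs rest, on SD-from-median values; paired differentials
are one-sample t of per-pair deltas against zero (equivalent to the
paired t-test on met vs primary). Gene-set overlap, TF-target
enrichment, and annotation-term enrichment are one-sided 2x2 tests on a
stated universe (Fisher exact / signed chi-square switch). Reference
signature scoring is the Pearson correlation of a profile with a
centered reference differential profile over shared genes. Drug
associations are Welch t on natural-log IC50, subtype lines vs the rest,
with "sensitive" meaning lower ln IC50 inside the subtype.

Gene-set construction uses nominal per-gene p cutoffs (default 0.01);
Storey q-values are reported alongside as a multiplicity diagnostic but
never used for selection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import enrichment_test, odds_ratio, one_sample_t, qvalues, welch_t_groups

__all__ = [
    "differential_expression",
    "paired_differential",
    "de_gene_sets",
    "gene_set_overlap",
    "orthogonal_overlap_matrix",
    "signature_score",
    "tf_enrichment",
    "annotation_enrichment",
    "merge_ic50",
    "drug_response_association",
]


def differential_expression(
    values: pd.DataFrame, labels: pd.Series, subtype: str, min_group: int = 3
) -> pd.DataFrame:
    """Per-gene Welch t of ``subtype`` vs all other samples.

    The ``highest_in_subtype`` flag marks genes whose mean inside the
    subtype exceeds every other subtype's mean (computed on the same
    SD-unit values); degenerate genes (either group under ``min_group``
    observations) are kept but flagged ``skipped``.
    """
    labels = labels.reindex(values.columns)
    in_mask = (labels == subtype).to_numpy()
    if in_mask.sum() == 0:
        raise ValueError(f"no samples labeled {subtype!r}")
    X = values.to_numpy(float)
    t, p, diff = welch_t_groups(X[:, in_mask], X[:, ~in_mask])
    n_in = np.sum(~np.isnan(X[:, in_mask]), axis=1)
    n_out = np.sum(~np.isnan(X[:, ~in_mask]), axis=1)
    skipped = (n_in < min_group) | (n_out < min_group)

    means = {}
    for lab in sorted(labels.dropna().unique()):
        cols = (labels == lab).to_numpy()
        with np.errstate(invalid="ignore"):
            means[lab] = np.nanmean(np.where(cols[None, :], X, np.nan), axis=1)
    own = means[subtype]
    others = [m for lab, m in means.items() if lab != subtype]
    highest = np.all([own > m for m in others], axis=0) & ~np.isnan(own)

    out = pd.DataFrame(
        {
            "gene": values.index,
            "subtype": subtype,
            "t": t,
            "p": p,
            "mean_diff": diff,
            "direction": np.where(diff > 0, "up", "down"),
            "highest_in_subtype": highest & (diff > 0),
            "skipped": skipped,
        }
    )
    out["q"] = qvalues(out["p"].to_numpy())
    return out


def paired_differential(deltas: pd.DataFrame, subset: list[str] | None = None) -> pd.DataFrame:
    """Per-gene one-sample t of paired met-primary deltas against zero."""
    block = deltas if subset is None else deltas[subset]
    if block.shape[1] < 3:
        raise ValueError("need >=3 pairs")
    X = block.to_numpy(float)
    t, p = one_sample_t(X, 0.0, axis=1)
    with np.errstate(invalid="ignore"):
        m = np.nanmean(X, axis=1)
    out = pd.DataFrame(
        {
            "gene": block.index,
            "t": t,
            "p": p,
            "mean_diff": m,
            "direction": np.where(m > 0, "up", "down"),
            "degenerate": ~np.isfinite(t),
        }
    )
    out["q"] = qvalues(out["p"].to_numpy())
    return out


def de_gene_sets(de_table: pd.DataFrame, p_cut: float = 0.01, direction: str = "up",
                 require_highest: bool = False) -> list[str]:
    """Nominal-p gene set from a differential table."""
    sel = (de_table["p"] < p_cut) & (de_table["direction"] == direction)
    if require_highest and "highest_in_subtype" in de_table:
        sel &= de_table["highest_in_subtype"]
    return sorted(de_table.loc[sel, "gene"])


def gene_set_overlap(
    set_a, set_b, universe, method: str = "auto", id_a: str = "A", id_b: str = "B"
) -> dict:
    """One-sided overlap enrichment of two gene sets in a universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    A, B = set(set_a) & universe, set(set_b) & universe
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(universe) - a - b - c
    p, used = enrichment_test(a, b, c, d, method=method)
    return {
        "set_a": id_a,
        "set_b": id_b,
        "universe": len(universe),
        "both": a,
        "a_only": b,
        "b_only": c,
        "neither": d,
        "odds": odds_ratio(a, b, c, d),
        "p_one_sided": p,
        "method": used,
    }


def orthogonal_overlap_matrix(
    subtype_sets: dict[str, list[str]],
    paired_sets: dict[str, list[str]],
    universe,
    p_cut: float = 1e-6,
    method: str = "auto",
) -> tuple[pd.DataFrame, list[str]]:
    """All K x K overlaps between two families of subtype gene sets.

    Returns the p matrix (rows = subtype family, columns = paired family)
    and the consensus gene set: the union over subtypes k of
    (subtype-k set ∩ paired-k set) for diagonal cells passing ``p_cut``.
    """
    rows = sorted(subtype_sets)
    cols = sorted(paired_sets)
    P = pd.DataFrame(np.nan, index=rows, columns=cols)
    for r in rows:
        for c in cols:
            res = gene_set_overlap(subtype_sets[r], paired_sets[c], universe, method)
            P.loc[r, c] = res["p_one_sided"]
    consensus: set[str] = set()
    for k in set(rows) & set(cols):
        if P.loc[k, k] < p_cut:
            consensus |= set(subtype_sets[k]) & set(paired_sets[k])
    return P, sorted(consensus)


def signature_score(profiles: pd.DataFrame, reference: pd.Series, min_shared: int = 30
                    ) -> pd.DataFrame:
    """Pearson correlation of each sample with a centered reference profile."""
    shared = profiles.index.intersection(reference.index)
    rows = []
    ref = reference.loc[shared].to_numpy(float)
    X = profiles.loc[shared].to_numpy(float)
    for j, sample in enumerate(profiles.columns):
        x = X[:, j]
        obs = ~np.isnan(x) & ~np.isnan(ref)
        n = int(obs.sum())
        if n < min_shared:
            raise ValueError(f"sample {sample!r} shares only {n} genes with reference")
        r = float(np.corrcoef(x[obs], ref[obs])[0, 1])
        rows.append({"sample_id": sample, "reference_id": reference.name, "score": r,
                     "n_shared": n})
    return pd.DataFrame(rows)


def tf_enrichment(
    tf_sets: dict[str, list[str]],
    de_sets_by_family: dict[str, dict[str, list[str]]],
    tf_expression: pd.DataFrame,
    labels_by_family: dict[str, pd.Series],
    universe,
    tf_gene_of: dict[str, str] | None = None,
    overlap_cut: float = 1e-6,
    expr_cut: float = 0.05,
    method: str = "auto",
) -> pd.DataFrame:
    """Joint target-overlap + TF-expression screen across dataset families.

    A TF passes for subtype k iff (i) its target set overlaps the
    subtype-k up-gene set at ``overlap_cut`` in EVERY dataset family and
    (ii) its own gene's subtype-vs-rest t-test p is below ``expr_cut``
    with a consistent direction in every family. ``tf_gene_of`` maps TF
    set names to gene ids (identity for names present in the matrix).
    """
    tf_gene_of = tf_gene_of or {}
    families = sorted(de_sets_by_family)
    subtypes = sorted({k for fam in families for k in de_sets_by_family[fam]})
    rows = []
    for tf, targets in tf_sets.items():
        gene = tf_gene_of.get(tf, tf)
        if gene not in tf_expression.index:
            raise ValueError(f"TF gene {gene!r} absent from expression data")
        for k in subtypes:
            overlap_ps, expr_ps, directions = [], [], []
            for fam in families:
                res = gene_set_overlap(targets, de_sets_by_family[fam].get(k, []),
                                       universe, method)
                overlap_ps.append(res["p_one_sided"])
                de = differential_expression(
                    tf_expression.loc[[gene]], labels_by_family[fam], k
                ).iloc[0]
                expr_ps.append(de["p"])
                directions.append(de["direction"])
            passes = all(p < overlap_cut for p in overlap_ps) and all(
                p < expr_cut for p in expr_ps
            ) and len(set(directions)) == 1
            rows.append(
                {
                    "tf": tf,
                    "subtype": k,
                    "max_overlap_p": max(overlap_ps),
                    "max_expr_p": max(expr_ps),
                    "direction": directions[0] if len(set(directions)) == 1 else "mixed",
                    "passes": bool(passes),
                }
            )
    return pd.DataFrame(rows)


def annotation_enrichment(gene_set, annotation: dict[str, list[str]], universe,
                          method: str = "fisher") -> pd.DataFrame:
    """One-sided Fisher enrichment of every annotation term in a gene set."""
    if not annotation:
        raise ValueError("empty annotation")
    rows = []
    for term, members in annotation.items():
        res = gene_set_overlap(gene_set, members, universe, method=method,
                               id_a="query", id_b=term)
        rows.append({"term": term, "both": res["both"], "term_size": res["both"] + res["b_only"],
                     "odds": res["odds"], "p_one_sided": res["p_one_sided"]})
    return pd.DataFrame(rows).sort_values("p_one_sided", kind="stable").reset_index(drop=True)


def merge_ic50(table1: pd.DataFrame, table2: pd.DataFrame) -> pd.DataFrame:
    """Merge two drug x cell-line ln IC50 tables.

    Cells present in both are averaged; cells present in one pass
    through; cells in neither stay missing. Symmetric in argument order.
    """
    drugs = table1.index.union(table2.index)
    lines = table1.columns.union(table2.columns)
    a = table1.reindex(index=drugs, columns=lines)
    b = table2.reindex(index=drugs, columns=lines)
    return pd.concat([a, b]).groupby(level=0).mean().reindex(drugs)


def drug_response_association(
    ln_ic50: pd.DataFrame, labels: pd.Series, min_group: int = 3
) -> pd.DataFrame:
    """Welch t of ln IC50, subtype lines vs rest, per (drug, subtype).

    ``direction`` is "sensitive" when the subtype's mean ln IC50 is lower
    (greater drug effect at lower concentration). Drugs measured in fewer
    than ``min_group`` lines on either side are flagged ``skipped`` with
    p = NaN.
    """
    labels = labels.reindex(ln_ic50.columns)
    subtypes = sorted(labels.dropna().unique())
    if len(subtypes) < 2:
        raise ValueError("need >=2 subtypes")
    X = ln_ic50.to_numpy(float)
    pieces = []
    for lab in subtypes:
        mask = (labels == lab).to_numpy()
        t, p, diff = welch_t_groups(X[:, mask], X[:, ~mask])
        n_in = np.sum(~np.isnan(X[:, mask]), axis=1)
        n_out = np.sum(~np.isnan(X[:, ~mask]), axis=1)
        skipped = (n_in < min_group) | (n_out < min_group)
        pieces.append(
            pd.DataFrame(
                {
                    "drug": ln_ic50.index,
                    "subtype": lab,
                    "n_in": n_in,
                    "n_out": n_out,
                    "mean_diff": diff,
                    "t": t,
                    "p": np.where(skipped, np.nan, p),
                    "direction": np.where(diff < 0, "sensitive", "resistant"),
                    "skipped": skipped,
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)
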