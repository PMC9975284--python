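"""Nearest-centroid subtype assignment and concordance statistics.

A profile in SD-from-median units is assigned to the subtype whose
centroid column (binary {0,1} or signed {-1,0,1} over the model's marker
genes) it has the highest Pearson correlation with, computed
pairwise-complete over the genes the profile actually carries. The
signed scheme additionally requires the best correlation to be
significant (t transform of r) and otherwise falls back to a nondescript
label — used for externally supplied signed centroid files.

Concordance statistics summarize label agreement within patients
(plurality: one subtype strictly outnumbering the rest of a patient's
tumors) and across metastasis-primary pairs (agreement fraction plus
per-subtype one-sided Fisher 2x2 overlaps).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import fisher_one_sided, pearson_pvalue

__all__ = [
    "assign_subtype",
    "assign_signed_subtype",
    "classify_dataset",
    "plurality_concordance",
    "paired_concordance",
]


def _profile_correlations(x: np.ndarray, M: np.ndarray):
    """Pearson r between a profile (NaN-tolerant) and each centroid column."""
    obs = ~np.isnan(x)
    n = int(obs.sum())
    xs = x[obs]
    corrs = np.full(M.shape[1], np.nan)
    if n < 2:
        return corrs, n
    xc = xs - xs.mean()
    xnorm = np.sqrt((xc**2).sum())
    for j in range(M.shape[1]):
        m = M[obs, j].astype(float)
        mc = m - m.mean()
        mnorm = np.sqrt((mc**2).sum())
        if xnorm == 0 or mnorm == 0:
            continue
        corrs[j] = float((xc @ mc) / (xnorm * mnorm))
    return corrs, n


def assign_subtype(profile: pd.Series, model, min_genes: int = 30) -> dict:
    """Assign one profile to the best-correlated binary centroid.

    Correlations use the model genes observed in the profile; ties break
    to the lowest subtype index and are flagged. Fewer than ``min_genes``
    shared genes is an error.
    """
    x = profile.reindex(model.model_genes).to_numpy(float)
    corrs, n = _profile_correlations(x, model.centroids.to_numpy(float))
    if n < min_genes:
        raise ValueError(f"only {n} model genes observed (floor {min_genes})")
    return _pick_label(corrs, n, model.labels)


def _pick_label(corrs: np.ndarray, n: int, labels) -> dict:
    finite = np.where(np.isfinite(corrs), corrs, -np.inf)
    best = int(np.argmax(finite))
    tie = bool(np.sum(finite == finite[best]) > 1)
    out = {"label": labels[best], "n_genes": n, "tie": tie}
    for lab, r in zip(labels, corrs):
        out[f"corr_{lab}"] = r
    return out


def assign_signed_subtype(
    profile: pd.Series, model, alpha: float = 0.05,
    fallback_label: str = "c2", min_genes: int = 30,
) -> dict:
    """Signed-centroid assignment with a significance fallback.

    The best correlation is tested once (two-sided, t transform with
    n - 2 df); profiles whose best r is not significant at ``alpha`` get
    ``fallback_label``.
    """
    x = profile.reindex(model.model_genes).to_numpy(float)
    corrs, n = _profile_correlations(x, model.centroids.to_numpy(float))
    if n <= 2:
        raise ValueError(f"only {n} model genes observed; need >2")
    if n < min_genes:
        raise ValueError(f"only {n} model genes observed (floor {min_genes})")
    out = _pick_label(corrs, n, model.labels)
    r = out[f"corr_{out['label']}"]
    p = pearson_pvalue(r, n)
    out["p_value"] = p
    out["fallback"] = bool(not np.isfinite(r) or p >= alpha)
    if out["fallback"]:
        out["label"] = fallback_label
    return out


def classify_dataset(values: pd.DataFrame, model, min_genes: int = 30) -> pd.DataFrame:
    """Row-wise centroid assignment of every sample column.

    Samples that cannot be classified (too few shared model genes) are
    kept as flagged rows with a missing label rather than aborting the
    dataset.
    """
    if not model.model_genes:
        raise ValueError("empty subtype model")
    X = values.reindex(model.model_genes).to_numpy(float)
    M = model.centroids.to_numpy(float)
    rows = []
    for j, sample in enumerate(values.columns):
        corrs, n = _profile_correlations(X[:, j], M)
        if n < min_genes:
            row = {"sample_id": sample, "label": None, "n_genes": n, "tie": False,
                   "flag": "too_few_genes"}
            for lab in model.labels:
                row[f"corr_{lab}"] = np.nan
        else:
            row = {"sample_id": sample, **_pick_label(corrs, n, model.labels), "flag": ""}
        rows.append(row)
    return pd.DataFrame(rows)


def plurality_concordance(labels: pd.Series, patients: pd.Series) -> dict:
    """Within-patient plurality agreement over patients with >=2 tumors.

    A patient is concordant when one subtype strictly outnumbers every
    other among their tumors; tied modes count as non-concordant.
    """
    frame = pd.DataFrame({"label": labels, "patient": patients}).dropna()
    per_patient = []
    for patient, grp in frame.groupby("patient"):
        if len(grp) < 2:
            continue
        counts = grp["label"].value_counts()
        strict = len(counts) == 1 or counts.iloc[0] > counts.iloc[1]
        per_patient.append(
            {
                "patient_id": patient,
                "n_tumors": len(grp),
                "plurality_label": counts.index[0] if strict else None,
                "concordant": bool(strict),
            }
        )
    if not per_patient:
        raise ValueError("no patient has >=2 tumors")
    table = pd.DataFrame(per_patient)
    return {
        "per_patient": table,
        "n_patients": len(table),
        "plurality_fraction": float(table["concordant"].mean()),
    }


def paired_concordance(
    met_labels: pd.Series, primary_labels: pd.Series, pairs: pd.DataFrame
) -> dict:
    """Metastasis-vs-primary label agreement plus per-subtype 2x2 overlaps.

    For each subtype k, the 2x2 table crosses met==k against primary==k
    over all pairs, with a one-sided Fisher exact enrichment p.
    """
    met = pairs["met_sample"].map(met_labels)
    pri = pairs["primary_sample"].map(primary_labels)
    if met.isna().any() or pri.isna().any():
        raise ValueError("every pair needs both a metastasis and a primary label")
    agree = float((met.values == pri.values).mean())
    rows = []
    n = len(pairs)
    for lab in sorted(set(met) | set(pri)):
        a = int(((met == lab) & (pri == lab)).sum())
        b = int(((met == lab) & (pri != lab)).sum())
        c = int(((met != lab) & (pri == lab)).sum())
        d = n - a - b - c
        rows.append(
            {
                "subtype": lab,
                "both": a,
                "met_only": b,
                "primary_only": c,
                "neither": d,
                "p_one_sided": fisher_one_sided(a, b, c, d),
            }
        )
    return {
        "agreement_fraction": agree,
        "n_pairs": n,
        "overlap_table": pd.DataFrame(rows),
    }
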