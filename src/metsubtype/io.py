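"""Reading and writing the package's plain-text interchange formats.

Matrices are tab-delimited gene x sample tables (first column gene id,
header row of sample ids). Annotations are TSV with fixed column names.
Gene sets use the GMT convention (name, description, members). Subtype
models are a TSV of (gene, subtype, rank, weight) plus a JSON header.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

ANNOTATION_COLUMNS = [
    "sample_id",
    "patient_id",
    "study_id",
    "cancer_type",
    "sample_class",
    "biopsy_site",
]


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_annotations(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS[:5] if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")
    return ann


def write_annotations(ann: pd.DataFrame, path) -> None:
    cols = [c for c in ANNOTATION_COLUMNS if c in ann.columns]
    cols += [c for c in ann.columns if c not in cols]
    ann[cols].to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def write_model(model, prefix) -> None:
    """Serialize a SubtypeModel to ``<prefix>.tsv`` + ``<prefix>.json``."""
    prefix = Path(prefix)
    rows = []
    for label in model.labels:
        for rank, gene in enumerate(model.top_genes[label], start=1):
            rows.append((gene, label, rank, 1))
    pd.DataFrame(rows, columns=["gene", "subtype", "rank", "weight"]).to_csv(
        prefix.with_suffix(".tsv"), sep="\t", index=False
    )
    header = {
        "k": len(model.labels),
        "n_top": model.n_top,
        "labels": list(model.labels),
        "n_genes": len(model.gene_universe),
        "model_genes": list(model.centroids.index),
    }
    prefix.with_suffix(".json").write_text(json.dumps(header, indent=2) + "\n")


def read_model(prefix):
    from .subtyping import SubtypeModel  # local import avoids a cycle

    prefix = Path(prefix)
    header = json.loads(prefix.with_suffix(".json").read_text())
    table = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    top = {
        label: list(table.loc[table["subtype"] == label].sort_values("rank")["gene"])
        for label in header["labels"]
    }
    universe = header.get("model_genes") or list(dict.fromkeys(table["gene"]))
    return SubtypeModel.from_top_lists(top, universe, n_top=header["n_top"])
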