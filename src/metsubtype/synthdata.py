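"""Synthetic multi-study compendia with planted subtype structure.

The generators emulate the statistical structure the analysis pipeline
assumes: several studies, each covering several cancer types, with
study- and tissue-level location effects per gene; K expression subtypes
defined by disjoint blocks ("modules") of genes shifted in log2 space;
per-study missing genes; paired primary/metastasis profiles with a
controllable subtype-switch rate; subtype-enriched copy gains on top of a
ploidy mixture; subtype-enriched mutations; subtype-shifted ln IC50 drug
responses; and reference signature profiles / TF-target gene sets aligned
with the planted modules.

Expression noise is i.i.d. Gaussian in log2 space (sigma = ``noise_sd``),
exponentiated to a TPM-like positive scale; the pipeline normalizes
everything to SD units, so only relative structure matters. Real RNA-seq
count overdispersion, gene-length bias and CNA segment structure are
deliberately not modeled.

Reproducibility: one seed in :class:`SynthConfig`; each generator draws
from a named child seed so generators are bit-reproducible independently
of call order.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_compendium",
    "generate_paired_cohort",
    "generate_copy_number",
    "generate_mutations",
    "generate_drug_response",
    "generate_references",
]


@dataclass
class SynthConfig:
    """Parameters of the planted-structure generative model.

    Effect sizes are in SD units of the log2 noise; ``effect_size_delta``
    is the mean shift applied to a subtype's module genes in that
    subtype's samples.
    """

    n_studies: int = 4
    cancer_types_per_study: int = 3
    samples_per_study: int = 100
    n_genes: int = 2000
    k_subtypes: int = 4
    genes_per_subtype_module: int = 150
    effect_size_delta: float = 1.5
    study_shift_sd: float = 1.0
    tissue_shift_sd: float = 0.5
    noise_sd: float = 1.0
    missing_gene_fraction: float = 0.05
    multi_tumor_fraction: float = 0.2
    intra_patient_switch_rate: float = 0.0
    n_pairs: int = 100
    switch_rate: float = 0.1
    ploidy_weights: dict[int, float] = field(
        default_factory=lambda: {2: 0.8, 3: 0.1, 4: 0.1}
    )
    gain_baseline_rate: float = 0.05
    gain_enrichment_odds: float = 8.0
    n_mutation_genes: int = 102
    mutation_baseline_rate: float = 0.05
    mutation_rate_ratio: float = 5.0
    mutated_genes_per_subtype: int = 3
    n_drugs: int = 40
    cell_lines_per_subtype: int = 150
    sensitive_drugs_per_subtype: int = 2
    drug_effect: float = 1.0
    drug_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_studies": self.n_studies,
            "cancer_types_per_study": self.cancer_types_per_study,
            "samples_per_study": self.samples_per_study,
            "n_genes": self.n_genes,
            "k_subtypes": self.k_subtypes,
            "genes_per_subtype_module": self.genes_per_subtype_module,
            "n_pairs": self.n_pairs,
            "n_drugs": self.n_drugs,
            "cell_lines_per_subtype": self.cell_lines_per_subtype,
        }
        for name, v in counts.items():
            if int(v) != v or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        fractions = {
            "missing_gene_fraction": self.missing_gene_fraction,
            "switch_rate": self.switch_rate,
            "multi_tumor_fraction": self.multi_tumor_fraction,
            "intra_patient_switch_rate": self.intra_patient_switch_rate,
            "gain_baseline_rate": self.gain_baseline_rate,
            "mutation_baseline_rate": self.mutation_baseline_rate,
        }
        for name, v in fractions.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.k_subtypes * self.genes_per_subtype_module > self.n_genes:
            raise ValueError("subtype modules exceed the gene universe")
        if self.gain_enrichment_odds <= 0 or self.mutation_rate_ratio <= 0:
            raise ValueError("odds/rate multipliers must be positive")
        w = dict(self.ploidy_weights)
        if not w or any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise ValueError("ploidy_weights must be non-negative with positive sum")

    def rng(self, name: str) -> np.random.Generator:
        """Named child RNG: stable across runs and independent per generator."""
        key = zlib.crc32(name.encode("utf8"))
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), key]))


@dataclass
class GroundTruth:
    """Planted structure against which recovery is scored."""

    subtype_labels: list[str]
    genes: list[str]
    sample_subtype: dict[str, str] = field(default_factory=dict)
    gene_module: dict[str, str] = field(default_factory=dict)  # gene -> subtype
    pair_subtypes: dict[str, tuple[str, str]] = field(default_factory=dict)
    gain_enriched: set = field(default_factory=set)  # {(gene, subtype)}
    mutation_enriched: set = field(default_factory=set)
    sensitive: set = field(default_factory=set)  # {(drug, subtype)}

    def __post_init__(self):
        seen: dict[str, str] = {}
        for g, s in self.gene_module.items():
            if g in seen and seen[g] != s:
                raise ValueError(f"gene {g} mapped to two modules")
            seen[g] = s

    def module_genes(self, subtype: str) -> list[str]:
        return [g for g, s in self.gene_module.items() if s == subtype]

    def to_json(self, path) -> None:
        payload = {
            "subtype_labels": self.subtype_labels,
            "genes": self.genes,
            "sample_subtype": self.sample_subtype,
            "gene_module": self.gene_module,
            "pair_subtypes": {k: list(v) for k, v in self.pair_subtypes.items()},
            "gain_enriched": sorted(map(list, self.gain_enriched)),
            "mutation_enriched": sorted(map(list, self.mutation_enriched)),
            "sensitive": sorted(map(list, self.sensitive)),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _gene_universe(cfg: SynthConfig) -> list[str]:
    return [f"g{i:05d}" for i in range(cfg.n_genes)]


def _plant_modules(cfg: SynthConfig, rng: np.random.Generator) -> dict[str, str]:
    genes = _gene_universe(cfg)
    labels = [f"s{k + 1}" for k in range(cfg.k_subtypes)]
    chosen = rng.choice(
        cfg.n_genes, size=cfg.k_subtypes * cfg.genes_per_subtype_module, replace=False
    )
    module: dict[str, str] = {}
    for k, label in enumerate(labels):
        block = chosen[k * cfg.genes_per_subtype_module : (k + 1) * cfg.genes_per_subtype_module]
        for gi in block:
            module[genes[gi]] = label
    return module


def _batch_effects(cfg: SynthConfig, rng: np.random.Generator):
    studies = [f"study{j + 1}" for j in range(cfg.n_studies)]
    tissues = [f"ct{j + 1}" for j in range(cfg.cancer_types_per_study)]
    baseline = rng.normal(6.0, 1.5, size=cfg.n_genes)
    study_shift = {s: rng.normal(0.0, cfg.study_shift_sd, cfg.n_genes) for s in studies}
    tissue_shift = {t: rng.normal(0.0, cfg.tissue_shift_sd, cfg.n_genes) for t in tissues}
    return studies, tissues, baseline, study_shift, tissue_shift


def _log2_profile(cfg, rng, baseline, study_shift, tissue_shift, module_idx, subtype):
    x = baseline + study_shift + tissue_shift + rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
    x = x.copy()
    x[module_idx[subtype]] += cfg.effect_size_delta
    return x


def generate_compendium(cfg: SynthConfig):
    """Per-study raw expression tables, annotations, and ground truth.

    Expression is built in log2 space (gene baseline + study shift + tissue
    shift + module shift + noise) and exponentiated to a TPM-like positive
    scale. A ``missing_gene_fraction`` of genes is dropped per study, with
    independent draws per study. A ``multi_tumor_fraction`` of patients
    contributes 2-5 tumors sharing one subtype (unless an intra-patient
    switch fires), which exercises the plurality statistics downstream.
    """
    rng = cfg.rng("compendium")
    genes = _gene_universe(cfg)
    module = _plant_modules(cfg, cfg.rng("modules"))
    labels = [f"s{k + 1}" for k in range(cfg.k_subtypes)]
    module_idx = {
        lab: np.array([i for i, g in enumerate(genes) if module.get(g) == lab], int)
        for lab in labels
    }
    studies, tissues, baseline, study_shift, tissue_shift = _batch_effects(
        cfg, cfg.rng("batch")
    )

    truth = GroundTruth(subtype_labels=labels, genes=genes, gene_module=module)
    tables: dict[str, pd.DataFrame] = {}
    ann_rows = []
    patient_counter = 0
    for study in studies:
        cols, data = [], []
        n_done = 0
        while n_done < cfg.samples_per_study:
            patient_counter += 1
            patient = f"pt{patient_counter:05d}"
            n_tumors = 1
            if rng.random() < cfg.multi_tumor_fraction:
                n_tumors = int(rng.integers(2, 6))
            n_tumors = min(n_tumors, cfg.samples_per_study - n_done)
            pat_subtype = labels[int(rng.integers(cfg.k_subtypes))]
            tissue = tissues[int(rng.integers(cfg.cancer_types_per_study))]
            for t in range(n_tumors):
                subtype = pat_subtype
                if t > 0 and rng.random() < cfg.intra_patient_switch_rate:
                    others = [lab for lab in labels if lab != pat_subtype]
                    subtype = others[int(rng.integers(len(others)))]
                sample = f"{study}_smp{n_done + 1:04d}"
                x = _log2_profile(
                    cfg, rng, baseline, study_shift[study], tissue_shift[tissue],
                    module_idx, subtype,
                )
                cols.append(sample)
                data.append(2.0**x)
                truth.sample_subtype[sample] = subtype
                ann_rows.append(
                    {
                        "sample_id": sample,
                        "patient_id": patient,
                        "study_id": study,
                        "cancer_type": tissue,
                        "sample_class": "PDX",
                        "biopsy_site": tissue,
                    }
                )
                n_done += 1
        table = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
        n_drop = int(round(cfg.missing_gene_fraction * cfg.n_genes))
        if n_drop:
            drop = rng.choice(cfg.n_genes, size=n_drop, replace=False)
            table = table.drop(index=[genes[i] for i in drop])
        tables[study] = table
    annotations = pd.DataFrame(ann_rows)
    return tables, annotations, truth


def generate_paired_cohort(cfg: SynthConfig, truth: GroundTruth):
    """Paired primary/metastasis expression with a planted switch rate.

    Each pair shares a patient id; the metastasis keeps the primary's
    subtype with probability 1 - ``switch_rate``, otherwise switches to a
    uniformly drawn other subtype. Profiles are generated from the same
    log2 model as the compendium (complete, no per-study gene dropout).
    """
    rng = cfg.rng("paired")
    genes = truth.genes
    labels = truth.subtype_labels
    module_idx = {
        lab: np.array([i for i, g in enumerate(genes) if truth.gene_module.get(g) == lab], int)
        for lab in labels
    }
    studies, tissues, baseline, study_shift, tissue_shift = _batch_effects(
        cfg, cfg.rng("batch")
    )
    met_cols, met_data, pri_cols, pri_data, rows = [], [], [], [], []
    for i in range(cfg.n_pairs):
        study = studies[i % len(studies)]
        tissue = tissues[int(rng.integers(len(tissues)))]
        primary_st = labels[int(rng.integers(len(labels)))]
        met_st = primary_st
        if rng.random() < cfg.switch_rate:
            others = [lab for lab in labels if lab != primary_st]
            met_st = others[int(rng.integers(len(others)))]
        pair = f"pair{i + 1:04d}"
        met_id, pri_id = f"{pair}_met", f"{pair}_pri"
        for sid, st, cols, data in (
            (met_id, met_st, met_cols, met_data),
            (pri_id, primary_st, pri_cols, pri_data),
        ):
            x = _log2_profile(
                cfg, rng, baseline, study_shift[study], tissue_shift[tissue],
                module_idx, st,
            )
            cols.append(sid)
            data.append(2.0**x)
            truth.sample_subtype[sid] = st
        truth.pair_subtypes[pair] = (primary_st, met_st)
        rows.append(
            {
                "pair_id": pair,
                "met_sample": met_id,
                "primary_sample": pri_id,
                "patient_id": f"ppt{i + 1:04d}",
                "study_id": study,
                "cancer_type": tissue,
            }
        )
    met = pd.DataFrame(np.column_stack(met_data), index=genes, columns=met_cols)
    primary = pd.DataFrame(np.column_stack(pri_data), index=genes, columns=pri_cols)
    return met, primary, pd.DataFrame(rows), truth


def generate_copy_number(cfg: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Integer gene x sample copy table with subtype-enriched gains.

    Baseline copy equals the sample's ploidy (drawn from
    ``ploidy_weights``). Each (gene, sample) gains +1 or +2 copies with
    probability ``gain_baseline_rate``, raised by ``gain_enrichment_odds``
    (on the odds scale) for module genes in their own subtype's samples.
    """
    rng = cfg.rng("copynumber")
    samples = [s for s in truth.sample_subtype if "_met" not in s and "_pri" not in s]
    if not samples:
        samples = list(truth.sample_subtype)
    genes = truth.genes
    ploidies = np.array(sorted(cfg.ploidy_weights))
    w = np.array([cfg.ploidy_weights[p] for p in ploidies], float)
    w = w / w.sum()
    ploidy = rng.choice(ploidies, size=len(samples), p=w)

    p0 = cfg.gain_baseline_rate
    odds = cfg.gain_enrichment_odds
    p_enriched = odds * p0 / (1.0 - p0 + odds * p0)
    prob = np.full((len(genes), len(samples)), p0)
    gene_pos = {g: i for i, g in enumerate(genes)}
    subtype_of = np.array([truth.sample_subtype[s] for s in samples])
    for lab in truth.subtype_labels:
        cols = np.where(subtype_of == lab)[0]
        gidx = [gene_pos[g] for g in truth.module_genes(lab)]
        if len(cols) and len(gidx):
            prob[np.ix_(gidx, cols)] = p_enriched
            if odds != 1.0:
                truth.gain_enriched.update((genes[i], lab) for i in gidx)
    gains = (rng.random(prob.shape) < prob) * rng.integers(1, 3, size=prob.shape)
    copies = np.maximum(ploidy[None, :] + gains, 0).astype(int)
    return pd.DataFrame(copies, index=genes, columns=samples)


def generate_mutations(cfg: SynthConfig, truth: GroundTruth) -> pd.DataFrame:
    """Binary mutation table over a cancer-gene panel.

    Panel = ``mutated_genes_per_subtype`` planted genes per subtype (drawn
    from that subtype's module) plus background genes to ``n_mutation_genes``.
    Planted genes mutate at ``mutation_rate_ratio`` x the baseline rate in
    their subtype's samples.
    """
    rng = cfg.rng("mutations")
    samples = [s for s in truth.sample_subtype if "_met" not in s and "_pri" not in s]
    if not samples:
        samples = list(truth.sample_subtype)
    planted: list[str] = []
    for lab in truth.subtype_labels:
        pool = truth.module_genes(lab)
        take = min(cfg.mutated_genes_per_subtype, len(pool))
        picked = list(rng.choice(pool, size=take, replace=False))
        planted.extend(picked)
        if cfg.mutation_rate_ratio != 1.0:
            truth.mutation_enriched.update((g, lab) for g in picked)
    background_pool = [g for g in truth.genes if g not in set(planted)]
    n_bg = max(cfg.n_mutation_genes - len(planted), 0)
    panel = planted + list(rng.choice(background_pool, size=n_bg, replace=False))

    rate = np.full((len(panel), len(samples)), cfg.mutation_baseline_rate)
    subtype_of = np.array([truth.sample_subtype[s] for s in samples])
    for i, g in enumerate(panel):
        lab = truth.gene_module.get(g)
        if (g, lab) in truth.mutation_enriched:
            cols = np.where(subtype_of == lab)[0]
            rate[i, cols] = min(cfg.mutation_baseline_rate * cfg.mutation_rate_ratio, 0.95)
    table = (rng.random(rate.shape) < rate).astype(int)
    return pd.DataFrame(table, index=panel, columns=samples)


def generate_drug_response(cfg: SynthConfig, truth: GroundTruth):
    """Drug x cell-line ln IC50 plus a matched cell-line expression table.

    ln IC50 = per-drug baseline + Gaussian noise, minus ``drug_effect`` for
    cell lines of a subtype planted as sensitive to that drug. Cell-line
    expression follows the compendium's log2 model (single study), so the
    lines can be classified by the same centroid model.
    """
    rng = cfg.rng("drugs")
    labels = truth.subtype_labels
    genes = truth.genes
    module_idx = {
        lab: np.array([i for i, g in enumerate(genes) if truth.gene_module.get(g) == lab], int)
        for lab in labels
    }
    _, tissues, baseline, study_shift, tissue_shift = _batch_effects(cfg, cfg.rng("batch"))
    lines, data, ann_rows = [], [], []
    line_subtype = {}
    i = 0
    for lab in labels:
        for _ in range(cfg.cell_lines_per_subtype):
            i += 1
            line = f"cl{i:04d}"
            tissue = tissues[int(rng.integers(len(tissues)))]
            x = _log2_profile(
                cfg, rng, baseline, np.zeros(cfg.n_genes), tissue_shift[tissue],
                module_idx, lab,
            )
            lines.append(line)
            data.append(2.0**x)
            line_subtype[line] = lab
            truth.sample_subtype[line] = lab
            ann_rows.append(
                {
                    "sample_id": line,
                    "patient_id": line,
                    "study_id": "cellpanel",
                    "cancer_type": tissue,
                    "sample_class": "cell_line",
                    "biopsy_site": "",
                }
            )
    expr = pd.DataFrame(np.column_stack(data), index=genes, columns=lines)

    drugs = [f"drug{d + 1:03d}" for d in range(cfg.n_drugs)]
    if cfg.drug_effect != 0.0:
        flat = [(d, lab) for lab in labels for d in range(cfg.sensitive_drugs_per_subtype)]
        pick = rng.choice(cfg.n_drugs, size=min(len(flat), cfg.n_drugs), replace=False)
        for (offset, lab), di in zip(flat, pick):
            truth.sensitive.add((drugs[di], lab))
    base = rng.normal(3.0, 1.0, size=cfg.n_drugs)
    ic50 = base[:, None] + rng.normal(0.0, cfg.drug_noise_sd, (cfg.n_drugs, len(lines)))
    for d, drug in enumerate(drugs):
        for lab in labels:
            if (drug, lab) in truth.sensitive:
                cols = [j for j, ln in enumerate(lines) if line_subtype[ln] == lab]
                ic50[d, cols] -= cfg.drug_effect
    ic50 = pd.DataFrame(ic50, index=drugs, columns=lines)
    return ic50, expr, pd.DataFrame(ann_rows), truth


def generate_references(cfg: SynthConfig, truth: GroundTruth, fidelity: float = 1.0):
    """Reference differential profiles and TF-target / annotation gene sets.

    One centered reference profile per subtype (positive weight on its
    module genes, small noise elsewhere). TF-target and annotation sets
    contain a ``fidelity`` fraction of the module's genes, padded with
    random off-module genes to the module size.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise ValueError("fidelity must lie in [0, 1]")
    rng = cfg.rng("references")
    genes = truth.genes
    refs = {}
    for lab in truth.subtype_labels:
        v = rng.normal(0.0, 0.1, len(genes))
        idx = [i for i, g in enumerate(genes) if truth.gene_module.get(g) == lab]
        v[idx] += cfg.effect_size_delta
        refs[f"ref_{lab}"] = v
    references = pd.DataFrame(refs, index=genes)
    references -= references.mean(axis=0)

    def _noisy_set(mod: list[str]) -> list[str]:
        n_true = int(round(fidelity * len(mod)))
        kept = list(rng.choice(mod, size=n_true, replace=False)) if n_true else []
        off = [g for g in genes if truth.gene_module.get(g) is None]
        pad = list(rng.choice(off, size=len(mod) - n_true, replace=False))
        return sorted(kept + pad)

    tf_sets = {f"TF_{lab}": _noisy_set(truth.module_genes(lab)) for lab in truth.subtype_labels}
    annot_sets = {
        f"module_{lab}_term": _noisy_set(truth.module_genes(lab))
        for lab in truth.subtype_labels
    }
    return references, tf_sets, annot_sets


def config_to_dict(cfg: SynthConfig) -> dict:
    return asdict(cfg)
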