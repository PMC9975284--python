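# metsubtype

Pan-cancer molecular subtyping of metastatic tumors from multi-study
expression compendia.

Metastatic tumors profiled across dozens of independent studies (patient
biopsies, patient-derived xenografts, cell lines) cannot be compared
directly: platform, laboratory and tissue-of-origin effects dominate the
raw expression values. `metsubtype` implements the full analysis chain
that makes such a comparison possible and extracts tissue-agnostic
molecular subtypes from it:

1. **Cross-study normalization** — per study: optional TPM conversion and
   quantile normalization, collapse of multi-feature genes to the most
   variable feature, log2 transform, then per-gene conversion to unitless
   *SD-from-median* values within each study × cancer-type stratum,
   `x' = (x − median(x)) / SD(x)`. Paired metastasis–primary profiles are
   instead centered on the primary (whose own differential is identically
   zero) and scaled per study.
2. **Subtype discovery** — Monti-style consensus clustering: repeated
   subsampling, Ward-linkage hierarchical clustering on `1 − r` (Pearson)
   distance, a consensus matrix per candidate K with the CDF/Δ-area
   stability diagnostic, and one-shot reclassification of minor clusters
   into the major subtypes by best centroid fit.
3. **Centroid classification** — any profile in SD units is assigned to
   the subtype whose binary {0,1} top-gene centroid (or signed {−1,0,1}
   centroid with a significance fallback) it correlates with best;
   concordance statistics summarize agreement within patients (plurality)
   and across metastasis–primary pairs.
4. **Genomic and pharmacologic associations** — ploidy correction and
   gain/loss/amplification calling of gene copy values, CNA burden,
   per-gene copy-gain and mutation enrichment by subtype, differential
   expression (Welch and paired t), gene-set overlap on a stated universe
   (one-sided Fisher exact or signed chi-square), TF-target enrichment,
   reference-signature scoring, and drug-response association on ln IC50.
5. **Synthetic data** — a first-class generator of multi-study compendia
   with planted subtype modules, batch effects, missing genes, paired
   cohorts with a controllable subtype-switch rate, subtype-enriched copy
   gains and mutations, and subtype-shifted drug responses, with full
   ground truth for validating every stage.

The package is aimed at computational biologists who assemble their own
expression compendia and want a tested, reproducible implementation of
this subtype-discovery-and-association workflow, plus the means to verify
it recovers known structure before trusting it on real data.

## Worked example

Discover subtypes in a synthetic 4-study compendium (400 samples, 2,000
genes, four planted subtypes of 150 module genes each, shifted by 1.5 SD):

```python
import numpy as np, pandas as pd
from metsubtype import synthdata as sd, compendium as comp
from metsubtype.subtyping import (select_clustering_genes, consensus_cluster,
                                  reclassify_minor_clusters)
from metsubtype.classify import classify_dataset, plurality_concordance
from sklearn.metrics import adjusted_rand_score

cfg = sd.SynthConfig(seed=1)
tables, ann, truth = sd.generate_compendium(cfg)
raw = [comp.RawStudyTable(study_id=s, values=v) for s, v in tables.items()]
matrix, ann = comp.assemble_compendium(raw, ann, universe_rule="union")
compendium = comp.center_scale_within_strata(matrix, ann)

genes = select_clustering_genes(compendium.values, 1000, min_presence=360, seed=1)
result = consensus_cluster(compendium.values.loc[genes], k_range=[2, 3, 4, 5],
                           reps=60, subsample_fraction=0.8, seed=1)
labels, model = reclassify_minor_clusters(
    compendium.values, result.assignments[4],
    keep=sorted(result.assignments[4].unique()), n_top=200)

truth_labels = pd.Series(truth.sample_subtype).reindex(labels.index)
print("ARI vs planted subtypes:",
      round(adjusted_rand_score(truth_labels, labels), 3))
calls = classify_dataset(compendium.values, model).set_index("sample_id")
print("self-consistency:", (calls["label"] == labels).mean())
patients = ann.set_index("sample_id")["patient_id"]
res = plurality_concordance(calls["label"], patients.reindex(calls.index))
print(f"plurality concordance: {res['plurality_fraction']:.2%} "
      f"over {res['n_patients']} multi-tumor patients")
```

Output:

```
ARI vs planted subtypes: 0.987
self-consistency: 0.995
plurality concordance: 100.00% over 52 multi-tumor patients
```

The adjusted Rand index of 0.987 says the K=4 consensus partition almost
exactly reproduces the planted subtypes; self-consistency is the fraction
of training samples whose centroid classification matches their discovery
label; plurality concordance is the fraction of multi-tumor patients
whose tumors share a strict modal subtype.

The same pipeline is available from the shell:

```sh
metsubtype simulate --config cfg.yaml --outdir sim/
metsubtype normalize --config studies.yaml --annotations sim/annotations.tsv --out comp.tsv
metsubtype discover --in comp.tsv --k-min 2 --k-max 15 --reps 1000 --frac 0.8 \
    --seed 1 --k-work 7 --keep 1,2,3,4 --out-prefix disc
metsubtype classify --model disc_model --in comp.tsv --out calls.tsv
metsubtype concordance --calls calls.tsv --annotations sim/annotations.tsv --out conc.json
```

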