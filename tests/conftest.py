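import numpy as np
import pandas as pd
import pytest

from metsubtype import compendium as comp
from metsubtype import synthdata as sd


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: upper-tail hypergeometric sum for [[a,b],[c,d]].

    P(X >= a) where X ~ Hypergeom(N=a+b+c+d, K=a+b draws of the a+c
    successes), computed by direct summation of the pmf.
    """
    from scipy.stats import hypergeom

    N, K, n = a + b + c + d, a + c, a + b
    hi = min(K, n)
    return float(sum(hypergeom.pmf(k, N, K, n) for k in range(a, hi + 1)))


@pytest.fixture(scope="session")
def small_cfg():
    return sd.SynthConfig(
        n_studies=2,
        cancer_types_per_study=2,
        samples_per_study=60,
        n_genes=400,
        k_subtypes=4,
        genes_per_subtype_module=30,
        effect_size_delta=1.5,
        missing_gene_fraction=0.05,
        n_pairs=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """Generated tables + normalized compendium + truth for the small config."""
    tables, ann, truth = sd.generate_compendium(small_cfg)
    raw = [comp.RawStudyTable(study_id=s, values=v, units="tpm") for s, v in tables.items()]
    matrix, ann2 = comp.assemble_compendium(raw, ann, universe_rule="union")
    compendium = comp.center_scale_within_strata(matrix, ann2)
    labels = pd.Series(truth.sample_subtype).reindex(compendium.values.columns)
    return {
        "cfg": small_cfg,
        "tables": tables,
        "annotations": ann2,
        "compendium": compendium,
        "truth": truth,
        "labels": labels,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
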