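import numpy as np
import pandas as pd
import pytest

import crossmode as cm
from crossmode.categories import POE_CATEGORIES, InheritanceCategory as C


@pytest.fixture(scope="session")
def liver_design():
    return cm.make_design(tissues=["liver"])


@pytest.fixture()
def toy_matrix():
    """5 genes x 4 samples with hand-checkable counts."""
    counts = pd.DataFrame(
        {
            "s1": [100, 3, 0, 40, 7],
            "s2": [90, 0, 1, 50, 9],
            "s3": [110, 2, 0, 45, 8],
            "s4": [95, 1, 2, 55, 6],
        },
        index=[f"g{i}" for i in range(1, 6)],
    )
    return cm.CountMatrix(counts)


def poe_heavy_config(seed, n_genes=500):
    """Simulation mix weighted toward parent-of-origin/dominance classes,
    at the prescribed recovery-test conditions (phi=0.05, |effect|>=2)."""
    props = {C.NULL: 0.2, C.ADDITIVE: 0.2, C.COMPLEX: 0.04}
    for cat in POE_CATEGORIES:
        props[cat] = 0.07
    return cm.SimulationConfig(
        n_genes=n_genes,
        category_proportions=props,
        effect_low=2.0,
        effect_high=4.0,
        dispersion_log_mean=float(np.log(0.05)),
        dispersion_log_sd=0.0,
        seed=seed,
    )


def measure_recovery(seed, design):
    """Fraction of planted parent/dominance genes whose category the full
    filter -> TMM -> log-CPM -> group-means -> classify chain recovers."""
    cfg = poe_heavy_config(seed)
    truth = cm.assign_gene_truth(cfg)
    mat = cm.simulate_counts(design, truth, cfg)
    mat = cm.filter_low_expression(mat)
    logmat = cm.log_cpm(mat, cm.tmm_factors(mat))
    profiles = cm.group_means(logmat, design)
    planted = truth[truth["category"].isin([c.value for c in POE_CATEGORIES])]
    planted = planted[planted["gene_id"].isin(profiles["gene_id"])]
    calls = cm.classify_table(profiles, set(planted["gene_id"]))
    merged = calls.merge(
        planted[["gene_id", "category"]], on="gene_id", suffixes=("_called", "_true")
    )
    return float((merged["category_called"] == merged["category_true"]).mean())


def null_pvalue_fraction(seed, design, alpha=0.05):
    """Fraction of null genes with Welch p < alpha after the full
    normalization chain (including batch centering)."""
    cfg = cm.SimulationConfig(
        n_genes=1000,
        category_proportions={C.NULL: 1.0},
        dispersion_log_mean=float(np.log(0.05)),
        dispersion_log_sd=0.3,
        seed=seed,
    )
    truth = cm.assign_gene_truth(cfg)
    mat = cm.simulate_counts(design, truth, cfg)
    mat = cm.filter_low_expression(mat)
    logmat = cm.log_cpm(mat, cm.tmm_factors(mat))
    logmat = cm.batch_center(logmat, design, preserve=("group", "sex"))
    res = cm.de_test(logmat, design, "liver", 1, 4)
    return float((res["p_value"] < alpha).mean()), len(res)
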