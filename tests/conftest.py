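"""Shared fixtures: bundled catalogs and the default synthetic cohort."""
import numpy as np
import pandas as pd
import pytest

import leukotype as lk
from leukotype import simulate as sim


@pytest.fixture(scope="session")
def fusion_catalog():
    return lk.load_fusion_catalog()


@pytest.fixture(scope="session")
def hotspot_catalog():
    return lk.load_hotspot_catalog()


@pytest.fixture(scope="session")
def ruleset(fusion_catalog, hotspot_catalog):
    return lk.load_ruleset(None, fusion_catalog, hotspot_catalog)


@pytest.fixture(scope="session")
def default_cohort():
    """The default five-class cohort: 30 samples per class, seed 42."""
    spec = sim.CohortSpec(n_per_class={c: 30 for c in lk.KARYOTYPE_CLASSES},
                          seed=42)
    return sim.generate_cohort(spec)


@pytest.fixture(scope="session")
def default_features(default_cohort):
    """186-feature matrix and karyotype labels for the default cohort."""
    X = pd.DataFrame([lk.extract_features(s.dosage, s.maf)
                      for s in default_cohort.samples])
    y = default_cohort.truth["karyotype_class"].to_numpy()
    return X, y


@pytest.fixture(scope="session")
def masked_cohort():
    """Three-class cohort whose near-haploids are all genome-doubled.

    Masked near-haploids are dosage-identical to diploids, so separating
    them from the "other" class requires the MAF-derived features.
    """
    spec = sim.CohortSpec(
        n_per_class={"near_haploid": 12, "high_hyperdiploid": 12,
                     "other": 12},
        mask_prob=1.0, n_genes=3000, seed=7)
    cohort = sim.generate_cohort(spec)
    X = pd.DataFrame([lk.extract_features(s.dosage, s.maf)
                      for s in cohort.samples])
    y = cohort.truth["karyotype_class"].to_numpy()
    return cohort, X, y
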