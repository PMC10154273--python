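import numpy as np
import pandas as pd
import pytest

from famvc import (
    CovariateSpec,
    FitOptions,
    SimulationConfig,
    SubjectRecord,
    build_kinship_grm,
    fit_model,
    residualize,
    simulate_dataset,
)


@pytest.fixture
def mixed_subjects():
    """Three families: an MZ pair, a DZ pair with a younger sibling, and a
    singleton — the minimal structure exercising all kinship rules."""
    return [
        SubjectRecord("m1", "fam1", "2008-01-01", "MZ"),
        SubjectRecord("m2", "fam1", "2008-01-01", "MZ"),
        SubjectRecord("d1", "fam2", "2009-03-05", "DZ"),
        SubjectRecord("d2", "fam2", "2009-03-05", "DZ"),
        SubjectRecord("s1", "fam2", "2011-07-21", None),
        SubjectRecord("x1", "fam3", "2008-11-30", None),
    ]


@pytest.fixture(scope="session")
def ace_toy():
    """90 two-child families simulated from an additive-genetic-heavy ACE
    truth, with its no-CI fit — shared by several engine tests."""
    cfg = SimulationConfig(
        n_mz=30, n_dz=30, n_sib=30,
        fractions={"A": 0.6, "C": 0.2, "E": 0.2},
        age_slope=0.05, sex_effect=0.3, seed=5,
    )
    table, grm, truth = simulate_dataset(cfg)
    fit = fit_model(table, "pheno", "ACE", options=FitOptions(compute_ci=False))
    return {"table": table, "grm": grm, "truth": truth, "fit": fit, "config": cfg}


def residuals_and_obs(table, covariates=("age", "sex"), phenotype="pheno"):
    """Residualize and return (ResidualizedPhenotype, aligned observations)."""
    rp = residualize(table, CovariateSpec(tuple(covariates)), phenotype)
    obs = table.loc[rp.values.index, ["subject_id", "family_id", "visit"]].copy()
    return rp, obs
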