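"""Shared fixtures: small simulated populations and recovery experiments."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from layres import genparams as gp
from layres import animal_model as am
from layres.config import SimConfig
from layres.pedigree import PedigreeRelationship
from layres.simdata import (
    simulate_breeding_values,
    simulate_pedigree,
    simulate_population,
)

LNVAR = "ln_variance|25-83|1wk|batch"


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        n_generations=2, n_sires=8, n_dams_per_sire=3, n_offspring_per_dam=10,
        nab_sample_fraction=0.5, seed=5,
    )


@pytest.fixture(scope="session")
def small_pop(small_cfg):
    return simulate_population(small_cfg)


@pytest.fixture(scope="session")
def small_rel(small_pop):
    return PedigreeRelationship.from_pedigree(small_pop.pedigree)


@pytest.fixture(scope="session")
def small_dataset(small_pop):
    return gp.indicator_dataset(small_pop)


def _projection_truth(data, bvs, trait, cfg):
    """Additive variance of a derived trait by linear projection on the
    generative breeding values (level, env-sensitivity)."""
    d = data.merge(bvs, on="animal")
    m = d[trait].notna()
    X = np.column_stack(
        [np.ones(int(m.sum())), d.loc[m, "bv_level"], d.loc[m, "bv_env"]]
    )
    y = d.loc[m, trait].to_numpy()
    b = np.linalg.lstsq(X, y, rcond=None)[0]
    va = b[1] ** 2 * cfg.sigma2_a_level + b[2] ** 2 * cfg.sigma2_a_env
    return float(va), float(np.var(y, ddof=1))


@pytest.fixture(scope="session")
def recovery():
    """Ten replicate pipeline runs at the default study scale (~2,000 hens).

    For each seed: simulate, build the 1-week batch-reference indicator
    dataset, fit the ln(variance) animal model, and record the REML h2
    next to the generative truth (projection of the trait on the known
    breeding values).  Also records the weekly-EP-mean trait's additive
    variance estimate and truth for the generative-recovery invariant.
    """
    rows = []
    for seed in range(1, 11):
        cfg = SimConfig(seed=seed)
        pop = simulate_population(cfg)
        rel = PedigreeRelationship.from_pedigree(pop.pedigree)
        data = gp.indicator_dataset(pop, include_individual=False, intervals=(1,))
        # per-bird mean weekly EP over the laying period as a plain trait
        from layres import eggrecords as er

        egglog, removed = er.remove_super_biological(pop.egglog)
        weekly = er.aggregate_intervals(egglog, 1)
        sub = er.split_periods(weekly, 1, pop.hens)["25-83"]
        epw = sub.groupby("bird")["avg_daily_ep"].mean().rename("ep_weekly_mean")
        data = data.merge(epw, left_on="animal", right_index=True, how="left")

        rec = {"seed": seed}
        for trait, kind in ((LNVAR, "ln_variance"), ("ep_weekly_mean", "general")):
            spec = am.ModelSpec(response=trait, fixed=gp.EGG_FIXED)
            fit = am.reml_fit(spec, data, rel, compute_se=False)
            va_true, vp = _projection_truth(data, pop.breeding_values, trait, cfg)
            rec[f"{trait}:h2_est"] = fit.sigma2_a / fit.sigma2_p
            rec[f"{trait}:h2_true"] = va_true / vp
            rec[f"{trait}:va_est"] = fit.sigma2_a
            rec[f"{trait}:va_true"] = va_true
        # sign material for the qualitative checks
        sk = data["skewness|25-83|1wk|batch"]
        rec["frac_skew_negative"] = float((sk.dropna() < 0).mean())
        rows.append(rec)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def bivariate_recovery():
    """Ten replicates of bivariate REML on traits simulated with r_a = 0.8."""
    out = []
    for seed in range(1, 11):
        cfg = SimConfig(seed=seed, sigma2_a_level=0.5, sigma2_a_env=0.5,
                        r_a_level_env=0.8)
        ped = simulate_pedigree(cfg)
        bvs = simulate_breeding_values(ped, cfg)
        rel = PedigreeRelationship.from_pedigree(ped)
        rng = np.random.default_rng(seed + 1000)
        d = ped[ped["generation"] > 0].merge(bvs, on="animal")
        d = d.sample(n=2000, random_state=seed)
        data = pd.DataFrame({
            "animal": d["animal"],
            "t1": d["bv_level"] + rng.normal(0, np.sqrt(0.5), len(d)),
            "t2": d["bv_env"] + rng.normal(0, np.sqrt(0.5), len(d)),
        })
        fit = am.reml_fit_bivariate(
            am.ModelSpec(response="t1"), am.ModelSpec(response="t2"),
            data, rel, compute_se=False,
            nm_options={"xatol": 2e-4, "fatol": 1e-5},
        )
        r, _ = gp.correlation_from_bifit(fit)
        out.append(r)
    return np.array(out)
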