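"""Derived genetic parameters and the full experiment grid.

Heritability h2 = sigma2_a / sigma2_p with sigma2_p = sigma2_a +
sigma2_e, extended by sigma2_m when the maternal environmental component
is significant (LRT).  The genetic coefficient of variation is
GCV = |sqrt(sigma2_a) / mu|; for ln-scale traits (ln(variance)) the
ln-transform already implies a multiplicative model, so
GCV = sqrt(sigma2_a) with no division by the mean.  Genetic correlations
r_a = sigma_a12 / (sigma_a1 * sigma_a2) come from bivariate fits.

``run_experiment_grid`` runs the whole design on one simulated (or
loaded) population: univariate fits for all 24 resilience-indicator
variants, the four egg-production period traits and the two antibody
isotypes, a maternal-effect LRT per trait, and six bivariate
correlation grids mirroring the comparisons of interest (intervals,
life periods, indicator types, expected-production references,
indicators x egg production, indicators x antibodies).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import animal_model as am
from . import eggrecords as er
from . import indicators as ind
from .config import SimConfig
from .pedigree import PedigreeRelationship
from .simdata import Population, simulate_population

logger = logging.getLogger(__name__)

SIGNIFICANCE = 0.05
TENDENCY = 0.10


class ParameterError(ValueError):
    pass


def heritability(
    sigma2_a: float, sigma2_e: float, sigma2_m: float | None = None
) -> tuple[float, float | None]:
    """(h2, m2); m2 is None when no maternal component is present."""
    if min(sigma2_a, sigma2_e) < 0 or (sigma2_m is not None and sigma2_m < 0):
        raise ParameterError("variance components must be non-negative")
    s2p = sigma2_a + sigma2_e + (sigma2_m or 0.0)
    if s2p <= 0:
        raise ParameterError("zero phenotypic variance")
    h2 = sigma2_a / s2p
    m2 = None if sigma2_m is None else sigma2_m / s2p
    return h2, m2


def gcv(sigma2_a: float, mu: float | None = None, trait_kind: str = "general") -> float:
    """Genetic coefficient of variation.

    trait_kind 'ln_variance': sqrt(sigma2_a), mean not used.
    Otherwise |sqrt(sigma2_a)/mu|; a zero mean is an error.
    """
    if sigma2_a < 0:
        raise ParameterError("sigma2_a must be non-negative")
    if trait_kind == "ln_variance":
        return float(np.sqrt(sigma2_a))
    if mu is None or mu == 0:
        raise ParameterError("mean required (non-zero) for the general GCV")
    return float(abs(np.sqrt(sigma2_a) / mu))


def genetic_correlation(
    sigma_a12: float, sigma2_a1: float, sigma2_a2: float
) -> float:
    """r_a = sigma_a12 / (sigma_a1 * sigma_a2), clipped to [-1, 1]."""
    if sigma2_a1 <= 0 or sigma2_a2 <= 0:
        raise ParameterError("genetic variances must be positive")
    r = sigma_a12 / np.sqrt(sigma2_a1 * sigma2_a2)
    if abs(r) > 1:
        logger.warning("genetic correlation %.4f outside [-1, 1]; clipped", r)
        r = float(np.clip(r, -1.0, 1.0))
    return float(r)


@dataclass
class TraitResult:
    """Univariate analysis of one trait: chosen fit plus derived parameters."""

    trait: str
    fit: am.VarCompFit
    fit_base: am.VarCompFit
    maternal_p: float
    maternal_significant: bool
    h2: float
    m2: float | None
    gcv: float
    heritable: bool
    a_lrt_p: float

    def row(self) -> dict:
        se = self.fit.se
        return {
            "trait": self.trait,
            "sigma2_a": self.fit.sigma2_a,
            "se_sigma2_a": se.get("sigma2_a", np.nan),
            "sigma2_m": self.fit.sigma2_m if self.maternal_significant else np.nan,
            "sigma2_e": self.fit.sigma2_e,
            "sigma2_p": self.fit.sigma2_p,
            "h2": self.h2,
            "m2": self.m2 if self.m2 is not None else np.nan,
            "gcv": self.gcv,
            "mean": self.fit.mean,
            "maternal_p": self.maternal_p,
            "a_lrt_p": self.a_lrt_p,
            "heritable": self.heritable,
            "converged": self.fit.converged,
        }


def analyze_trait(
    trait: str,
    data: pd.DataFrame,
    rel: PedigreeRelationship,
    fixed: tuple,
    covariates: tuple = (),
    trait_kind: str = "general",
    test_maternal: bool = True,
    nm_options: dict | None = None,
) -> TraitResult:
    """Univariate animal-model analysis with maternal and additive LRTs.

    The maternal environmental effect is kept when its LRT is significant
    (p <= 0.05); heritability is declared when the additive LRT is
    significant.
    """
    spec0 = am.ModelSpec(response=trait, fixed=fixed, covariates=covariates)
    fit0 = am.reml_fit(spec0, data, rel, nm_options=nm_options)
    maternal_p = np.nan
    maternal_significant = False
    fit = fit0
    if test_maternal and "dam" in data.columns:
        spec_m = am.ModelSpec(
            response=trait, fixed=fixed, covariates=covariates, maternal=True
        )
        fit_m = am.reml_fit(spec_m, data, rel, nm_options=nm_options)
        _, maternal_p = am.lrt_variance_component(fit0, fit_m)
        maternal_significant = maternal_p <= SIGNIFICANCE
        if maternal_significant:
            fit = fit_m
    # additive LRT: same model (incl. maternal term if selected) with the
    # additive variance fixed ~0
    spec_chosen = spec0 if not maternal_significant else am.ModelSpec(
        response=trait, fixed=fixed, covariates=covariates, maternal=True
    )
    fit_no_a = _fit_without_additive(spec_chosen, data, rel, fit, nm_options)
    a_stat, a_p = am.lrt_variance_component(fit_no_a, fit)
    h2, m2 = heritability(
        fit.sigma2_a, fit.sigma2_e, fit.sigma2_m if maternal_significant else None
    )
    g = gcv(fit.sigma2_a, mu=fit.mean if trait_kind != "ln_variance" else None,
            trait_kind=trait_kind)
    return TraitResult(
        trait=trait, fit=fit, fit_base=fit0, maternal_p=float(maternal_p),
        maternal_significant=maternal_significant,
        h2=h2, m2=m2, gcv=g, heritable=a_p <= SIGNIFICANCE, a_lrt_p=float(a_p),
    )


def _fit_without_additive(spec, data, rel, fit_with, nm_options):
    """Reduced-model fit (additive variance ratio pinned at the floor) for
    the additive LRT, using the profiled restricted likelihood."""
    parts = am._prepare_univariate(spec, data, rel)
    has_m = fit_with.sigma2_m is not None and spec.maternal
    lam_a = am._LAM_LO
    if has_m:
        from scipy.optimize import minimize_scalar

        def obj(u):
            return am._profiled_m2ll(parts, lam_a, float(np.exp(u)))[0]

        res = minimize_scalar(
            obj, bounds=(np.log(am._LAM_LO), np.log(am._LAM_HI)),
            method="bounded", options={"xatol": 1e-6},
        )
        lam_m = float(np.exp(res.x))
        m2ll, s2e, _ = am._profiled_m2ll(parts, lam_a, lam_m)
        s2m = lam_m * s2e
        converged = bool(res.success)
    else:
        m2ll, s2e, _ = am._profiled_m2ll(parts, lam_a, None)
        s2m = None
        converged = True
    return am.VarCompFit(
        sigma2_a=lam_a * s2e, sigma2_e=s2e, sigma2_m=s2m,
        loglik=float(-0.5 * m2ll), converged=converged,
        method="direct", n_records=parts.n, rank_X=parts.rank_X,
        mean=float(parts.y.mean()),
    )


def correlation_from_bifit(fit: am.VarCompFit) -> tuple[float, float]:
    """(r_a, delta-method SE) from a bivariate fit."""
    r = genetic_correlation(fit.sigma_a12, fit.sigma2_a, fit.sigma2_a2)
    se = np.nan
    cov = fit.se.get("_cov")
    if cov is not None:
        names = fit.se["_names"]
        ix = [names.index(k) for k in ("sigma2_a", "sigma2_a2", "sigma_a12")]
        v1, v2, c = fit.sigma2_a, fit.sigma2_a2, fit.sigma_a12
        grad = np.zeros(len(names))
        grad[ix[0]] = -c / (2.0 * v1 ** 1.5 * np.sqrt(v2))
        grad[ix[1]] = -c / (2.0 * v2 ** 1.5 * np.sqrt(v1))
        grad[ix[2]] = 1.0 / np.sqrt(v1 * v2)
        var = float(grad @ cov @ grad)
        if var > 0:
            se = float(np.sqrt(var))
    return r, se


# ---------------------------------------------------------------------------
# pipeline: population -> analysis tables


EGG_FIXED = ("batch", "loc_rl", "mac")


def indicator_dataset(pop: Population, include_individual: bool = True,
                      intervals: tuple = (1, 2, 3)) -> pd.DataFrame:
    """Bird-level analysis table: 24 indicator variants + EP traits + effects.

    Applies the super-biological filter, builds interval/deviation series
    for every (period, interval, reference) variant, computes trimmed
    indicators, the four egg-production period totals, and the fixed
    effects (batch, location x row*level, maximum age-class).
    """
    egglog, removed = er.remove_super_biological(pop.egglog)
    if removed:
        logger.info("removed %d birds with >2 eggs/day spans", len(removed))
    hens = pop.hens[~pop.hens["bird"].isin(removed)]
    # birds leaving before 25 weeks of age never enter the analysis
    hens = hens[hens["end_day"] >= er.ANCHOR_DAY].reset_index(drop=True)

    dev_sets = {}
    weekly_full = None
    for ivw in intervals:
        series = er.aggregate_intervals(egglog, ivw)
        if ivw == 1:
            weekly_full = series
        by_period = er.split_periods(series, ivw, hens)
        for period, sub in by_period.items():
            dev_sets[(period, ivw, "batch")] = er.deviations_batch(sub, hens)
    if include_individual and weekly_full is not None:
        curves = er.fit_individual_curves(weekly_full)
        by_period = er.split_periods(weekly_full, 1, hens)
        for period, sub in by_period.items():
            dev_sets[(period, 1, "individual")] = er.deviations_individual(
                sub, curves, 1
            )

    table = ind.compute_indicator_table(dev_sets)

    # egg production totals per period
    ep = _ep_period_totals(egglog, hens)
    out = hens.set_index("bird")[["batch", "location", "rowlevel", "dam"]].join(
        [table, ep]
    )
    out["loc_rl"] = out["location"].astype(str) + ":" + out["rowlevel"].astype(str)
    out["mac"] = ind.max_age_classes(hens).reindex(out.index)
    out.index.name = "bird"
    out = out.reset_index().rename(columns={"bird": "animal"})
    return out


def _ep_period_totals(egglog: pd.DataFrame, hens: pd.DataFrame) -> pd.DataFrame:
    """Egg counts per life period (full, early, 25-83, 83-end) per bird."""
    day25 = er.ANCHOR_DAY
    day83 = er.DAY_83
    rate = egglog["eggs"] / (egglog["end_day"] - egglog["start_day"] + 1)

    def overlap_eggs(lo, hi):
        s = np.maximum(egglog["start_day"], lo)
        e = np.minimum(egglog["end_day"], hi)
        days = np.clip(e - s + 1, 0, None)
        return (rate * days).groupby(egglog["bird"]).sum()

    big = 10**9
    out = pd.DataFrame(
        {
            "ep_full": overlap_eggs(-big, big),
            "ep_early": overlap_eggs(-big, day25 - 1),
            "ep_25_83": overlap_eggs(day25, day83 - 1),
            "ep_83_end": overlap_eggs(day83, big),
        }
    )
    out.index.name = "bird"
    return out.reindex(hens["bird"])


EP_TRAITS = ("ep_full", "ep_early", "ep_25_83", "ep_83_end")


@dataclass
class GridResult:
    univariate: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    trait_results: dict[str, TraitResult] = field(repr=False, default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _corr_cell(t1, t2, results, data, rel, nab_specs, nm_options):
    """One bivariate cell; returns dict with r_a, se or a not-tested reason."""
    r1, r2 = results.get(t1), results.get(t2)
    for t, r in ((t1, r1), (t2, r2)):
        if r is None:
            return {"trait1": t1, "trait2": t2, "r_a": np.nan, "se": np.nan,
                    "status": f"not tested: {t} missing"}
        if not r.heritable:
            return {"trait1": t1, "trait2": t2, "r_a": np.nan, "se": np.nan,
                    "status": "not tested: trait not heritable"}
    spec1 = _bi_spec(t1, r1, nab_specs)
    spec2 = _bi_spec(t2, r2, nab_specs)
    start = {
        "sigma2_a": r1.fit.sigma2_a, "sigma2_e": r1.fit.sigma2_e,
        "sigma2_a2": r2.fit.sigma2_a, "sigma2_e2": r2.fit.sigma2_e,
    }
    try:
        bifit = am.reml_fit_bivariate(
            spec1, spec2, data, rel, nm_options=nm_options, start=start
        )
        r, se = correlation_from_bifit(bifit)
        status = "ok" if bifit.converged else "did not converge"
        return {"trait1": t1, "trait2": t2, "r_a": r, "se": se, "status": status}
    except (am.ModelError, ParameterError) as exc:
        return {"trait1": t1, "trait2": t2, "r_a": np.nan, "se": np.nan,
                "status": f"failed: {exc}"}


def _bi_spec(trait, result, nab_specs):
    if trait in nab_specs:
        return nab_specs[trait]
    return am.ModelSpec(response=trait, fixed=EGG_FIXED,
                        maternal=result.maternal_significant)


def run_experiment_grid(
    cfg: SimConfig,
    pop: Population | None = None,
    nm_options: dict | None = None,
    bivariate: bool = True,
    out_dir: str | Path | None = None,
) -> GridResult:
    """Univariate fits for the full trait set plus six correlation grids.

    The grids compare: resilience indicators across interval lengths,
    across life periods, across indicator types, batch vs individual
    expected production, indicators x egg-production traits, and
    indicators x antibody traits.  A trait whose additive variance is not
    significant (LRT) is excluded from the grids with a recorded reason.
    """
    t0 = time.time()
    if pop is None:
        pop = simulate_population(cfg)
    ped = pop.pedigree
    rel = PedigreeRelationship.from_pedigree(ped)
    data = indicator_dataset(pop)

    nab = pop.antibodies
    nab_specs = {}
    nab_data = {}
    for iso in sorted(nab["isotype"].unique()):
        col = f"nab_{iso}"
        sub = nab[nab["isotype"] == iso].rename(columns={"titer": col})
        nab_data[col] = sub[["animal", col, "plate", "age_weeks", "sex"]]
        nab_specs[col] = am.ModelSpec(
            response=col, fixed=("plate", "sex"), covariates=("age_weeks",)
        )

    variants = [
        ind.variant_name(stat, period, ivw, ref)
        for (period, ivw, ref) in ind.standard_variant_keys()
        for stat in ind.STATS
    ]
    results: dict[str, TraitResult] = {}
    rows = []
    for trait in variants + list(EP_TRAITS):
        kind = "ln_variance" if trait.startswith("ln_variance") else "general"
        try:
            res = analyze_trait(trait, data, rel, EGG_FIXED, trait_kind=kind,
                                nm_options=nm_options)
            results[trait] = res
            rows.append(res.row())
        except (am.ModelError, ParameterError) as exc:
            logger.warning("analysis of %s failed: %s", trait, exc)
            rows.append({"trait": trait, "converged": False, "heritable": False,
                         "status": str(exc)})
    for col, sub in nab_data.items():
        merged = sub.merge(
            ped[["animal", "dam"]], on="animal", how="left"
        )
        res = analyze_trait(col, merged, rel, fixed=("plate", "sex"),
                            covariates=("age_weeks",), test_maternal=False,
                            nm_options=nm_options)
        results[col] = res
        rows.append(res.row())
    univariate = pd.DataFrame(rows)

    correlations: dict[str, pd.DataFrame] = {}
    if bivariate:
        nab_full = {
            col: data.merge(sub, on="animal", how="outer")
            for col, sub in nab_data.items()
        }

        def grid(name, pairs, frame_for=None):
            cells = []
            for t1, t2 in pairs:
                frame = frame_for(t1, t2) if frame_for else data
                cells.append(_corr_cell(t1, t2, results, frame, rel,
                                        nab_specs, nm_options))
            correlations[name] = pd.DataFrame(cells)

        periods = ind.PERIODS
        stats = ind.STATS
        v = ind.variant_name
        # 1. across interval lengths (batch reference)
        pairs = [
            (v(s, p, a, "batch"), v(s, p, b, "batch"))
            for s in stats for p in periods
            for a, b in ((1, 2), (1, 3), (2, 3))
        ]
        grid("intervals", pairs)
        # 2. across life periods (1-week, batch)
        grid("periods", [
            (v(s, "25-83", 1, "batch"), v(s, "83-end", 1, "batch")) for s in stats
        ])
        # 3. across indicator types (same period, 1-week, batch)
        grid("indicator_types", [
            (v(a, p, 1, "batch"), v(b, p, 1, "batch"))
            for p in periods
            for a, b in (("ln_variance", "skewness"),
                         ("ln_variance", "autocorrelation"),
                         ("skewness", "autocorrelation"))
        ])
        # 4. batch vs individual expected production
        grid("references", [
            (v(s, p, 1, "batch"), v(s, p, 1, "individual"))
            for s in stats for p in periods
        ])
        # 5. indicators (1-week, batch) x egg-production periods
        grid("indicators_x_ep", [
            (v(s, p, 1, "batch"), ep)
            for s in stats for p in periods for ep in EP_TRAITS
        ])
        # 6. indicators (1-week, batch) x antibody traits
        grid("indicators_x_nab", [
            (v(s, p, 1, "batch"), col)
            for s in stats for p in periods for col in sorted(nab_data)
        ], frame_for=lambda t1, t2: nab_full[t2])

    manifest = {
        "seed": cfg.seed,
        "n_hens": int(data.shape[0]),
        "n_animals": int(rel.n),
        "n_univariate": len(rows),
        "elapsed_s": round(time.time() - t0, 2),
    }
    result = GridResult(univariate=univariate, correlations=correlations,
                        trait_results=results, manifest=manifest)
    if out_dir is not None:
        write_report(result, out_dir)
    return result


def write_report(result: GridResult, out_dir: str | Path) -> None:
    """CSV tables (2-decimal rounding as in the report layer) + manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    uni = result.univariate.copy()
    for c in uni.columns:
        if uni[c].dtype.kind == "f":
            uni[c] = uni[c].round(3)
    uni.to_csv(out / "univariate.csv", index=False)
    for name, frame in result.correlations.items():
        f = frame.copy()
        for c in ("r_a", "se"):
            if c in f:
                f[c] = f[c].round(2)
        f.to_csv(out / f"correlations_{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))
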