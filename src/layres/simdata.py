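"""Synthetic laying-hen populations with known genetic architecture.

The generator produces, from one seed: a multi-generation hierarchical
pedigree spread over locations and batches, per-animal breeding values
for lay-probability level, log disturbance-sensitivity and an antibody
trait, a daily Bernoulli egg-laying process aggregated into 1-4 day
collection spans, batch-level disturbance events, mortality/censoring,
and a once-measured antibody titer on a subset of both sexes.

Daily lay model (hen i, day-of-age t, batch b):

    P(egg) = sigmoid( base(t) + bv_level_i + mat_i + cage + batch
                      - D_b(t) * exp(bv_env_i) )

where ``base`` rises from onset of lay to a plateau near 0.95 by ~30
weeks and declines on the logit scale after ~60 weeks, and ``D_b(t)`` is
the summed depth of disturbance events active in batch b.  The
multiplicative ``exp(bv_env)`` sensitivity makes the within-hen variance
of production deviations heritable on the log scale without forcing
heritable differences in mean production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig
from . import pedigree as pedmod

DAYS_PER_WEEK = 7
CAGING_WEEK = 17  # recording starts at individual caging


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def simulate_pedigree(cfg: SimConfig) -> pd.DataFrame:
    """Hierarchical mating design over discrete generations.

    Generation 0 founders: ``n_sires`` males and ``n_sires*n_dams_per_sire``
    females with unknown parents.  Each later generation mates ``n_sires``
    males (sampled from the previous generation for g >= 2) with
    ``n_dams_per_sire`` dams each, ``n_offspring_per_dam`` offspring per
    dam, sex ratio 1:1.  Every animal is assigned a location, batch and
    (females) a row*level cage identifier.
    """
    rng = _rng(cfg, 0)
    rows = []
    next_id = 1
    batch_codes = [
        (loc, f"L{loc}B{b}")
        for loc in range(1, cfg.n_locations + 1)
        for b in range(1, cfg.n_batches_per_location + 1)
    ]

    def assign_env(n, gen):
        ix = rng.integers(0, len(batch_codes), size=n)
        locs = np.array([batch_codes[i][0] for i in ix])
        batches = np.array([f"G{gen}{batch_codes[i][1]}" for i in ix])
        rls = rng.integers(1, cfg.n_rowlevels + 1, size=n)
        return locs, batches, rls

    founders_m = []
    founders_f = []
    locs, batches, rls = assign_env(cfg.n_sires, 0)
    for k in range(cfg.n_sires):
        rows.append((next_id, 0, 0, "M", 0, locs[k], batches[k], 0))
        founders_m.append(next_id)
        next_id += 1
    nf = cfg.n_sires * cfg.n_dams_per_sire
    locs, batches, rls = assign_env(nf, 0)
    for k in range(nf):
        rows.append((next_id, 0, 0, "F", 0, locs[k], batches[k], rls[k]))
        founders_f.append(next_id)
        next_id += 1

    males, females = founders_m, founders_f
    for gen in range(1, cfg.n_generations + 1):
        sires = list(rng.choice(males, size=cfg.n_sires, replace=False)) \
            if len(males) >= cfg.n_sires else list(males)
        dams_pool = rng.permutation(females)
        need = cfg.n_sires * cfg.n_dams_per_sire
        if len(dams_pool) < need:
            raise ConfigError("not enough dams for the mating design")
        dams = dams_pool[:need]
        n_off = len(sires) * cfg.n_dams_per_sire * cfg.n_offspring_per_dam
        locs, batches, rls = assign_env(n_off, gen)
        sexes = rng.permutation(
            np.array(["F", "M"])[np.arange(n_off) % 2]
        )
        new_m, new_f = [], []
        k = 0
        for si, sire in enumerate(sires):
            for dj in range(cfg.n_dams_per_sire):
                dam = dams[si * cfg.n_dams_per_sire + dj]
                for _ in range(cfg.n_offspring_per_dam):
                    sex = sexes[k]
                    rows.append(
                        (next_id, sire, dam, sex, gen, locs[k], batches[k],
                         rls[k] if sex == "F" else 0)
                    )
                    (new_f if sex == "F" else new_m).append(next_id)
                    next_id += 1
                    k += 1
        males, females = new_m, new_f

    return pd.DataFrame(
        rows,
        columns=["animal", "sire", "dam", "sex", "generation",
                 "location", "batch", "rowlevel"],
    )


def genetic_covariance(cfg: SimConfig) -> np.ndarray:
    """3x3 additive covariance over (level, env-sensitivity, nab)."""
    sl = np.sqrt(cfg.sigma2_a_level)
    se = np.sqrt(cfg.sigma2_a_env)
    sn = np.sqrt(cfg.sigma2_a_nab)
    G0 = np.array(
        [
            [sl * sl, cfg.r_a_level_env * sl * se, 0.0],
            [cfg.r_a_level_env * sl * se, se * se, cfg.r_a_nab_env * se * sn],
            [0.0, cfg.r_a_nab_env * se * sn, sn * sn],
        ]
    )
    return G0


def simulate_breeding_values(
    ped: pd.DataFrame,
    cfg: SimConfig,
    covariance: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-animal breeding values and maternal environmental effects.

    Founders are N(0, G0); non-founders are mid-parent plus a Mendelian
    deviation with covariance ``b_i * G0`` where
    ``b_i = 1 - 0.25*(1+F_s) - 0.25*(1+F_d)`` over known parents (so
    0.5*(1 - (F_s+F_d)/2) when both are known).  The maternal effect an
    animal experiences is one N(0, sigma2_m) draw per dam (iid per animal
    when the dam is unknown).
    """
    G0 = genetic_covariance(cfg) if covariance is None else np.asarray(covariance)
    w, v = np.linalg.eigh((G0 + G0.T) / 2)
    if np.any(w < -1e-10 * max(1.0, w.max(initial=0.0))):
        raise ConfigError("genetic covariance matrix is not positive semi-definite")
    L = v @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ v.T

    sire_ix, dam_ix, _ = pedmod._parent_indices(ped)
    F = pedmod.inbreeding(ped)
    n = len(ped)
    rng = _rng(cfg, 1)
    z = rng.standard_normal((n, 3))
    bv = np.zeros((n, 3))
    for i in range(n):
        s, d = sire_ix[i], dam_ix[i]
        b = 1.0
        mid = np.zeros(3)
        if s >= 0:
            b -= 0.25 * (1.0 + F[s])
            mid += 0.5 * bv[s]
        if d >= 0:
            b -= 0.25 * (1.0 + F[d])
            mid += 0.5 * bv[d]
        bv[i] = mid + np.sqrt(b) * (L @ z[i])

    dam_ids = ped["dam"].to_numpy()
    mat = np.zeros(n)
    sd_m = np.sqrt(cfg.sigma2_m)
    dam_draw: dict[int, float] = {}
    for i, d in enumerate(dam_ids):
        if d == 0:
            mat[i] = sd_m * rng.standard_normal()
        else:
            if d not in dam_draw:
                dam_draw[d] = sd_m * rng.standard_normal()
            mat[i] = dam_draw[d]

    return pd.DataFrame(
        {
            "animal": ped["animal"].to_numpy(),
            "bv_level": bv[:, 0],
            "bv_env": bv[:, 1],
            "bv_nab": bv[:, 2],
            "maternal_effect": mat,
        }
    )


def _baseline_logit(days: np.ndarray, onset_day: float, cfg: SimConfig) -> np.ndarray:
    """Logit lay probability trajectory for one hen (before genetic terms)."""
    plateau_logit = _logit(cfg.plateau_p)
    weeks = days / DAYS_PER_WEEK
    onset_week = onset_day / DAYS_PER_WEEK
    rise_span = max(cfg.plateau_week - onset_week, 0.5)
    frac = np.clip((weeks - onset_week) / rise_span, 0.0, 1.0)
    base = plateau_logit * frac
    decline = np.clip(weeks - cfg.decline_start_week, 0.0, None)
    base = base - cfg.decline_logit_per_week * decline
    base = np.where(days < onset_day, -np.inf, base)
    return base


def _batch_spans(start_day: int, end_day: int, cfg: SimConfig,
                 rng: np.random.Generator) -> list[tuple[int, int, bool]]:
    """Collection spans (start, end inclusive, imputed) covering a batch."""
    lengths = np.array(sorted(cfg.collection_span_days))
    probs = np.array([cfg.collection_span_days[int(k)] for k in lengths])
    spans = []
    d = start_day
    while d <= end_day:
        ln = int(rng.choice(lengths, p=probs))
        spans.append([d, min(d + ln - 1, end_day), False])
        d += ln
    # merge a fraction of adjacent span pairs into longer, flagged spans
    merged = []
    i = 0
    while i < len(spans):
        if i + 1 < len(spans) and rng.random() < cfg.imputed_fraction:
            merged.append([spans[i][0], spans[i + 1][1], True])
            i += 2
        else:
            merged.append(spans[i])
            i += 1
    return [(int(a), int(b), bool(f)) for a, b, f in merged]


def simulate_egg_log(
    ped: pd.DataFrame, bvs: pd.DataFrame, cfg: SimConfig,
    disturbances: bool = True,
    batch_events: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily Bernoulli laying aggregated to collection-span records.

    Returns ``(egglog, hens)``: egglog has one row per (bird, span) with
    columns bird/start_day/end_day/eggs/imputed; hens has one row per
    female with batch, location, rowlevel, death_day (NaN if censored)
    and end_day (death or batch emptying).

    ``batch_events`` overrides the random disturbance regime with fixed
    events per batch, as {batch_id: [(start_day, end_day, depth), ...]}
    (for controlled experiments; batches absent from the dict get none).
    """
    rng = _rng(cfg, 2)
    hens = ped[(ped["sex"] == "F") & (ped["generation"] > 0)].merge(
        bvs, on="animal"
    )
    lo, hi = cfg.batch_end_age_weeks
    batches = sorted(hens["batch"].unique())
    batch_end = {b: int(rng.integers(lo, hi + 1)) * DAYS_PER_WEEK for b in batches}

    # batch-level disturbance events and environmental effects
    events: dict[str, list[tuple[float, float, float]]] = {}
    batch_eff = {}
    for b in batches:
        weeks_active = batch_end[b] / DAYS_PER_WEEK - CAGING_WEEK
        lam = cfg.disturbance_rate * weeks_active / 100.0
        k = rng.poisson(lam) if disturbances and batch_events is None else 0
        evs = [] if batch_events is None else [
            tuple(map(float, e)) for e in batch_events.get(b, [])
        ]
        for _ in range(k):
            start_w = rng.uniform(CAGING_WEEK, batch_end[b] / DAYS_PER_WEEK)
            dur_w = rng.exponential(cfg.disturbance_duration_weeks)
            depth = rng.gamma(2.0, cfg.disturbance_depth / 2.0)
            evs.append((start_w * DAYS_PER_WEEK, (start_w + dur_w) * DAYS_PER_WEEK, depth))
        events[b] = evs
        batch_eff[b] = rng.normal(0.0, np.sqrt(cfg.sigma2_batch))

    rl_eff = {
        (loc, rl): rng.normal(0.0, np.sqrt(cfg.sigma2_rowlevel))
        for loc in hens["location"].unique()
        for rl in range(0, cfg.n_rowlevels + 1)
    }

    log_frames = []
    hen_frames = []
    start_day = CAGING_WEEK * DAYS_PER_WEEK
    for b in batches:
        sub = hens[hens["batch"] == b]
        end_day = batch_end[b]
        days = np.arange(start_day, end_day + 1)
        ndays = len(days)
        nh = len(sub)
        if nh == 0:
            continue
        birds = sub["animal"].to_numpy()
        bv_level = sub["bv_level"].to_numpy()
        bv_env = sub["bv_env"].to_numpy()
        mat = sub["maternal_effect"].to_numpy()
        locs = sub["location"].to_numpy()
        rls = sub["rowlevel"].to_numpy()

        onset_w = np.clip(
            rng.normal(cfg.onset_mean_weeks, cfg.onset_sd_weeks, size=nh), 18.0, 25.0
        )
        onset_day = np.round(onset_w * DAYS_PER_WEEK)

        # mortality: weekly hazard -> geometric death week, day uniform in week
        u = rng.random(nh)
        h = cfg.weekly_mortality_hazard
        if h > 0:
            death_week_offset = np.floor(np.log(u) / np.log1p(-h))
            death_day = (
                start_day
                + death_week_offset * DAYS_PER_WEEK
                + rng.integers(0, DAYS_PER_WEEK, size=nh)
            )
        else:
            death_day = np.full(nh, np.inf)
        last_day = np.minimum(death_day, end_day)

        D = np.zeros(ndays)
        for s, e, depth in events[b]:
            D += depth * ((days >= s) & (days < e))

        # baseline logit trajectory, vectorized over hens x days
        plateau_logit = _logit(cfg.plateau_p)
        weeks = days / DAYS_PER_WEEK
        onset_wk = onset_day[:, None] / DAYS_PER_WEEK
        rise_span = np.maximum(cfg.plateau_week - onset_wk, 0.5)
        frac = np.clip((weeks[None, :] - onset_wk) / rise_span, 0.0, 1.0)
        base = plateau_logit * frac
        base -= cfg.decline_logit_per_week * np.clip(
            weeks[None, :] - cfg.decline_start_week, 0.0, None
        )
        env_fixed = batch_eff[b] + np.array(
            [rl_eff[(lo, rl)] for lo, rl in zip(locs, rls)]
        )
        logits = (
            base
            + (bv_level + mat + env_fixed)[:, None]
            - np.exp(bv_env)[:, None] * D[None, :]
        )
        # individual disturbance events (injury, transient illness)
        if disturbances and cfg.indiv_disturbance_rate > 0:
            weeks_active = (end_day - start_day) / DAYS_PER_WEEK
            lam_i = cfg.indiv_disturbance_rate * weeks_active / 100.0
            n_ev = rng.poisson(lam_i, size=nh)
            sens = np.exp(bv_env)
            for r in np.nonzero(n_ev)[0]:
                for _ in range(n_ev[r]):
                    s0 = rng.uniform(start_day, end_day)
                    dur = rng.exponential(
                        cfg.indiv_disturbance_duration_weeks
                    ) * DAYS_PER_WEEK
                    depth = rng.gamma(2.0, cfg.indiv_disturbance_depth / 2.0)
                    j0 = int(s0 - start_day)
                    j1 = min(int(s0 + dur - start_day) + 1, ndays)
                    logits[r, j0:j1] -= depth * sens[r]
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-logits))
        p[days[None, :] < onset_day[:, None]] = 0.0
        lay = (rng.random((nh, ndays)) < p).astype(np.int32)

        # a laid egg is occasionally only collected the next day, producing
        # a 0-egg day followed by a 2-egg day
        if cfg.double_egg_rate > 0:
            shift = (rng.random((nh, ndays)) < cfg.double_egg_rate) & (lay > 0)
            shift[:, -1] = False
            lay = lay - shift.astype(np.int32)
            lay[:, 1:] += shift[:, :-1].astype(np.int32)

        lay *= days[None, :] <= last_day[:, None]

        spans = _batch_spans(start_day, end_day, cfg, rng)
        s_arr = np.array([s for s, _, _ in spans])
        e_arr = np.array([e for _, e, _ in spans])
        imp_arr = np.array([imp for _, _, imp in spans])
        cum = np.concatenate(
            [np.zeros((nh, 1), dtype=np.int64), np.cumsum(lay, axis=1)], axis=1
        )
        # truncate each hen's final span at her death day; drop later spans
        keep = s_arr[None, :] <= last_day[:, None]
        e_eff = np.minimum(e_arr[None, :], last_day[:, None]).astype(np.int64)
        j1 = np.clip(e_eff - start_day, 0, ndays - 1)
        j0 = np.broadcast_to(s_arr - start_day, j1.shape)
        eggs = np.take_along_axis(cum, j1 + 1, axis=1) - np.take_along_axis(
            cum, j0, axis=1
        )
        hi, si = np.nonzero(keep)
        log_frames.append(
            pd.DataFrame(
                {
                    "bird": birds[hi],
                    "start_day": s_arr[si],
                    "end_day": e_eff[hi, si],
                    "eggs": eggs[hi, si],
                    "imputed": imp_arr[si],
                }
            )
        )
        died = np.isfinite(death_day) & (death_day <= end_day)
        hen_frames.append(
            pd.DataFrame(
                {
                    "bird": birds,
                    "batch": b,
                    "location": locs,
                    "rowlevel": rls,
                    "dam": sub["dam"].to_numpy(),
                    "death_day": np.where(died, death_day, np.nan),
                    "end_day": last_day.astype(np.int64),
                    "batch_end_day": end_day,
                }
            )
        )

    egglog = pd.concat(log_frames, ignore_index=True)
    hens_out = pd.concat(hen_frames, ignore_index=True)
    return egglog, hens_out


def simulate_antibody_trait(
    ped: pd.DataFrame, bvs: pd.DataFrame, cfg: SimConfig,
    isotypes: tuple[str, ...] = ("IgM", "IgG"),
) -> pd.DataFrame:
    """Once-measured antibody-like titers on a subset of both sexes.

    titer = mu + plate + beta1*age + sex + bv_nab + e, with samples
    grouped onto plates of ``nab_plate_size`` and age at sampling drawn
    uniformly from 15-22 weeks.
    """
    rng = _rng(cfg, 3)
    last_gen = ped["generation"].max()
    pool = ped[ped["generation"] == last_gen]
    n_sample = max(2, int(round(cfg.nab_sample_fraction * len(pool))))
    sampled = pool.sample(n=n_sample, random_state=int(rng.integers(0, 2**31)))
    sampled = sampled.merge(bvs[["animal", "bv_nab"]], on="animal")
    n = len(sampled)
    ages = rng.integers(15, 23, size=n)
    order = rng.permutation(n)
    plate_of = np.empty(n, dtype=np.int64)
    plate_of[order] = np.arange(n) // cfg.nab_plate_size + 1

    out = []
    for iso in isotypes:
        n_plates = plate_of.max()
        plate_eff = rng.normal(0.0, cfg.nab_plate_sd, size=n_plates + 1)
        resid = rng.normal(0.0, np.sqrt(cfg.nab_sigma2_e), size=n)
        sexeff = np.where(sampled["sex"].to_numpy() == "M", cfg.nab_sex_effect, 0.0)
        titer = (
            cfg.nab_mu
            + plate_eff[plate_of]
            + cfg.nab_age_beta * ages
            + sexeff
            + sampled["bv_nab"].to_numpy()
            + resid
        )
        out.append(
            pd.DataFrame(
                {
                    "animal": sampled["animal"].to_numpy(),
                    "isotype": iso,
                    "titer": titer,
                    "plate": [f"{iso}-{p}" for p in plate_of],
                    "age_weeks": ages,
                    "sex": sampled["sex"].to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


@dataclass
class Population:
    """One simulated study population (all generator outputs bundled)."""

    cfg: SimConfig
    pedigree: pd.DataFrame
    breeding_values: pd.DataFrame
    egglog: pd.DataFrame
    hens: pd.DataFrame
    antibodies: pd.DataFrame


def simulate_population(cfg: SimConfig, disturbances: bool = True) -> Population:
    ped = simulate_pedigree(cfg)
    bvs = simulate_breeding_values(ped, cfg)
    egglog, hens = simulate_egg_log(ped, bvs, cfg, disturbances=disturbances)
    nab = simulate_antibody_trait(ped, bvs, cfg)
    return Population(cfg, ped, bvs, egglog, hens, nab)
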