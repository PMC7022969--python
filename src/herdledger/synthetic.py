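"""Synthetic herd-event generator.

Emulates the statistical structure of a national dairy-herd event database
so that the whole analysis pipeline (classification, trait derivation,
trend modelling, economics) is testable without proprietary data:

* herd-year trait means around published baselines (age at first calving,
  days open, daily milk yield, productive life, mastitis and lameness
  incidence) with between-herd heterogeneity and within-herd AR(1) serial
  correlation across follow-up years;
* adoption-level-dependent record availability: reproductive-only herds
  (LOW), reproductive+productive (MEDIUM), all three categories (HIGH);
* multiplicative (lognormal) structure for the two incidence traits, so
  the log of the value carries the additive model;
* animal-level event streams (`simulate_events`) whose derived herd-year
  traits converge to the generator's own herd-year means as the number of
  cows grows.

Two generators share one latent layer: :func:`simulate_traits` returns the
herd-year means directly, :func:`simulate_events` dresses the same means in
animal-level events. Ground truth is returned as :class:`SimTruth` for
recovery and consistency testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .records import BREED_GROUPS, EVENT_COLUMNS, ZONES

LEVELS = ("LOW", "MEDIUM", "HIGH")
TRAITS = ("AFC", "DO", "DMY", "PL", "MAST", "LAM")
LOGNORMAL_TRAITS = ("MAST", "LAM")

#: Traits a herd of a given adoption level actually records.
LEVEL_TRAITS = {
    "LOW": ("AFC", "DO"),
    "MEDIUM": ("AFC", "DO", "DMY", "PL"),
    "HIGH": ("AFC", "DO", "DMY", "PL", "MAST", "LAM"),
}

#: Days per month and per year used everywhere in the package.
DAYS_PER_MONTH = 30.4375
DAYS_PER_YEAR = 365.25


@dataclass
class TraitParams:
    """Generating parameters for one trait.

    ``mean``/``sd`` are the pooled herd-year mean and SD on the response
    scale. For the incidence traits (MAST, LAM) the additive machinery
    operates on the log scale: ``sd_between``/``sd_within`` and the trend
    slopes are then in log units, derived from the coefficient of
    variation when not given explicitly.
    """

    mean: float
    sd: float
    sd_between: float | None = None
    sd_within: float | None = None
    #: level -> (slope per follow-up year, ramp span in years); the drift
    #: is slope * (min(fy, span) - 1), i.e. linear up to `span` then flat.
    trend: dict = field(default_factory=dict)
    #: level -> additive offset (log-scale for incidence traits).
    level_offset: dict = field(default_factory=dict)
    #: SD of single-animal observations around the herd-year mean.
    animal_sd: float = 1.0
    lognormal: bool = False

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.mean <= 0:
            raise ValueError(f"baseline mean must be positive, got {self.mean}")
        total = self._total_latent_sd()
        # split total variance evenly between and within herds by default
        if self.sd_between is None:
            self.sd_between = float(total / np.sqrt(2.0))
        if self.sd_within is None:
            self.sd_within = float(np.sqrt(max(total**2 - self.sd_between**2, 0.0)))
        self.sd_between = float(self.sd_between)
        self.sd_within = float(self.sd_within)
        if self.sd_between < 0 or self.sd_within < 0:
            raise ValueError("variance components must be >= 0")

    def _total_latent_sd(self) -> float:
        if self.lognormal:
            return float(np.sqrt(np.log1p((self.sd / self.mean) ** 2)))
        return float(self.sd)

    def log_mu(self) -> float:
        """Log-scale location giving the configured arithmetic mean."""
        s2 = np.log1p((self.sd / self.mean) ** 2)
        return float(np.log(self.mean) - s2 / 2.0)

    def slope(self, level: str) -> tuple[float, float]:
        s = self.trend.get(level, (0.0, 1.0))
        return float(s[0]), float(s[1])


@dataclass
class SimConfig:
    """Full configuration of the synthetic population.

    Defaults encode the study conditions: 389/343/180 herds at the
    low/medium/high adoption level, up to 10 follow-up years, mean herd
    size 34 cows, trait baselines at the published pooled means/SDs, and
    prose-level trend magnitudes ramped linearly over their cited spans.
    """

    n_herds_per_level: tuple[int, int, int] = (389, 343, 180)
    followup_years: int = 10
    herd_size_mean: float = 34.0
    herd_size_sd: float = 30.0
    trait_baselines: dict | None = None
    rho_within: float = 0.5
    #: factor -> level -> offset in multiples of each trait's between-herd SD.
    fixed_effects: dict | None = None
    first_year_range: tuple[int, int] = (1996, 2008)
    traits: tuple = TRAITS
    #: events-per-herd shape knobs
    frac_first_calving: float = 0.25
    frac_conception: float = 0.80
    frac_cull: float = 0.18
    weighings_per_cow_year: int = 10
    milk_measurement_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trait_baselines is None:
            self.trait_baselines = default_trait_params()
        if any(n < 0 for n in self.n_herds_per_level):
            raise ValueError("herd counts must be non-negative")
        if not 5 <= self.followup_years <= 10:
            raise ValueError("followup_years must be in [5, 10]")
        if not abs(self.rho_within) < 1:
            raise ValueError("|rho_within| must be < 1")
        if self.herd_size_mean <= 0 or self.herd_size_sd < 0:
            raise ValueError("herd size parameters must be positive")
        if self.fixed_effects is None:
            self.fixed_effects = _default_fixed_effects()
        unknown = set(self.traits) - set(TRAITS)
        if unknown:
            raise ValueError(f"unknown traits {sorted(unknown)}")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["trait_baselines"] = {
            k: dataclasses.asdict(v) for k, v in self.trait_baselines.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "trait_baselines" in d and d["trait_baselines"]:
            d["trait_baselines"] = {
                k: TraitParams(**v) for k, v in d["trait_baselines"].items()
            }
        for key in ("n_herds_per_level", "first_year_range", "traits"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def default_trait_params() -> dict:
    """Trait baselines at the published pooled means/SDs with trend ramps
    matching the reported approximate changes over their year spans."""
    return {
        "AFC": TraitParams(
            31.3, 4.8, animal_sd=3.0,
            trend={"LOW": (0.23, 10), "MEDIUM": (-0.5, 4), "HIGH": (-0.25, 4)},
        ),
        "DO": TraitParams(
            100.6, 16.1, animal_sd=30.0,
            trend={"LOW": (-0.78, 10), "MEDIUM": (-0.56, 10), "HIGH": (-0.56, 10)},
            level_offset={"LOW": -4.0},
        ),
        "DMY": TraitParams(
            16.7, 4.5, animal_sd=4.0,
            trend={"LOW": (0.11, 10), "MEDIUM": (0.11, 10), "HIGH": (0.22, 10)},
        ),
        "PL": TraitParams(
            4.02, 1.45, animal_sd=1.2,
            trend={lvl: (1.0 / 7.0, 8) for lvl in LEVELS},
        ),
        "MAST": TraitParams(10.9, 10.7, lognormal=True),
        "LAM": TraitParams(
            17.9, 17.4, lognormal=True,
            trend={"LOW": (-0.10, 10), "MEDIUM": (-0.10, 10)},
        ),
    }


def _default_fixed_effects() -> dict:
    zone_off = dict(zip(ZONES, (0.0, 0.10, -0.10, 0.20, -0.20, 0.15, -0.15)))
    breed_off = dict(
        zip(BREED_GROUPS, (0.25, -0.05, 0.0, -0.10, -0.30, 0.20))
    )
    return {"zone": zone_off, "breed_group": breed_off}


def default_config(**overrides) -> SimConfig:
    """The study-condition configuration; keyword overrides for testing."""
    return SimConfig(**overrides)


@dataclass
class SimTruth:
    """Ground truth of a simulation run.

    ``herds`` — one row per herd (level, zone, breed, size, first year);
    ``herd_effects`` — realized random intercepts per herd x trait;
    ``expectations`` — per herd-year x trait: ``expectation`` (fixed part +
    herd effect, response scale) and ``herd_year_mean`` (including the
    AR(1) serial deviation — the mean animal-level observations are
    generated around).
    """

    config: SimConfig
    herds: pd.DataFrame
    herd_effects: pd.DataFrame
    expectations: pd.DataFrame


def _draw_herds(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for level, n in zip(LEVELS, config.n_herds_per_level):
        for i in range(n):
            rows.append((f"{level[0]}{i:04d}", level))
    herds = pd.DataFrame(rows, columns=["herd_id", "level"])
    h = len(herds)
    # lognormal herd sizes around the configured mean, at least 5 cows
    mu = np.log(config.herd_size_mean**2 /
                np.sqrt(config.herd_size_mean**2 + config.herd_size_sd**2))
    sig = np.sqrt(np.log1p((config.herd_size_sd / config.herd_size_mean) ** 2))
    sizes = np.maximum(np.round(rng.lognormal(mu, sig, h)), 5).astype(int)
    herds["n_cows"] = sizes
    herds["zone"] = rng.choice(ZONES, h)
    herds["breed_group"] = rng.choice(BREED_GROUPS, h)
    lo, hi = config.first_year_range
    herds["first_year"] = rng.integers(lo, hi + 1, h)
    return herds


def _herd_year_latents(config: SimConfig, rng: np.random.Generator,
                       herds: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Latent layer shared by both generators: herd effects and the
    per herd-year response-scale means."""
    fy = np.arange(1, config.followup_years + 1)
    eff_rows, exp_frames = [], []
    for trait in config.traits:
        tp = config.trait_baselines[trait]
        avail = herds["level"].map(
            {lvl: trait in LEVEL_TRAITS[lvl] for lvl in LEVELS}
        ).to_numpy()
        sub = herds[avail].reset_index(drop=True)
        if sub.empty:
            continue
        h, f = len(sub), len(fy)
        b = rng.normal(0.0, tp.sd_between, h)
        e = np.empty((h, f))
        e[:, 0] = rng.normal(0.0, tp.sd_within, h)
        innov_sd = tp.sd_within * np.sqrt(1.0 - config.rho_within**2)
        for t in range(1, f):
            e[:, t] = config.rho_within * e[:, t - 1] + rng.normal(0.0, innov_sd, h)

        base = tp.log_mu() if tp.lognormal else tp.mean
        det = np.full((h, f), base)
        for factor, offsets in config.fixed_effects.items():
            if factor in sub.columns:
                det += np.array(
                    [offsets.get(v, 0.0) for v in sub[factor]]
                )[:, None] * tp.sd_between
        det += np.array(
            [tp.level_offset.get(lvl, 0.0) for lvl in sub["level"]]
        )[:, None]
        slopes = np.array([tp.slope(lvl)[0] for lvl in sub["level"]])[:, None]
        spans = np.array([tp.slope(lvl)[1] for lvl in sub["level"]])[:, None]
        det += slopes * (np.minimum(fy[None, :], spans) - 1.0)

        lin_exp = det + b[:, None]
        lin_mean = lin_exp + e
        if tp.lognormal:
            expectation = np.exp(lin_exp)
            herd_year_mean = np.minimum(np.exp(lin_mean), 100.0)
        else:
            expectation = np.maximum(lin_exp, 0.0)
            herd_year_mean = np.maximum(lin_mean, 0.0)

        eff_rows.extend(zip(sub["herd_id"], [trait] * h, b))
        frame = pd.DataFrame({
            "herd_id": np.repeat(sub["herd_id"].to_numpy(), f),
            "level": np.repeat(sub["level"].to_numpy(), f),
            "n_cows": np.repeat(sub["n_cows"].to_numpy(), f),
            "first_year": np.repeat(sub["first_year"].to_numpy(), f),
            "trait": trait,
            "followup_year": np.tile(fy, h),
            "expectation": expectation.ravel(),
            "herd_year_mean": herd_year_mean.ravel(),
        })
        frame["calendar_year"] = frame["first_year"] + frame["followup_year"] - 1
        exp_frames.append(frame)
    effects = pd.DataFrame(eff_rows, columns=["herd_id", "trait", "effect"])
    expectations = pd.concat(exp_frames, ignore_index=True)
    return effects, expectations


def _n_units(config: SimConfig, trait: str, n_cows: np.ndarray) -> np.ndarray:
    n_afc = np.maximum(np.round(config.frac_first_calving * n_cows), 1)
    n_do = np.maximum(np.round(config.frac_conception * n_cows), 1)
    if trait == "AFC":
        return n_afc.astype(int)
    if trait == "DO":
        return n_do.astype(int)
    if trait == "DMY":
        return ((n_afc + n_do) * config.weighings_per_cow_year).astype(int)
    if trait == "PL":
        return np.maximum(np.round(config.frac_cull * n_cows), 1).astype(int)
    return (n_afc + n_do).astype(int)  # lactations for MAST/LAM


def simulate_traits(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate the herd-year trait table directly from the latent layer.

    The observed value of a herd-year cell is its latent herd-year mean
    (fixed part + herd intercept + AR(1) serial deviation); sampling noise
    from finite animals only enters through :func:`simulate_events`.
    """
    from .traits import calendar_period, herd_size_class

    rng = np.random.default_rng(config.seed)
    herds = _draw_herds(config, rng)
    effects, expectations = _herd_year_latents(config, rng, herds)
    out = expectations.copy()
    out["value"] = out["herd_year_mean"]
    out["n_units"] = _n_units(config, "AFC", out["n_cows"].to_numpy())
    for trait in config.traits:
        m = out["trait"] == trait
        out.loc[m, "n_units"] = _n_units(config, trait, out.loc[m, "n_cows"].to_numpy())
    out["herd_size_class"] = out["n_cows"].map(herd_size_class)
    out["calendar_period"] = out["calendar_year"].map(calendar_period)
    cols = ["herd_id", "calendar_year", "followup_year", "trait", "value",
            "n_units", "herd_size_class", "calendar_period"]
    truth = SimTruth(config, herds, effects, expectations)
    return out[cols].reset_index(drop=True), truth


def _year_dates(rng: np.random.Generator, year: int, n: int) -> np.ndarray:
    start = np.datetime64(f"{year}-01-01")
    return start + rng.integers(0, 365, n).astype("timedelta64[D]")


def simulate_events(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate animal-level event streams consistent with the latent layer.

    Per herd and follow-up year: first-calvers carry BIRTH + first CALVING
    (age at first calving around the herd-year mean), conceiving cows carry
    CALVING + CONCEPTION (days open), milking cows daily MILK_WEIGH records,
    culled cows a backdated first CALVING + CULL (productive life), and
    mastitis/lameness flags are attached per lactation with the herd-year
    incidence as Bernoulli probability. Only event categories the herd's
    adoption level records are emitted.
    """
    rng = np.random.default_rng(config.seed)
    herds = _draw_herds(config, rng)
    effects, expectations = _herd_year_latents(config, rng, herds)
    truth = SimTruth(config, herds, effects, expectations)

    mean_lookup: dict[tuple[str, str, int], float] = {
        (r.herd_id, r.trait, int(r.followup_year)): r.herd_year_mean
        for r in expectations.itertuples()
    }
    tb = config.trait_baselines
    frames: list[pd.DataFrame] = []
    calvings: list[pd.DataFrame] = []  # lactation starts, for health flags

    def emit(herd, animal_ids, dates, etype, values=None, parity=None):
        frames.append(pd.DataFrame({
            "herd_id": herd,
            "animal_id": animal_ids,
            "event_date": pd.to_datetime(dates),
            "event_type": etype,
            "value": np.nan if values is None else values,
            "parity": pd.array([parity] * len(animal_ids), dtype="Int64")
            if parity is not None else pd.array([None] * len(animal_ids), dtype="Int64"),
        }))

    for herd in herds.itertuples():
        level_traits = [t for t in LEVEL_TRAITS[herd.level] if t in config.traits]
        for fy in range(1, config.followup_years + 1):
            year = int(herd.first_year) + fy - 1
            size = int(herd.n_cows)
            afc_cow_ids: list = []
            do_cow_ids: list = []

            if "AFC" in level_traits:
                n_afc = max(1, round(config.frac_first_calving * size))
                mu = mean_lookup[(herd.herd_id, "AFC", fy)]
                afc = np.maximum(rng.normal(mu, tb["AFC"].animal_sd, n_afc), 15.0)
                cdates = _year_dates(rng, year, n_afc)
                bdates = cdates - (afc * DAYS_PER_MONTH).astype("timedelta64[D]")
                ids = [f"{herd.herd_id}-H{year}-{i}" for i in range(n_afc)]
                emit(herd.herd_id, ids, bdates, "BIRTH")
                emit(herd.herd_id, ids, cdates, "CALVING", parity=1)
                calvings.append(pd.DataFrame(
                    {"herd_id": herd.herd_id, "animal_id": ids,
                     "event_date": pd.to_datetime(cdates), "year": year}))
                afc_cow_ids = ids

            if "DO" in level_traits:
                n_do = max(1, round(config.frac_conception * size))
                mu = mean_lookup[(herd.herd_id, "DO", fy)]
                do = np.maximum(rng.normal(mu, tb["DO"].animal_sd, n_do), 20.0)
                odates = _year_dates(rng, year, n_do)
                cvdates = odates - do.astype("timedelta64[D]")
                ids = [f"{herd.herd_id}-C{year}-{i}" for i in range(n_do)]
                emit(herd.herd_id, ids, cvdates, "CALVING", parity=2)
                emit(herd.herd_id, ids, odates, "CONCEPTION")
                calvings.append(pd.DataFrame(
                    {"herd_id": herd.herd_id, "animal_id": ids,
                     "event_date": pd.to_datetime(cvdates),
                     "year": pd.to_datetime(cvdates).year}))
                do_cow_ids = ids

            # --- milk weighings (DMY) on this year's calvers ---
            if "DMY" in level_traits:
                mu = mean_lookup[(herd.herd_id, "DMY", fy)]
                cows = afc_cow_ids + do_cow_ids
                cow_mu = np.maximum(
                    rng.normal(mu, tb["DMY"].animal_sd, len(cows)), 0.5)
                w = config.weighings_per_cow_year
                wdates = _year_dates(rng, year, len(cows) * w)
                vals = np.maximum(
                    np.repeat(cow_mu, w)
                    + rng.normal(0.0, config.milk_measurement_sd, len(cows) * w),
                    0.1)
                emit(herd.herd_id, np.repeat(cows, w), wdates, "MILK_WEIGH",
                     values=vals)

            # --- cullings (PL) with backdated first calving ---
            if "PL" in level_traits:
                n_cull = max(1, round(config.frac_cull * size))
                mu = mean_lookup[(herd.herd_id, "PL", fy)]
                pl = np.maximum(rng.normal(mu, tb["PL"].animal_sd, n_cull), 0.5)
                udates = _year_dates(rng, year, n_cull)
                fdates = udates - (pl * DAYS_PER_YEAR).astype("timedelta64[D]")
                ids = [f"{herd.herd_id}-X{year}-{i}" for i in range(n_cull)]
                emit(herd.herd_id, ids, fdates, "CALVING", parity=1)
                emit(herd.herd_id, ids, udates, "CULL")
                # their (backdated) lactation starts are also at risk of
                # health events in the year they fall in
                calvings.append(pd.DataFrame(
                    {"herd_id": herd.herd_id, "animal_id": ids,
                     "event_date": pd.to_datetime(fdates),
                     "year": pd.to_datetime(fdates).year}))

    events = pd.concat(frames, ignore_index=True)

    # --- health flags per lactation (HIGH herds only) ---
    lact = (pd.concat(calvings, ignore_index=True)
            if calvings else pd.DataFrame(
                columns=["herd_id", "animal_id", "event_date", "year"]))
    high = set(herds.loc[herds["level"] == "HIGH", "herd_id"])
    fy_of: dict[tuple[str, int], int] = {}
    for h, fyr in zip(herds["herd_id"], herds["first_year"]):
        for fy in range(1, config.followup_years + 1):
            fy_of[(h, int(fyr) + fy - 1)] = fy
    health_frames = []
    for etype, trait in (("MASTITIS", "MAST"), ("LAMENESS", "LAM")):
        if trait not in config.traits:
            continue
        sub = lact[lact["herd_id"].isin(high)]
        if sub.empty:
            continue
        probs = np.array([
            mean_lookup.get((h, trait, fy_of.get((h, int(y)), -1)), np.nan) / 100.0
            for h, y in zip(sub["herd_id"], sub["year"])
        ])
        probs = np.nan_to_num(probs, nan=0.0)
        hit = rng.random(len(sub)) < probs
        flagged = sub[hit].copy()
        offs = rng.integers(5, 250, len(flagged)).astype("timedelta64[D]")
        dates = flagged["event_date"].to_numpy() + offs
        # a health-recording herd has, by construction, at least one
        # recorded case dated within every follow-up year: without it the
        # herd-year would look like one that records nothing
        covered = set(zip(flagged["herd_id"],
                          pd.to_datetime(dates).year))
        extra_rows = []
        required = sub[probs > 0].sort_values("event_date")
        for (h, y), grp in required.groupby(["herd_id", "year"], sort=False):
            if (h, y) in covered:
                continue
            first = grp.iloc[0]
            date = min(first["event_date"] + pd.Timedelta(days=5),
                       pd.Timestamp(int(y), 12, 31))
            extra_rows.append((h, first["animal_id"], date))
        frame = pd.DataFrame({
            "herd_id": np.concatenate([flagged["herd_id"].to_numpy(),
                                       [r[0] for r in extra_rows]]),
            "animal_id": np.concatenate([flagged["animal_id"].to_numpy(),
                                         [r[1] for r in extra_rows]]),
            "event_date": pd.to_datetime(
                list(dates) + [r[2] for r in extra_rows]),
            "event_type": etype,
            "value": np.nan,
        })
        frame["parity"] = pd.array([None] * len(frame), dtype="Int64")
        if not frame.empty:
            health_frames.append(frame)
    if health_frames:
        events = pd.concat([events] + health_frames, ignore_index=True)

    events = events.sort_values(
        ["herd_id", "animal_id", "event_date"], kind="stable"
    ).reset_index(drop=True)[EVENT_COLUMNS]

    meta = herds.rename(columns={"first_year": "first_followup_year"})[
        ["herd_id", "zone", "breed_group", "first_followup_year"]
    ].copy()
    return events, meta, truth
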