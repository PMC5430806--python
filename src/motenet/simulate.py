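"""Synthetic mote-study generator with planted effects.

Emulates a proximity-sensing field study in mobile forager camps: several
camps of 15-45 people wear sensors for 5-9 days; every two minutes between
05:00 and 20:00 each co-present dyad is detected with a probability driven
by household co-membership, kinship and individual gregariousness. Mothers'
reproductive and health outcomes are then generated with *known* planted
effects of their realized network centrality, so that the downstream
estimation pipeline has an exact recovery target.

Two generation paths exist for the contact process:

``simulate_ping_log``
    emits the full directed detection log (timestamps, both directions,
    asymmetric radio loss) — what a real deployment produces.
``simulate_dyad_counts``
    draws each dyad's total event count directly from the implied
    Binomial(co-present slots, p_ij) law. Because slot outcomes are
    independent Bernoulli trials, the per-dyad count is a sufficient
    statistic for everything downstream of ingestion; replicate studies
    use this path for speed.

Outcome model (mothers only)
----------------------------
Living offspring are Poisson with mean

    mu_i = exp(a + b*age + c*age^2) + beta_cf * x_i + beta_ai * x_i * x_age,

where ``x_i`` is the mother's *realized* camp-standardized centrality
rescaled over two sample standard deviations (the same transform the
regression stage applies), and ``x_age`` the analogously rescaled
mean-centred age. Planting the centrality effect additively on the
expected-count scale makes the ordinary-least-squares coefficient of the
age-residualized offspring count on the standardized centrality equal to
``beta_cf`` exactly, which is what parameter-recovery checks need.

Sickness counts (0-2 diagnosed instances over two weeks) are truncated
Poisson with log-rate

    log lam_i = s0 + beta_cs * x_close_i + beta_ds * n_dependents_i,

a direct closeness effect plus a dependents channel (children as disease
vectors / parity costs). Number of dependents equals the mother's living
offspring count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import time as dtime

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidConfigError, MissingDataError
from .ingest import DEFAULT_WINDOW, daytime_hours

#: Arbitrary but fixed origin for simulated study calendars.
STUDY_START = pd.Timestamp("2014-02-01")

CENTRALITY_MEASURES = ("degree", "strength", "ec", "betweenness", "closeness")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated mote deployment.

    Rates and boosts parameterize the per-slot contact probability

        p_ij = clamp(base_rate * household_boost^{same hh} * kin_boost^{kin}
                     * g_i * g_j, 0, 1)

    with ``g`` individual gregariousness, lognormal with unit mean.
    Planted effect sizes are in per-two-SD standardized units (see module
    docstring).
    """

    n_camps: int = 6
    camp_size_range: tuple[int, int] = (15, 45)
    study_days: int = 7                      # 5-9 in the field protocol
    slot_minutes: int = 2
    day_window: tuple[dtime, dtime] = DEFAULT_WINDOW
    base_rate: float = 0.005                 # per dyad-slot detection prob.
    household_boost: float = 8.0
    kin_boost: float = 3.0
    kin_pair_prob: float = 0.02              # cross-household kin ties
    gregariousness_sd: float = 0.5           # sd of log g
    drop_prob: float = 0.1                   # one-directional radio loss
    late_frac: float = 0.15                  # P(arrive late), P(leave early)
    mean_household_size: float = 4.5
    # planted effects (all zero -> null generator)
    beta_centrality_fertility: float = 0.0
    fertility_measure: str = "betweenness"
    beta_age_interaction: float = 0.0
    beta_closeness_sickness: float = 0.0
    sickness_measure: str = "closeness"
    beta_dependents_sickness: float = 0.0
    sickness_base: float = -0.05             # log baseline sickness rate
    fertility_curve: tuple[float, float, float] = (-1.028, 0.1172, -0.001302)
    population: str = "A"
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.camp_size_range
        if lo < 2 or hi < lo:
            raise InvalidConfigError(
                f"camp_size_range {self.camp_size_range} must satisfy 2 <= lo <= hi")
        if self.n_camps < 1 or self.study_days < 1:
            raise InvalidConfigError("n_camps and study_days must be >= 1")
        for name in ("base_rate", "drop_prob", "late_frac", "kin_pair_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name}={v} must lie in [0, 1]")
        if self.household_boost < 1 or self.kin_boost < 1:
            raise InvalidConfigError("household_boost and kin_boost must be >= 1")
        if self.fertility_measure not in CENTRALITY_MEASURES:
            raise InvalidConfigError(f"unknown measure {self.fertility_measure!r}")
        if self.sickness_measure not in CENTRALITY_MEASURES:
            raise InvalidConfigError(f"unknown measure {self.sickness_measure!r}")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @property
    def slots_per_day(self) -> int:
        w0, w1 = self.day_window
        minutes = (w1.hour * 60 + w1.minute) - (w0.hour * 60 + w0.minute)
        return minutes // self.slot_minutes


def load_config(path) -> SimConfig:
    """Read a flat key-value YAML file into a :class:`SimConfig`.

    Keys match field names; ``camp_size_range`` and ``fertility_curve``
    are lists; ``day_window`` is a pair of ``HH:MM`` strings.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
    if "camp_size_range" in raw:
        raw["camp_size_range"] = tuple(raw["camp_size_range"])
    if "fertility_curve" in raw:
        raw["fertility_curve"] = tuple(raw["fertility_curve"])
    if "day_window" in raw:
        raw["day_window"] = tuple(
            dtime(*map(int, s.split(":"))) for s in raw["day_window"])
    cfg = SimConfig(**raw)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# population and presence


def simulate_population(config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a multi-camp roster and camp presence intervals.

    Ages are uniform on [2, 75] years (a deliberately flat stand-in for a
    forager age pyramid; children under 12 matter only as non-network
    household members). Every woman aged 17+ is a mother; camps are
    adjusted so each holds at least five mothers. A ``late_frac`` share of
    individuals arrive up to a third of the study late, and independently
    the same share leave early.

    Returns ``(roster, presence)`` frames. Deterministic given the config
    seed (or an explicit ``rng``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lo, hi = config.camp_size_range
    rows = []
    for c in range(config.n_camps):
        camp = f"C{c + 1}"
        size = int(rng.integers(lo, hi + 1))
        settled = bool(rng.random() < 0.5)
        ages = rng.uniform(2.0, 75.0, size)
        sexes = np.where(rng.random(size) < 0.5, "F", "M")
        # households: contiguous blocks with size ~ 1 + Poisson(mean - 1)
        hh = np.empty(size, dtype=object)
        i = h = 0
        while i < size:
            n = 1 + int(rng.poisson(config.mean_household_size - 1.0))
            hh[i:i + n] = f"{camp}-H{h + 1}"
            i += n
            h += 1
        is_mother = (sexes == "F") & (ages >= 17.0)
        # guarantee at least five mothers per camp (all of it, if tiny)
        while is_mother.sum() < min(5, size):
            j = int(rng.integers(size))
            if not is_mother[j]:
                sexes[j] = "F"
                ages[j] = rng.uniform(18.0, 60.0)
                is_mother[j] = True
        for j in range(size):
            rows.append({
                "id": f"{camp}-{j + 1:03d}",
                "camp": camp,
                "age": round(float(ages[j]), 2),
                "sex": sexes[j],
                "household": hh[j],
                "is_mother": bool(is_mother[j]),
                "settled": settled,
                "mobile": bool(rng.random() < 0.3),
                "belongings": round(float(rng.lognormal(1.0, 0.6)), 3),
                "gregariousness": float(rng.lognormal(
                    -config.gregariousness_sd ** 2 / 2.0,
                    config.gregariousness_sd)),
            })
    roster = pd.DataFrame(rows)

    w0, _ = config.day_window
    start = STUDY_START + pd.Timedelta(hours=w0.hour, minutes=w0.minute)
    end = start + pd.Timedelta(days=config.study_days)
    # Entry/exit times are snapped to the slot grid: the field protocol
    # records them at sensor resolution, and alignment makes co-presence
    # hours an exact multiple of the slot length.
    slot = pd.Timedelta(minutes=config.slot_minutes)
    max_slots = int(config.study_days * 8.0 * 60 / config.slot_minutes)
    pres = []
    for r in roster.itertuples(index=False):
        enter, exit_ = start, end
        if rng.random() < config.late_frac:
            enter = start + slot * int(rng.integers(0, max_slots + 1))
        if rng.random() < config.late_frac:
            exit_ = max(end - slot * int(rng.integers(0, max_slots + 1)),
                        enter + slot)
        pres.append({"individual": r.id, "camp": r.camp,
                     "enter": enter, "exit": exit_})
    presence = pd.DataFrame(pres)
    return roster, presence


def _kin_pairs(roster_camp: pd.DataFrame, config: SimConfig,
               rng: np.random.Generator) -> set[frozenset]:
    """Cross-household kin ties, drawn pairwise with ``kin_pair_prob``."""
    ids = roster_camp["id"].to_numpy()
    hh = roster_camp["household"].to_numpy()
    n = len(ids)
    iu, ju = np.triu_indices(n, 1)
    cross = hh[iu] != hh[ju]
    pick = cross & (rng.random(len(iu)) < config.kin_pair_prob)
    return {frozenset((ids[i], ids[j]))
            for i, j in zip(iu[pick], ju[pick])}


def _dyad_slot_probabilities(roster_camp: pd.DataFrame, config: SimConfig,
                             kin: set[frozenset]) -> pd.DataFrame:
    """Per-dyad contact probability for one camp (upper-triangle rows)."""
    ids = roster_camp["id"].to_numpy()
    hh = roster_camp["household"].to_numpy()
    g = roster_camp["gregariousness"].to_numpy()
    iu, ju = np.triu_indices(len(ids), 1)
    p = config.base_rate * g[iu] * g[ju]
    p = np.where(hh[iu] == hh[ju], p * config.household_boost, p)
    if kin:
        is_kin = np.fromiter(
            (frozenset((ids[i], ids[j])) in kin for i, j in zip(iu, ju)),
            dtype=bool, count=len(iu))
        p = np.where(is_kin, p * config.kin_boost, p)
    return pd.DataFrame({"id_a": ids[iu], "id_b": ids[ju],
                         "p": np.clip(p, 0.0, 1.0)})


def _slot_grid(config: SimConfig) -> pd.DatetimeIndex:
    """Start times of every daytime slot across the study period."""
    w0, _ = config.day_window
    day0 = STUDY_START + pd.Timedelta(hours=w0.hour, minutes=w0.minute)
    days = [day0 + pd.Timedelta(days=d) for d in range(config.study_days)]
    per_day = config.slots_per_day
    step = pd.Timedelta(minutes=config.slot_minutes)
    return pd.DatetimeIndex(
        [d + k * step for d in days for k in range(per_day)])


def _copresent_slot_mask(slots: pd.DatetimeIndex, pres_i, pres_j,
                         config: SimConfig) -> np.ndarray:
    lo = max(pres_i.enter, pres_j.enter)
    hi = min(pres_i.exit, pres_j.exit)
    step = pd.Timedelta(minutes=config.slot_minutes)
    return np.asarray((slots >= lo) & ((slots + step) <= hi))


def simulate_ping_log(roster: pd.DataFrame, presence: pd.DataFrame,
                      config: SimConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Emit the full directed detection log for every camp.

    For each daytime slot where a dyad is co-present a contact occurs with
    probability ``p_ij``; each contact yields up to two directed records
    (i hears j and j hears i), each independently lost with ``drop_prob``.
    Returns a frame ``emitter,receiver,timestamp`` sorted by time.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    slots = _slot_grid(config)
    pres = presence.set_index("individual")
    out_e, out_r, out_t = [], [], []
    for camp, group in roster.groupby("camp", sort=True):
        kin = _kin_pairs(group, config, rng)
        dyads = _dyad_slot_probabilities(group, config, kin)
        for d in dyads.itertuples(index=False):
            mask = _copresent_slot_mask(slots, pres.loc[d.id_a],
                                        pres.loc[d.id_b], config)
            avail = slots[mask]
            if len(avail) == 0 or d.p == 0.0:
                continue
            k = int(rng.binomial(len(avail), d.p))
            if k == 0:
                continue
            hit = avail[np.sort(rng.choice(len(avail), k, replace=False))]
            for t in hit:
                for e, r in ((d.id_a, d.id_b), (d.id_b, d.id_a)):
                    if rng.random() >= config.drop_prob:
                        out_e.append(e)
                        out_r.append(r)
                        out_t.append(t)
    log = pd.DataFrame({"emitter": out_e, "receiver": out_r,
                        "timestamp": pd.DatetimeIndex(out_t)})
    return (log.sort_values(["timestamp", "emitter", "receiver"])
               .reset_index(drop=True))


def simulate_dyad_counts(roster: pd.DataFrame, presence: pd.DataFrame,
                         config: SimConfig,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Draw per-dyad contact-event totals directly (sufficient-statistic path).

    Distributionally identical, dyad by dyad, to counting the unique
    dyad-slot events of :func:`simulate_ping_log`: each co-present slot is
    an independent Bernoulli(p_ij) trial, so the total is
    Binomial(#co-present slots, p_ij). Radio loss does not enter because a
    one-sided detection still counts as a contact event downstream.

    Returns ``camp,id_a,id_b,events,overlap_hours``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    slots = _slot_grid(config).asi8          # slot start times, ns since epoch
    step_ns = config.slot_minutes * 60 * 10 ** 9
    enter = presence.set_index("individual")["enter"]
    exit_ = presence.set_index("individual")["exit"]
    frames = []
    for camp, group in roster.groupby("camp", sort=True):
        kin = _kin_pairs(group, config, rng)
        dyads = _dyad_slot_probabilities(group, config, kin)
        lo = np.maximum(enter.loc[dyads["id_a"]].to_numpy().astype("int64"),
                        enter.loc[dyads["id_b"]].to_numpy().astype("int64"))
        hi = np.minimum(exit_.loc[dyads["id_a"]].to_numpy().astype("int64"),
                        exit_.loc[dyads["id_b"]].to_numpy().astype("int64"))
        # slots fully inside [lo, hi]: start >= lo and start + step <= hi
        m = (np.searchsorted(slots, hi - step_ns, side="right")
             - np.searchsorted(slots, lo, side="left"))
        m = np.maximum(m, 0)
        # presence is slot-aligned, so daytime co-presence is exactly the
        # co-present slot count times the slot length
        hours = m * (config.slot_minutes / 60.0)
        events = rng.binomial(m, dyads["p"].to_numpy())
        frames.append(pd.DataFrame({
            "camp": camp, "id_a": dyads["id_a"], "id_b": dyads["id_b"],
            "events": events, "overlap_hours": hours}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# outcomes


def two_sd_units(x: np.ndarray) -> np.ndarray:
    """Center and rescale a vector over two sample standard deviations."""
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise InvalidConfigError("cannot rescale a zero-variance vector")
    return (x - x.mean()) / (2.0 * sd)


def simulate_outcomes(roster: pd.DataFrame, centrality: pd.DataFrame,
                      config: SimConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Plant fertility and sickness outcomes on realized centrality.

    ``centrality`` must carry camp-standardized columns ``z_<measure>``
    indexed like its ``id`` column for every mother in the roster. Returns
    a copy of the roster with ``n_living_offspring``, ``n_dependents`` and
    ``sickness_count`` filled for mothers (zero elsewhere).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    cent = centrality.set_index("id")
    out = roster.copy()
    mothers = out[out["is_mother"]]
    missing = [i for i in mothers["id"] if i not in cent.index]
    if missing:
        raise MissingDataError(
            f"mothers missing from centrality table: {missing[:10]}")

    zf = cent.loc[mothers["id"], f"z_{config.fertility_measure}"].to_numpy()
    zs = cent.loc[mothers["id"], f"z_{config.sickness_measure}"].to_numpy()
    age = mothers["age"].to_numpy()
    x_f = two_sd_units(zf)
    x_s = two_sd_units(zs)
    x_age = two_sd_units(age)

    a, b, c = config.fertility_curve
    mu = np.exp(a + b * age + c * age ** 2)
    mu = mu + config.beta_centrality_fertility * x_f \
            + config.beta_age_interaction * x_f * x_age
    mu = np.clip(mu, 0.05, None)
    offspring = rng.poisson(mu)

    lam = np.exp(config.sickness_base
                 + config.beta_closeness_sickness * x_s
                 + config.beta_dependents_sickness * offspring)
    sickness = np.minimum(2, rng.poisson(lam))

    out["n_living_offspring"] = 0
    out["n_dependents"] = 0
    out["sickness_count"] = 0
    out.loc[mothers.index, "n_living_offspring"] = offspring
    out.loc[mothers.index, "n_dependents"] = offspring
    out.loc[mothers.index, "sickness_count"] = sickness
    return out


# ---------------------------------------------------------------------------
# writers (round-trip with the ingest dialects)


def write_outputs(roster: pd.DataFrame, presence: pd.DataFrame,
                  pings: pd.DataFrame, outdir) -> None:
    """Write roster/presence/ping CSVs in the dialects ``ingest`` reads."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    roster.to_csv(outdir / "roster.csv", index=False)
    presence.to_csv(outdir / "presence.csv", index=False,
                    date_format="%Y-%m-%dT%H:%M:%S")
    pings.to_csv(outdir / "pings.csv", index=False,
                 columns=["emitter", "receiver", "timestamp"],
                 date_format="%Y-%m-%dT%H:%M:%S")
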