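"""Synthetic sessions for the cued change-detection task.

Generates trial tables, Poisson spike trains, and behavioral outcomes with the
statistical structure the downstream analyses assume: three stimulus locations
(top, middle, bottom), pre-cue trials in which a ring cue marks the only
location where a color change can occur, and no-cue trials in which a
behavioral agent covertly attends exactly one location of its own choosing.

Units are epoch-wise homogeneous Poisson processes. A unit's rate in an epoch
is ``baseline * location_gain[attended] * prod(color_gain(loc, color)^e)``
where the exponent ``e`` equals ``attn_gain`` at the trial's attended location
and 1 elsewhere. With ``attn_gain == 1`` attention has no effect on color
coding, which is the simulator's null.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LOCATIONS: tuple[str, str, str] = ("top", "middle", "bottom")
UNIT_CLASSES: tuple[str, str, str, str] = ("location_only", "color_only", "both", "untuned")
OUTCOMES: tuple[str, ...] = ("hit", "miss", "correct_rejection", "false_alarm")


class InvalidConfigError(ValueError):
    """Raised when a generator configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolConfig:
    """Task epoch timing in seconds, from ITI onset.

    The pre-cue path (cue 200 ms + 500 ms delay) must equal the no-cue delay
    (700 ms) so that sample onset is time-locked across trial types.
    """

    iti_s: float = 2.0
    cue_dur_s: float = 0.2
    postcue_delay_s: float = 0.5
    nocue_delay_s: float = 0.7
    sample_dur_s: float = 0.4
    memory_delay_s: float = 1.1
    compare_dur_s: float = 0.4
    n_trials: int = 480
    locations: tuple[str, ...] = LOCATIONS
    n_palette_colors: int = 15

    def __post_init__(self) -> None:
        durs = (
            self.iti_s, self.cue_dur_s, self.postcue_delay_s, self.nocue_delay_s,
            self.sample_dur_s, self.memory_delay_s, self.compare_dur_s,
        )
        if any(d <= 0 for d in durs):
            raise InvalidConfigError("all durations must be > 0")
        if abs((self.cue_dur_s + self.postcue_delay_s) - self.nocue_delay_s) > 1e-9:
            raise InvalidConfigError(
                "cue_dur_s + postcue_delay_s must equal nocue_delay_s "
                "(sample onset is time-locked across trial types)"
            )
        if self.n_trials < 1:
            raise InvalidConfigError("n_trials must be >= 1")

    # Event times relative to trial start (= ITI onset). Initiation happens at
    # t = iti_s; sample onset is iti_s + nocue_delay_s in both trial types.
    @property
    def init_time(self) -> float:
        return self.iti_s

    @property
    def cue_on(self) -> float:
        return self.iti_s

    @property
    def cue_off(self) -> float:
        return self.iti_s + self.cue_dur_s

    @property
    def sample_on(self) -> float:
        return self.iti_s + self.nocue_delay_s

    @property
    def sample_off(self) -> float:
        return self.sample_on + self.sample_dur_s

    @property
    def compare_on(self) -> float:
        return self.sample_off + self.memory_delay_s

    @property
    def choice_on(self) -> float:
        return self.compare_on + self.compare_dur_s

    @property
    def trial_duration(self) -> float:
        return self.choice_on


@dataclass(frozen=True)
class UnitSpec:
    """Tuning specification of one Poisson unit.

    ``location_tuning`` multiplies the rate (from cue onset through the
    compare phase) according to the trial's attended location.
    ``color_tuning`` maps ``(location, color_index)`` to a gain active while
    colors are on screen or memorized; at the attended location the gain is
    raised to ``attn_gain``.
    """

    unit_id: int
    baseline_hz: float
    location_tuning: Mapping[str, float] = field(default_factory=dict)
    color_tuning: Mapping[tuple[str, int], float] = field(default_factory=dict)
    attn_gain: float = 1.0
    noise_model: str = "poisson"

    def __post_init__(self) -> None:
        if self.baseline_hz < 0:
            raise InvalidConfigError("baseline_hz must be >= 0")
        if self.attn_gain < 1:
            raise InvalidConfigError("attn_gain must be >= 1")
        if any(g <= 0 for g in self.location_tuning.values()):
            raise InvalidConfigError("location gains must be > 0")
        if any(g <= 0 for g in self.color_tuning.values()):
            raise InvalidConfigError("color gains must be > 0")

    def loc_gain(self, location: str) -> float:
        return float(self.location_tuning.get(location, 1.0))

    def color_gain(self, location: str, color: int) -> float:
        return float(self.color_tuning.get((location, int(color)), 1.0))


@dataclass(frozen=True)
class AgentConfig:
    """Behavioral agent: attends exactly one location per trial.

    ``fixed`` always attends ``fixed_location``; ``switching`` re-draws its
    attended location with probability ``switch_hazard`` every
    ``block_len_trials`` trials (uniform over the three locations, so a hazard
    of 1 with a short block yields a uniformly switching agent).
    """

    strategy: str = "switching"
    fixed_location: str | None = None
    switch_hazard: float = 0.5
    p_hit_attended: float = 0.9
    p_cr: float = 0.95
    p_hit_unattended: float = 0.05
    block_len_trials: int = 50

    def __post_init__(self) -> None:
        if self.strategy not in ("fixed", "switching"):
            raise InvalidConfigError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "fixed" and self.fixed_location not in LOCATIONS:
            raise InvalidConfigError("strategy='fixed' requires a valid fixed_location")
        for name in ("switch_hazard", "p_hit_attended", "p_cr", "p_hit_unattended"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if self.block_len_trials < 1:
            raise InvalidConfigError("block_len_trials must be >= 1")


@dataclass
class SpikeData:
    """Per-(unit, trial) spike timestamps, stored long-format.

    ``df`` has columns unit_id, trial_id, spike_time_s; times are seconds from
    trial start, strictly increasing within each (unit, trial). ``unit_ids``
    lists every unit, including silent ones that contribute no rows.
    """

    df: pd.DataFrame
    unit_ids: np.ndarray

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids)

    def spike_times(self, unit_id: int, trial_id: int) -> np.ndarray:
        m = (self.df["unit_id"] == unit_id) & (self.df["trial_id"] == trial_id)
        return self.df.loc[m, "spike_time_s"].to_numpy()

    def grouped(self) -> dict[tuple[int, int], np.ndarray]:
        """Dict of sorted spike-time arrays keyed by (unit_id, trial_id)."""
        times = self.df["spike_time_s"].to_numpy()
        return {
            key: times[idx]
            for key, idx in self.df.groupby(["unit_id", "trial_id"]).indices.items()
        }


TRIAL_COLUMNS = [
    "trial_id", "session_id", "trial_type", "cue_location",
    "sample_color_top", "sample_color_middle", "sample_color_bottom",
    "compare_color_top", "compare_color_middle", "compare_color_bottom",
    "change_location", "response_location", "outcome", "attended_location",
    "cue_on", "cue_off", "sample_on", "sample_off", "compare_on", "choice_on",
]


# ---------------------------------------------------------------------------
# Population construction
# ---------------------------------------------------------------------------


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    """Integer allocation of ``n`` by largest-remainder (Hare) rounding."""
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    short = n - sum(counts)
    remainders = np.array([q - c for q, c in zip(quotas, counts)])
    for i in np.argsort(-remainders)[:short]:
        counts[int(i)] += 1
    return counts


def make_population(
    n_units: int,
    class_fractions: Mapping[str, float],
    seed: int,
    *,
    baseline_range_hz: tuple[float, float] = (4.0, 12.0),
    loc_gain: float = 2.0,
    color_gain: float = 1.5,
    attn_gain: float = 2.0,
) -> list[UnitSpec]:
    """Draw a unit population matching the requested tuning-class fractions.

    Class counts follow largest-remainder rounding of ``n_units * fraction``.
    Preferred locations are assigned round-robin within each tuned class so no
    location dominates the population code. Deterministic given ``seed``.
    """
    fracs = [float(class_fractions.get(c, 0.0)) for c in UNIT_CLASSES]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise InvalidConfigError("class fractions must sum to 1")
    if any(f < 0 for f in fracs):
        raise InvalidConfigError("class fractions must be >= 0")
    counts = _largest_remainder(n_units, fracs)
    rng = np.random.default_rng(seed)

    units: list[UnitSpec] = []
    uid = 0
    for cls, cnt in zip(UNIT_CLASSES, counts):
        for k in range(cnt):
            baseline = float(rng.uniform(*baseline_range_hz))
            loc_tuning: dict[str, float] = {}
            col_tuning: dict[tuple[str, int], float] = {}
            if cls in ("location_only", "both"):
                pref = LOCATIONS[k % 3]
                loc_tuning = {loc: (loc_gain if loc == pref else 1.0) for loc in LOCATIONS}
            if cls in ("color_only", "both"):
                pref = LOCATIONS[k % 3]
                hi = 1 if rng.random() < 0.5 else 2
                col_tuning = {
                    (pref, hi): color_gain,
                    (pref, 3 - hi): 1.0 / color_gain,
                }
            units.append(
                UnitSpec(
                    unit_id=uid,
                    baseline_hz=baseline,
                    location_tuning=loc_tuning,
                    color_tuning=col_tuning,
                    attn_gain=attn_gain,
                )
            )
            uid += 1
    return units


# ---------------------------------------------------------------------------
# Trial-sequence construction
# ---------------------------------------------------------------------------


def _constrained_location_sequence(
    counts: Mapping[str, int], rng: np.random.Generator, max_run: int = 2
) -> list[str]:
    """Random order of location labels with no run longer than ``max_run``.

    Greedy weighted draw over remaining counts, excluding the label that would
    extend a maximal run; restarts on the rare deadlock.
    """
    labels = [loc for loc in LOCATIONS if counts.get(loc, 0) > 0]
    for _attempt in range(1000):
        remaining = {loc: counts.get(loc, 0) for loc in labels}
        seq: list[str] = []
        ok = True
        while sum(remaining.values()) > 0:
            banned = None
            if len(seq) >= max_run and all(s == seq[-1] for s in seq[-max_run:]):
                banned = seq[-1]
            avail = [l for l in labels if remaining[l] > 0 and l != banned]
            if not avail:
                ok = False
                break
            w = np.array([remaining[l] for l in avail], dtype=float)
            seq.append(avail[rng.choice(len(avail), p=w / w.sum())])
            remaining[seq[-1]] -= 1
        if ok:
            return seq
    raise RuntimeError("could not build a constrained cue sequence")  # pragma: no cover


def _build_trial_conditions(
    protocol: ProtocolConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Balanced, shuffled per-trial conditions (before agent/outcomes)."""
    n = protocol.n_trials
    n_pre, n_nocue = _largest_remainder(n, [0.5, 0.5])

    # Pre-cue: 3 locations x {change, no-change}, counts differing by <= 1.
    pre_cells = [(loc, ch) for loc in LOCATIONS for ch in (True, False)]
    pre_counts = _largest_remainder(n_pre, [1 / 6] * 6)
    # No-cue: {change, no-change} split, change subdivided over locations.
    n_change, n_nochange = _largest_remainder(n_nocue, [0.5, 0.5])
    nocue_change_counts = _largest_remainder(n_change, [1 / 3] * 3)

    # Order pre-cue cue locations under the <=2-repeat constraint, then pair
    # each slot with a change flag drawn balanced within its location.
    loc_totals = {
        loc: sum(c for (l, _), c in zip(pre_cells, pre_counts) if l == loc)
        for loc in LOCATIONS
    }
    cue_seq = _constrained_location_sequence(loc_totals, rng)
    flags_per_loc: dict[str, list[bool]] = {}
    for (loc, ch), cnt in zip(pre_cells, pre_counts):
        flags_per_loc.setdefault(loc, []).extend([ch] * cnt)
    for loc in flags_per_loc:
        rng.shuffle(flags_per_loc[loc])
    pre_rows = []
    cursor = {loc: 0 for loc in LOCATIONS}
    for loc in cue_seq:
        ch = flags_per_loc[loc][cursor[loc]]
        cursor[loc] += 1
        pre_rows.append(("pre_cue", loc, loc if ch else "none"))

    nocue_rows = [("no_cue", "none", loc) for loc, c in zip(LOCATIONS, nocue_change_counts) for _ in range(c)]
    nocue_rows += [("no_cue", "none", "none")] * n_nochange
    rng.shuffle(nocue_rows)

    # Interleave trial types at random positions, preserving each type's order
    # (so the pre-cue constraint survives the merge).
    type_order = np.array([0] * n_pre + [1] * n_nocue)
    rng.shuffle(type_order)
    it_pre = iter(pre_rows)
    it_nocue = iter(nocue_rows)
    rows = [next(it_pre) if t == 0 else next(it_nocue) for t in type_order]

    df = pd.DataFrame(rows, columns=["trial_type", "cue_location", "change_location"])
    # Sample colors: balanced {1, 2} within each (trial type, cue location,
    # change/no-change) cell, independently per location, so every color
    # condition has (near-)equal likelihood.
    changed = (df["change_location"] != "none").to_numpy()
    for loc in LOCATIONS:
        col = np.empty(n, dtype=int)
        for _, idx in df.groupby(["trial_type", "cue_location", changed]).indices.items():
            m = len(idx)
            cell = np.tile([1, 2], (m + 1) // 2)[:m]
            rng.shuffle(cell)
            col[idx] = cell
        df[f"sample_color_{loc}"] = col
    for loc in LOCATIONS:
        col = df[f"sample_color_{loc}"].to_numpy().copy()
        flip = (df["change_location"] == loc).to_numpy()
        col[flip] = 3 - col[flip]
        df[f"compare_color_{loc}"] = col
    return df


def _run_agent(
    df: pd.DataFrame, agent: AgentConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Attended locations and outcomes for every trial."""
    n = len(df)
    attended = np.empty(n, dtype=object)
    current = (
        agent.fixed_location
        if agent.strategy == "fixed"
        else LOCATIONS[rng.integers(3)]
    )
    for i in range(n):
        if agent.strategy == "switching" and i > 0 and i % agent.block_len_trials == 0:
            if rng.random() < agent.switch_hazard:
                current = LOCATIONS[rng.integers(3)]
        attended[i] = (
            df["cue_location"].iat[i] if df["trial_type"].iat[i] == "pre_cue" else current
        )

    outcome = np.empty(n, dtype=object)
    response = np.empty(n, dtype=object)
    u = rng.random(n)
    for i in range(n):
        chg = df["change_location"].iat[i]
        if chg == "none":
            if u[i] < agent.p_cr:
                outcome[i], response[i] = "correct_rejection", "center"
            else:
                outcome[i], response[i] = "false_alarm", attended[i]
        else:
            p = agent.p_hit_attended if chg == attended[i] else agent.p_hit_unattended
            if u[i] < p:
                outcome[i], response[i] = "hit", chg
            else:
                outcome[i], response[i] = "miss", "center"
    out = df.copy()
    out["attended_location"] = attended
    out["outcome"] = outcome
    out["response_location"] = response
    return out


# ---------------------------------------------------------------------------
# Spike generation
# ---------------------------------------------------------------------------

_EPOCHS = ("iti", "early", "sample", "delay", "compare")


def _epoch_edges(protocol: ProtocolConfig) -> np.ndarray:
    return np.array([
        0.0, protocol.iti_s, protocol.sample_on,
        protocol.sample_off, protocol.compare_on, protocol.choice_on,
    ])


def _rate_matrix(
    population: Sequence[UnitSpec], trials: pd.DataFrame, protocol: ProtocolConfig
) -> np.ndarray:
    """Expected rate [units x trials x epochs] of the piecewise-constant model."""
    n_u, n_t = len(population), len(trials)
    rates = np.empty((n_u, n_t, len(_EPOCHS)))
    attended = trials["attended_location"].to_numpy()
    colors = {loc: trials[f"sample_color_{loc}"].to_numpy() for loc in LOCATIONS}
    for ui, unit in enumerate(population):
        base = unit.baseline_hz
        locg = np.array([unit.loc_gain(a) for a in attended])
        colg = np.ones(n_t)
        for loc in LOCATIONS:
            g = np.array([unit.color_gain(loc, c) for c in colors[loc]])
            expo = np.where(attended == loc, unit.attn_gain, 1.0)
            colg *= g ** expo
        rates[ui, :, 0] = base
        rates[ui, :, 1] = base * locg
        for e in (2, 3, 4):
            rates[ui, :, e] = base * locg * colg
    return rates


def _draw_spikes(
    rates: np.ndarray,
    trial_ids: np.ndarray,
    unit_ids: np.ndarray,
    edges: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    durs = np.diff(edges)
    counts = rng.poisson(rates * durs[None, None, :])  # [U, T, E]
    total = int(counts.sum())
    flat = counts.ravel()
    nz = np.flatnonzero(flat)
    reps = flat[nz]
    u_idx, t_idx, e_idx = np.unravel_index(nz, counts.shape)
    starts = np.repeat(edges[:-1][e_idx], reps)
    widths = np.repeat(durs[e_idx], reps)
    times = starts + rng.random(total) * widths
    df = pd.DataFrame({
        "unit_id": np.repeat(unit_ids[u_idx], reps),
        "trial_id": np.repeat(trial_ids[t_idx], reps),
        "spike_time_s": times,
    })
    df.sort_values(["unit_id", "trial_id", "spike_time_s"], inplace=True, kind="stable")
    df.reset_index(drop=True, inplace=True)
    # Enforce strictly increasing times within (unit, trial): nudge exact ties.
    t = df["spike_time_s"].to_numpy()
    same = (df["unit_id"].to_numpy()[1:] == df["unit_id"].to_numpy()[:-1]) & (
        df["trial_id"].to_numpy()[1:] == df["trial_id"].to_numpy()[:-1]
    )
    ties = np.flatnonzero(same & (np.diff(t) <= 0))
    for i in ties:
        t[i + 1] = np.nextafter(t[i], np.inf)
    df["spike_time_s"] = t
    return df


def simulate_session(
    population: Sequence[UnitSpec],
    protocol: ProtocolConfig,
    agent: AgentConfig,
    seed: int,
    session_id: str = "S0",
) -> tuple[pd.DataFrame, SpikeData]:
    """Simulate one session: balanced trial table + Poisson spike trains.

    Randomness flows from ``seed`` through three named substreams (trials,
    agent, spikes) so each component can be reproduced independently.
    """
    if protocol.n_trials < 1:
        raise InvalidConfigError("n_trials must be >= 1")
    ss = np.random.SeedSequence(seed)
    rng_trials, rng_agent, rng_spikes = (np.random.default_rng(c) for c in ss.spawn(3))

    trials = _build_trial_conditions(protocol, rng_trials)
    trials = _run_agent(trials, agent, rng_agent)
    n = len(trials)
    trials.insert(0, "trial_id", np.arange(n))
    trials.insert(1, "session_id", session_id)
    is_pre = (trials["trial_type"] == "pre_cue").to_numpy()
    trials["cue_on"] = np.where(is_pre, protocol.cue_on, np.nan)
    trials["cue_off"] = np.where(is_pre, protocol.cue_off, np.nan)
    trials["sample_on"] = protocol.sample_on
    trials["sample_off"] = protocol.sample_off
    trials["compare_on"] = protocol.compare_on
    trials["choice_on"] = protocol.choice_on
    trials = trials[TRIAL_COLUMNS]

    unit_ids = np.array([u.unit_id for u in population], dtype=int)
    if len(population):
        rates = _rate_matrix(population, trials, protocol)
        spikes_df = _draw_spikes(
            rates, trials["trial_id"].to_numpy(), unit_ids, _epoch_edges(protocol), rng_spikes
        )
    else:
        spikes_df = pd.DataFrame(
            {"unit_id": np.array([], dtype=int), "trial_id": np.array([], dtype=int),
             "spike_time_s": np.array([], dtype=float)}
        )
    return trials, SpikeData(df=spikes_df, unit_ids=unit_ids)


# ---------------------------------------------------------------------------
# Canonical fixtures
# ---------------------------------------------------------------------------


def canonical_fixtures() -> dict[str, dict]:
    """Specs of the three canonical sessions used in tests and docs.

    ``bird1_like``: switching agent, mixed tuned population. ``bird2_like``:
    fixed-top agent, strong location tuning. ``null``: untuned units with
    attn_gain 1 — no location or color signal anywhere.
    """
    mixed = {"location_only": 0.29, "color_only": 0.04, "both": 0.23, "untuned": 0.44}
    return {
        "bird1_like": dict(
            n_units=30, fractions=mixed, attn_gain=2.0,
            agent=AgentConfig(strategy="switching", switch_hazard=1.0, block_len_trials=20),
        ),
        "bird2_like": dict(
            n_units=30, fractions=mixed, attn_gain=2.0,
            agent=AgentConfig(strategy="fixed", fixed_location="top",
                              p_hit_attended=0.95, p_hit_unattended=0.03),
        ),
        "null": dict(
            n_units=30,
            fractions={"location_only": 0.0, "color_only": 0.0, "both": 0.0, "untuned": 1.0},
            attn_gain=1.0,
            agent=AgentConfig(strategy="switching", switch_hazard=1.0, block_len_trials=20),
        ),
    }


def generate_fixture_suite(
    out_dir: str | Path, seed: int, n_trials: int = 240
) -> dict[str, dict[str, str]]:
    """Write the three canonical sessions as CSV; returns per-file checksums."""
    from .io import write_spikes, write_trials  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    protocol = ProtocolConfig(n_trials=n_trials)
    manifest: dict[str, dict[str, str]] = {}
    for i, (name, spec) in enumerate(canonical_fixtures().items()):
        pop = make_population(spec["n_units"], spec["fractions"],
                              seed=seed + i, attn_gain=spec["attn_gain"])
        trials, spikes = simulate_session(pop, protocol, spec["agent"],
                                          seed=seed + 100 + i, session_id=name)
        paths = {
            "trials": out / f"{name}_trials.csv",
            "spikes": out / f"{name}_spikes.csv",
        }
        write_trials(trials, paths["trials"])
        write_spikes(spikes, paths["spikes"])
        manifest[name] = {
            k: hashlib.sha256(p.read_bytes()).hexdigest() for k, p in paths.items()
        }
    (out / "fixtures.json").write_text(json.dumps(manifest, indent=2))
    return manifest
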