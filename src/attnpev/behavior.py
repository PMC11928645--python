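"""Behavioral performance metrics and the block-based location-preference
surrogate.

The surrogate estimates which location an animal covertly attended in no-cue
trials: each session's completed trials are split into equal contiguous
blocks, the no-cue change-detection hit rate is computed per location within
each block, locations are ranked per block (preferred / intermediate / least
preferred, ties broken by display order: top before middle before bottom),
and the session's preferred location is the one most often ranked preferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import completed_trials
from .synth import LOCATIONS

_RANKS = ("preferred", "intermediate", "least")


@dataclass
class SessionPerformance:
    """Hit and correct-rejection rates in percent, per location.

    Undefined rates (zero denominator) are NaN, never 0. For no-cue trials
    the correct-rejection rate has no location and is stored under 'pooled'.
    """

    hit_rate: dict[str, float]
    cr_rate: dict[str, float]
    n_change: dict[str, int]
    n_nochange: dict[str, int]


def _rate(num: int, den: int) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def session_performance(
    trials: pd.DataFrame, trial_type: str = "pre_cue"
) -> SessionPerformance:
    """Per-location hit and correct-rejection rates from completed trials.

    Pre-cue trials group by cue location (both hit and CR); no-cue change
    trials group by change location and the CR rate is pooled.
    """
    comp = completed_trials(trials)
    comp = comp[comp["trial_type"] == trial_type]
    hit_rate: dict[str, float] = {}
    n_change: dict[str, int] = {}
    cr_rate: dict[str, float] = {}
    n_nochange: dict[str, int] = {}
    group_col = "cue_location" if trial_type == "pre_cue" else "change_location"
    for loc in LOCATIONS:
        chg = comp[(comp[group_col] == loc) & (comp["change_location"] != "none")]
        hits = int((chg["outcome"] == "hit").sum())
        misses = int((chg["outcome"] == "miss").sum())
        hit_rate[loc] = _rate(hits, hits + misses)
        n_change[loc] = hits + misses
    if trial_type == "pre_cue":
        for loc in LOCATIONS:
            nc = comp[(comp["cue_location"] == loc) & (comp["change_location"] == "none")]
            crs = int((nc["outcome"] == "correct_rejection").sum())
            fas = int((nc["outcome"] == "false_alarm").sum())
            cr_rate[loc] = _rate(crs, crs + fas)
            n_nochange[loc] = crs + fas
    else:
        nc = comp[comp["change_location"] == "none"]
        crs = int((nc["outcome"] == "correct_rejection").sum())
        fas = int((nc["outcome"] == "false_alarm").sum())
        cr_rate["pooled"] = _rate(crs, crs + fas)
        n_nochange["pooled"] = crs + fas
    return SessionPerformance(hit_rate, cr_rate, n_change, n_nochange)


# ---------------------------------------------------------------------------
# Block preference surrogate
# ---------------------------------------------------------------------------


@dataclass
class BlockLabels:
    """Per-block location ranking with the underlying hit rates."""

    labels: list[dict[str, str]]       # per block: location -> rank
    hit_rates: list[dict[str, float]]  # per block: location -> % (NaN if undefined)
    block_sizes: list[int]


def _rank_block(rates: Mapping[str, float]) -> dict[str, str]:
    """Rank locations by descending hit rate; NaN ranks last; ties by display
    order (top before middle before bottom)."""
    order = sorted(
        range(3),
        key=lambda i: (
            np.isnan(rates[LOCATIONS[i]]),          # undefined last
            -(rates[LOCATIONS[i]] if not np.isnan(rates[LOCATIONS[i]]) else 0.0),
            i,                                       # display-order tie-break
        ),
    )
    return {LOCATIONS[i]: _RANKS[pos] for pos, i in enumerate(order)}


def block_preference(trials: pd.DataFrame, n_blocks: int = 5) -> BlockLabels:
    """Rank locations by no-cue change hit rate within equal session blocks.

    Blocks are contiguous, non-overlapping spans of the session's completed
    trials (sizes differing by at most 1); hit rates within a block use only
    its no-cue change trials.
    """
    comp = completed_trials(trials)
    nocue_change = ((comp["trial_type"] == "no_cue")
                    & (comp["change_location"] != "none"))
    if int(nocue_change.sum()) < n_blocks:
        raise ValueError("need at least n_blocks no-cue change trials")
    chunks = np.array_split(np.arange(len(comp)), n_blocks)
    labels, rates_out, sizes = [], [], []
    for chunk in chunks:
        blk = comp.iloc[chunk]
        blk = blk[(blk["trial_type"] == "no_cue") & (blk["change_location"] != "none")]
        rates = {}
        for loc in LOCATIONS:
            at = blk[blk["change_location"] == loc]
            hits = int((at["outcome"] == "hit").sum())
            n = int(at["outcome"].isin(["hit", "miss"]).sum())
            rates[loc] = _rate(hits, n)
        labels.append(_rank_block(rates))
        rates_out.append(rates)
        sizes.append(len(chunk))
    return BlockLabels(labels, rates_out, sizes)


def session_preference(blocks: BlockLabels) -> tuple[str, str, str]:
    """Order locations by how often each was the block-preferred one.

    The highest count wins; ties resolve by display position (top, then
    middle, then bottom); medium and least follow from the ranking.
    """
    counts = {loc: 0 for loc in LOCATIONS}
    for lab in blocks.labels:
        for loc, rank in lab.items():
            if rank == "preferred":
                counts[loc] += 1
    order = sorted(range(3), key=lambda i: (-counts[LOCATIONS[i]], i))
    return tuple(LOCATIONS[i] for i in order)  # type: ignore[return-value]


@dataclass
class PreferenceResult:
    """Dataset-level block-preference fractions with a block-size sweep."""

    block_fractions: dict[int, dict[str, float]]   # s -> location -> fraction
    session_preferred: dict[int, list[str]]        # s -> preferred per session
    stable: bool                                   # same modal location at all s
    modal_location: dict[int, str]


def preference_fractions(
    sessions: Sequence[pd.DataFrame],
    s_values: Sequence[int] = tuple(range(3, 11)),
    default_s: int = 5,
) -> PreferenceResult:
    """Fraction of all blocks (all sessions) preferring each location.

    Recomputed for every block count ``s``; stability means the modal
    session-preferred location is identical across the sweep (reported, not
    enforced).
    """
    if len(sessions) == 0:
        raise ValueError("need at least one session")
    s_all = sorted(set(list(s_values) + [default_s]))
    block_fractions: dict[int, dict[str, float]] = {}
    session_preferred: dict[int, list[str]] = {}
    modal: dict[int, str] = {}
    for s in s_all:
        counts = {loc: 0 for loc in LOCATIONS}
        total = 0
        per_session: list[str] = []
        for trials in sessions:
            blocks = block_preference(trials, n_blocks=s)
            for lab in blocks.labels:
                for loc, rank in lab.items():
                    if rank == "preferred":
                        counts[loc] += 1
                total += 1
            per_session.append(session_preference(blocks)[0])
        block_fractions[s] = {loc: counts[loc] / total for loc in LOCATIONS}
        session_preferred[s] = per_session
        # modal session-level preference, display-order tie-break
        tallies = {loc: per_session.count(loc) for loc in LOCATIONS}
        modal[s] = max(LOCATIONS, key=lambda l: (tallies[l], -LOCATIONS.index(l)))
    stable = len(set(modal.values())) == 1
    return PreferenceResult(block_fractions, session_preferred, stable, modal)


# ---------------------------------------------------------------------------
# Location tests
# ---------------------------------------------------------------------------


@dataclass
class LocationTests:
    h_stat: float
    p_value: float
    degenerate: bool
    posthoc: pd.DataFrame  # pairwise Dunn z and Bonferroni p


def _dunn_posthoc(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons with Bonferroni control."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    # tie correction term
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    splits = np.cumsum([len(groups[g]) for g in names])[:-1]
    mean_ranks = {g: r.mean() for g, r in zip(names, np.split(ranks, splits))}
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            na, nb = len(groups[a]), len(groups[b])
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            rows.append({"group_a": a, "group_b": b, "z": z,
                         "p_corrected": min(p * m, 1.0)})
    return pd.DataFrame(rows)


def location_tests(rates_by_location: Mapping[str, Sequence[float]]) -> LocationTests:
    """Kruskal-Wallis omnibus on per-session rates grouped by location, with
    Dunn-Bonferroni pairwise post hocs.

    Identical data across all groups yields p = 1 with the degenerate flag.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in rates_by_location.items()}
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 sessions per location")
    arrays = list(groups.values())
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]) and np.ptp(arrays[0]) == 0:
        posthoc = _dunn_posthoc(groups)
        return LocationTests(0.0, 1.0, True, posthoc)
    h, p = stats.kruskal(*arrays)
    return LocationTests(float(h), float(p), False, _dunn_posthoc(groups))
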