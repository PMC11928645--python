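"""Sliding-window firing-rate tensors and trial inclusion rules.

Rates are computed in overlapping bins (default 200 ms advanced in 20 ms
steps) aligned to a task event. Bin intervals are half-open ``[t, t + width)``
anchored at the window start, so a spike on a boundary belongs to exactly one
non-overlapping bin. Bin timestamps are reported at bin centers; with 200 ms
bins this smears any rate change by +/-100 ms, so apparent effects can precede
the aligning event by up to half a bin width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import SpikeData

COMPLETED_OUTCOMES = frozenset({"hit", "miss", "correct_rejection", "false_alarm"})


class MissingEventError(ValueError):
    """An align event is absent (NaN) for one or more trials."""

    def __init__(self, event: str, trial_ids: Sequence):
        self.trial_ids = list(trial_ids)
        super().__init__(f"align event {event!r} missing for trials {self.trial_ids}")


class EmptySelectionError(ValueError):
    """Inclusion filters removed every unit or every trial."""


class InsufficientTrialsError(ValueError):
    """A condition has fewer trials than the requested subsample."""


@dataclass(frozen=True)
class BinGrid:
    """Sliding-bin layout relative to an align event.

    ``window`` is ``(start, end)`` in seconds relative to the event; bins are
    ``[start + k*step, start + k*step + bin_width)`` for every k that fits
    inside the window.
    """

    align_event: str = "sample_on"
    window: tuple[float, float] = (-0.7, 1.9)
    bin_width_s: float = 0.2
    step_s: float = 0.02

    def __post_init__(self) -> None:
        if self.bin_width_s <= 0 or self.step_s <= 0:
            raise ValueError("bin_width_s and step_s must be > 0")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must be < window end")
        if self.window[1] - self.window[0] < self.bin_width_s - 1e-12:
            raise ValueError("window shorter than one bin")

    @property
    def n_bins(self) -> int:
        span = self.window[1] - self.window[0] - self.bin_width_s
        return int(np.floor(span / self.step_s + 1e-9)) + 1

    @property
    def starts(self) -> np.ndarray:
        return self.window[0] + self.step_s * np.arange(self.n_bins)

    @property
    def centers(self) -> np.ndarray:
        return self.starts + self.bin_width_s / 2.0


@dataclass
class RateTensor:
    """Firing rates [units x trials x bins] in spikes/s with bin metadata."""

    values: np.ndarray
    unit_ids: np.ndarray
    trial_ids: np.ndarray
    grid: BinGrid
    bin_centers: np.ndarray | None = None  # set when bins were subselected

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.unit_ids = np.asarray(self.unit_ids)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.values.shape != (len(self.unit_ids), len(self.trial_ids),
                                 self.n_bins):
            raise ValueError("values shape inconsistent with id lists")
        if self.bin_centers is None:
            self.bin_centers = self.grid.centers

    @property
    def n_bins(self) -> int:
        return self.values.shape[2] if self.values.ndim == 3 else self.grid.n_bins

    def select_bins(self, idx: np.ndarray | Sequence[int]) -> "RateTensor":
        idx = np.asarray(idx, dtype=int)
        return RateTensor(self.values[:, :, idx], self.unit_ids, self.trial_ids,
                          self.grid, bin_centers=np.asarray(self.bin_centers)[idx])

    def select_trials(self, trial_ids: Iterable) -> "RateTensor":
        wanted = np.asarray(list(trial_ids))
        pos = {t: i for i, t in enumerate(self.trial_ids)}
        idx = np.array([pos[t] for t in wanted], dtype=int)
        return RateTensor(self.values[:, idx, :], self.unit_ids, wanted,
                          self.grid, bin_centers=self.bin_centers)

    def select_units(self, unit_ids: Iterable) -> "RateTensor":
        wanted = np.asarray(list(unit_ids))
        pos = {u: i for i, u in enumerate(self.unit_ids)}
        idx = np.array([pos[u] for u in wanted], dtype=int)
        return RateTensor(self.values[idx, :, :], wanted, self.trial_ids,
                          self.grid, bin_centers=self.bin_centers)


def bin_firing_rates(
    spikes: SpikeData, trials: pd.DataFrame, grid: BinGrid
) -> RateTensor:
    """Count spikes in sliding half-open bins and convert to spikes/s.

    A spike may contribute to several overlapping bins; a bin with zero spikes
    is exactly 0. Trials lacking the align event raise
    :class:`MissingEventError` listing the offending trial ids.
    """
    if grid.align_event not in trials.columns:
        raise MissingEventError(grid.align_event, trials["trial_id"].tolist())
    align = trials[grid.align_event].to_numpy(dtype=float)
    missing = trials.loc[np.isnan(align), "trial_id"]
    if len(missing):
        raise MissingEventError(grid.align_event, missing.tolist())

    unit_ids = np.asarray(spikes.unit_ids)
    trial_ids = trials["trial_id"].to_numpy()
    starts = grid.starts
    ends = starts + grid.bin_width_s
    counts = np.zeros((len(unit_ids), len(trial_ids), grid.n_bins))
    upos = {u: i for i, u in enumerate(unit_ids)}
    tpos = {t: j for j, t in enumerate(trial_ids)}
    for (u, t), times in spikes.grouped().items():
        if u not in upos or t not in tpos:
            continue
        rel = times - align[tpos[t]]
        counts[upos[u], tpos[t], :] = (
            np.searchsorted(rel, ends, side="left")
            - np.searchsorted(rel, starts, side="left")
        )
    return RateTensor(counts / grid.bin_width_s, unit_ids, trial_ids, grid)


def select_nonoverlapping(grid: BinGrid, stride_bins: int | None = None) -> np.ndarray:
    """Indices of bins spaced so the selected bins are pairwise disjoint.

    For 200 ms bins at a 20 ms step the default stride is 10 (every 10th bin,
    i.e. 200 ms bins advanced in 200 ms steps).
    """
    if stride_bins is None:
        stride_bins = int(np.ceil(grid.bin_width_s / grid.step_s - 1e-9))
    if stride_bins * grid.step_s < grid.bin_width_s - 1e-9:
        raise ValueError(
            f"stride_bins={stride_bins} leaves bins overlapping "
            f"(need stride*step >= bin_width)"
        )
    return np.arange(0, grid.n_bins, stride_bins)


def completed_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Trials with a behavioral response (aborted trials are never analyzed)."""
    return trials[trials["outcome"].isin(COMPLETED_OUTCOMES)].copy()


def apply_inclusion_filters(
    spikes: SpikeData,
    trials: pd.DataFrame,
    min_trials_per_condition: int = 20,
    min_iti_rate_hz: float = 0.5,
    *,
    iti_window: tuple[float, float] = (0.0, 2.0),
    condition_cols: Sequence[str] = ("trial_type", "cue_location"),
) -> tuple[np.ndarray, pd.DataFrame]:
    """Apply the unit and condition inclusion criteria.

    Units must fire at least ``min_iti_rate_hz`` on average during the ITI of
    completed trials; conditions (grouped by ``condition_cols``) must have at
    least ``min_trials_per_condition`` completed trials. Returns the kept unit
    ids and the kept trial rows. Raises :class:`EmptySelectionError` rather
    than silently returning nothing.
    """
    kept = completed_trials(trials)
    if kept.empty:
        raise EmptySelectionError("no completed trials")

    lo, hi = iti_window
    tids = set(kept["trial_id"])
    df = spikes.df
    in_iti = (
        df["trial_id"].isin(tids)
        & (df["spike_time_s"] >= lo)
        & (df["spike_time_s"] < hi)
    )
    n_spk = df.loc[in_iti].groupby("unit_id").size()
    total_time = len(kept) * (hi - lo)
    unit_ids = np.asarray(spikes.unit_ids)
    rates = np.array([n_spk.get(u, 0) / total_time for u in unit_ids])
    kept_units = unit_ids[rates >= min_iti_rate_hz]
    if len(kept_units) == 0:
        raise EmptySelectionError("all units below the ITI firing-rate floor")

    sizes = kept.groupby(list(condition_cols))["trial_id"].transform("size")
    kept = kept[sizes >= min_trials_per_condition]
    if kept.empty:
        raise EmptySelectionError("every condition below the trial-count floor")
    return kept_units, kept


def subsample_first_k(
    trials: pd.DataFrame,
    by: str | Sequence[str],
    k: int = 20,
) -> pd.DataFrame:
    """First ``k`` completed trials per condition, in session order.

    ``by`` names the column(s) defining a condition. Deterministic; raises
    :class:`InsufficientTrialsError` naming any condition with fewer than
    ``k`` trials, so downstream analyses never compare unequal samples.
    """
    cols = [by] if isinstance(by, str) else list(by)
    comp = completed_trials(trials)
    counts = comp.groupby(cols).size()
    low = counts[counts < k]
    if len(low):
        raise InsufficientTrialsError(
            f"conditions with fewer than {k} trials: {low.to_dict()}"
        )
    return comp.groupby(cols, group_keys=False, sort=False).head(k)
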