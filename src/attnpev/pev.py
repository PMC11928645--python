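"""ANOVA effect sizes as percent explained variance (PEV) and the
attentional-shift statistics built on them.

The information a task factor carries about a unit's firing rate is the
one-way ANOVA effect size, expressed either as

    omega^2   = (SSQ_e - df_e * MS_err) / (SSQ_total + MS_err)
    omega_p^2 = df_e * (F - 1) / (df_e * (F - 1) + n)

which are algebraically identical for one-way designs. omega^2 may be
negative for weak effects; negative values are kept as-is everywhere except
the display transform. Significance of a PEV time course is judged against an
empirical null built by shuffling the group labels: a bin is significant when
the observed value exceeds the 95th percentile of the shuffled values
(upper-tail criterion); the [2.5, 97.5] band is also exposed for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .binning import RateTensor


class InvalidInputError(ValueError):
    pass


class DegenerateValueError(ValueError):
    """The requested statistic is undefined for this input (zero variance)."""


# ---------------------------------------------------------------------------
# One-way ANOVA and effect sizes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    ssq_effect: float
    ssq_total: float
    ms_error: float
    df_effect: int
    df_error: int
    f_stat: float
    n_obs: int
    p_value: float


def one_way_anova(values: Sequence[float], labels: Sequence) -> AnovaResult:
    """Standard one-way decomposition of ``values`` grouped by ``labels``.

    Requires at least two groups, each non-empty. With zero within-group
    variance the F statistic is +inf (p = 0) when the group means differ,
    and 0 (p = 1) when they do not.
    """
    y = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    if y.shape != lab.shape or y.ndim != 1:
        raise InvalidInputError("values and labels must be 1-D and aligned")
    groups, inv = np.unique(lab, return_inverse=True)
    if len(groups) < 2:
        raise InvalidInputError("need at least two groups")
    n_g = np.bincount(inv)
    if np.any(n_g == 0):  # pragma: no cover - unique() cannot produce this
        raise InvalidInputError("every group must be non-empty")

    n = y.size
    grand = y.mean()
    means = np.bincount(inv, weights=y) / n_g
    ssb = float(np.sum(n_g * (means - grand) ** 2))
    sst = float(np.sum((y - grand) ** 2))
    ssw = max(sst - ssb, 0.0)
    df_e = len(groups) - 1
    df_err = n - len(groups)
    if df_err <= 0:
        raise InvalidInputError("need more observations than groups")
    msw = ssw / df_err
    if msw > 0:
        f = (ssb / df_e) / msw
        p = float(stats.f.sf(f, df_e, df_err))
    else:
        f = np.inf if ssb > 0 else 0.0
        p = 0.0 if ssb > 0 else 1.0
    return AnovaResult(ssb, sst, msw, df_e, df_err, float(f), int(n), p)


def omega_squared(a: AnovaResult) -> float:
    """Effect size omega^2 from a one-way ANOVA; may be negative."""
    denom = a.ssq_total + a.ms_error
    if denom == 0:
        raise DegenerateValueError("omega^2 undefined: total variance is zero")
    return (a.ssq_effect - a.df_effect * a.ms_error) / denom


def partial_omega_squared(f_stat: float, df_effect: int, n_obs: int) -> float:
    """Partial omega^2 from the F statistic, effect df, and observation count."""
    if df_effect < 1:
        raise InvalidInputError("df_effect must be >= 1")
    if n_obs < 2:
        raise InvalidInputError("n_obs must be >= 2")
    x = df_effect * (f_stat - 1.0)
    return x / (x + n_obs)


# ---------------------------------------------------------------------------
# Vectorized omega^2 over a rate tensor
# ---------------------------------------------------------------------------


def _omega_sq_tensor(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """omega^2 for every (unit, bin) of a [units x trials x bins] tensor.

    Same decomposition as :func:`one_way_anova`, vectorized over units and
    bins for a shared label vector. Degenerate (zero-variance) cells are NaN.
    """
    groups, inv = np.unique(np.asarray(labels), return_inverse=True)
    g = len(groups)
    if g < 2:
        raise InvalidInputError("need at least two groups")
    n = values.shape[1]
    n_g = np.bincount(inv).astype(float)
    ind = np.zeros((n, g))
    ind[np.arange(n), inv] = 1.0

    # group sums: [U, G, B]
    gs = np.einsum("utb,tg->ugb", values, ind)
    means = gs / n_g[None, :, None]
    grand = values.mean(axis=1)  # [U, B]
    ssb = np.einsum("g,ugb->ub", n_g, (means - grand[:, None, :]) ** 2)
    sst = np.sum((values - grand[:, None, :]) ** 2, axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    msw = ssw / (n - g)
    denom = sst + msw
    with np.errstate(invalid="ignore", divide="ignore"):
        om = (ssb - (g - 1) * msw) / denom
    om[denom == 0] = np.nan
    return om


# ---------------------------------------------------------------------------
# Time courses, permutation nulls, population summaries
# ---------------------------------------------------------------------------


@dataclass
class PevSeries:
    """Per-unit PEV time course with optional permutation null."""

    unit_id: object
    bin_centers: np.ndarray
    pev: np.ndarray
    null_lo: np.ndarray | None = None    # 2.5th percentile of shuffles
    null_hi: np.ndarray | None = None    # 97.5th percentile
    null_upper: np.ndarray | None = None  # 95th percentile (significance cut)
    significant: np.ndarray | None = None


def pev_timecourse(
    rates: RateTensor, labels: Sequence
) -> list[PevSeries]:
    """omega^2 of the label factor per unit per bin."""
    lab = np.asarray(labels)
    if len(lab) != len(rates.trial_ids):
        raise InvalidInputError("labels must align with trial_ids")
    om = _omega_sq_tensor(rates.values, lab)
    return [
        PevSeries(unit_id=u, bin_centers=np.asarray(rates.bin_centers), pev=om[i])
        for i, u in enumerate(rates.unit_ids)
    ]


def permutation_band(
    rates: RateTensor,
    labels: Sequence,
    n_perm: int = 1000,
    quantiles: tuple[float, float] = (0.025, 0.975),
    seed: int = 0,
) -> list[PevSeries]:
    """PEV time courses with a shuffled-label null per unit-bin.

    Labels are permuted across trials ``n_perm`` times (one shared permutation
    per iteration, as the shuffle breaks the trial-label pairing for all units
    at once). A bin is flagged significant when the observed omega^2 exceeds
    the 95th percentile of its shuffled values.
    """
    if n_perm < 100:
        raise InvalidInputError("n_perm must be >= 100")
    lab = np.asarray(labels)
    if len(np.unique(lab)) < 2:
        raise InvalidInputError("labels are constant")
    if len(lab) != len(rates.trial_ids):
        raise InvalidInputError("labels must align with trial_ids")

    rng = np.random.default_rng(seed)
    observed = _omega_sq_tensor(rates.values, lab)
    null = np.empty((n_perm,) + observed.shape)
    for p in range(n_perm):
        null[p] = _omega_sq_tensor(rates.values, rng.permutation(lab))
    lo = np.quantile(null, quantiles[0], axis=0)
    hi = np.quantile(null, quantiles[1], axis=0)
    upper = np.quantile(null, 0.95, axis=0)
    sig = observed > upper
    return [
        PevSeries(
            unit_id=u, bin_centers=np.asarray(rates.bin_centers), pev=observed[i],
            null_lo=lo[i], null_hi=hi[i], null_upper=upper[i], significant=sig[i],
        )
        for i, u in enumerate(rates.unit_ids)
    ]


@dataclass
class PopulationSummary:
    bin_centers: np.ndarray
    mean_pev: np.ndarray
    sem_pev: np.ndarray
    pct_significant: np.ndarray | None
    sem_degenerate: bool = False


def population_summary(series: Sequence[PevSeries]) -> PopulationSummary:
    """Mean/SEM of PEV across units plus percent of significant units per bin.

    With a single unit the SEM is undefined and reported as 0 with the
    ``sem_degenerate`` flag set.
    """
    if len(series) == 0:
        raise InvalidInputError("need at least one unit")
    pev = np.stack([s.pev for s in series])
    n = pev.shape[0]
    mean = np.nanmean(pev, axis=0)
    if n > 1:
        sem = np.nanstd(pev, axis=0, ddof=1) / np.sqrt(n)
        degenerate = False
    else:
        sem = np.zeros(pev.shape[1])
        degenerate = True
    pct = None
    if all(s.significant is not None for s in series):
        sig = np.stack([s.significant for s in series])
        pct = 100.0 * sig.sum(axis=0) / n
    return PopulationSummary(np.asarray(series[0].bin_centers), mean, sem, pct, degenerate)


# ---------------------------------------------------------------------------
# Unit classification by factor
# ---------------------------------------------------------------------------


def _anova_p_tensor(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way ANOVA p-value for every (unit, bin), vectorized."""
    groups, inv = np.unique(np.asarray(labels), return_inverse=True)
    g = len(groups)
    n = values.shape[1]
    n_g = np.bincount(inv).astype(float)
    ind = np.zeros((n, g))
    ind[np.arange(n), inv] = 1.0
    gs = np.einsum("utb,tg->ugb", values, ind)
    means = gs / n_g[None, :, None]
    grand = values.mean(axis=1)
    ssb = np.einsum("g,ugb->ub", n_g, (means - grand[:, None, :]) ** 2)
    sst = np.sum((values - grand[:, None, :]) ** 2, axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    msw = ssw / (n - g)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ssb / (g - 1)) / msw
    p = np.where(msw > 0, stats.f.sf(np.where(msw > 0, f, 0.0), g - 1, n - g), np.where(ssb > 0, 0.0, 1.0))
    return p


def classify_units(
    rates: RateTensor,
    location_labels: Sequence,
    color_labels: Sequence | Mapping[str, Sequence],
    alpha: float = 0.05,
) -> tuple[dict[str, int], list[str]]:
    """Partition units into location_only / color_only / both / none.

    A unit is significant for a factor when any tested bin's one-way ANOVA
    p-value falls below ``alpha`` after Bonferroni correction over all
    (bin x factor-test) comparisons performed for that unit. ``color_labels``
    may be a single label vector or a mapping location -> labels (the color
    factor tested independently at each location); any significant color test
    makes the unit color-significant. Pass ``rates`` restricted to
    non-overlapping bins so the corrected tests are independent.
    """
    loc_p = _anova_p_tensor(rates.values, np.asarray(location_labels))
    if isinstance(color_labels, Mapping):
        color_sets = [np.asarray(v) for v in color_labels.values()]
    else:
        color_sets = [np.asarray(color_labels)]
    col_p = [_anova_p_tensor(rates.values, lab) for lab in color_sets]

    n_bins = rates.values.shape[2]
    m = n_bins * (1 + len(color_sets))  # Bonferroni scope: bins x factor tests
    thresh = alpha / m
    counts = {"location_only": 0, "color_only": 0, "both": 0, "none": 0}
    categories: list[str] = []
    for i in range(len(rates.unit_ids)):
        loc_sig = bool(np.nanmin(loc_p[i]) < thresh)
        col_sig = any(bool(np.nanmin(p[i]) < thresh) for p in col_p)
        cat = {
            (True, False): "location_only",
            (False, True): "color_only",
            (True, True): "both",
            (False, False): "none",
        }[(loc_sig, col_sig)]
        counts[cat] += 1
        categories.append(cat)
    return counts, categories


# ---------------------------------------------------------------------------
# Attentional shift (Delta PEV)
# ---------------------------------------------------------------------------


@dataclass
class ShiftTable:
    """Attentional shift of color information, per unit x bin.

    ``gain`` = PEV(pre-cue at location) - PEV(no-cue);
    ``loss`` = PEV(pre-cue at location) - PEV(cue at another location);
    ``overall`` = (gain + loss) / 2 per unit-bin. The population-level
    "absolute average" shift is ``abs(mean over units)`` of ``overall``.
    """

    bin_centers: np.ndarray
    unit_ids: np.ndarray
    gain: np.ndarray
    loss: np.ndarray
    overall: np.ndarray

    def population_overall(self) -> np.ndarray:
        return np.abs(np.nanmean(self.overall, axis=0))


def attentional_shift(
    pev_precue: np.ndarray,
    pev_nocue: np.ndarray,
    pev_cueother: np.ndarray,
    bin_centers: np.ndarray,
    unit_ids: np.ndarray | None = None,
) -> ShiftTable:
    """Delta-PEV gain and loss from three condition-wise PEV arrays.

    All three arrays must share the same [units x bins] shape on the same
    (non-overlapping) bin grid.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (pev_precue, pev_nocue, pev_cueother))
    if not (a.shape == b.shape == c.shape):
        raise InvalidInputError("condition PEV arrays must share a shape")
    if a.shape[-1] != len(bin_centers):
        raise InvalidInputError("bin grid mismatch")
    if a.ndim == 1:
        a, b, c = a[None, :], b[None, :], c[None, :]
    if unit_ids is None:
        unit_ids = np.arange(a.shape[0])
    gain = a - b
    loss = a - c
    if not (np.isfinite(gain).all() and np.isfinite(loss).all()):
        raise InvalidInputError("shift values must be finite")
    return ShiftTable(np.asarray(bin_centers), np.asarray(unit_ids),
                      gain, loss, (gain + loss) / 2.0)


def signrank_bonferroni(
    shift_values: np.ndarray,
    n_bins_tested: int | None = None,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Wilcoxon signed-rank against 0 per bin, Bonferroni over bins.

    ``shift_values`` is [units x bins]. Returns (corrected p per bin,
    significant flags, degenerate flags); an all-zero bin gets p = 1 and is
    flagged degenerate. Needs >= 6 units for any corrected significance.
    """
    x = np.asarray(shift_values, dtype=float)
    if x.ndim != 2:
        raise InvalidInputError("shift_values must be [units x bins]")
    if x.shape[0] < 6:
        raise InvalidInputError("need >= 6 units for the signed-rank test")
    n_bins = x.shape[1]
    if n_bins_tested is None:
        n_bins_tested = n_bins
    p = np.ones(n_bins)
    degenerate = np.zeros(n_bins, dtype=bool)
    for b in range(n_bins):
        col = x[:, b]
        col = col[np.isfinite(col)]
        if np.all(col == 0) or col.size == 0:
            degenerate[b] = True
            continue
        p[b] = stats.wilcoxon(col, alternative=alternative).pvalue
    p_corr = np.minimum(p * n_bins_tested, 1.0)
    return p_corr, p_corr < alpha, degenerate


def display_log_transform(
    values: np.ndarray, floor: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Sign-split decadic log transform used only for display.

    Returns (sign, log10 of the floored magnitude); e.g. -0.001 -> (-1, -3).
    Zeros take positive sign by convention and the floor. Statistics are
    always computed on the original values, never on this transform.
    """
    v = np.asarray(values, dtype=float)
    sign = np.where(v < 0, -1.0, 1.0)
    mag = np.maximum(np.abs(v), floor)
    return sign, np.log10(mag)


# ---------------------------------------------------------------------------
# Session-level condition wiring for the color-shift analysis
# ---------------------------------------------------------------------------


def color_condition_masks(trials, location: str) -> dict[str, np.ndarray]:
    """Boolean masks over trial rows for the three color-PEV conditions.

    ``cue_at``: pre-cue trials with the cue at ``location``; ``no_cue``:
    no-cue trials; ``cue_other``: pre-cue trials with the cue elsewhere. The
    color labels in every condition are the session color index shown at
    ``location``.
    """
    pre = (trials["trial_type"] == "pre_cue").to_numpy()
    at = (trials["cue_location"] == location).to_numpy()
    return {
        "cue_at": pre & at,
        "no_cue": ~pre,
        "cue_other": pre & ~at,
    }


def session_color_shift(
    rates: RateTensor,
    trials,
    subsample_k: int | None = 20,
) -> ShiftTable:
    """Attentional color-information shift for a whole session.

    For every location, computes the color-PEV time course (labels: the color
    index shown at that location) separately for pre-cue-at-location, no-cue,
    and cue-other trials, optionally equalizing trial counts to the first
    ``subsample_k`` per color within each condition, then averages gain and
    loss over the three locations per unit. ``rates`` should already be
    restricted to non-overlapping bins.
    """
    from .binning import subsample_first_k
    from .synth import LOCATIONS

    gains, losses = [], []
    for loc in LOCATIONS:
        masks = color_condition_masks(trials, loc)
        pevs = {}
        for cond, mask in masks.items():
            sub = trials[mask]
            if subsample_k is not None:
                sub = subsample_first_k(sub, by=f"sample_color_{loc}", k=subsample_k)
            r = rates.select_trials(sub["trial_id"])
            pevs[cond] = _omega_sq_tensor(r.values, sub[f"sample_color_{loc}"].to_numpy())
        gains.append(pevs["cue_at"] - pevs["no_cue"])
        losses.append(pevs["cue_at"] - pevs["cue_other"])
    gain = np.nanmean(gains, axis=0)
    loss = np.nanmean(losses, axis=0)
    return ShiftTable(np.asarray(rates.bin_centers), rates.unit_ids,
                      gain, loss, (gain + loss) / 2.0)
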