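"""Pseudo-simultaneous population construction and cross-temporal decoding.

A pseudo-population matrix is assembled by drawing, independently for each
unit, one of that unit's real trials of the matching condition per
pseudo-trial (default 120 pseudo-trials, 40 per cue location). A linear
max-margin classifier (one-vs-one SVM) is trained on a stratified 90% of the
pseudo-trials in one time bin and tested in every bin, repeated over random
splits; chance is 1/3. Significance is judged against an identical pipeline
run on shuffled labels, and cross-temporal cells survive only in connected
clusters larger than five neighboring bins (4-connectivity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage, stats
from sklearn.svm import SVC

from .binning import RateTensor
from .synth import LOCATIONS


class InvalidConfigError(ValueError):
    pass


class InvalidInputError(ValueError):
    pass


class InsufficientTrialsError(ValueError):
    pass


def default_classifier() -> SVC:
    """Linear max-margin multi-class classifier (one-vs-one reduction)."""
    return SVC(kernel="linear", C=1.0, decision_function_shape="ovo")


# ---------------------------------------------------------------------------
# Pseudo-trial assembly and normalization
# ---------------------------------------------------------------------------


@dataclass
class PseudoTrialSet:
    """Pseudo-simultaneous rates [pseudo-trials x units x bins].

    ``labels`` is None for unlabeled sets (e.g. no-cue test trials).
    """

    X: np.ndarray
    labels: np.ndarray | None
    unit_ids: np.ndarray
    bin_centers: np.ndarray
    n_per_condition: int
    degenerate_bins: np.ndarray | None = None  # set by zscore_per_bin

    @property
    def n_pseudo(self) -> int:
        return self.X.shape[0]

    @property
    def n_bins(self) -> int:
        return self.X.shape[2]


def build_pseudo_trials(
    rates: RateTensor,
    labels: Sequence | None,
    n_per_condition: int = 40,
    seed: int = 0,
    replace_draws: bool | str = "auto",
) -> PseudoTrialSet:
    """Assemble a pseudo-simultaneous population from single-unit trials.

    For each condition and each pseudo-trial, every unit contributes the rate
    vector of one of its own real trials of that condition, drawn
    independently per unit. ``replace_draws``: True, False, or "auto" (with
    replacement only when a unit has fewer real trials than pseudo-trials).
    ``labels=None`` builds one unlabeled pool of ``n_per_condition`` rows from
    all trials.
    """
    rng = np.random.default_rng(seed)
    n_units, n_trials, n_bins = rates.values.shape
    if labels is None:
        conds = [None]
        cond_idx = {None: np.arange(n_trials)}
    else:
        lab = np.asarray(labels)
        if len(lab) != n_trials:
            raise InvalidInputError("labels must align with trials")
        conds = sorted(np.unique(lab).tolist())
        cond_idx = {c: np.flatnonzero(lab == c) for c in conds}

    rows: list[np.ndarray] = []
    out_labels: list = []
    for c in conds:
        idx = cond_idx[c]
        use_replace = replace_draws
        if use_replace == "auto":
            use_replace = len(idx) < n_per_condition
        if not use_replace and len(idx) < n_per_condition:
            raise InsufficientTrialsError(
                f"condition {c!r} has {len(idx)} trials < {n_per_condition} "
                "pseudo-trials and replacement is disabled"
            )
        # draws[u, p]: trial index for unit u, pseudo-trial p
        if use_replace:
            draws = rng.choice(idx, size=(n_units, n_per_condition), replace=True)
        else:
            draws = np.stack([
                rng.permutation(idx)[:n_per_condition] for _ in range(n_units)
            ])
        for p in range(n_per_condition):
            rows.append(rates.values[np.arange(n_units), draws[:, p], :])
            out_labels.append(c)
    X = np.stack(rows)  # [P, U, B]
    lab_arr = None if labels is None else np.asarray(out_labels)
    return PseudoTrialSet(X, lab_arr, np.asarray(rates.unit_ids),
                          np.asarray(rates.bin_centers), n_per_condition)


def zscore_per_bin(pseudo: PseudoTrialSet, per_unit: bool = False) -> PseudoTrialSet:
    """Z-score rates per bin.

    Default pools the mean and SD over all units and pseudo-trials in the bin
    (population-level normalization); ``per_unit=True`` normalizes each unit
    separately instead. Zero-variance entries are left at 0 and flagged.
    """
    X = pseudo.X.astype(float).copy()
    axes = (0, 1) if not per_unit else (0,)
    m = X.mean(axis=axes, keepdims=True)
    s = X.std(axis=axes, keepdims=True)
    degenerate = s == 0
    s_safe = np.where(degenerate, 1.0, s)
    X = (X - m) / s_safe
    X[np.broadcast_to(degenerate, X.shape)] = 0.0
    flags = np.any(degenerate, axis=(0, 1)) if not per_unit else np.any(degenerate, axis=0).any(axis=0)
    return PseudoTrialSet(X, pseudo.labels, pseudo.unit_ids, pseudo.bin_centers,
                          pseudo.n_per_condition, degenerate_bins=np.asarray(flags))


# ---------------------------------------------------------------------------
# Cross-temporal decoding
# ---------------------------------------------------------------------------


@dataclass
class DecodingMatrix:
    """Train-bin x test-bin classification performance with nulls/clusters."""

    performance: np.ndarray          # mean fraction correct [B x B]
    spread: np.ndarray               # SD over resamples
    obs_lo: np.ndarray               # 2.5th percentile over resamples
    obs_hi: np.ndarray               # 97.5th percentile
    bin_centers: np.ndarray
    chance: float
    n_resamples: int
    metadata: dict = field(default_factory=dict)
    null_lo: np.ndarray | None = None
    null_hi: np.ndarray | None = None
    null_q95: np.ndarray | None = None
    null_mean: np.ndarray | None = None
    significant: np.ndarray | None = None
    significant_diagonal: np.ndarray | None = None
    clusters: list[dict] | None = None


def _stratified_split(
    labels: np.ndarray, train_frac: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for c in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == c))
        k = int(round(train_frac * len(idx)))
        train_idx.append(idx[:k])
        test_idx.append(idx[k:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def _decode_loop(
    pseudo: PseudoTrialSet,
    train_frac: float,
    n_resamples: int,
    rng: np.random.Generator,
    classifier_factory: Callable[[], object],
    shuffle_labels: bool,
) -> np.ndarray:
    """Performance samples [n_resamples x B x B]."""
    if pseudo.labels is None:
        raise InvalidInputError("pseudo-trial set must be labeled")
    labels = np.asarray(pseudo.labels)
    n_test_per_cond = round((1.0 - train_frac) * pseudo.n_per_condition)
    if n_test_per_cond < 1:
        raise InvalidConfigError("train_frac leaves < 1 test trial per condition")
    B = pseudo.n_bins
    perf = np.empty((n_resamples, B, B))
    for r in range(n_resamples):
        lab = rng.permutation(labels) if shuffle_labels else labels
        tr, te = _stratified_split(lab, train_frac, rng)
        y_tr, y_te = lab[tr], lab[te]
        for i in range(B):
            clf = classifier_factory()
            clf.fit(pseudo.X[tr, :, i], y_tr)
            for j in range(B):
                pred = clf.predict(pseudo.X[te, :, j])
                perf[r, i, j] = np.mean(pred == y_te)
    return perf


def decode_cross_temporal(
    pseudo: PseudoTrialSet,
    train_frac: float = 0.9,
    n_resamples: int = 1000,
    seed: int = 0,
    classifier_factory: Callable[[], object] | None = None,
) -> DecodingMatrix:
    """Cross-temporal (temporal generalization) decoding of the labels.

    Per resample a stratified ``train_frac`` split is drawn; the classifier is
    fit on each train bin and tested on every bin; performance is the fraction
    of held-out pseudo-trials labeled correctly. Deterministic given ``seed``.
    """
    factory = classifier_factory or default_classifier
    rng = np.random.default_rng(seed)
    perf = _decode_loop(pseudo, train_frac, n_resamples, rng, factory, False)
    n_classes = len(np.unique(pseudo.labels))
    return DecodingMatrix(
        performance=perf.mean(axis=0),
        spread=perf.std(axis=0, ddof=1) if n_resamples > 1 else np.zeros(perf.shape[1:]),
        obs_lo=np.quantile(perf, 0.025, axis=0),
        obs_hi=np.quantile(perf, 0.975, axis=0),
        bin_centers=np.asarray(pseudo.bin_centers),
        chance=1.0 / n_classes,
        n_resamples=n_resamples,
        metadata={
            "classifier": "SVC(kernel=linear), one-vs-one",
            "train_frac": train_frac,
            "seed": seed,
        },
    )


def shuffled_baseline(
    pseudo: PseudoTrialSet,
    n_resamples: int = 1000,
    seed: int = 0,
    train_frac: float = 0.9,
    classifier_factory: Callable[[], object] | None = None,
) -> dict[str, np.ndarray]:
    """Null decoding distribution: labels permuted independently per resample.

    Returns per-cell mean, inner-95% band (2.5/97.5 percentiles), and the 95th
    percentile used for the cross-temporal 5% criterion.
    """
    factory = classifier_factory or default_classifier
    rng = np.random.default_rng(seed)
    perf = _decode_loop(pseudo, train_frac, n_resamples, rng, factory, True)
    return {
        "mean": perf.mean(axis=0),
        "lo": np.quantile(perf, 0.025, axis=0),
        "hi": np.quantile(perf, 0.975, axis=0),
        "q95": np.quantile(perf, 0.95, axis=0),
    }


def attach_null(matrix: DecodingMatrix, null: dict[str, np.ndarray]) -> DecodingMatrix:
    return replace(matrix, null_lo=null["lo"], null_hi=null["hi"],
                   null_q95=null["q95"], null_mean=null["mean"])


def significance_map(
    matrix: DecodingMatrix, min_cluster_bins: int = 5
) -> DecodingMatrix:
    """Flag significant cells and prune small cross-temporal clusters.

    Diagonal cells are significant when the observed inner-95% interval lies
    wholly above the null inner-95% interval (p < 0.025, conservative).
    Off-diagonal cells are first flagged at the 5% level (observed mean above
    the null 95th percentile); only 4-connected regions larger than
    ``min_cluster_bins`` cells survive.
    """
    if matrix.null_hi is None or matrix.null_q95 is None:
        raise InvalidInputError("attach a shuffled baseline first")
    diag_sig = np.diag(matrix.obs_lo) > np.diag(matrix.null_hi)
    flagged = matrix.performance > matrix.null_q95
    labeled, n_lab = ndimage.label(flagged)  # default structure = 4-connectivity
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n_lab + 1))
    keep = np.zeros_like(flagged, dtype=bool)
    clusters = []
    for lab_id, size in zip(range(1, n_lab + 1), sizes):
        if size > min_cluster_bins:
            keep |= labeled == lab_id
            cells = np.argwhere(labeled == lab_id)
            clusters.append({"size": int(size), "cells": cells.tolist()})
    return replace(matrix, significant=keep, significant_diagonal=diag_sig,
                   clusters=clusters)


# ---------------------------------------------------------------------------
# Cross-trial-type transfer
# ---------------------------------------------------------------------------


@dataclass
class TransferResult:
    """Classification of unlabeled pseudo-trials by a pre-cue-trained decoder."""

    bin_centers: np.ndarray
    classes: tuple
    fractions: np.ndarray        # [B x n_classes], mean over resamples
    chi2: np.ndarray             # per-bin goodness of fit vs uniform
    df: int
    p_corrected: np.ndarray      # Bonferroni over bins
    significant: np.ndarray
    n_test: int
    overall_fractions: np.ndarray  # unweighted mean over bins


def transfer_decode(
    train_pseudo: PseudoTrialSet,
    test_pseudo: PseudoTrialSet,
    n_resamples: int = 100,
    seed: int = 0,
    train_frac: float = 0.9,
    alpha: float = 0.05,
    classifier_factory: Callable[[], object] | None = None,
) -> TransferResult:
    """Train on labeled (pre-cue) pseudo-trials, classify unlabeled ones.

    Train and test bins are matched (same time bin on both sides). Per bin,
    the fraction of test pseudo-trials assigned to each class is averaged over
    resampled training subsets, and a chi-square goodness-of-fit test against
    the uniform expectation (N/3 per location) is Bonferroni-corrected over
    bins.
    """
    if train_pseudo.labels is None:
        raise InvalidInputError("training set must be labeled")
    if not np.array_equal(train_pseudo.unit_ids, test_pseudo.unit_ids):
        raise InvalidInputError("train and test sets must share units")
    if train_pseudo.n_bins != test_pseudo.n_bins:
        raise InvalidInputError("train and test sets must share bins")
    factory = classifier_factory or default_classifier
    rng = np.random.default_rng(seed)
    labels = np.asarray(train_pseudo.labels)
    classes = tuple(sorted(np.unique(labels).tolist()))
    B = train_pseudo.n_bins
    n_test = test_pseudo.n_pseudo
    frac = np.zeros((B, len(classes)))
    for _ in range(n_resamples):
        tr, _te = _stratified_split(labels, train_frac, rng)
        for b in range(B):
            clf = factory()
            clf.fit(train_pseudo.X[tr, :, b], labels[tr])
            pred = clf.predict(test_pseudo.X[:, :, b])
            for k, c in enumerate(classes):
                frac[b, k] += np.mean(pred == c)
    frac /= n_resamples

    counts = frac * n_test
    chi2 = np.empty(B)
    p = np.empty(B)
    for b in range(B):
        res = stats.chisquare(counts[b])
        chi2[b], p[b] = res.statistic, res.pvalue
    p_corr = np.minimum(p * B, 1.0)
    return TransferResult(
        bin_centers=np.asarray(train_pseudo.bin_centers),
        classes=classes,
        fractions=frac,
        chi2=chi2,
        df=len(classes) - 1,
        p_corrected=p_corr,
        significant=p_corr < alpha,
        n_test=n_test,
        overall_fractions=frac.mean(axis=0),
    )
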