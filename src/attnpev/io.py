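"""File I/O, run configuration, and the end-to-end pipeline.

Sessions travel as two plain CSV files: a trial table (one row per trial)
and a long-format spike table (unit_id, trial_id, spike_time_s). The pipeline
chains simulate -> filter/subsample -> bin -> PEV/shift -> decode/transfer ->
behavior, writing every artifact plus a JSON manifest that records the config
snapshot, seeds, and per-file checksums so deterministic outputs can be
reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .binning import (
    BinGrid, RateTensor, apply_inclusion_filters, bin_firing_rates,
    select_nonoverlapping, subsample_first_k,
)
from .synth import (
    LOCATIONS, TRIAL_COLUMNS, AgentConfig, ProtocolConfig, SpikeData,
    make_population, simulate_session,
)

log = logging.getLogger("attnpev")

_ENUMS = {
    "trial_type": {"pre_cue", "no_cue"},
    "cue_location": set(LOCATIONS) | {"none"},
    "change_location": set(LOCATIONS) | {"none"},
    "response_location": set(LOCATIONS) | {"center", "none"},
    "outcome": {"hit", "miss", "correct_rejection", "false_alarm", "aborted"},
}


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Trial table as CSV; event times as 6-decimal fixed point."""
    trials.to_csv(path, index=False, float_format="%.6f")


def write_spikes(spikes: SpikeData, path: str | Path) -> None:
    spikes.df.to_csv(path, index=False, float_format="%.6f")


def read_tables(
    trial_csv: str | Path, spike_csv: str | Path
) -> tuple[pd.DataFrame, SpikeData]:
    """Read and validate a session; schema violations name the offending rows."""
    trials = pd.read_csv(trial_csv)
    required = [c for c in TRIAL_COLUMNS if c != "attended_location"]
    missing = [c for c in required if c not in trials.columns]
    if missing:
        raise ParseError(f"{trial_csv}: missing columns {missing}")
    for col, allowed in _ENUMS.items():
        bad = ~trials[col].isin(allowed)
        if bad.any():
            rows = trials.index[bad].tolist()[:5]
            raise ParseError(f"{trial_csv}: invalid {col} values at rows {rows}")
    if trials["trial_id"].duplicated().any():
        raise ParseError(f"{trial_csv}: duplicate trial_id values")

    sdf = pd.read_csv(spike_csv)
    for col in ("unit_id", "trial_id", "spike_time_s"):
        if col not in sdf.columns:
            raise ParseError(f"{spike_csv}: missing column {col!r}")
    neg = sdf["spike_time_s"] < 0
    if neg.any():
        raise ParseError(
            f"{spike_csv}: negative spike times at rows {sdf.index[neg].tolist()[:5]}"
        )
    unknown = ~sdf["trial_id"].isin(set(trials["trial_id"]))
    if unknown.any():
        raise ParseError(
            f"{spike_csv}: unknown trial_id at rows {sdf.index[unknown].tolist()[:5]}"
        )
    # strictly increasing within (unit, trial)
    t = sdf["spike_time_s"].to_numpy()
    same = (sdf["unit_id"].to_numpy()[1:] == sdf["unit_id"].to_numpy()[:-1]) & (
        sdf["trial_id"].to_numpy()[1:] == sdf["trial_id"].to_numpy()[:-1]
    )
    bad = np.flatnonzero(same & (np.diff(t) <= 0))
    if len(bad):
        raise ParseError(
            f"{spike_csv}: non-monotone spike times at rows {(bad + 1).tolist()[:5]}"
        )
    unit_ids = np.unique(sdf["unit_id"].to_numpy())
    return trials, SpikeData(df=sdf, unit_ids=unit_ids)


def save_rate_tensor(rates: RateTensor, stem: str | Path) -> tuple[Path, Path]:
    """Dense array file + JSON sidecar with ids and the bin grid."""
    stem = Path(stem)
    npy = stem.with_suffix(".npy")
    sidecar = stem.with_suffix(".json")
    np.save(npy, rates.values)
    sidecar.write_text(json.dumps({
        "unit_ids": rates.unit_ids.tolist(),
        "trial_ids": rates.trial_ids.tolist(),
        "bin_centers": np.asarray(rates.bin_centers).tolist(),
        "grid": dataclasses.asdict(rates.grid),
    }, indent=2))
    return npy, sidecar


def load_rate_tensor(stem: str | Path) -> RateTensor:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    grid_meta = meta["grid"]
    grid_meta["window"] = tuple(grid_meta["window"])
    grid = BinGrid(**grid_meta)
    return RateTensor(
        np.load(stem.with_suffix(".npy")),
        np.asarray(meta["unit_ids"]),
        np.asarray(meta["trial_ids"]),
        grid,
        bin_centers=np.asarray(meta["bin_centers"]),
    )


# ---------------------------------------------------------------------------
# Run configuration / manifest
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one pipeline run needs; every stochastic stage has a seed."""

    out_dir: str = "attnpev_out"
    trials_csv: str | None = None
    spikes_csv: str | None = None
    # simulation (used when no input files are given)
    simulate: bool = True
    n_units: int = 30
    n_trials: int = 480
    agent_strategy: str = "switching"
    agent_fixed_location: str | None = None
    attn_gain: float = 2.0
    # binning
    align_event: str = "sample_on"
    window_start_s: float = -0.7
    window_end_s: float = 1.9
    bin_width_s: float = 0.2
    step_s: float = 0.02
    min_trials_per_condition: int = 20
    subsample_k: int = 20
    # analysis toggles
    run_pev: bool = True
    run_shift: bool = True
    run_decode: bool = True
    run_transfer: bool = True
    run_behavior: bool = True
    # stats parameters
    n_perm: int = 1000
    n_resamples: int = 1000
    train_frac: float = 0.9
    n_per_condition: int = 40
    min_cluster_bins: int = 5
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key=value text config (lines of ``key = value``; # comments)."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParseError(f"{path}:{lineno}: expected key = value")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ParseError(f"{path}:{lineno}: unknown key {key!r}")
            raw = raw.strip("'\"")
            ftype = fields[key].type
            if raw.lower() in ("none", ""):
                kwargs[key] = None
            elif "bool" in str(ftype):
                kwargs[key] = raw.lower() in ("1", "true", "yes")
            elif "int" in str(ftype):
                kwargs[key] = int(raw)
            elif "float" in str(ftype):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    def grid(self) -> BinGrid:
        return BinGrid(self.align_event, (self.window_start_s, self.window_end_s),
                       self.bin_width_s, self.step_s)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(type(o))
    path.write_text(json.dumps(obj, indent=2, default=default))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run manifest.

    Artifacts are written under ``config.out_dir``; the manifest records the
    config snapshot, package version, per-file checksums and wall-clock times
    (informational only).
    """
    from . import behavior as beh
    from . import decoding as dec
    from . import pev as pv

    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage_seconds: dict[str, float] = {}

    def done(stage: str, since: float) -> None:
        stage_seconds[stage] = round(time.time() - since, 3)
        log.info("[%s] finished in %.2fs", stage, stage_seconds[stage])

    def emit(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    # --- simulate or load -------------------------------------------------
    ts = time.time()
    if config.trials_csv and config.spikes_csv:
        log.info("[load] reading %s / %s", config.trials_csv, config.spikes_csv)
        trials, spikes = read_tables(config.trials_csv, config.spikes_csv)
        done("load", ts)
    elif config.simulate:
        log.info("[simulate] %d units, %d trials, seed=%d",
                 config.n_units, config.n_trials, config.seed)
        fracs = {"location_only": 0.29, "color_only": 0.04, "both": 0.23, "untuned": 0.44}
        pop = make_population(config.n_units, fracs, seed=config.seed,
                              attn_gain=config.attn_gain)
        agent = AgentConfig(
            strategy=config.agent_strategy,
            fixed_location=config.agent_fixed_location,
            switch_hazard=1.0 if config.agent_strategy == "switching" else 0.0,
            block_len_trials=20,
        )
        protocol = ProtocolConfig(n_trials=config.n_trials)
        trials, spikes = simulate_session(pop, protocol, agent, seed=config.seed + 1)
        write_trials(trials, out / "trials.csv")
        write_spikes(spikes, out / "spikes.csv")
        emit("trials", out / "trials.csv")
        emit("spikes", out / "spikes.csv")
        done("simulate", ts)
    else:
        raise ParseError("either provide trials/spikes CSVs or enable simulate")

    # --- filter & bin -----------------------------------------------------
    ts = time.time()
    kept_units, kept_trials = apply_inclusion_filters(
        spikes, trials, min_trials_per_condition=config.min_trials_per_condition
    )
    grid = config.grid()
    rates = bin_firing_rates(spikes, kept_trials, grid).select_units(kept_units)
    nov = select_nonoverlapping(grid)
    rates_nov = rates.select_bins(nov)
    save_rate_tensor(rates, out / "rates")
    emit("rates", out / "rates.npy")
    done("bin", ts)

    pre_mask = (kept_trials["trial_type"] == "pre_cue").to_numpy()

    # --- PEV time course of cue location ----------------------------------
    if config.run_pev:
        ts = time.time()
        pre = subsample_first_k(kept_trials[pre_mask], by="cue_location",
                                k=config.subsample_k)
        r_pre = rates.select_trials(pre["trial_id"])
        series = pv.permutation_band(
            r_pre, pre["cue_location"].to_numpy(),
            n_perm=config.n_perm, seed=config.seed + 2,
        )
        rows = []
        for s in series:
            for b in range(len(s.bin_centers)):
                rows.append({
                    "unit_id": s.unit_id, "bin_center_s": s.bin_centers[b],
                    "pev": s.pev[b], "null_lo": s.null_lo[b],
                    "null_hi": s.null_hi[b], "significant": bool(s.significant[b]),
                })
        pd.DataFrame(rows).to_csv(out / "pev_location.csv", index=False)
        summary = pv.population_summary(series)
        _write_json(out / "pev_summary.json", {
            "seed": config.seed + 2, "n_perm": config.n_perm,
            "bin_centers": summary.bin_centers, "mean_pev": summary.mean_pev,
            "sem_pev": summary.sem_pev, "pct_significant": summary.pct_significant,
        })
        emit("pev_location", out / "pev_location.csv")
        emit("pev_summary", out / "pev_summary.json")
        done("pev", ts)

    # --- attentional shift ------------------------------------------------
    if config.run_shift:
        ts = time.time()
        shift = pv.session_color_shift(rates_nov, kept_trials,
                                       subsample_k=config.subsample_k)
        p_gain, sig_gain, _ = pv.signrank_bonferroni(shift.gain)
        p_loss, sig_loss, _ = pv.signrank_bonferroni(shift.loss)
        rows = []
        for i, u in enumerate(shift.unit_ids):
            for b, c in enumerate(shift.bin_centers):
                rows.append({"unit_id": u, "bin_center_s": c,
                             "gain": shift.gain[i, b], "loss": shift.loss[i, b],
                             "overall": shift.overall[i, b]})
        pd.DataFrame(rows).to_csv(out / "shift.csv", index=False)
        _write_json(out / "shift_summary.json", {
            "bin_centers": shift.bin_centers,
            "population_overall": shift.population_overall(),
            "p_gain": p_gain, "p_loss": p_loss,
            "sig_gain": sig_gain, "sig_loss": sig_loss,
        })
        emit("shift", out / "shift.csv")
        emit("shift_summary", out / "shift_summary.json")
        done("shift", ts)

    # --- decoding ---------------------------------------------------------
    loc_sig_units = None
    if config.run_decode or config.run_transfer:
        pre = subsample_first_k(kept_trials[pre_mask], by="cue_location",
                                k=config.subsample_k)
        r_cls = rates_nov.select_trials(pre["trial_id"])
        color_sets = {
            loc: pre[f"sample_color_{loc}"].to_numpy() for loc in LOCATIONS
        }
        _counts, cats = pv.classify_units(
            r_cls, pre["cue_location"].to_numpy(), color_sets
        )
        loc_sig_units = rates.unit_ids[
            np.array([c in ("location_only", "both") for c in cats])
        ]
        if len(loc_sig_units) == 0:
            log.warning("[decode] no location-significant units; using all units")
            loc_sig_units = rates.unit_ids

    if config.run_decode:
        ts = time.time()
        r_dec = rates_nov.select_units(loc_sig_units).select_trials(pre["trial_id"])
        pseudo = dec.build_pseudo_trials(
            r_dec, pre["cue_location"].to_numpy(),
            n_per_condition=config.n_per_condition, seed=config.seed + 3,
        )
        pseudo = dec.zscore_per_bin(pseudo)
        matrix = dec.decode_cross_temporal(
            pseudo, train_frac=config.train_frac,
            n_resamples=config.n_resamples, seed=config.seed + 4,
        )
        null = dec.shuffled_baseline(
            pseudo, n_resamples=config.n_resamples, seed=config.seed + 5,
            train_frac=config.train_frac,
        )
        matrix = dec.significance_map(dec.attach_null(matrix, null),
                                      min_cluster_bins=config.min_cluster_bins)
        np.save(out / "decoding.npy", matrix.performance)
        _write_json(out / "decoding.json", {
            "bin_centers": matrix.bin_centers, "chance": matrix.chance,
            "n_resamples": matrix.n_resamples, "metadata": matrix.metadata,
            "spread": matrix.spread, "null_lo": matrix.null_lo,
            "null_hi": matrix.null_hi, "significant": matrix.significant,
            "significant_diagonal": matrix.significant_diagonal,
            "clusters": matrix.clusters,
            "units": loc_sig_units,
        })
        emit("decoding", out / "decoding.npy")
        emit("decoding_meta", out / "decoding.json")
        done("decode", ts)

    # --- transfer ---------------------------------------------------------
    if config.run_transfer:
        ts = time.time()
        r_units = rates_nov.select_units(loc_sig_units)
        r_pre = r_units.select_trials(pre["trial_id"])
        nocue = kept_trials[~pre_mask]
        r_nocue = r_units.select_trials(nocue["trial_id"])
        train = dec.build_pseudo_trials(
            r_pre, pre["cue_location"].to_numpy(),
            n_per_condition=config.n_per_condition, seed=config.seed + 6,
        )
        test = dec.build_pseudo_trials(
            r_nocue, None, n_per_condition=config.n_per_condition,
            seed=config.seed + 7,
        )
        res = dec.transfer_decode(train, test,
                                  n_resamples=max(10, config.n_resamples // 10),
                                  seed=config.seed + 8,
                                  train_frac=config.train_frac)
        df = pd.DataFrame({
            "bin_center_s": res.bin_centers,
            **{f"frac_{c}": res.fractions[:, k] for k, c in enumerate(res.classes)},
            "chi2": res.chi2, "p": res.p_corrected, "significant": res.significant,
        })
        df.to_csv(out / "transfer.csv", index=False)
        emit("transfer", out / "transfer.csv")
        done("transfer", ts)

    # --- behavior ---------------------------------------------------------
    if config.run_behavior:
        ts = time.time()
        perf_pre = beh.session_performance(trials, "pre_cue")
        perf_nocue = beh.session_performance(trials, "no_cue")
        pref = beh.preference_fractions([trials])
        _write_json(out / "behavior.json", {
            "pre_cue": dataclasses.asdict(perf_pre),
            "no_cue": dataclasses.asdict(perf_nocue),
            "block_fractions": {str(k): v for k, v in pref.block_fractions.items()},
            "stable": pref.stable,
            "modal_location": {str(k): v for k, v in pref.modal_location.items()},
        })
        emit("behavior", out / "behavior.json")
        done("behavior", ts)

    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "stages_seconds": stage_seconds,
        "artifacts": {k: {"path": v, "sha256": _sha256(Path(v))}
                      for k, v in artifacts.items()},
        "wall_clock_s": round(time.time() - t0, 3),
    }
    _write_json(out / "manifest.json", manifest)
    return manifest
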