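import numpy as np
import pandas as pd
import pytest

import attnpev as ap

MIXED_FRACTIONS = {"location_only": 0.29, "color_only": 0.04, "both": 0.23, "untuned": 0.44}


@pytest.fixture(scope="session")
def mixed_session():
    """One mid-size session with a mixed tuned population (switching agent)."""
    pop = ap.make_population(30, MIXED_FRACTIONS, seed=101)
    protocol = ap.ProtocolConfig(n_trials=360)
    agent = ap.AgentConfig(strategy="switching", switch_hazard=1.0, block_len_trials=20)
    trials, spikes = ap.simulate_session(pop, protocol, agent, seed=102)
    return pop, protocol, trials, spikes


@pytest.fixture(scope="session")
def default_grid():
    return ap.BinGrid()


@pytest.fixture(scope="session")
def mixed_binned(mixed_session, default_grid):
    """Inclusion-filtered rates for the mixed session (sliding bins)."""
    _pop, _protocol, trials, spikes = mixed_session
    kept_units, kept = ap.apply_inclusion_filters(spikes, trials)
    rates = ap.bin_firing_rates(spikes, kept, default_grid).select_units(kept_units)
    return kept, rates


def make_trials(rows: list[dict], session_id: str = "T") -> pd.DataFrame:
    """Minimal hand-built trial table for behavior tests.

    Each row dict may give trial_type, cue_location, change_location, outcome;
    everything else gets consistent defaults.
    """
    protocol = ap.ProtocolConfig(n_trials=max(1, len(rows)))
    out = []
    for i, r in enumerate(rows):
        trial_type = r.get("trial_type", "no_cue")
        change = r.get("change_location", "none")
        rec = {
            "trial_id": i,
            "session_id": session_id,
            "trial_type": trial_type,
            "cue_location": r.get("cue_location", "none"),
            "change_location": change,
            "response_location": r.get(
                "response_location",
                change if r.get("outcome") == "hit" else "center",
            ),
            "outcome": r.get("outcome", "correct_rejection"),
            "attended_location": r.get("attended_location", "top"),
            "cue_on": protocol.cue_on if trial_type == "pre_cue" else np.nan,
            "cue_off": protocol.cue_off if trial_type == "pre_cue" else np.nan,
            "sample_on": protocol.sample_on,
            "sample_off": protocol.sample_off,
            "compare_on": protocol.compare_on,
            "choice_on": protocol.choice_on,
        }
        for loc in ap.LOCATIONS:
            rec[f"sample_color_{loc}"] = r.get(f"sample_color_{loc}", 1)
            rec[f"compare_color_{loc}"] = (
                3 - rec[f"sample_color_{loc}"] if loc == change else rec[f"sample_color_{loc}"]
            )
        out.append(rec)
    return pd.DataFrame(out)
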