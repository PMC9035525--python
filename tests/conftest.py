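import copy

import numpy as np
import pytest

import perictal as pc


def short_config(**kwargs) -> pc.CohortConfig:
    """A fast cohort plan for unit tests: full analysis structure, short spans."""
    defaults = dict(baseline_s=60.0, preictal_s=15.0, ictal_s=30.0,
                    postictal_s=12.0, seed=0)
    defaults.update(kwargs)
    return pc.CohortConfig(**defaults)


def quiet_lfp_params() -> pc.LfpParams:
    """LfpParams with between-animal jitter disabled (parameter-recovery tests)."""
    p = pc.LfpParams()
    p.amp_jitter = p.m_jitter = p.rho_jitter = p.gain_jitter = 0.0
    return p


def quiet_ecg_params() -> pc.EcgParams:
    p = pc.EcgParams()
    p.hr_jitter_bpm = 0.0
    return p


def neutral_outcome_params() -> pc.LfpParams:
    """Jitter-free params where outcomes differ only through coupling gains."""
    p = quiet_lfp_params()
    for b in p.dr_suppression:
        p.dr_suppression[b] = 1.0
    p.dr_background_suppression = 1.0
    for region in p.pac_m.values():
        for sub in region.values():
            sub["non_survivor"] = sub["survivor"]
    p.delta_sync_ictal["non_survivor"] = p.delta_sync_ictal["survivor"]
    p.gc_ictal_gain["non_survivor"] = copy.deepcopy(p.gc_ictal_gain["survivor"])
    return p


@pytest.fixture(scope="session")
def survivor_recording() -> pc.SeizureRecording:
    return pc.generate_recording(short_config(), "survivor", 7, "S01")


@pytest.fixture(scope="session")
def non_survivor_recording() -> pc.SeizureRecording:
    return pc.generate_recording(short_config(), "non_survivor", 8, "N01")


def sinusoid(freq, rate=1000.0, duration=30.0, amp=1.0, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return pc.TimeSeries(amp * np.sin(2 * np.pi * freq * t + phase), rate,
                         label=f"{freq}Hz")
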