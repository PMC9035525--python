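"""One-off calibration of the generator's non-survivor coupling gains.

Stage 1 bisects each ictal injection gain on a small common-random-number
cohort until the analysis pipeline measures the target non-survivor /
survivor band-mean GC fold (2.8 alpha, 3.8 beta, 3.3 gamma DR->M1;
2.6 gamma M1->DR).  Stage 2 refines the gains on a 12-cohort replication:
the measured fold decomposes into a gain-independent spillover part S
(driven by the shared ictal delta source) plus an injected part ~ gain²,
so each gain is rescaled by sqrt((target - S) / (measured - S)).  A final
independent replication reports the frozen values, which are hard-coded
as the LfpParams defaults.

Run from the repository root:  python scripts/calibrate_defaults.py
"""

import copy

import numpy as np

import perictal as pc
from perictal.synth import _measure_band_gc, calibrate_gc_coupling

TARGETS = {
    ("dr_to_m1", "alpha"): 2.8,
    ("dr_to_m1", "beta"): 3.8,
    ("dr_to_m1", "gamma"): 3.3,
    ("m1_to_dr", "gamma"): 2.6,
}


def replicated_folds(gains, n_seeds=12, entropy=7000):
    """Mean (and SD) of per-cohort group-mean GC folds over fixed seed sets."""
    folds = {k: [] for k in TARGETS}
    for k in range(n_seeds):
        cfg = pc.CohortConfig(seed=1)
        cfg.lfp.gc_ictal_gain["non_survivor"] = copy.deepcopy(gains)
        surv_seeds = [int(np.random.SeedSequence([entropy, k, i]).generate_state(1)[0]
                          % 2**31) for i in range(7)]
        ns_seeds = [int(np.random.SeedSequence([entropy, k, 100 + i]).generate_state(1)[0]
                        % 2**31) for i in range(5)]
        ref = _measure_band_gc(cfg, "survivor", surv_seeds)
        got = _measure_band_gc(cfg, "non_survivor", ns_seeds)
        for key in TARGETS:
            folds[key].append(got[key] / ref[key])
    return ({key: float(np.mean(v)) for key, v in folds.items()},
            {key: float(np.std(v)) for key, v in folds.items()})


def main():
    base = pc.LfpParams()
    try:
        gains = calibrate_gc_coupling(TARGETS, tolerance=0.15, seed=42,
                                      n_recordings=6, max_iter=6)
    except Exception as exc:  # fall back to the current defaults as seed point
        print("stage 1 bisection incomplete:", exc)
        gains = copy.deepcopy(base.gc_ictal_gain["non_survivor"])
    print("stage 1 gains:", gains)

    spill, _ = replicated_folds(base.gc_ictal_gain["survivor"])
    print("spillover folds:", {k: round(v, 2) for k, v in spill.items()})
    # Joint relaxation on a fixed CRN replication: the injected part of the
    # fold scales ~ gain^2 above the gain-independent spillover.
    for refinement in range(3):
        meas, sd = replicated_folds(gains)
        print(f"stage 2.{refinement} folds:",
              {k: f"{meas[k]:.2f}+-{sd[k]:.2f}" for k in TARGETS})
        done = True
        for (d, b), target in TARGETS.items():
            if abs(meas[(d, b)] - target) <= 0.15:
                continue
            inj = max(meas[(d, b)] - spill[(d, b)], 0.10)
            want = max(target - spill[(d, b)], 0.10)
            factor = np.clip(np.sqrt(want / inj), 0.6, 1.7)  # damped step
            gains[d][b] = float(np.clip(gains[d][b] * factor, 0.005, 0.6))
            done = False
        if done:
            break
    print("refined gains:", gains)
    meas, sd = replicated_folds(gains, n_seeds=16, entropy=9000)
    for key, t in TARGETS.items():
        print(f"{key}: target {t:.1f}, independent fold {meas[key]:.2f} "
              f"+- {sd[key]:.2f}")
    return gains


if __name__ == "__main__":
    main()
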