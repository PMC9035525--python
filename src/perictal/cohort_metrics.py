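"""Per-animal figure-analog metrics and multi-seed cohort replications.

These helpers compute, from generated raw signals, exactly the per-animal
quantities the group-level analyses summarize: ictal delta:gamma PAC box
means per region, ictal (and optionally baseline) PLV / Geweke GC band
means, baseline-normalized ictal band power, and stage heart rates.  They
are the workhorses of the closed-loop recovery checks, where the synthetic
generator's programmed effect sizes must be recovered by the full analysis
path.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cardiac import detect_r_peaks, epoch_mean_hr
from .connectivity import FREQ_GRID, analyze_pair
from .core import Epoch, SeizureRecording, SUMMARY_BANDS, segment_epochs
from .pac import delta_gamma_boxes
from .spectral import band_power, broadband_ratio, compute_psd, normalize_psd
from .synth import CohortConfig, generate_cohort


def recording_metrics(rec: SeizureRecording, include=("pac", "connectivity",
                                                      "power"),
                      baseline_connectivity: bool = False,
                      baseline_window_s: float = 40.0,
                      with_plv: bool = True) -> dict:
    """One row of per-animal metrics from raw signals."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        epochs = segment_epochs(rec)
    row = {"animal_id": rec.animal_id, "outcome": rec.outcome}
    ictal = epochs["ictal"]

    if "pac" in include:
        for region, ts in (("m1", rec.m1), ("dr", rec.dr)):
            lg, hg = delta_gamma_boxes(ts, ictal)
            row[f"pac_lg_{region}"] = lg
            row[f"pac_hg_{region}"] = hg

    if "connectivity" in include:
        res = analyze_pair(rec.m1, rec.dr, ictal, compute_plv=with_plv)
        for band in SUMMARY_BANDS:
            row[f"plv_{band}"] = res.band_means[band]["plv"]
            row[f"gc_dm_{band}"] = res.band_means[band]["gc_dr_to_m1"]
            row[f"gc_md_{band}"] = res.band_means[band]["gc_m1_to_dr"]
        if baseline_connectivity:
            base = epochs["baseline"]
            sub = Epoch("baseline", max(base.start, base.end - baseline_window_s),
                        base.end)
            bres = analyze_pair(rec.m1, rec.dr, sub,
                                freqs=FREQ_GRID)
            row["base_plv_delta"] = bres.band_means["delta"]["plv"]
            row["base_gc_dm"] = float(np.mean(
                [bres.band_means[b]["gc_dr_to_m1"] for b in ("alpha", "beta",
                                                             "gamma")]))

    if "power" in include:
        for region, ts in (("m1", rec.m1), ("dr", rec.dr)):
            f, b = compute_psd(ts, epochs["baseline"])
            _, i = compute_psd(ts, ictal)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ns = normalize_psd(i, b, freqs=f, epoch_kind="ictal")
            row[f"power_bb_{region}"] = broadband_ratio(ns)
            bp = band_power(ns).set_index("band")["mean_ratio"]
            for band in SUMMARY_BANDS:
                row[f"power_{band}_{region}"] = bp[band]
    return row


def cohort_metrics(config: CohortConfig, **kwargs) -> pd.DataFrame:
    """Per-animal metrics for a full generated cohort."""
    return pd.DataFrame([recording_metrics(rec, **kwargs)
                         for rec in generate_cohort(config)])


def group_means(df: pd.DataFrame, column: str) -> tuple[float, float]:
    """(survivor mean, non-survivor mean) of a metric column."""
    g = df.groupby("outcome")[column].mean()
    return float(g["survivor"]), float(g["non_survivor"])


def stage_heart_rates(rec: SeizureRecording) -> dict:
    """Per-epoch mean instant HR for one recording."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        epochs = segment_epochs(rec)
    rr = detect_r_peaks(rec.ecg)
    out = {"animal_id": rec.animal_id, "outcome": rec.outcome}
    for kind in ("baseline", "ictal", "postictal"):
        out[f"hr_{kind}"], _ = epoch_mean_hr(rr, epochs[kind])
    return out
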