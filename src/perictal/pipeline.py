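"""End-to-end orchestration: generate or load a cohort, run every analysis
stage, and emit per-animal tables plus a cohort statistics report."""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cardiac import detect_r_peaks, epoch_mean_hr, hrv_metrics
from .connectivity import analyze_pair
from .core import SURVIVOR, NON_SURVIVOR, SeizureRecording, segment_epochs
from .edf import read_recording, write_recording
from .errors import ParameterError
from .pac import delta_gamma_boxes
from .spectral import band_power, broadband_ratio, compute_psd, normalize_psd
from .stats import compare_two_groups, factorial_anova
from .synth import CohortConfig, generate_cohort

log = logging.getLogger("perictal")

ALL_STAGES = ("spectral", "pac", "connectivity", "cardiac", "stats")


@dataclass
class PipelineConfig:
    mode: str = "generate"                      # generate | load
    cohort: CohortConfig = field(default_factory=CohortConfig)
    manifest_path: Optional[str] = None         # load mode
    out_dir: Optional[str] = None
    stages: tuple = ALL_STAGES
    seed: Optional[int] = None                  # overrides cohort.seed

    def __post_init__(self):
        if self.mode not in ("generate", "load"):
            raise ParameterError(f"unknown input mode {self.mode!r}")
        if self.mode == "load" and not self.manifest_path:
            raise ParameterError("load mode requires a manifest path")
        if self.seed is not None:
            self.cohort.seed = int(self.seed)


@dataclass
class CohortResults:
    epochs: pd.DataFrame
    spectra: pd.DataFrame
    bandpower: pd.DataFrame
    pac: pd.DataFrame
    connectivity: pd.DataFrame
    cardiac: pd.DataFrame
    stats_report: str
    seed: int = 0


def analyze_recording(rec: SeizureRecording, stages=ALL_STAGES) -> dict:
    """All per-animal metrics for one recording, grouped per stage."""
    epochs = segment_epochs(rec)
    out = {"epochs": [
        {"animal_id": rec.animal_id, "outcome": rec.outcome, "epoch": k,
         "start_s": e.start, "end_s": e.end}
        for k, e in epochs.items()]}

    if "spectral" in stages:
        spectra, bands = [], []
        for region, ts in (("M1", rec.m1), ("DR", rec.dr)):
            f, base = compute_psd(ts, epochs["baseline"])
            f, ict = compute_psd(ts, epochs["ictal"])
            nspec = normalize_psd(ict, base, freqs=f, epoch_kind="ictal")
            keep = nspec.freqs <= 60.5
            for fi, ri in zip(nspec.freqs[keep], nspec.ratio[keep]):
                spectra.append({"animal_id": rec.animal_id, "outcome": rec.outcome,
                                "region": region, "epoch": "ictal",
                                "freq_hz": fi, "power_ratio": ri})
            bp = band_power(nspec)
            for _, row in bp.iterrows():
                bands.append({"animal_id": rec.animal_id, "outcome": rec.outcome,
                              "region": region, "band": row["band"],
                              "mean_ratio": row["mean_ratio"]})
            bands.append({"animal_id": rec.animal_id, "outcome": rec.outcome,
                          "region": region, "band": "broadband_1_60",
                          "mean_ratio": broadband_ratio(nspec)})
        out["spectra"] = spectra
        out["bandpower"] = bands

    if "pac" in stages:
        rows = []
        for region, ts in (("M1", rec.m1), ("DR", rec.dr)):
            lg, hg = delta_gamma_boxes(ts, epochs["ictal"])
            rows.append({"animal_id": rec.animal_id, "outcome": rec.outcome,
                         "region": region, "delta_low_gamma": lg,
                         "delta_high_gamma": hg})
        out["pac"] = rows

    if "connectivity" in stages:
        rows = []
        for kind in ("baseline", "ictal"):
            res = analyze_pair(rec.m1, rec.dr, epochs[kind])
            for band, vals in res.band_means.items():
                rows.append({"animal_id": rec.animal_id, "outcome": rec.outcome,
                             "epoch": kind, "band": band, **vals})
        out["connectivity"] = rows

    if "cardiac" in stages:
        rr = detect_r_peaks(rec.ecg)
        rows = []
        for kind in ("baseline", "ictal", "postictal"):
            hr, n = epoch_mean_hr(rr, epochs[kind])
            rows.append({"animal_id": rec.animal_id, "outcome": rec.outcome,
                         "epoch": kind, "mean_hr_bpm": hr, "n_beats": n})
        base_rr = detect_r_peaks(rec.ecg, epochs["baseline"])
        if base_rr.rr.size >= 2:
            hv = hrv_metrics(base_rr)
            rows.append({"animal_id": rec.animal_id, "outcome": rec.outcome,
                         "epoch": "baseline_hrv", "mean_hr_bpm": 60000.0 / hv.mean_rr,
                         "n_beats": base_rr.n_peaks, "sdnn_ms": hv.sdnn,
                         "cv_pct": hv.cv, "rmssd_ms": hv.rmssd})
        out["cardiac"] = rows
    return out


def analyze_cohort(recordings, stages=ALL_STAGES, seed: int = 0) -> CohortResults:
    acc: dict[str, list] = {}
    for rec in recordings:
        t0 = time.time()
        res = analyze_recording(rec, stages)
        for key, rows in res.items():
            acc.setdefault(key, []).extend(rows)
        log.info("analyzed %s (%s) in %.1f s", rec.animal_id, rec.outcome,
                 time.time() - t0)
    frames = {k: pd.DataFrame(v) for k, v in acc.items()}
    empty = pd.DataFrame()
    results = CohortResults(
        epochs=frames.get("epochs", empty), spectra=frames.get("spectra", empty),
        bandpower=frames.get("bandpower", empty), pac=frames.get("pac", empty),
        connectivity=frames.get("connectivity", empty),
        cardiac=frames.get("cardiac", empty), stats_report="", seed=seed)
    if "stats" in stages:
        results.stats_report = report_summary(results)
    return results


# ---------------------------------------------------------------------------
# statistics report
# ---------------------------------------------------------------------------

def _two_group(df, col, label):
    surv = df.loc[df["outcome"] == SURVIVOR, col].dropna().values
    nsur = df.loc[df["outcome"] == NON_SURVIVOR, col].dropna().values
    if min(surv.size, nsur.size) < 3:
        return f"  {label}: insufficient group sizes\n"
    r = compare_two_groups(surv, nsur, "survivor", "non_survivor")
    gs = r.group_stats.set_index("group")
    return ("  {label}: survivor {sm:.4g} ± {ss:.3g} (n={sn}), "
            "non-survivor {nm:.4g} ± {ns_:.3g} (n={nn}); {test}, p = {p:.4g}\n"
            .format(label=label, sm=gs.loc["survivor", "mean"],
                    ss=gs.loc["survivor", "sem"], sn=int(gs.loc["survivor", "n"]),
                    nm=gs.loc["non_survivor", "mean"],
                    ns_=gs.loc["non_survivor", "sem"],
                    nn=int(gs.loc["non_survivor", "n"]), test=r.test, p=r.p_value))


def report_summary(results: CohortResults) -> str:
    """Human-readable cohort report with group means ± SEM, n, and tests."""
    import warnings

    if results.epochs.empty:
        warnings.warn("empty results: report will be empty", stacklevel=2)
        return "(empty results)\n"
    lines = [f"perictal cohort report (seed {results.seed})", ""]

    if not results.bandpower.empty:
        lines.append("== Power (ictal / baseline ratio) ==")
        bp = results.bandpower
        for region in ("M1", "DR"):
            sub = bp[(bp["region"] == region) & (bp["band"] == "broadband_1_60")]
            lines.append(_two_group(sub, "mean_ratio", f"{region} 1-60 Hz").rstrip())
        try:
            cell = bp[bp["band"] == "broadband_1_60"].rename(
                columns={"mean_ratio": "value"})
            an = factorial_anova(cell, ["outcome", "region"], posthoc="sidak")
            lines.append(f"  two-way ANOVA outcome x region: "
                         f"F = {an.statistic:.3g}, p = {an.p_value:.4g}")
        except Exception as exc:  # report survives stats failures
            lines.append(f"  ANOVA unavailable: {exc}")
        lines.append("")

    if not results.pac.empty:
        lines.append("== PAC (ictal delta:gamma coupling strength) ==")
        for region in ("M1", "DR"):
            sub = results.pac[results.pac["region"] == region]
            for col in ("delta_low_gamma", "delta_high_gamma"):
                lines.append(_two_group(sub, col, f"{region} {col}").rstrip())
        lines.append("")

    if not results.connectivity.empty:
        conn = results.connectivity
        lines.append("== PLV (ictal M1-DR phase locking) ==")
        for band in ("delta", "theta", "alpha", "beta", "gamma"):
            sub = conn[(conn["epoch"] == "ictal") & (conn["band"] == band)]
            lines.append(_two_group(sub, "plv", band).rstrip())
        lines.append("")
        lines.append("== GC (ictal spectral Granger causality) ==")
        for direction in ("gc_dr_to_m1", "gc_m1_to_dr"):
            arrow = "DR->M1" if direction.endswith("dr_to_m1") else "M1->DR"
            for band in ("alpha", "beta", "gamma"):
                sub = conn[(conn["epoch"] == "ictal") & (conn["band"] == band)]
                g = sub.groupby("outcome")[direction].mean()
                fold = g.get(NON_SURVIVOR, np.nan) / g.get(SURVIVOR, np.nan)
                lines.append(_two_group(sub, direction, f"{arrow} {band}").rstrip()
                             + f" [fold {fold:.2f}]")
        lines.append("")

    if not results.cardiac.empty:
        lines.append("== Heart rate ==")
        for kind in ("baseline", "ictal", "postictal"):
            sub = results.cardiac[results.cardiac["epoch"] == kind]
            lines.append(_two_group(sub, "mean_hr_bpm", f"{kind} HR (b.p.m.)").rstrip())
        lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# file plumbing
# ---------------------------------------------------------------------------

def write_cohort_files(recordings, out_dir: str) -> str:
    """Write EDF + marker files per animal plus a cohort manifest."""
    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for rec in recordings:
        edf = os.path.join(out_dir, f"{rec.animal_id}.edf")
        mrk = os.path.join(out_dir, f"{rec.animal_id}_markers.tsv")
        write_recording(rec, edf, mrk)
        rows.append({"animal_id": rec.animal_id, "outcome": rec.outcome,
                     "edf": os.path.basename(edf),
                     "markers": os.path.basename(mrk)})
    manifest = os.path.join(out_dir, "cohort_manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def load_cohort(manifest_path: str) -> list[SeizureRecording]:
    df = pd.read_csv(manifest_path, sep="\t")
    base = os.path.dirname(os.path.abspath(manifest_path))
    recs = []
    for _, row in df.iterrows():
        recs.append(read_recording(os.path.join(base, row["edf"]),
                                   os.path.join(base, row["markers"]),
                                   outcome=row["outcome"],
                                   animal_id=row["animal_id"]))
    return recs


def _write_results(results: CohortResults, config: PipelineConfig, out_dir: str):
    os.makedirs(out_dir, exist_ok=True)
    tables = {"epochs.tsv": results.epochs, "spectra.tsv": results.spectra,
              "bandpower.tsv": results.bandpower, "pac.tsv": results.pac,
              "connectivity.tsv": results.connectivity,
              "cardiac.tsv": results.cardiac}
    for name, df in tables.items():
        if not df.empty:
            df.to_csv(os.path.join(out_dir, name), sep="\t", index=False,
                      float_format="%.6g")
    if results.stats_report:
        with open(os.path.join(out_dir, "stats_report.txt"), "w") as fh:
            fh.write(results.stats_report)
    with open(os.path.join(out_dir, "manifest.txt"), "w") as fh:
        fh.write(f"perictal version: {__version__}\n")
        fh.write(f"mode: {config.mode}\nseed: {config.cohort.seed}\n")
        fh.write(f"stages: {','.join(config.stages)}\n")
        fh.write(f"cohort config: {config.cohort!r}\n")


def run_pipeline(config: PipelineConfig) -> CohortResults:
    """Run every enabled stage over a generated or loaded cohort."""
    t0 = time.time()
    if config.mode == "generate":
        recordings = generate_cohort(config.cohort)
        log.info("generated %d recordings in %.1f s", len(recordings),
                 time.time() - t0)
    else:
        recordings = load_cohort(config.manifest_path)
        log.info("loaded %d recordings", len(recordings))
    try:
        results = analyze_cohort(recordings, stages=config.stages,
                                 seed=config.cohort.seed)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    if config.out_dir:
        _write_results(results, config, config.out_dir)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return results
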