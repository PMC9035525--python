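"""Minimal EDF(+C) I/O and recording-level read/write.

Signals are stored as 16-bit integers against a declared physical range
(default ±2000 µV for LFP, ±5 mV for ECG), one-second data records, so
channels with different rates (1000 Hz LFP, 2000 Hz ECG) coexist in one
file.  Event markers live in a sidecar tab-separated file with columns
``event_name``/``time_s`` — EDF+ annotation channels are deliberately not
used so markers stay diff-able plain text.

The format is the plain fixed-width-ASCII-header EDF layout; only the
subset needed for continuous multirate recordings is implemented.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .core import EventMarkers, SeizureRecording, TimeSeries, SURVIVOR, NON_SURVIVOR
from .errors import FormatError, ValidationError

#: Default physical ranges per channel kind (label -> (min, max, unit)).
PHYSICAL_RANGES = {
    "M1": (-2000.0, 2000.0, "uV"),
    "DR": (-2000.0, 2000.0, "uV"),
    "ECG": (-5.0, 5.0, "mV"),
}
_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    s = str(text)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str, channels: Sequence[TimeSeries], patient_id: str = "X") -> str:
    """Write channels to an EDF file with 1 s data records.

    All channels are truncated to the longest whole number of seconds they
    share; samples outside the declared physical range are clipped.
    """
    if not channels:
        raise ValidationError("no channels to write")
    for ch in channels:
        if ch.n == 0:
            raise ValidationError(f"channel {ch.label!r} has zero length")
        if abs(ch.rate - round(ch.rate)) > 1e-9:
            raise ValidationError("EDF writer requires integer sampling rates")
    n_records = int(min(ch.duration for ch in channels))
    if n_records < 1:
        raise ValidationError("channels must cover at least 1 s")
    ns = len(channels)
    header = bytearray()
    header += _pad("0", 8)                     # version
    header += _pad(patient_id, 80)             # patient
    header += _pad("perictal recording", 80)   # recording id
    header += _pad("01.01.20", 8)              # start date (placeholder)
    header += _pad("00.00.00", 8)              # start time
    header += _pad(str(256 * (ns + 1)), 8)     # header bytes
    header += _pad("EDF+C", 44)                # reserved
    header += _pad(str(n_records), 8)
    header += _pad("1", 8)                     # record duration, s
    header += _pad(str(ns), 4)

    ranges = []
    for ch in channels:
        pmin, pmax, unit = PHYSICAL_RANGES.get(
            ch.label.upper(), (-2000.0, 2000.0, ch.units or "uV")
        )
        ranges.append((pmin, pmax))
    fields = [
        [_pad(ch.label, 16) for ch in channels],                      # label
        [_pad("", 80) for _ in channels],                             # transducer
        [_pad(PHYSICAL_RANGES.get(ch.label.upper(), (0, 0, ch.units or "uV"))[2], 8)
         for ch in channels],                                         # phys dim
        [_pad(f"{r[0]:g}", 8) for r in ranges],                       # phys min
        [_pad(f"{r[1]:g}", 8) for r in ranges],                       # phys max
        [_pad(str(_DIG_MIN), 8) for _ in channels],                   # dig min
        [_pad(str(_DIG_MAX), 8) for _ in channels],                   # dig max
        [_pad("", 80) for _ in channels],                             # prefilter
        [_pad(str(int(ch.rate)), 8) for ch in channels],              # samples/record
        [_pad("", 32) for _ in channels],                             # reserved
    ]
    for fld in fields:
        for item in fld:
            header += item

    digitized = []
    for ch, (pmin, pmax) in zip(channels, ranges):
        x = np.clip(ch.samples, pmin, pmax)
        scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
        d = np.round((x - pmin) * scale + _DIG_MIN).astype("<i2")
        digitized.append(d)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for rec in range(n_records):
            for ch, d in zip(channels, digitized):
                spr = int(ch.rate)
                fh.write(d[rec * spr:(rec + 1) * spr].tobytes())
    return path


def read_edf(path: str) -> list[TimeSeries]:
    """Read all channels of an EDF file written by :func:`write_edf`."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise FormatError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            rec_dur = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise FormatError(f"{path}: malformed EDF header") from exc
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise FormatError(f"{path}: truncated EDF signal headers")

        def field(offset, width, i):
            start = offset * ns + i * width
            return sig[start:start + width].decode("ascii").strip()

        labels, units, pmins, pmaxs, dmins, dmaxs, sprs = [], [], [], [], [], [], []
        off = 0
        widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
        base = [0]
        for w in widths:
            base.append(base[-1] + w)
        for i in range(ns):
            labels.append(sig[base[0] * ns + i * 16: base[0] * ns + (i + 1) * 16]
                          .decode("ascii").strip())
        def col(j, width, conv):
            out = []
            start0 = base[j] * ns
            for i in range(ns):
                raw = sig[start0 + i * width: start0 + (i + 1) * width].decode("ascii").strip()
                out.append(conv(raw))
            return out
        units = col(2, 8, str)
        pmins = col(3, 8, float)
        pmaxs = col(4, 8, float)
        dmins = col(5, 8, int)
        dmaxs = col(6, 8, int)
        sprs = col(8, 8, int)

        data = [np.empty(n_records * spr, dtype=np.float64) for spr in sprs]
        for rec in range(n_records):
            for i, spr in enumerate(sprs):
                raw = fh.read(2 * spr)
                if len(raw) < 2 * spr:
                    raise FormatError(f"{path}: truncated data record {rec}")
                d = np.frombuffer(raw, dtype="<i2").astype(np.float64)
                scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
                data[i][rec * spr:(rec + 1) * spr] = (d - dmins[i]) * scale + pmins[i]

    out = []
    for i in range(ns):
        out.append(TimeSeries(data[i], rate=sprs[i] / rec_dur, t0=0.0,
                              label=labels[i], units=units[i]))
    return out


# ---------------------------------------------------------------------------
# Marker files and recording-level round trip
# ---------------------------------------------------------------------------

_MARKER_NAMES = ("flurothyl_start", "gs_onset", "convulsion_end", "death_time")


def write_markers(path: str, markers: EventMarkers) -> str:
    rows = [("flurothyl_start", markers.flurothyl_start),
            ("gs_onset", markers.gs_onset),
            ("convulsion_end", markers.convulsion_end)]
    if markers.death_time is not None:
        rows.append(("death_time", markers.death_time))
    pd.DataFrame(rows, columns=["event_name", "time_s"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f")
    return path


def read_markers(path: str) -> EventMarkers:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse marker file") from exc
    if not {"event_name", "time_s"} <= set(df.columns):
        raise FormatError(f"{path}: marker file needs event_name/time_s columns")
    events = dict(zip(df["event_name"], df["time_s"].astype(float)))
    missing = [m for m in _MARKER_NAMES[:3] if m not in events]
    if missing:
        raise FormatError(f"{path}: missing marker rows {missing}")
    return EventMarkers(
        flurothyl_start=events["flurothyl_start"],
        gs_onset=events["gs_onset"],
        convulsion_end=events["convulsion_end"],
        death_time=events.get("death_time"),
    )


def _find_channel(channels, label):
    for ch in channels:
        if ch.label.upper() == label.upper():
            return ch
    raise FormatError(f"channel {label} not found")


def read_recording(signal_path: str, marker_path: str, outcome: str,
                   animal_id: str = "") -> SeizureRecording:
    """Load a SeizureRecording from an EDF file plus marker sidecar."""
    channels = read_edf(signal_path)
    m1 = _find_channel(channels, "M1")
    dr = _find_channel(channels, "DR")
    ecg = _find_channel(channels, "ECG")
    markers = read_markers(marker_path)
    if not animal_id:
        animal_id = os.path.splitext(os.path.basename(signal_path))[0]
    return SeizureRecording(m1=m1, dr=dr, ecg=ecg, markers=markers,
                            outcome=outcome, animal_id=animal_id)


def write_recording(recording: SeizureRecording, signal_path: str,
                    marker_path: str) -> tuple[str, str]:
    """Write a recording as EDF + marker TSV; inverse of :func:`read_recording`."""
    write_edf(signal_path, [recording.m1, recording.dr, recording.ecg],
              patient_id=recording.animal_id or "X")
    write_markers(marker_path, recording.markers)
    return signal_path, marker_path
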