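"""Minimal EDF+ persistence for simulated recordings.

Writing produces an EDF+C file: 16-bit signals at one data record per
second plus an ``EDF Annotations`` channel carrying the protocol and
artifact events as time-stamped annotation lists. Reading goes through
MNE's EDF reader, which also serves as an independent check that the files
we emit are standard-conforming.
"""
from __future__ import annotations

import math

import numpy as np

from .recording import Annotation, EEGRecording


def _num8(v: float) -> str:
    """Densest decimal representation of ``v`` that fits 8 EDF header bytes."""
    for p in range(8, 0, -1):
        s = f"{v:.{p}g}"
        if len(s) <= 8 and "e" not in s:
            return s
    return f"{v:.0f}"[:8]


def _fixed(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as EDF+C with annotations.

    Signals are quantized to 16 bits over a symmetric physical range per
    channel; with typical EEG amplitudes the quantization step is well
    below 0.1 μV.
    """
    fs = rec.fs
    spr = int(round(fs))  # samples per 1 s data record
    if abs(spr - fs) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    n_rec = math.ceil(rec.n_samples / spr)
    n_sig = rec.n_channels + 1  # + annotations channel

    # Annotation payload: one timekeeping TAL per record; all event TALs in
    # the first record.
    tals = []
    for i in range(n_rec):
        chunks = [f"+{i}\x14\x14\x00".encode("ascii")]
        if i == 0:
            for ann in sorted(rec.annotations, key=lambda a: a.onset):
                chunks.append(
                    f"+{ann.onset:.3f}\x15{ann.duration:.3f}"
                    f"\x14{ann.label}\x14\x00".encode("utf-8"))
        tals.append(b"".join(chunks))
    ann_bytes = max(len(t) for t in tals)
    ann_spr = math.ceil(ann_bytes / 2) + 1  # 2-byte samples, spare room

    pmins, pmaxs, scaled = [], [], []
    dmin, dmax = -32768, 32767
    for c in range(rec.n_channels):
        amp = float(np.max(np.abs(rec.data[c]))) if rec.n_samples else 1.0
        amp = max(amp, 1.0) * 1.001
        pmins.append(-amp)
        pmaxs.append(amp)
        gain = (dmax - dmin) / (2 * amp)
        dig = np.round((rec.data[c] + amp) * gain + dmin).astype(np.int16)
        full = np.zeros(n_rec * spr, dtype=np.int16)
        full[:rec.n_samples] = dig
        scaled.append(full)

    header_bytes = 256 * (1 + n_sig)
    patient = f"X {rec.sex or 'X'} X {rec.subject_id}"
    recording_field = "Startdate X X X X"
    head = b"".join([
        _fixed("0", 8),
        _fixed(patient, 80),
        _fixed(recording_field, 80),
        _fixed("01.01.00", 8),
        _fixed("00.00.00", 8),
        _fixed(str(header_bytes), 8),
        _fixed("EDF+C", 44),
        _fixed(str(n_rec), 8),
        _fixed("1", 8),  # record duration, seconds
        _fixed(str(n_sig), 4),
    ])
    labels = [_fixed(name, 16) for name in rec.channel_names]
    labels.append(_fixed("EDF Annotations", 16))
    transducer = [_fixed("", 80)] * n_sig
    phys_dim = [_fixed("uV", 8)] * rec.n_channels + [_fixed("", 8)]
    phys_min = [_fixed(_num8(v), 8) for v in pmins] + [_fixed("-1", 8)]
    phys_max = [_fixed(_num8(v), 8) for v in pmaxs] + [_fixed("1", 8)]
    dig_min = [_fixed(str(dmin), 8)] * rec.n_channels + [_fixed("-32768", 8)]
    dig_max = [_fixed(str(dmax), 8)] * rec.n_channels + [_fixed("32767", 8)]
    prefilt = [_fixed("", 80)] * n_sig
    n_samp = [_fixed(str(spr), 8)] * rec.n_channels + [_fixed(str(ann_spr), 8)]
    reserved = [_fixed("", 32)] * n_sig

    with open(path, "wb") as fh:
        fh.write(head)
        for part in (labels, transducer, phys_dim, phys_min, phys_max,
                     dig_min, dig_max, prefilt, n_samp, reserved):
            fh.write(b"".join(part))
        for i in range(n_rec):
            for c in range(rec.n_channels):
                fh.write(scaled[c][i * spr:(i + 1) * spr].tobytes())
            tal = tals[i]
            fh.write(tal + b"\x00" * (ann_spr * 2 - len(tal)))


def read_edf(path, subject_id: str | None = None,
             group: str | None = None) -> EEGRecording:
    """Load an EDF/EDF+ file into an :class:`EEGRecording` (via MNE)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns Volts
    anns = [Annotation(onset=float(a["onset"]), duration=float(a["duration"]),
                       label=str(a["description"]))
            for a in raw.annotations]
    sid = subject_id
    if sid is None:
        info_sid = (raw.info.get("subject_info") or {}).get("last_name")
        sid = info_sid or "unknown"
    return EEGRecording(data=data, fs=float(raw.info["sfreq"]),
                        channel_names=list(raw.ch_names),
                        annotations=anns, subject_id=sid, group=group)
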