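"""Readers and writers for BrainVision and EDF+ recordings, with event sidecars.

Both formats store int16 samples, so writing quantizes the signal: the
BrainVision writer declares an explicit resolution (µV/bit) per channel, the
EDF writer maps the physical range of each signal onto the 16-bit digital
range.  Markers round-trip exactly; they are also emitted as a plain
tab-separated sidecar (onset_sample, duration_sample, label) next to the
data files.
"""

from __future__ import annotations

import datetime as _dt
import os
import re
from dataclasses import dataclass

import numpy as np

__all__ = ["Recording", "write_recording", "read_recording", "write_events_tsv",
           "read_events_tsv"]


@dataclass
class Recording:
    """Continuous multi-channel signal in µV plus event markers.

    ``markers`` is a list of (sample_index, label); ``meta`` carries whatever
    the producer wants to attach (e.g. simulation ground truth) and is not
    serialized to the EEG formats.
    """

    signal: np.ndarray  # (n_channels, n_samples), µV
    sampling_rate: float
    channel_names: list[str]
    markers: list[tuple[int, str]]
    meta: dict | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be (n_channels, n_samples)")
        if len(self.channel_names) != self.signal.shape[0]:
            raise ValueError("channel_names length mismatch")
        self.markers = sorted(self.markers)
        for smp, _ in self.markers:
            if not 0 <= smp < self.signal.shape[1]:
                raise ValueError(f"marker sample {smp} outside recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


# ---------------------------------------------------------------- events TSV

def write_events_tsv(path: str, markers: list[tuple[int, str]]) -> None:
    with open(path, "w") as fh:
        fh.write("onset_sample\tduration_sample\tlabel\n")
        for smp, label in sorted(markers):
            fh.write(f"{smp}\t0\t{label}\n")


def read_events_tsv(path: str) -> list[tuple[int, str]]:
    out = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            onset, _dur, label = line.rstrip("\n").split("\t")
            out.append((int(onset), label))
    return out


# ---------------------------------------------------------------- BrainVision

_BV_RESOLUTION = 0.1  # µV per bit; ±3276.7 µV range


def _write_brainvision(rec: Recording, stem: str) -> None:
    base = os.path.basename(stem)
    n_ch = rec.n_channels
    with open(stem + ".vhdr", "w") as fh:
        fh.write("Brain Vision Data Exchange Header File Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={base}.eeg\nMarkerFile={base}.vmrk\n")
        fh.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        fh.write(f"NumberOfChannels={n_ch}\n")
        fh.write(f"SamplingInterval={1e6 / rec.sampling_rate:g}\n\n")
        fh.write("[Binary Infos]\nBinaryFormat=INT_16\n\n")
        fh.write("[Channel Infos]\n")
        for i, name in enumerate(rec.channel_names, start=1):
            fh.write(f"Ch{i}={name},,{_BV_RESOLUTION:g},µV\n")
    with open(stem + ".vmrk", "w") as fh:
        fh.write("Brain Vision Data Exchange Marker File, Version 1.0\n\n")
        fh.write("[Common Infos]\n")
        fh.write(f"DataFile={base}.eeg\n\n")
        fh.write("[Marker Infos]\n")
        fh.write("Mk1=New Segment,,1,1,0,0\n")
        for i, (smp, label) in enumerate(rec.markers, start=2):
            # BrainVision marker positions are 1-based
            fh.write(f"Mk{i}=Stimulus,{label},{smp + 1},1,0\n")
    data = np.round(rec.signal / _BV_RESOLUTION)
    data = np.clip(data, -32768, 32767).astype("<i2")
    data.T.tofile(stem + ".eeg")  # multiplexed: sample-major
    write_events_tsv(stem + "_events.tsv", rec.markers)


def _read_brainvision(stem: str) -> Recording:
    header: dict[str, str] = {}
    channels: list[tuple[str, float]] = []
    with open(stem + ".vhdr") as fh:
        section = ""
        for line in fh:
            line = line.strip()
            if line.startswith("["):
                section = line
            elif "=" in line and not line.startswith(";"):
                key, val = line.split("=", 1)
                if section == "[Channel Infos]":
                    parts = val.split(",")
                    channels.append((parts[0], float(parts[2] or 1.0)))
                else:
                    header[key] = val
    if header.get("BinaryFormat", "INT_16") != "INT_16":
        raise ValueError("only INT_16 BrainVision data supported")
    n_ch = int(header["NumberOfChannels"])
    fs = 1e6 / float(header["SamplingInterval"])
    raw = np.fromfile(stem + ".eeg", dtype="<i2").reshape(-1, n_ch).T
    res = np.array([r for _, r in channels])[:, None]
    markers: list[tuple[int, str]] = []
    with open(stem + ".vmrk") as fh:
        for line in fh:
            m = re.match(r"Mk\d+=Stimulus,([^,]*),(\d+),", line.strip())
            if m:
                markers.append((int(m.group(2)) - 1, m.group(1)))
    return Recording(raw * res, fs, [c for c, _ in channels], markers)


# ---------------------------------------------------------------------- EDF+

def _edf_header_fields(rec: Recording, n_records: int, record_dur: float,
                       phys_min: np.ndarray, phys_max: np.ndarray,
                       spr: int, ann_spr: int) -> bytes:
    n_sig = rec.n_channels + 1  # + annotations channel
    now = _dt.datetime(2000, 1, 1)
    h = b""
    h += b"0" + b" " * 7
    h += ("X X X X".ljust(80)).encode()
    h += ("Startdate X X X X".ljust(80)).encode()
    h += now.strftime("%d.%m.%y%H.%M.%S").encode()
    h += str(256 * (n_sig + 1)).ljust(8).encode()
    h += "EDF+C".ljust(44).encode()
    h += str(n_records).ljust(8).encode()
    h += f"{record_dur:g}".ljust(8).encode()
    h += str(n_sig).ljust(4).encode()

    labels = [name.ljust(16)[:16] for name in rec.channel_names]
    labels.append("EDF Annotations ")
    fields = [
        ("".join(labels)).encode(),
        b" " * 80 * n_sig,  # transducer
        ("".join(["uV".ljust(8)] * rec.n_channels + [" " * 8])).encode(),
        ("".join([f"{v:.8g}"[:8].ljust(8) for v in phys_min] + ["-1".ljust(8)])).encode(),
        ("".join([f"{v:.8g}"[:8].ljust(8) for v in phys_max] + ["1".ljust(8)])).encode(),
        ("".join(["-32768".ljust(8)] * rec.n_channels + ["-32768".ljust(8)])).encode(),
        ("".join(["32767".ljust(8)] * rec.n_channels + ["32767".ljust(8)])).encode(),
        b" " * 80 * n_sig,  # prefiltering
        ("".join([str(spr).ljust(8)] * rec.n_channels + [str(ann_spr).ljust(8)])).encode(),
        b" " * 32 * n_sig,  # reserved
    ]
    return h + b"".join(fields)


def _write_edf(rec: Recording, path: str) -> None:
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    spr = fs  # one-second data records
    n_samples = rec.n_samples
    n_records = int(np.ceil(n_samples / spr))
    phys_max = np.maximum(np.abs(rec.signal).max(axis=1), 1e-6)
    phys_min = -phys_max
    gain = (phys_max - phys_min) / 65535.0  # µV per bit

    # annotations: one timestamp TAL per record + event TALs
    tals: list[list[bytes]] = [[] for _ in range(n_records)]
    for ridx in range(n_records):
        tals[ridx].append(f"+{ridx}\x14\x14\x00".encode())
    for smp, label in rec.markers:
        ridx = min(smp // spr, n_records - 1)
        onset = smp / fs
        tals[ridx].append(f"+{onset:.6f}\x14{label}\x14\x00".encode())
    ann_bytes = [b"".join(t) for t in tals]
    ann_spr = (max(len(b) for b in ann_bytes) + 1) // 2 + 8

    header = _edf_header_fields(rec, n_records, 1.0, phys_min, phys_max, spr, ann_spr)
    # standard EDF mapping: phys_min <-> digital -32768
    digital = np.round((rec.signal - phys_min[:, None]) / gain[:, None]) - 32768.0
    digital = np.clip(digital, -32768, 32767).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for ridx in range(n_records):
            sl = slice(ridx * spr, (ridx + 1) * spr)
            chunk = digital[:, sl]
            if chunk.shape[1] < spr:  # pad final record
                chunk = np.pad(chunk, ((0, 0), (0, spr - chunk.shape[1])))
            fh.write(chunk.astype("<i2").tobytes())
            ann = ann_bytes[ridx].ljust(2 * ann_spr, b"\x00")
            fh.write(ann)
    write_events_tsv(os.path.splitext(path)[0] + "_events.tsv", rec.markers)


def _read_edf(path: str) -> Recording:
    with open(path, "rb") as fh:
        fh.read(252)
        n_sig = int(fh.read(4))
        labels = [fh.read(16).decode().strip() for _ in range(n_sig)]
        fh.seek(256 + n_sig * (16 + 80 + 8))
        pmin = np.array([float(fh.read(8)) for _ in range(n_sig)])
        pmax = np.array([float(fh.read(8)) for _ in range(n_sig)])
        dmin = np.array([float(fh.read(8)) for _ in range(n_sig)])
        dmax = np.array([float(fh.read(8)) for _ in range(n_sig)])
        fh.seek(256 + n_sig * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80))
        spr = np.array([int(fh.read(8)) for _ in range(n_sig)])
        fh.seek(236)
        n_records = int(fh.read(8))
        record_dur = float(fh.read(8))
        fh.seek(256 * (n_sig + 1))
        payload = fh.read()

    ann_idx = labels.index("EDF Annotations")
    sig_idx = [i for i in range(n_sig) if i != ann_idx]
    fs = spr[sig_idx[0]] / record_dur
    rec_len = int(spr.sum()) * 2
    chunks: list[list[np.ndarray]] = [[] for _ in range(n_sig)]
    ann_raw = b""
    for r in range(n_records):
        off = r * rec_len
        pos = 0
        for i in range(n_sig):
            nb = spr[i] * 2
            buf = payload[off + pos: off + pos + nb]
            if i == ann_idx:
                ann_raw += buf
            else:
                chunks[i].append(np.frombuffer(buf, dtype="<i2"))
            pos += nb
    gain = (pmax - pmin) / (dmax - dmin)
    sig = np.vstack([
        np.concatenate(chunks[i]).astype(float) * gain[i]
        + (pmin[i] - dmin[i] * gain[i])
        for i in sig_idx
    ])
    markers: list[tuple[int, str]] = []
    for tal in ann_raw.split(b"\x00"):
        if not tal:
            continue
        parts = tal.split(b"\x14")
        if len(parts) >= 2 and parts[1]:
            onset = float(parts[0].replace(b"\x15", b"."))
            markers.append((int(round(onset * fs)), parts[1].decode()))
    return Recording(sig, float(fs), [labels[i] for i in sig_idx], markers)


# ------------------------------------------------------------------- facade

def write_recording(rec: Recording, path: str, format: str = "brainvision") -> str:
    """Write a recording; returns the header/data path written.

    ``brainvision`` writes ``<path>.vhdr/.vmrk/.eeg``; ``edf`` (EDF+) writes
    ``<path>.edf``.  An events TSV sidecar is always written alongside.
    """
    fmt = format.lower().replace("+", "")
    stem = re.sub(r"\.(vhdr|edf)$", "", path)
    if fmt == "brainvision":
        _write_brainvision(rec, stem)
        return stem + ".vhdr"
    if fmt == "edf":
        _write_edf(rec, stem + ".edf")
        return stem + ".edf"
    raise ValueError(f"unknown format: {format!r}")


def read_recording(path: str) -> Recording:
    """Read a BrainVision (.vhdr) or EDF+ (.edf) recording written by this module."""
    if path.endswith(".vhdr"):
        return _read_brainvision(path[:-5])
    if path.endswith(".edf"):
        return _read_edf(path)
    raise ValueError("path must end in .vhdr or .edf")
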