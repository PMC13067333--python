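"""Continuous-data filtering and variable-length epoching.

Filtering follows the conventional chain for DBS-contaminated recordings:
0.5 Hz high-pass against slow drifts, 95 Hz low-pass against high-frequency
stimulator artifacts, and a 49.5-50.5 Hz band-stop for line noise.  Each
stage is a 4th-order Butterworth applied forward-backward (zero phase).

Epochs are cut from 1240 ms before movement onset to 1240 ms after the
offset of the reappeared stimulus, so their lengths vary with the movement
interval and delta-t (4546-6914 ms under the default design); they are kept
ragged and rectangularized only at event-aligned windowing.  An ICA stage
exists as a pluggable no-op: synthetic data carry no blink/EMG/cardiac
artifacts, but real data can slot a decomposition in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import Recording
from .task import TaskDesign, TrialSpec

__all__ = ["FilterSpec", "Epoch", "filter_continuous", "epoch", "no_op_ica"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    highpass_hz: float = 0.5
    lowpass_hz: float = 95.0
    bandstop_hz: tuple[float, float] = (49.5, 50.5)
    order: int = 4  # per pass; effective order doubles with filtfilt

    def __post_init__(self) -> None:
        if not self.highpass_hz < self.lowpass_hz:
            raise ValueError("highpass must be below lowpass")
        if not (self.highpass_hz < self.bandstop_hz[0]
                < self.bandstop_hz[1] < self.lowpass_hz):
            raise ValueError("bandstop must lie inside the passband")


def filter_continuous(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase high-pass, low-pass and band-stop filtering (Butterworth SOS)."""
    spec = spec or FilterSpec()
    fs = rec.sampling_rate
    ny = fs / 2.0
    if spec.lowpass_hz >= ny:
        raise ValueError("lowpass at or above Nyquist")
    x = rec.signal
    # pad by ~3 periods of the slowest pole: the scipy default pad is far
    # too short for a 0.5 Hz high-pass and leaves seconds-long transients
    pads = {"highpass": spec.highpass_hz, "lowpass": spec.lowpass_hz,
            "bandstop": spec.bandstop_hz[1] - spec.bandstop_hz[0]}
    for btype, w in (("highpass", spec.highpass_hz / ny),
                     ("lowpass", spec.lowpass_hz / ny),
                     ("bandstop", (spec.bandstop_hz[0] / ny,
                                   spec.bandstop_hz[1] / ny))):
        sos = sps.butter(spec.order, w, btype=btype, output="sos")
        padlen = min(x.shape[1] - 1, int(3 * fs / pads[btype]))
        x = sps.sosfiltfilt(sos, x, axis=1, padlen=padlen)
    return Recording(x, fs, list(rec.channel_names), list(rec.markers),
                     meta=rec.meta)


@dataclass
class Epoch:
    """One ragged trial segment with event offsets into it (samples)."""

    trial_id: int
    data: np.ndarray  # (n_channels, n_samples)
    events: dict[str, int]  # event name -> sample index within the epoch


def _marker_samples(rec: Recording) -> dict[tuple[int, str], int]:
    out = {}
    for smp, label in rec.markers:
        if "/" in label:
            name, tid = label.rsplit("/", 1)
            out[(int(tid), name)] = smp
    return out


def no_op_ica(epochs: list[Epoch]) -> list[Epoch]:
    """Placeholder for the artifact-rejection stage (identity on synthetic data)."""
    return epochs


def epoch(rec: Recording, schedule: list[TrialSpec],
          design: TaskDesign | None = None) -> list[Epoch]:
    """Cut padded variable-length epochs around each scheduled trial.

    Trials whose markers are missing or fall outside the recording are
    dropped with a log entry; trial-count accounting is up to the caller
    (len(epochs) + dropped == len(schedule)).
    """
    design = design or TaskDesign()
    fs = rec.sampling_rate
    pad = int(round(design.epoch_pad * fs / 1000.0))
    marks = _marker_samples(rec)
    names = ("move_on", "disappear", "reappear", "offset")
    out: list[Epoch] = []
    for tr in schedule:
        try:
            ev = {nm: marks[(tr.trial_id, nm)] for nm in names}
        except KeyError as e:
            log.warning("trial %d dropped: missing marker %s", tr.trial_id, e)
            continue
        i0 = ev["move_on"] - pad
        i1 = ev["offset"] + pad + 1
        if i0 < 0 or i1 > rec.n_samples:
            log.warning("trial %d dropped: epoch outside recording", tr.trial_id)
            continue
        out.append(Epoch(tr.trial_id, rec.signal[:, i0:i1].copy(),
                         {nm: ev[nm] - i0 for nm in names}))
    return out
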