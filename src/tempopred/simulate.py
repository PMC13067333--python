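"""Synthetic cohorts with known behavioral and oscillatory ground truth.

The generator writes down an explicit "world": a logistic observer whose
point of subjective equality (PSE) and psychometric steepness are stated on
the same scale the analysis recovers, and an EEG made of 1/f background
noise plus two dipolar generators — a beta-band (13-30 Hz) source whose
amplitude envelope drops during the prediction interval, and a delta-band
source whose oscillatory phase is reset at stimulus disappearance to a von
Mises draw.  Because the truth is known, every downstream stage (psychometric
fit, time-frequency power, ITPC, cluster statistics, beamformer) can be
checked for recovery rather than eyeballed.

Amplitudes are in µV at the sensors.  The delta generator produces phase
locking without any power change (a pure phase reset), so power effects and
phase effects can be manipulated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.special import expit
from scipy.stats import truncnorm

from ._rng import substream
from .io import Recording
from .layout import SensorLayout, standard_layout
from .source import HeadModel, leadfield_at
from .task import TaskDesign, TrialSpec

__all__ = ["ObserverParams", "OscillatoryTruth", "simulate_responses",
           "simulate_eeg"]

EVENT_NAMES = ("move_on", "disappear", "reappear", "offset")


@dataclass(frozen=True)
class ObserverParams:
    """Logistic observer on the field's steepness scale.

    ``steepness`` is 1 / (delta-t span between 25% and 75% "late" rates),
    in 1/ms; the logistic slope is b1 = 2 ln(3) * steepness so that fitting
    a plain binomial logistic model recovers ``steepness`` exactly.
    """

    pse_ms: float = 0.0
    steepness: float = 0.004  # 1/ms
    lapse: float = 0.0
    rt_mean: float = 500.0  # ms
    rt_sd: float = 150.0

    def __post_init__(self) -> None:
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if not 0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")

    @property
    def slope_logodds(self) -> float:
        return 2.0 * np.log(3.0) * self.steepness

    def p_late(self, delta_ms: np.ndarray | float) -> np.ndarray | float:
        """P(respond "late" | delta-t)."""
        core = expit(self.slope_logodds * (np.asarray(delta_ms, float) - self.pse_ms))
        return self.lapse / 2.0 + (1.0 - self.lapse) * core


@dataclass(frozen=True)
class OscillatoryTruth:
    """Ground-truth oscillatory effects injected into the synthetic EEG."""

    beta_center_hz: float = 20.0
    beta_suppression: float = -0.4  # fractional power change in [-1, 0]
    delta_center_hz: float = 2.0
    delta_kappa: float = 2.0  # von Mises concentration; 0 = no locking
    delta_preferred_phase: float = 0.0  # radians at t_disappear
    # row 0: beta generator (medial fronto-central); rows 1..: the delta
    # generator, modeled as a coherent cortical patch (all patch dipoles share
    # the same phase-reset draw), centered occipito-parietally
    source_locations: np.ndarray = field(
        default_factory=lambda: np.array([[20.0, 0.0, 55.0],
                                          [-55.0, 0.0, 30.0],
                                          [-45.0, -25.0, 30.0],
                                          [-45.0, 25.0, 30.0],
                                          [-30.0, 0.0, 50.0]])
    )
    source_orientations: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 1.0, 0.0]] * 5)
    )
    noise_exponent: float = 1.0  # 1/f^a amplitude slope of the background
    snr: float = 1.0  # generator-to-background sensor amplitude ratio
    background_rms_uv: float = 10.0

    def __post_init__(self) -> None:
        if not 13.0 <= self.beta_center_hz <= 30.0:
            raise ValueError("beta_center_hz must lie in [13, 30]")
        if not 0.5 <= self.delta_center_hz <= 4.0:
            raise ValueError("delta_center_hz must lie in [0.5, 4]")
        if not -1.0 <= self.beta_suppression <= 0.0:
            raise ValueError("beta_suppression must lie in [-1, 0]")
        if self.delta_kappa < 0:
            raise ValueError("delta_kappa must be >= 0")


# ------------------------------------------------------------------ behavior

def simulate_responses(schedule: list[TrialSpec], observer: ObserverParams,
                       seed: int = 0) -> pd.DataFrame:
    """Draw early/late judgments and reaction times for a schedule.

    Returns a table with columns trial_id, delta_ms, response ("early" /
    "late"), rt_ms.  RTs are truncated-normal, positive.
    """
    rng = substream(seed, "responses")
    deltas = np.array([t.delta_ms for t in schedule])
    p = np.asarray(observer.p_late(deltas))
    late = rng.random(len(schedule)) < p
    a = -observer.rt_mean / observer.rt_sd  # truncate at 0
    rt = truncnorm.rvs(a, np.inf, loc=observer.rt_mean, scale=observer.rt_sd,
                       size=len(schedule), random_state=rng)
    return pd.DataFrame({
        "trial_id": [t.trial_id for t in schedule],
        "delta_ms": deltas,
        "response": np.where(late, "late", "early"),
        "rt_ms": rt,
    })


# ----------------------------------------------------------------------- EEG

def _one_over_f(rng: np.random.Generator, n_ch: int, n_samp: int, fs: float,
                exponent: float) -> np.ndarray:
    """1/f^a-amplitude Gaussian background, unit RMS per channel."""
    white = rng.standard_normal((n_ch, n_samp))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_samp, 1.0 / fs)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * shaping, n=n_samp, axis=1)
    out /= out.std(axis=1, keepdims=True)
    return out


def _beta_envelope(n_samp: int, fs: float, schedule: list[TrialSpec],
                   suppression: float, ramp_ms: float = 100.0) -> np.ndarray:
    """Amplitude envelope: 1 at rest, sqrt(1+suppression) during prediction."""
    gain = np.sqrt(1.0 + suppression)
    env = np.ones(n_samp)
    ramp = int(round(ramp_ms * fs / 1000.0))
    half = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp))) if ramp > 1 else np.ones(0)
    for tr in schedule:
        i0 = int(round(tr.t_move_on * fs / 1000.0))
        i1 = int(round(tr.t_reappear * fs / 1000.0))
        i0, i1 = max(i0, 0), min(i1, n_samp)
        if i1 <= i0:
            continue
        env[i0:i1] = gain
        j0 = max(i0 - ramp, 0)
        env[j0:i0] = 1 + (gain - 1) * half[ramp - (i0 - j0):]
        j1 = min(i1 + ramp, n_samp)
        env[i1:j1] = gain - (gain - 1) * half[: j1 - i1]
    return env


def _delta_source(n_samp: int, fs: float, schedule: list[TrialSpec],
                  f_delta: float, kappa: float, mu: float,
                  rng: np.random.Generator, xfade_ms: float = 200.0) -> np.ndarray:
    """Constant-amplitude delta oscillation, phase reset at each disappearance.

    Per trial the oscillation runs with phase 2*pi*f*(t - t_dis) + theta_n,
    theta_n ~ von Mises(mu, kappa) (uniform when kappa = 0); segments meet
    midway between consecutive disappearances with a raised-cosine crossfade,
    so the amplitude envelope stays ~1 and only the phase carries structure.
    """
    t = np.arange(n_samp) / fs  # s
    if kappa > 0:
        thetas = rng.vonmises(mu, kappa, size=len(schedule))
    else:
        thetas = rng.uniform(-np.pi, np.pi, size=len(schedule))
    t_dis = np.array([tr.t_disappear for tr in schedule]) / 1000.0  # s
    bounds = np.concatenate(([0.0], 0.5 * (t_dis[1:] + t_dis[:-1]), [n_samp / fs]))
    xf = xfade_ms / 1000.0
    out = np.zeros(n_samp)
    for n in range(len(schedule)):
        lo, hi = bounds[n], bounds[n + 1]
        i0 = max(int((lo - xf) * fs), 0)
        i1 = min(int((hi + xf) * fs) + 1, n_samp)
        seg_t = t[i0:i1]
        w = np.clip((seg_t - (lo - xf)) / (2 * xf), 0, 1) * \
            np.clip(((hi + xf) - seg_t) / (2 * xf), 0, 1)
        w = 0.5 * (1 - np.cos(np.pi * np.minimum(2 * w, 1)))  # raised cosine edges
        out[i0:i1] += w * np.cos(2 * np.pi * f_delta * (seg_t - t_dis[n]) + thetas[n])
    return out


def simulate_eeg(schedule: list[TrialSpec], truth: OscillatoryTruth,
                 layout: SensorLayout | None = None,
                 design: TaskDesign | None = None, seed: int = 0,
                 head: HeadModel | None = None,
                 dbs_artifact_hz: float | None = None) -> Recording:
    """Render a continuous sensor-space recording for one session.

    The two dipolar generators are projected to the sensors through the
    homogeneous-sphere forward model; each generator's sensor signal is
    scaled so its RMS across channels equals ``snr`` times the background
    RMS.  With ``snr=0`` the output is pure background.  Markers are emitted
    for move_on / disappear / reappear / offset of every trial.

    ``dbs_artifact_hz`` optionally adds a comb of sinusoids at the given
    stimulation frequency and its harmonics up to Nyquist (exercises the
    band-stop / low-pass stages; off by default since the synthetic cohort
    carries no stimulator).
    """
    if not schedule:
        raise ValueError("schedule must be nonempty")
    design = design or TaskDesign()
    layout = layout or standard_layout()
    head = head or HeadModel()
    fs = design.sampling_rate
    rng_noise = substream(seed, "noise")
    rng_osc = substream(seed, "oscillators")

    locs = np.atleast_2d(np.asarray(truth.source_locations, float))
    if np.any(np.linalg.norm(locs, axis=1) >= head.radius_mm):
        raise ValueError("source_locations must lie inside the head sphere")

    n_samp = int(round((schedule[-1].t_offset + design.epoch_pad
                        + design.fixation) * fs / 1000.0))
    sig = truth.background_rms_uv * _one_over_f(
        rng_noise, layout.n_channels, n_samp, fs, truth.noise_exponent)

    if truth.snr > 0:
        sensors_mm = layout.positions * head.radius_mm
        oris = np.atleast_2d(np.asarray(truth.source_orientations, float))
        oris = oris / np.linalg.norm(oris, axis=1, keepdims=True)
        lfs = [leadfield_at(locs[k], sensors_mm, head) @ oris[k]
               for k in range(len(locs))]
        # beta = single dipole (row 0); delta = coherent patch (rows 1..)
        gains = [lfs[0], np.mean(lfs[1:], axis=0) if len(lfs) > 1 else lfs[0]]

        # beta: narrowband noise carrier, envelope drops during prediction
        ny = fs / 2.0
        bw = 2.5
        sos = sps.butter(4, [(truth.beta_center_hz - bw) / ny,
                             (truth.beta_center_hz + bw) / ny], "bandpass",
                         output="sos")
        carrier = sps.sosfiltfilt(sos, rng_osc.standard_normal(n_samp))
        carrier /= carrier.std()
        beta_src = carrier * _beta_envelope(n_samp, fs, schedule,
                                            truth.beta_suppression)
        delta_src = _delta_source(n_samp, fs, schedule, truth.delta_center_hz,
                                  truth.delta_kappa,
                                  truth.delta_preferred_phase, rng_osc)
        target = truth.snr * truth.background_rms_uv
        for src, g in zip((beta_src, delta_src), gains):
            proj = np.outer(g, src)
            rms = np.sqrt(np.mean(proj ** 2))
            if rms > 0:
                sig += proj * (target / rms)

    if dbs_artifact_hz:
        t = np.arange(n_samp) / fs
        for h in range(1, int(fs / 2 / dbs_artifact_hz) + 1):
            sig += 5.0 * np.sin(2 * np.pi * dbs_artifact_hz * h * t
                                + rng_osc.uniform(0, 2 * np.pi))

    markers = []
    for tr in schedule:
        for name, tt in zip(EVENT_NAMES, (tr.t_move_on, tr.t_disappear,
                                          tr.t_reappear, tr.t_offset)):
            markers.append((int(round(tt * fs / 1000.0)), f"{name}/{tr.trial_id}"))
    return Recording(sig, fs, list(layout.labels), markers,
                     meta={"truth": truth, "schedule": schedule,
                           "design": design})
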