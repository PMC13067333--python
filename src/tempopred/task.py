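"""Occluded-motion temporal prediction task: design parameters and trial schedules.

A trial shows a target moving for 1000-1500 ms, occludes it for a base
interval of 1500 ms perturbed by a signed offset delta-t, then redisplays it
for 500 ms.  The observer judges the reappearance as *early* or *late*.  The
:class:`TaskDesign` holds the printed task constants; :func:`build_schedule`
lays out a balanced, seed-permuted session as a list of :class:`TrialSpec`
with absolute event times, shared by the simulator, the epoching stage and
the behavioral analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream

__all__ = ["TaskDesign", "TrialSpec", "build_schedule", "epoch_span_range"]


def _default_delta_levels() -> tuple[int, ...]:
    mags = range(34, 935, 100)  # 34, 134, ..., 934
    return tuple(sorted([-m for m in mags] + list(mags)))


@dataclass(frozen=True)
class TaskDesign:
    """Constants of the temporal prediction paradigm (times in ms)."""

    base_interval: float = 1500.0
    movement_min: float = 1000.0
    movement_max: float = 1500.0
    delta_levels: tuple[int, ...] = field(default_factory=_default_delta_levels)
    reappearance_duration: float = 500.0
    fixation: float = 1500.0
    epoch_pad: float = 1240.0
    trials_per_block: int = 60
    blocks_per_session: int = 8
    sessions_per_control: int = 2  # controls run the condition twice
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        lv = np.asarray(self.delta_levels, dtype=float)
        if lv.size == 0 or not np.array_equal(np.sort(lv), lv):
            raise ValueError("delta_levels must be non-empty and sorted")
        if not np.allclose(lv, -lv[::-1]):
            raise ValueError("delta_levels must be symmetric about 0")
        if lv.size > 1 and not np.allclose(np.diff(lv[lv > 0]), 100.0):
            raise ValueError("positive delta_levels must step by 100 ms")
        if self.movement_min > self.movement_max:
            raise ValueError("movement_min must be <= movement_max")
        for name in ("base_interval", "movement_min", "reappearance_duration",
                     "fixation", "epoch_pad", "sampling_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_levels(self) -> int:
        return len(self.delta_levels)

    @property
    def trials_per_session(self) -> int:
        return self.trials_per_block * self.blocks_per_session

    @property
    def control_total_trials(self) -> int:
        return self.trials_per_session * self.sessions_per_control


@dataclass(frozen=True)
class TrialSpec:
    """Timing skeleton of one trial; event times in ms from recording start."""

    trial_id: int
    movement_ms: float
    delta_ms: float
    t_move_on: float
    t_disappear: float
    t_reappear: float
    t_offset: float

    def epoch_span_ms(self, design: TaskDesign) -> float:
        """Length of the padded analysis epoch for this trial."""
        return (self.t_offset - self.t_move_on) + 2 * design.epoch_pad


def epoch_span_range(design: TaskDesign) -> tuple[float, float]:
    """Closed-form (min, max) padded epoch duration under a design.

    span = pad + movement + (base_interval + delta) + reappearance + pad,
    minimised/maximised over the movement interval and delta levels.
    Defaults give (4546, 6914) ms.
    """
    lo = (design.epoch_pad + design.movement_min + design.base_interval
          + min(design.delta_levels) + design.reappearance_duration
          + design.epoch_pad)
    hi = (design.epoch_pad + design.movement_max + design.base_interval
          + max(design.delta_levels) + design.reappearance_duration
          + design.epoch_pad)
    return lo, hi


def build_schedule(design: TaskDesign, n_trials: int | None = None,
                   seed: int = 0) -> list[TrialSpec]:
    """Lay out a session: balanced delta levels, uniform movement intervals.

    Each delta level appears floor(n/k) or ceil(n/k) times (k levels); the
    trial order is a seed-determined permutation.  Movement durations are
    drawn uniformly from [movement_min, movement_max] and rounded to the
    sample grid; consecutive trials are separated by the fixation interval.

    Parameters
    ----------
    design : TaskDesign
    n_trials : int, optional
        Number of trials; defaults to the session size (480).
    seed : int
        Root seed; the schedule is bit-reproducible given (design, n, seed).
    """
    if n_trials is None:
        n_trials = design.trials_per_session
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    k = design.n_levels
    if n_trials % k:
        warnings.warn(
            f"n_trials={n_trials} not divisible by {k} levels; "
            "filling round-robin so counts differ by at most 1",
            stacklevel=2,
        )
    rng = substream(seed, "schedule")
    # round-robin fill then permute: counts per level differ by <= 1
    levels = np.asarray(design.delta_levels, dtype=float)
    deltas = levels[np.arange(n_trials) % k]
    rng.shuffle(deltas)
    dt = 1000.0 / design.sampling_rate
    movement = rng.uniform(design.movement_min, design.movement_max, size=n_trials)
    movement = np.round(movement / dt) * dt  # snap to sample grid

    specs: list[TrialSpec] = []
    t = design.fixation + design.epoch_pad  # leave room for the first pad
    for i in range(n_trials):
        t_move = t
        t_dis = t_move + movement[i]
        t_re = t_dis + design.base_interval + deltas[i]
        t_off = t_re + design.reappearance_duration
        specs.append(TrialSpec(i, float(movement[i]), float(deltas[i]),
                               t_move, t_dis, t_re, t_off))
        t = t_off + design.epoch_pad + design.fixation + design.epoch_pad
    return specs
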