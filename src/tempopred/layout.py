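"""Idealized spherical 64-channel 10-10 montage and its neighborhood graph.

Electrode positions are generated from row/column arc coordinates of the
10-10 naming scheme on a unit sphere.  They are a stand-in for a digitized
actiCAP geometry: good enough to define a forward model and a sensible
sensor adjacency, not anatomically exact.  Adjacency is defined by a
great-circle distance threshold solved so that the median neighbor count is
approximately six.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SensorLayout", "standard_layout"]

# (row letter, anterior-posterior coefficient): +1 = nasion, -1 = inion
_ROWS = {
    "Fp": 0.8, "AF": 0.6, "F": 0.4, "FC": 0.2, "C": 0.0,
    "CP": -0.2, "P": -0.4, "PO": -0.6, "O": -0.8, "T": 0.0,
    "FT": 0.2, "TP": -0.2,
}

# 64-channel actiCAP-style label set (10-10 subset)
_LABELS64 = [
    "Fp1", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8", "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
]

# compact 16-channel subset spanning the scalp, for scaled-down runs
_LABELS16 = [
    "Fp1", "Fp2", "F3", "Fz", "F4", "T7", "C3", "Cz", "C4", "T8",
    "P3", "Pz", "P4", "O1", "Oz", "O2",
]


def _arc_coords(label: str) -> tuple[float, float]:
    """(anterior-posterior, left-right) arc coefficients in [-1, 1] for a label."""
    if label[-1] in "zZ":
        row, col = label[:-1], "z"
    else:
        i = len(label) - 1
        while label[:i] not in _ROWS and i > 1:
            i -= 1
        row, col = label[:i], label[i:]
    a = _ROWS[row]
    if col == "z":
        lr = 0.0
    else:
        n = int(col)
        # odd numbers left, even right; 1/2 -> 0.2 ... 9/10 -> 1.0
        mag = ((n + 1) // 2) * 0.2
        lr = -mag if n % 2 else mag
    # temporal labels sit on the 0.8 circle
    if row in ("T", "FT", "TP") and abs(lr) >= 0.6:
        lr = np.sign(lr) * 0.8
        if row == "T":
            a = 0.0
    return a, lr


def _position(label: str) -> np.ndarray:
    a, lr = _arc_coords(label)
    r = np.hypot(a, lr)
    if r == 0:
        return np.array([0.0, 0.0, 1.0])
    # azimuthal-equidistant mapping: vertex angle proportional to arc radius
    theta = r * (np.pi / 2) * 1.125  # 0.8 circle sits slightly below equator
    phi = np.arctan2(lr, a)  # 0 = nasion, +pi/2 = right
    return np.array([np.sin(theta) * np.cos(phi),
                     -np.sin(theta) * np.sin(phi),
                     np.cos(theta)])


@dataclass(frozen=True)
class SensorLayout:
    """Channel labels, unit-sphere positions, and the neighbor relation."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3) unit vectors, x = nasion, y = left, z = up
    adjacency: np.ndarray  # (n, n) symmetric bool, irreflexive

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n_channels, 3)")
        A = self.adjacency
        if A.shape != (n, n) or not np.array_equal(A, A.T) or A.diagonal().any():
            raise ValueError("adjacency must be symmetric and irreflexive")
        if not A.any(axis=1).all():
            raise ValueError("every channel needs at least one neighbor")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


def _adjacency(pos: np.ndarray, target_median: float = 6.0) -> np.ndarray:
    """Great-circle threshold adjacency with median degree ~= target."""
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    ang = np.arccos(cosang)
    np.fill_diagonal(ang, np.inf)
    # choose the threshold whose median degree is closest to target
    cands = np.unique(ang[np.isfinite(ang)])
    best, best_err = None, np.inf
    for th in cands:
        deg = (ang <= th).sum(axis=1)
        if deg.min() < 1:
            continue
        err = abs(np.median(deg) - target_median)
        if err < best_err:
            best, best_err = th, err
        if np.median(deg) > target_median + 2:
            break
    A = ang <= best
    return A & A.T


def standard_layout(n_channels: int = 64) -> SensorLayout:
    """Build the idealized 10-10 montage (64 channels, or a 16-channel subset)."""
    if n_channels == 64:
        labels = _LABELS64
    elif n_channels == 16:
        labels = _LABELS16
    else:
        raise ValueError("supported montage sizes: 16, 64")
    pos = np.array([_position(lb) for lb in labels])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return SensorLayout(tuple(labels), pos, _adjacency(pos))
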