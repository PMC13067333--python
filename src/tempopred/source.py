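"""Spherical EEG forward model and DICS beamformer source analysis.

The volume conductor is a homogeneous sphere with an insulating boundary;
the surface potential of a current dipole has the classical Legendre-series
solution, evaluated here by stable recurrences.  For a dipole at radius b
(unit direction b-hat) inside a sphere of radius R, conductivity sigma, the
potential at a surface point r-hat is

    V = 1/(4 pi sigma R^2) * sum_{n>=1} (b/R)^(n-1)
        [ (2n+1) (m . b-hat) P_n(c)
          + ((2n+1)/n) P_n'(c) ((m . r-hat) - (m . b-hat) c) ],

with c = b-hat . r-hat.  This replaces an MRI-based single-shell model: it
is a documented approximation chosen for closed-form testability, and the
DICS machinery accepts externally supplied leadfields so a realistic model
can be dropped in.

Sources live on a regular lattice restricted to an inner "brain" sphere
(default 0.85 of the head radius): real cortex lies below the scalp, and
the series converges slowly for dipoles arbitrarily close to the sensors.

DICS (Dynamic Imaging of Coherent Sources) computes adaptive spatial
filters from a band-averaged cross-spectral density (CSD) matrix:
W = (L^T C^-1 L)^-1 L^T C^-1 with C regularized as Re(C) + lambda I.  One
*common* filter set, estimated from condition-pooled data, is applied to
every condition so that condition differences cannot be driven by filter
differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["HeadModel", "SourceGrid", "Leadfield", "DICSFilters",
           "build_grid", "leadfield_at", "leadfield_sphere", "csd",
           "csd_band_average", "dics_filters", "source_power", "source_itpc",
           "itpc_behavior_correlation", "grid_adjacency"]


@dataclass(frozen=True)
class HeadModel:
    """Homogeneous conducting sphere (mm; conductivity S/m)."""

    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius_mm: float = 85.0
    conductivity: float = 0.33
    brain_fraction: float = 0.85  # sources restricted to this fraction of R

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.conductivity <= 0:
            raise ValueError("radius and conductivity must be positive")
        if not 0 < self.brain_fraction < 1:
            raise ValueError("brain_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SourceGrid:
    """Regular source lattice strictly inside the brain sphere."""

    positions_mm: np.ndarray  # (n_voxels, 3)
    spacing_mm: float

    @property
    def n_voxels(self) -> int:
        return self.positions_mm.shape[0]


@dataclass(frozen=True)
class Leadfield:
    """Average-referenced forward solutions: (n_voxels, n_channels, 3)."""

    matrix: np.ndarray
    grid: SourceGrid


@dataclass(frozen=True)
class DICSFilters:
    """Scalar (dominant-orientation) DICS filters, one row per voxel."""

    weights: np.ndarray       # (n_voxels, n_channels), real
    orientations: np.ndarray  # (n_voxels, 3)
    lambda_: float
    csd_common: np.ndarray    # the (regularized-from) common CSD


# -------------------------------------------------------------------- grid

def _lattice_count(radius: float, spacing: float) -> int:
    k = int(np.floor(radius / spacing))
    ax = np.arange(-k, k + 1) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return int((X**2 + Y**2 + Z**2 < radius**2).sum())


def build_grid(head: HeadModel, spacing_mm: float | None = None,
               target_count: int | None = None) -> SourceGrid:
    """Cubic lattice clipped to the brain sphere.

    Either ``spacing_mm`` is given directly, or ``target_count`` is given
    and the spacing is solved by bisection so the voxel count lands within
    2% of the target.
    """
    r = head.radius_mm * head.brain_fraction
    if spacing_mm is None:
        if target_count is None:
            raise ValueError("give spacing_mm or target_count")
        lo, hi = r / 200.0, r  # bracket: huge count .. 1 voxel
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            c = _lattice_count(r, mid)
            if abs(c - target_count) <= 0.02 * target_count:
                spacing_mm = mid
                break
            if c > target_count:
                lo = mid
            else:
                hi = mid
        else:
            raise ValueError(f"cannot reach target_count={target_count}")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")
    k = int(np.floor(r / spacing_mm))
    ax = np.arange(-k, k + 1) * spacing_mm
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    pts = pts[np.einsum("ij,ij->i", pts, pts) < r**2]
    if len(pts) == 0:
        raise ValueError("spacing too large: empty grid")
    return SourceGrid(pts + head.center_mm, float(spacing_mm))


def grid_adjacency(grid: SourceGrid) -> np.ndarray:
    """26-connectivity neighbor relation on the lattice (symmetric bool)."""
    d = grid.positions_mm[:, None, :] - grid.positions_mm[None, :, :]
    steps = np.abs(d) / grid.spacing_mm
    near = (steps < 1.5).all(axis=2)
    np.fill_diagonal(near, False)
    return near


# --------------------------------------------------------------- leadfields

def leadfield_at(loc_mm: np.ndarray, sensors_mm: np.ndarray, head: HeadModel,
                 tol: float = 1e-14, n_max: int = 4000,
                 average_reference: bool = True) -> np.ndarray:
    """(n_sensors, 3) potential of unit x/y/z dipoles at one location.

    Volts per A*m.  Sensors are projected onto the sphere surface.  A voxel
    at the center is handled by the n=1 closed form; its radial orientation
    column is then exactly zero there (silent source, flagged by a warning
    elsewhere, not an error).
    """
    c0 = np.asarray(head.center_mm, float)
    p = (np.asarray(loc_mm, float) - c0) / 1000.0  # m
    R = head.radius_mm / 1000.0
    sens = np.asarray(sensors_mm, float) - c0
    rhat = sens / np.linalg.norm(sens, axis=1, keepdims=True)
    b = np.linalg.norm(p)
    if b >= R:
        raise ValueError("dipole outside the sphere")
    scale = 1.0 / (4.0 * np.pi * head.conductivity * R**2)

    if b < 1e-12:
        # central dipole: V = 3 (m . r-hat) / (4 pi sigma R^2)
        L = 3.0 * scale * rhat
    else:
        bhat = p / b
        f = b / R
        c = np.clip(rhat @ bhat, -1.0, 1.0)
        A = np.zeros_like(c)   # multiplies (m . b-hat)
        B = np.zeros_like(c)   # multiplies (m . r-hat)
        Pnm1, Pn = np.ones_like(c), c          # P_0, P_1
        dPnm1, dPn = np.zeros_like(c), np.ones_like(c)  # P_0', P_1'
        fpow = 1.0  # f^(n-1)
        n = 1
        while n <= n_max:
            coef = (2 * n + 1) * fpow
            A += coef * Pn - (coef / n) * c * dPn
            B += (coef / n) * dPn
            # term bound ~ (2n+1) f^(n-1) n(n+1)/2 (P_n' bound)
            if coef * n * (n + 1) < tol:
                break
            Pnp1 = ((2 * n + 1) * c * Pn - n * Pnm1) / (n + 1)
            dPnp1 = dPnm1 + (2 * n + 1) * Pn
            Pnm1, Pn, dPnm1, dPn = Pn, Pnp1, dPn, dPnp1
            fpow *= f
            n += 1
        L = scale * (A[:, None] * bhat[None, :] + B[:, None] * rhat)
    if average_reference:
        L = L - L.mean(axis=0, keepdims=True)
    return L


def leadfield_sphere(grid: SourceGrid, layout, head: HeadModel) -> Leadfield:
    """Average-referenced spherical leadfields for every grid voxel."""
    sensors_mm = np.asarray(layout.positions, float) * head.radius_mm + head.center_mm
    mats = np.empty((grid.n_voxels, sensors_mm.shape[0], 3))
    silent = 0
    for v in range(grid.n_voxels):
        mats[v] = leadfield_at(grid.positions_mm[v], sensors_mm, head)
        if np.linalg.norm(mats[v]) == 0:
            silent += 1
    if silent:
        warnings.warn(f"{silent} silent source(s) (central radial dipoles)",
                      stacklevel=2)
    return Leadfield(mats, grid)


# ---------------------------------------------------------------------- CSD

def csd(coefficients: np.ndarray, times_ms: np.ndarray,
        bin_ms: float = 100.0) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged cross-spectral density in 100 ms steps.

    Parameters
    ----------
    coefficients : complex (n_trials, n_channels, n_freqs, n_times)
        Event-aligned wavelet coefficients.
    times_ms : (n_times,) time axis of the coefficients.

    Returns
    -------
    C : complex (n_freqs, n_bins, n_channels, n_channels), Hermitian.
    bin_centers_ms : (n_bins,)
    """
    x = np.asarray(coefficients)
    n_tr, n_ch, n_f, n_t = x.shape
    if n_tr < 1:
        raise ValueError("need at least one trial")
    edges = np.arange(times_ms[0], times_ms[-1] + 1e-9, bin_ms)
    if len(edges) < 2:
        raise ValueError("window shorter than one bin")
    idx = np.searchsorted(edges, times_ms, side="right") - 1
    n_bins = len(edges) - 1
    C = np.zeros((n_f, n_bins, n_ch, n_ch), complex)
    counts = np.zeros(n_bins, int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b] == 0:
            continue
        xb = x[:, :, :, sel]  # (tr, ch, f, t_in_bin)
        C[:, b] = np.einsum("naft,nbft->fab", xb, xb.conj()) / (n_tr * counts[b])
    return C, edges[:-1] + bin_ms / 2.0


def csd_band_average(C: np.ndarray, freqs: np.ndarray, bin_centers_ms: np.ndarray,
                     band_hz: tuple[float, float],
                     window_ms: tuple[float, float]) -> np.ndarray:
    """Average the per-(freq, bin) CSDs over a band and time window."""
    fsel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    tsel = (bin_centers_ms >= window_ms[0]) & (bin_centers_ms <= window_ms[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("empty band/window selection")
    return C[np.ix_(fsel, tsel)].mean(axis=(0, 1))


# --------------------------------------------------------------------- DICS

def dics_filters(csd_common: np.ndarray, lf: Leadfield,
                 lambda_frac: float = 0.05) -> DICSFilters:
    """Scalar DICS filters from a common CSD.

    The real part of the CSD is regularized by lambda = lambda_frac * mean
    sensor power; per voxel the vector filter is W = (L^T C^-1 L)^-1 L^T C^-1
    and the scalar filter follows the dominant orientation (largest
    eigenvalue of the 3x3 source CSD W C W^T).
    """
    C = np.real(np.asarray(csd_common))
    n_ch = C.shape[0]
    lam = lambda_frac * np.trace(C) / n_ch
    Cr = C + lam * np.eye(n_ch)
    Ci = np.linalg.inv(Cr)
    n_vox = lf.grid.n_voxels
    W = np.empty((n_vox, n_ch))
    oris = np.empty((n_vox, 3))
    for v in range(n_vox):
        L = lf.matrix[v]  # (n_ch, 3)
        G = L.T @ Ci @ L
        try:
            Gi = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            Gi = np.linalg.pinv(G)
        Wv = Gi @ L.T @ Ci  # (3, n_ch) vector filter
        S = Wv @ C @ Wv.T   # 3x3 source CSD
        vals, vecs = np.linalg.eigh(S)
        u = vecs[:, -1]
        oris[v] = u
        W[v] = u @ Wv
    return DICSFilters(W, oris, float(lam), np.asarray(csd_common))


def vector_filters(csd_common: np.ndarray, lf: Leadfield,
                   lambda_frac: float = 0.05) -> np.ndarray:
    """(n_voxels, 3, n_channels) unreduced vector filters (for diagnostics)."""
    C = np.real(np.asarray(csd_common))
    n_ch = C.shape[0]
    lam = lambda_frac * np.trace(C) / n_ch
    Ci = np.linalg.inv(C + lam * np.eye(n_ch))
    out = np.empty((lf.grid.n_voxels, 3, n_ch))
    for v in range(lf.grid.n_voxels):
        L = lf.matrix[v]
        G = L.T @ Ci @ L
        try:
            Gi = np.linalg.inv(G)
        except np.linalg.LinAlgError:
            Gi = np.linalg.pinv(G)
        out[v] = Gi @ L.T @ Ci
    return out


def source_power(filters: DICSFilters, csd_condition: np.ndarray,
                 normalize: str | None = None) -> np.ndarray:
    """Per-voxel power w C w^T through the common scalar filters.

    ``normalize``: None (raw), "zscore" (across voxels, matching the
    z-scored source summaries), "nai" (neural activity index: power divided
    by the white-noise gain w w^T of each filter, removing the depth bias of
    raw minimum-variance power — use this for localization), or "relative"
    against a second map via :func:`relative_change`.
    """
    C = np.real(np.asarray(csd_condition))
    P = np.einsum("vc,cd,vd->v", filters.weights, C, filters.weights)
    if normalize is None:
        return P
    if normalize == "nai":
        return P / np.einsum("vc,vc->v", filters.weights, filters.weights)
    if normalize == "zscore":
        sd = P.std()
        if sd == 0:
            return np.zeros_like(P)
        return (P - P.mean()) / sd
    raise ValueError(f"unknown normalize mode {normalize!r}")


def relative_change(P: np.ndarray, P_baseline: np.ndarray) -> np.ndarray:
    if np.any(P_baseline <= 0):
        raise ValueError("baseline power must be positive")
    return (P - P_baseline) / P_baseline


def source_itpc(filters: DICSFilters, coefficients: np.ndarray,
                times_ms: np.ndarray, freqs: np.ndarray,
                band_hz: tuple[float, float],
                window_ms: tuple[float, float]) -> np.ndarray:
    """Per-voxel ITPC of beamformed source time courses.

    Channel coefficients are projected through the scalar filters per trial;
    ITPC is computed per (voxel, freq, time) across trials, then averaged
    over the band and window.
    """
    x = np.asarray(coefficients)  # (tr, ch, f, t)
    fsel = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    tsel = (times_ms >= window_ms[0]) & (times_ms <= window_ms[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("empty band/window selection")
    xs = x[:, :, fsel][..., tsel]  # (tr, ch, fb, tb)
    src = np.einsum("vc,ncft->nvft", filters.weights, xs)
    mag = np.abs(src)
    mag[mag == 0] = 1.0
    phasors = src / mag
    R = np.minimum(np.abs(phasors.mean(axis=0)), 1.0)  # (v, fb, tb)
    return R.mean(axis=(1, 2))


def export_voxel_map_tsv(path: str, grid: SourceGrid,
                         values: np.ndarray) -> None:
    """Flat TSV (voxel index, x, y, z, value) for external visualization."""
    vals = np.asarray(values, float)
    if vals.shape[0] != grid.n_voxels:
        raise ValueError("values length must equal the voxel count")
    with open(path, "w") as fh:
        fh.write("voxel\tx_mm\ty_mm\tz_mm\tvalue\n")
        for i, (p, v) in enumerate(zip(grid.positions_mm, vals)):
            fh.write(f"{i}\t{p[0]:.3f}\t{p[1]:.3f}\t{p[2]:.3f}\t{v:.8g}\n")


def itpc_behavior_correlation(itpc_maps: np.ndarray, steepness: np.ndarray):
    """Per-voxel Pearson r between subject delta ITPC and psychometric steepness.

    Returns (r_map, valid): r is NaN-flagged (valid False) where either
    variable has zero variance across subjects.
    """
    X = np.asarray(itpc_maps, float)  # (n_subjects, n_voxels)
    y = np.asarray(steepness, float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 subjects for correlation")
    yc = y - y.mean()
    sy = np.sqrt((yc**2).sum())
    Xc = X - X.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    valid = (sx > 0) & (sy > 0)
    r = np.full(X.shape[1], np.nan)
    if sy > 0:
        nz = sx > 0
        r[nz] = (Xc[:, nz] * yc[:, None]).sum(axis=0) / (sx[nz] * sy)
    return r, valid
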