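"""Probe-particle transport analysis: partitioning, diffusion, permeability.

The pipeline mirrors the solubility–diffusion treatment of small-molecule
membrane permeation. The hydrophobic core is located where the tail mass
density exceeds the head density; the partition coefficient K_p is the
ratio of probe occupancy inside vs outside that core; diffusion
coefficients come from ordinary least squares on multiple-time-origin MSD
curves (D = slope/2d per dimensionality d, converted Å²/ps → cm²/s); and
the permeability is the simplified homogeneous solubility–diffusion
estimate

    P_m = D_m · K_p / δ,

with δ the bilayer thickness. D_m defaults to the membrane-normal D_z (the
component that governs crossing) and the anisotropy D_z/D_xy is always
reported alongside.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (A2_PER_PS_TO_CM2_PER_S, CM_PER_ANGSTROM, DensityProfile,
                   ProbeTrajectory)

__all__ = [
    "MsdCurve", "DiffusionFit", "TransportConfig", "TransportSummary",
    "classify_regions", "partition_coefficient", "msd", "fit_diffusion",
    "transport_summary",
]


# ------------------------------------------------------------------ regions

def classify_regions(profile: DensityProfile, heads_label: str = "heads",
                     tails_label: str = "tails") -> tuple[float, float]:
    """Boundaries of the hydrophobic core from a density profile.

    The core is the contiguous z-interval around the midplane where the
    tail density exceeds the head density; its boundaries are the two
    crossover points, linearly interpolated between bins.
    """
    for lab in (heads_label, tails_label):
        if lab not in profile.densities or not np.any(profile.densities[lab] > 0):
            raise ValueError(f"profile lacks nonzero '{lab}' density")
    z = profile.bin_centers
    diff = profile.densities[tails_label] - profile.densities[heads_label]
    i0 = int(np.argmin(np.abs(z)))
    if diff[i0] <= 0:
        raise ValueError("tail density does not exceed head density at the midplane")

    def cross(direction: int) -> float:
        i = i0
        while 0 < i < len(z) - 1:
            j = i + direction
            if diff[j] <= 0:
                f = diff[i] / (diff[i] - diff[j])
                return float(z[i] + f * (z[j] - z[i]))
            i = j
        raise ValueError("no head/tail density crossover found "
                         f"{'above' if direction > 0 else 'below'} the midplane")

    return cross(-1), cross(+1)


# -------------------------------------------------------------- partitioning

def partition_coefficient(ptraj: ProbeTrajectory,
                          boundaries: tuple[float, float] | None = None,
                          discard_fraction: float = 0.2) -> float:
    """K_p = time-summed probe count inside the core / count outside.

    Counts frame-instantaneous positions of all particles over the frames
    surviving the initial discard window.
    """
    if boundaries is None:
        boundaries = ptraj.region_boundaries
    if boundaries is None:
        raise ValueError("no region boundaries available")
    z_lo, z_hi = boundaries
    n_drop = int(round(discard_fraction * ptraj.n_frames))
    if n_drop >= ptraj.n_frames:
        raise ValueError("discard window removes every frame")
    z = ptraj.positions[n_drop:, :, 2]
    inside = int(np.sum((z >= z_lo) & (z <= z_hi)))
    outside = z.size - inside
    if outside == 0:
        raise ValueError("probe never leaves core; K_p undefined")
    return inside / outside


# --------------------------------------------------------------------- MSD

@dataclass
class MsdCurve:
    lags: np.ndarray          # ps
    msd_z: np.ndarray         # Å²
    msd_xy: np.ndarray
    msd_3d: np.ndarray
    n_origin_pairs: np.ndarray

    def component(self, name: str) -> np.ndarray:
        return {"z": self.msd_z, "xy": self.msd_xy, "3d": self.msd_3d}[name]


def _unwrap_xy(ptraj: ProbeTrajectory) -> np.ndarray:
    """Accumulate minimum-image xy displacements into unwrapped coordinates."""
    xy = ptraj.positions[:, :, :2]
    box = ptraj.boxes[1:, None, :2]
    d = np.diff(xy, axis=0)
    d -= box * np.round(d / box)
    out = np.empty_like(xy)
    out[0] = xy[0]
    out[1:] = xy[0] + np.cumsum(d, axis=0)
    return out


def _msd_1d(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Multiple-time-origin MSD of one coordinate, all particles.

    x: (n_frames, n_particles). FFT autocorrelation formulation — exact
    (to floating point) equivalent of the O(N²) double loop over origins.
    """
    n = x.shape[0]
    nfft = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(fx * np.conj(fx), n=nfft, axis=0)[:n].real
    sq = x ** 2
    ssum = 2.0 * sq.sum(axis=0)
    s1 = np.empty((max_lag + 1, x.shape[1]))
    s1[0] = ssum - 0.0
    run = ssum.copy()
    for m in range(1, max_lag + 1):
        run -= sq[m - 1] + sq[n - m]
        s1[m] = run
    counts = (n - np.arange(max_lag + 1))[:, None]
    msd = (s1 - 2.0 * acf[:max_lag + 1]) / counts
    msd[0] = 0.0
    return msd.mean(axis=1)


def msd(ptraj: ProbeTrajectory) -> MsdCurve:
    """MSD(τ) over all particles and time origins, per component.

    xy positions are unwrapped across the periodic images first; z is
    treated as bounded. Lags run to half the trajectory length.
    """
    if ptraj.n_frames < 3:
        raise ValueError("MSD needs at least 3 frames")
    max_lag = ptraj.n_frames // 2
    xy = _unwrap_xy(ptraj)
    z = ptraj.positions[:, :, 2]
    m_x = _msd_1d(xy[:, :, 0], max_lag)
    m_y = _msd_1d(xy[:, :, 1], max_lag)
    m_z = _msd_1d(z, max_lag)
    dt = ptraj.dt
    lags = dt * np.arange(max_lag + 1, dtype=float)
    pairs = ptraj.n_particles * (ptraj.n_frames - np.arange(max_lag + 1))
    return MsdCurve(lags=lags, msd_z=m_z, msd_xy=m_x + m_y,
                    msd_3d=m_x + m_y + m_z, n_origin_pairs=pairs)


# ---------------------------------------------------------------- diffusion

@dataclass
class DiffusionFit:
    d: float                  # cm²/s
    r2: float
    window: tuple[float, float]
    component: str
    degenerate: bool = False
    window_auto: bool = False
    windows_rejected: bool = False


_DIMS = {"z": 1, "xy": 2, "3d": 3}


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, icept = np.polyfit(t, y, 1)
    resid = y - (slope * t + icept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(icept), r2


def fit_diffusion(curve: MsdCurve, window: tuple[float, float] | None = None,
                  component: str = "z", r2_floor: float = 0.99,
                  default_window: tuple[float, float] = (2000.0, 10_000.0)
                  ) -> DiffusionFit:
    """OLS of MSD vs lag on a window; D = slope / (2·dim), in cm²/s.

    With no window given: the 2–10 ns span is used when the lags reach it;
    otherwise the longest candidate window with r² ≥ ``r2_floor`` is
    auto-selected (``windows_rejected`` is set whenever longer candidates
    failed the floor). A non-positive slope reports D = 0 with the
    ``degenerate`` flag.
    """
    if component not in _DIMS:
        raise ValueError(f"component must be one of {sorted(_DIMS)}")
    lags, y = curve.lags, curve.component(component)
    auto = window is None
    rejected = False
    if auto:
        window = None
        if lags[-1] >= default_window[1]:
            sel = (lags >= default_window[0]) & (lags <= default_window[1])
            yy = y[sel]
            if sel.sum() >= 5 and not np.allclose(yy, yy[0]):
                _, _, r2 = _ols(lags[sel], yy)
                if r2 >= r2_floor:
                    window = default_window
                else:
                    rejected = True
        if window is None:
            window, rej = _auto_window(lags, y, r2_floor)
            rejected = rejected or rej
    lo, hi = window
    if lo < lags[0] or hi > lags[-1]:
        raise ValueError(f"window {window} outside available lags "
                         f"[{lags[0]}, {lags[-1]}] ps")
    sel = (lags >= lo) & (lags <= hi)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 MSD points in the fit window")
    slope, _, r2 = _ols(lags[sel], y[sel])
    if slope <= 0:
        return DiffusionFit(d=0.0, r2=r2, window=(lo, hi), component=component,
                            degenerate=True, window_auto=auto,
                            windows_rejected=rejected)
    d = slope / (2.0 * _DIMS[component]) * A2_PER_PS_TO_CM2_PER_S
    return DiffusionFit(d=d, r2=r2, window=(lo, hi), component=component,
                        window_auto=auto, windows_rejected=rejected)


def _auto_window(lags: np.ndarray, y: np.ndarray,
                 r2_floor: float) -> tuple[tuple[float, float], bool]:
    """Longest candidate window whose linear fit clears the r² floor."""
    n = len(lags)
    fracs = np.linspace(0.0, 0.9, 10)
    cands = []
    for f_lo in fracs:
        for f_hi in np.linspace(f_lo + 0.1, 1.0, 9):
            i = int(f_lo * (n - 1))
            j = int(f_hi * (n - 1))
            if j - i >= 5:
                cands.append((i, j))
    cands.sort(key=lambda ij: lags[ij[1]] - lags[ij[0]], reverse=True)
    rejected = False
    for i, j in cands:
        t, yy = lags[i:j + 1], y[i:j + 1]
        if np.allclose(yy, yy[0]):
            continue
        _, _, r2 = _ols(t, yy)
        if r2 >= r2_floor:
            return (float(lags[i]), float(lags[j])), rejected
        rejected = True
    # nothing clears the floor: shortest candidate, flagged
    i, j = cands[-1]
    return (float(lags[i]), float(lags[j])), True


# ----------------------------------------------------------------- summary

@dataclass
class TransportConfig:
    discard_fraction: float = 0.2
    fit_window: tuple[float, float] | None = None
    d_m_estimator: str = "dz"   # which component stands in for D_m

    def validate(self) -> None:
        if not 0.0 <= self.discard_fraction <= 0.9:
            raise ValueError("discard_fraction must be in [0, 0.9]")
        if self.d_m_estimator not in ("dz", "xy", "3d"):
            raise ValueError("d_m_estimator must be 'dz', 'xy' or '3d'")


@dataclass
class TransportSummary:
    k_p: float
    d_z: float
    d_xy: float
    anisotropy: float
    d_m: float
    delta: float              # Å
    p_m: float                # cm/s
    fit_window: tuple[float, float]
    fit_r2: float
    d_m_estimator: str = "dz"

    def to_dict(self) -> dict:
        return {
            "k_p": self.k_p, "d_z_cm2_s": self.d_z, "d_xy_cm2_s": self.d_xy,
            "anisotropy_dz_dxy": self.anisotropy, "d_m_cm2_s": self.d_m,
            "delta_A": self.delta, "p_m_cm_s": self.p_m,
            "fit_window_ps": list(self.fit_window), "fit_r2": self.fit_r2,
            "d_m_estimator": self.d_m_estimator,
        }


def permeability(d_m: float, k_p: float, delta_angstrom: float) -> float:
    """P_m = D_m·K_p/δ in cm/s, with δ given in Å."""
    if delta_angstrom <= 0:
        raise ValueError("membrane thickness must be positive")
    return d_m * k_p / (delta_angstrom * CM_PER_ANGSTROM)


def transport_summary(ptraj: ProbeTrajectory, delta_angstrom: float,
                      config: TransportConfig | None = None,
                      boundaries: tuple[float, float] | None = None
                      ) -> TransportSummary:
    """K_p, D_z, D_xy, anisotropy, D_m and P_m in one record.

    ``delta_angstrom`` is the bilayer thickness δ, normally the mean from a
    :class:`~membkit.structure.StructureSummary`.
    """
    cfg = config or TransportConfig()
    cfg.validate()
    if delta_angstrom <= 0:
        raise ValueError("membrane thickness must be positive")
    k_p = partition_coefficient(ptraj, boundaries, cfg.discard_fraction)
    curve = msd(ptraj)
    fit_z = fit_diffusion(curve, cfg.fit_window, "z")
    fit_xy = fit_diffusion(curve, cfg.fit_window, "xy")
    fit_3d = fit_diffusion(curve, cfg.fit_window, "3d")
    by_comp = {"dz": fit_z, "xy": fit_xy, "3d": fit_3d}
    d_m_fit = by_comp[cfg.d_m_estimator]
    anisotropy = fit_z.d / fit_xy.d if fit_xy.d > 0 else float("nan")
    return TransportSummary(
        k_p=k_p, d_z=fit_z.d, d_xy=fit_xy.d, anisotropy=anisotropy,
        d_m=d_m_fit.d, delta=delta_angstrom,
        p_m=permeability(d_m_fit.d, k_p, delta_angstrom),
        fit_window=d_m_fit.window, fit_r2=d_m_fit.r2,
        d_m_estimator=cfg.d_m_estimator,
    )
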