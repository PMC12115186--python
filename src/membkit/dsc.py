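"""Differential scanning calorimetry thermogram parameterization.

Extracts the thermotropic descriptors of a lipid phase transition from an
excess-heat-capacity trace: main-transition temperature T_m (apex, refined
by 3-point parabolic interpolation so the resolution beats the sampling
step), peak width ΔT_b (full width at half maximum — the convention that
ties width to van't Hoff cooperativity), calorimetric enthalpy ΔH (area of
the main peak by the trapezoid rule over the detected peak bounds), and
scan hysteresis ΔT_h = T_m(heating) − T_m(cooling). Delta-vs-control tables
and dose series (lipid:drug ratio sweeps with biphasic-trend detection) are
built on top.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .core import warn

__all__ = [
    "Thermogram", "TransitionParams", "DeltaReport", "PeakRecord",
    "subtract_baseline", "detect_transitions", "transition_params",
    "hysteresis", "delta_report", "dose_series",
]


@dataclass
class Thermogram:
    """A temperature / excess-heat-capacity trace.

    temperature in °C (stored ascending), cp_excess in kcal/(mol·°C).
    """

    temperature: np.ndarray
    cp_excess: np.ndarray
    direction: str = "heating"
    scan_rate: float = 0.2  # °C/min
    label: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        c = np.asarray(self.cp_excess, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("temperature and cp_excess must be equal-length 1-D")
        if len(t) < 2:
            raise ValueError("a thermogram needs at least two samples")
        order = np.argsort(t, kind="stable")
        t, c = t[order], c[order]
        if (np.diff(t) <= 0).any():
            raise ValueError("temperature grid must be strictly monotone")
        self.temperature, self.cp_excess = t, c
        if self.direction not in ("heating", "cooling"):
            raise ValueError("direction must be 'heating' or 'cooling'")


@dataclass
class PeakRecord:
    apex_t: float
    apex_cp: float
    prominence: float
    bounds: tuple[float, float]
    area: float
    kind: str = "main"  # or "pre-transition"


@dataclass
class TransitionParams:
    t_m: float            # °C
    delta_t_b: float      # °C, FWHM
    delta_h: float        # kcal/mol
    pre_transition_t: float | None = None
    peak_bounds: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.delta_t_b <= 0:
            raise ValueError("delta_t_b must be positive")
        if self.delta_h < 0:
            raise ValueError("delta_h must be non-negative")
        lo, hi = self.peak_bounds
        if not lo <= self.t_m <= hi:
            raise ValueError("peak_bounds must bracket t_m")


@dataclass
class DeltaReport:
    """Drug-minus-control changes of the thermotropic parameters."""

    ratio_label: str
    d_t_m: float
    dd_t_b: float
    dd_t_h: float
    dd_h: float

    def __post_init__(self) -> None:
        vals = (self.d_t_m, self.dd_t_b, self.dd_t_h, self.dd_h)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("delta report fields must be finite")


def subtract_baseline(trace: Thermogram) -> Thermogram:
    """Remove a linear baseline anchored on the scan edges.

    The baseline passes through the median Cp of the first and last 10% of
    the temperature range (the pre- and post-transition flats). Off-peak
    residuals may be slightly negative; that is expected and harmless for
    the downstream trapezoidal integration.
    """
    t, c = trace.temperature, trace.cp_excess
    span = t[-1] - t[0]
    if span < 5.0:
        raise ValueError(f"temperature range {span:.2f} °C is too short (< 5 °C)")
    n_edge = max(2, int(round(0.10 * len(t))))
    t_lo, c_lo = float(np.median(t[:n_edge])), float(np.median(c[:n_edge]))
    t_hi, c_hi = float(np.median(t[-n_edge:])), float(np.median(c[-n_edge:]))
    slope = (c_hi - c_lo) / (t_hi - t_lo)
    baseline = c_lo + slope * (t - t_lo)
    out = replace(trace, temperature=t, cp_excess=c - baseline,
                  warnings=list(trace.warnings))
    peak = float(np.max(out.cp_excess)) if len(c) else 0.0
    if peak > 0 and abs(c_hi - c_lo) > 0.20 * peak:
        out.warnings.append("scan-edge baselines differ by >20% of peak height; "
                            "a linear baseline may be inadequate")
    return out


def detect_transitions(trace: Thermogram,
                       prominence_fraction: float = 0.05,
                       bound_fraction: float = 0.01,
                       min_prominence: float = 0.0) -> list[PeakRecord]:
    """Locate transition peaks on a baseline-subtracted trace.

    Local maxima with prominence ≥ ``prominence_fraction`` of the global
    maximum (and ≥ the absolute ``min_prominence``, for rejecting
    instrument noise) are kept. The largest-area peak is "main"; any
    detected peak at lower temperature is a "pre-transition". Peak bounds
    extend to where Cp falls to ``bound_fraction`` of the apex or a clear
    local minimum (a rise exceeding 5% of the apex) intervenes. Returns an
    empty list when nothing clears the prominence floor.
    """
    t, c = trace.temperature, trace.cp_excess
    top = float(np.max(c))
    if top <= 0:
        return []
    prom_floor = max(prominence_fraction * top, min_prominence)
    idx, props = find_peaks(c, prominence=prom_floor)
    records: list[PeakRecord] = []
    for i, prom in zip(idx, props["prominences"]):
        floor = bound_fraction * c[i]
        rise_guard = 0.05 * c[i]
        lo = i
        while lo > 0 and c[lo - 1] >= floor and c[lo - 1] - c[lo] <= rise_guard:
            lo -= 1
        hi = i
        while hi < len(c) - 1 and c[hi + 1] >= floor and c[hi + 1] - c[hi] <= rise_guard:
            hi += 1
        area = float(np.trapezoid(c[lo:hi + 1], t[lo:hi + 1]))
        records.append(PeakRecord(
            apex_t=float(t[i]), apex_cp=float(c[i]), prominence=float(prom),
            bounds=(float(t[lo]), float(t[hi])), area=area,
        ))
    records.sort(key=lambda r: r.area, reverse=True)
    if records:
        records[0].kind = "main"
        for r in records[1:]:
            r.kind = "pre-transition" if r.apex_t < records[0].apex_t else "post"
    return records


def _parabolic_apex(t: np.ndarray, c: np.ndarray, i: int) -> tuple[float, float]:
    """Refine the apex through the 3 points around index ``i``."""
    if i == 0 or i == len(t) - 1:
        return float(t[i]), float(c[i])
    y0, y1, y2 = c[i - 1], c[i], c[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not locally concave; keep the grid point
        return float(t[i]), float(c[i])
    delta = 0.5 * (y0 - y2) / denom
    h = 0.5 * (t[i + 1] - t[i - 1])
    return float(t[i] + delta * h), float(y1 - 0.25 * (y0 - y2) * delta)


def _cross(t: np.ndarray, c: np.ndarray, i_apex: int, level: float,
           side: str) -> float:
    """Temperature where c first falls through ``level`` walking out from
    the apex (linear interpolation; robust to bound truncation)."""
    if side == "left":
        for j in range(i_apex, 0, -1):
            if c[j - 1] < level <= c[j]:
                f = (level - c[j - 1]) / (c[j] - c[j - 1])
                return float(t[j - 1] + f * (t[j] - t[j - 1]))
    else:
        for j in range(i_apex, len(c) - 1):
            if c[j] >= level > c[j + 1]:
                f = (c[j] - level) / (c[j] - c[j + 1])
                return float(t[j] + f * (t[j + 1] - t[j]))
    raise ValueError(f"half-height not reached on the {side} side of the peak")


def transition_params(trace: Thermogram, *,
                      baseline_subtracted: bool = False) -> TransitionParams:
    """Parameterize the main transition of a thermogram.

    Runs :func:`subtract_baseline` first unless told the trace is already
    flat. The input temperature grid may be in any order (sorted
    internally by the :class:`Thermogram` constructor).
    """
    work = trace if baseline_subtracted else subtract_baseline(trace)
    peaks = detect_transitions(work)
    if not peaks:
        raise ValueError("no transition peak detected above the prominence floor")
    main = peaks[0]
    t, c = work.temperature, work.cp_excess
    i_apex = int(np.argmin(np.abs(t - main.apex_t)))
    t_m, cp_apex = _parabolic_apex(t, c, i_apex)

    i_lo = int(np.searchsorted(t, main.bounds[0]))
    i_hi = int(np.searchsorted(t, main.bounds[1]))
    half = 0.5 * cp_apex
    left = _cross(t, c, i_apex, half, "left")
    right = _cross(t, c, i_apex, half, "right")
    width = right - left

    seg = slice(i_lo, i_hi + 1)
    area = float(np.trapezoid(c[seg], t[seg]))

    pre = [p for p in peaks if p.kind == "pre-transition"]
    pre_t = pre[0].apex_t if pre else None
    return TransitionParams(
        t_m=t_m, delta_t_b=width, delta_h=area,
        pre_transition_t=pre_t, peak_bounds=main.bounds,
    )


def hysteresis(heating: TransitionParams, cooling: TransitionParams) -> float:
    """ΔT_h = T_m(heating) − T_m(cooling).

    Positive for the usual supercooling of the transition; a negative value
    (cooling apex above heating) is preserved as-is.
    """
    return heating.t_m - cooling.t_m


def delta_report(treated: tuple[TransitionParams, TransitionParams],
                 control: tuple[TransitionParams, TransitionParams],
                 ratio_label: str) -> DeltaReport:
    """Drug-minus-control table row from (heating, cooling) pairs.

    The heating scan is the reference for ΔT_m, ΔΔT_b and ΔΔH; ΔΔT_h is the
    change of the heating–cooling hysteresis.
    """
    th, tc = treated
    ch, cc = control
    return DeltaReport(
        ratio_label=ratio_label,
        d_t_m=th.t_m - ch.t_m,
        dd_t_b=th.delta_t_b - ch.delta_t_b,
        dd_t_h=hysteresis(th, tc) - hysteresis(ch, cc),
        dd_h=th.delta_h - ch.delta_h,
    )


def _drug_fraction(label: str) -> float:
    lipid, _, drug = label.partition(":")
    return float(drug) / float(lipid)


def dose_series(reports: list[DeltaReport]) -> dict:
    """Order delta reports by increasing drug fraction and flag biphasic T_m.

    A series is "biphasic" when the sign of the successive-difference slope
    of ΔT_m changes exactly once (one interior extremum), which requires at
    least 3 ratios; with fewer the flag is suppressed and noted.
    """
    labels = [r.ratio_label for r in reports]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate ratio labels in dose series")
    if len(reports) < 2:
        raise ValueError("a dose series needs at least 2 ratios")
    ordered = sorted(reports, key=lambda r: _drug_fraction(r.ratio_label))
    note = ""
    biphasic = False
    extremum_between: tuple[str, str] | None = None
    if len(ordered) < 3:
        note = "biphasic detection suppressed: fewer than 3 ratios"
    else:
        vals = np.array([r.d_t_m for r in ordered])
        d = np.diff(vals)
        signs = np.sign(d[d != 0])
        changes = int(np.sum(signs[1:] != signs[:-1])) if len(signs) > 1 else 0
        if changes == 1:
            biphasic = True
            ext = vals.min() if signs[0] < 0 else vals.max()
            at = np.flatnonzero(vals == ext)
            i_lo, i_hi = int(at[0]), int(at[-1])
            if i_lo == i_hi:  # strict extremum: bracket by its neighbours
                i_lo, i_hi = max(i_lo - 1, 0), min(i_hi + 1, len(ordered) - 1)
            extremum_between = (ordered[i_lo].ratio_label,
                                ordered[i_hi].ratio_label)
    return {
        "series": ordered,
        "biphasic": biphasic,
        "extremum_between": extremum_between,
        "note": note,
    }
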