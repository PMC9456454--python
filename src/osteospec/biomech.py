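"""Mechanical-curve analysis for tendon tensile tests and femoral
three-point bending.

Tendon: cross-sectional area from mass/(density*length), stress-strain
conversion (strain as percent of initial length), elastic modulus as the
maximum least-squares slope over contiguous windows of the pre-ultimate
strain range, ultimate point at peak stress, and toughness as the area
under the stress-strain curve to failure.

Bone: structural parameters from the load-displacement curve — stiffness,
yield by a toe-corrected 10% secant-deviation rule (0.2%-offset
alternative), ultimate load, post-yield displacement and work-to-fracture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TensileCurve",
    "TensileResult",
    "BendingCurve",
    "BendingResult",
    "TENDON_DENSITY",
    "cross_sectional_area",
    "to_stress_strain",
    "elastic_modulus",
    "ultimate_point",
    "toughness",
    "bending_stiffness",
    "yield_point",
    "detect_failure",
    "post_yield_displacement",
    "work_to_fracture",
    "final_ramp",
    "analyze_tensile",
    "analyze_bending",
]

#: Tendon mass density (mg/mm^3) used to convert mass and length to CSA;
#: standard tendon literature value, configurable per curve.
TENDON_DENSITY = 1.12


class BiomechError(ValueError):
    pass


@dataclass
class TensileCurve:
    displacement: np.ndarray  # mm
    force: np.ndarray  # N
    mass: float  # mg
    length: float  # mm (initial)
    density: float = TENDON_DENSITY  # mg/mm^3
    time: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, float)
        self.force = np.asarray(self.force, float)
        if len(self.displacement) != len(self.force):
            raise BiomechError("displacement and force must have equal length")
        if not np.all(np.isfinite(self.force)):
            raise BiomechError("force must be finite")
        if self.mass <= 0 or self.length <= 0 or self.density <= 0:
            raise BiomechError("mass, length and density must be positive")


@dataclass(frozen=True)
class TensileResult:
    csa: float  # mm^2
    elastic_modulus: float  # N/mm^2 (per unit fractional strain)
    ultimate_stress: float  # N/mm^2
    ultimate_strain: float  # %
    toughness: float  # N/mm^2
    failure_detected: bool = True

    def as_dict(self) -> dict:
        return {
            "csa_mm2": self.csa,
            "elastic_modulus_MPa": self.elastic_modulus,
            "ultimate_stress_MPa": self.ultimate_stress,
            "ultimate_strain_pct": self.ultimate_strain,
            "toughness_MPa": self.toughness,
            "failure_detected": self.failure_detected,
        }


@dataclass
class BendingCurve:
    displacement: np.ndarray  # mm, strictly increasing
    load: np.ndarray  # N
    span: float = 6.0  # mm, support span
    label: str = ""

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, float)
        self.load = np.asarray(self.load, float)
        if len(self.displacement) != len(self.load):
            raise BiomechError("displacement and load must have equal length")
        if not np.all(np.diff(self.displacement) > 0):
            raise BiomechError("bending displacement must be strictly increasing")
        if not np.all(np.isfinite(self.load)):
            raise BiomechError("load must be finite")


@dataclass(frozen=True)
class BendingResult:
    ultimate_load: float  # N
    stiffness: float  # N/mm
    yield_load: float  # N
    yield_displacement: float  # mm
    post_yield_displacement: float  # mm
    work_to_fracture: float  # N*mm
    yield_criterion: str = "secant10"
    brittle: bool = False
    failure_detected: bool = True

    def as_dict(self) -> dict:
        return {
            "ultimate_load_N": self.ultimate_load,
            "stiffness_N_per_mm": self.stiffness,
            "yield_load_N": self.yield_load,
            "post_yield_displacement_mm": self.post_yield_displacement,
            "work_to_fracture_Nmm": self.work_to_fracture,
            "yield_criterion": self.yield_criterion,
            "brittle": self.brittle,
        }


def cross_sectional_area(mass: float, length: float, density: float = TENDON_DENSITY) -> float:
    """CSA (mm^2) = mass / (density * length)."""
    if mass <= 0 or length <= 0 or density <= 0:
        raise BiomechError("mass, length and density must be positive")
    return mass / (density * length)


def final_ramp(displacement: np.ndarray, tol_fraction: float = 1e-3) -> int:
    """Start index of the final monotone ramp to fracture.

    The tensile protocol interleaves load/hold/unload cycles before the
    terminal ramp; only the last monotone-non-decreasing stretch of the
    displacement trace is analyzed.  Returns the first index of that
    stretch.
    """
    d = np.asarray(displacement, float)
    tol = tol_fraction * max(float(np.ptp(d)), 1e-12)
    drops = np.flatnonzero(np.diff(d) < -tol)
    return int(drops[-1] + 1) if len(drops) else 0


def to_stress_strain(c: TensileCurve) -> tuple[np.ndarray, np.ndarray]:
    """(strain %, stress N/mm^2) of the final ramp of a tensile curve."""
    start = final_ramp(c.displacement)
    csa = cross_sectional_area(c.mass, c.length, c.density)
    disp = c.displacement[start:]
    strain = 100.0 * disp / c.length
    stress = c.force[start:] / csa
    return strain, stress


def _max_window_slope(x: np.ndarray, y: np.ndarray, window_fraction: float, stop: int) -> float:
    """Maximum OLS slope over contiguous windows spanning ``window_fraction``
    of x[0..stop]; x must be increasing."""
    x, y = x[: stop + 1], y[: stop + 1]
    if len(x) < 20:
        raise BiomechError(f"need >= 20 points before the ultimate point, got {len(x)}")
    width = window_fraction * (x[-1] - x[0])
    best = -np.inf
    for i in range(len(x)):
        j = int(np.searchsorted(x, x[i] + width, side="left"))
        if j >= len(x):
            break
        j = max(j, i + 3)
        if j >= len(x):
            j = len(x) - 1
        if j - i < 3:
            continue
        xx, yy = x[i : j + 1], y[i : j + 1]
        xm, ym = xx.mean(), yy.mean()
        denom = float(np.sum((xx - xm) ** 2))
        if denom <= 0:
            continue
        slope = float(np.sum((xx - xm) * (yy - ym)) / denom)
        best = max(best, slope)
    if not np.isfinite(best):
        raise BiomechError("could not place a regression window")
    return best


def detect_failure(values: np.ndarray, drop_fraction: float = 0.10, persistence: int = 3) -> tuple[int, bool]:
    """(failure index, detected flag).

    Failure is the running maximum preceding the first point where the
    signal drops below ``1 - drop_fraction`` of its running maximum and
    stays there for up to ``persistence`` consecutive samples (or to the end
    of the record).  A monotone curve returns its last index with
    ``detected=False``.
    """
    v = np.asarray(values, float)
    if len(v) < 10:
        raise BiomechError("need >= 10 points to detect failure")
    runmax = np.maximum.accumulate(v)
    # noise guard: a 10% relative drop is only meaningful once the signal
    # has risen clearly above the noisy toe region
    significant = runmax >= 0.5 * float(np.max(v))
    below = (v < (1.0 - drop_fraction) * runmax) & significant
    for i in np.flatnonzero(below):
        end = min(i + persistence, len(v))
        if np.all(v[i:end] < (1.0 - drop_fraction) * runmax[i]):
            peak = int(np.argmax(v[: i + 1]))
            return peak, True
    return len(v) - 1, False


def ultimate_point(strain: np.ndarray, stress: np.ndarray) -> tuple[float, float, bool]:
    """(ultimate stress, strain at ultimate, failure detected)."""
    idx, detected = detect_failure(stress)
    k = int(np.argmax(stress[: idx + 1]))
    return float(stress[k]), float(strain[k]), detected


def elastic_modulus(strain: np.ndarray, stress: np.ndarray, window_fraction: float = 0.20) -> float:
    """Slope of the stiffest contiguous window before the ultimate point.

    ``strain`` is in percent; the returned modulus is stress per unit
    *fractional* strain (N/mm^2), the convention of the study's figures.
    """
    idx, _ = detect_failure(stress)
    k = int(np.argmax(stress[: idx + 1]))
    return _max_window_slope(np.asarray(strain, float) / 100.0, np.asarray(stress, float), window_fraction, k)


def toughness(strain: np.ndarray, stress: np.ndarray) -> float:
    """Area under stress vs fractional strain from 0 to the failure point."""
    if len(strain) < 2:
        raise BiomechError("need >= 2 points")
    idx, _ = detect_failure(stress) if len(stress) >= 10 else (len(stress) - 1, False)
    k = int(np.argmax(stress[: idx + 1]))
    return float(np.trapezoid(stress[: k + 1], np.asarray(strain[: k + 1], float) / 100.0))


def bending_stiffness(c: BendingCurve, window_fraction: float = 0.20) -> float:
    """Maximum-slope-window stiffness (N/mm) of the pre-ultimate curve."""
    idx, _ = detect_failure(c.load)
    k = int(np.argmax(c.load[: idx + 1]))
    return _max_window_slope(c.displacement, c.load, window_fraction, k)


def _elastic_intercept(c: BendingCurve, stiffness: float, stop: int) -> float:
    """Zero-load displacement intercept of the elastic line (toe correction)."""
    # anchor the elastic line at the point whose tangent region matches the
    # stiffness best: use the point of maximum load/(d - d0) consistency via
    # least squares over the stiffest window
    d, F = c.displacement[: stop + 1], c.load[: stop + 1]
    width = 0.20 * (d[-1] - d[0])
    best, b0 = -np.inf, 0.0
    for i in range(len(d)):
        j = int(np.searchsorted(d, d[i] + width, side="left"))
        j = min(max(j, i + 3), len(d) - 1)
        if j - i < 3:
            continue
        xx, yy = d[i : j + 1], F[i : j + 1]
        xm, ym = xx.mean(), yy.mean()
        denom = float(np.sum((xx - xm) ** 2))
        if denom <= 0:
            continue
        slope = float(np.sum((xx - xm) * (yy - ym)) / denom)
        if slope > best:
            best, b0 = slope, float(xm - ym / slope) if slope > 0 else 0.0
    return b0


def yield_point(
    c: BendingCurve,
    stiffness: float,
    criterion: str = "secant10",
    offset_fraction: float = 0.002,
) -> tuple[float, float, bool]:
    """(yield load N, yield displacement mm, brittle flag).

    ``secant10``: first point after the elastic region where the secant
    slope from the toe-corrected origin (zero-load intercept of the elastic
    line) falls below 90% of the stiffness.  ``offset``: intersection with
    the elastic line shifted by ``offset_fraction`` of the span (0.2%
    default).  If the curve fails before the criterion fires, yield is the
    ultimate point and the brittle flag is set.
    """
    if stiffness <= 0:
        raise BiomechError("stiffness must be positive")
    idx, _ = detect_failure(c.load)
    k = int(np.argmax(c.load[: idx + 1]))
    d, F = c.displacement, c.load
    d0 = _elastic_intercept(c, stiffness, k)

    if criterion == "secant10":
        eligible = np.flatnonzero((d[: k + 1] > d0) & (F[: k + 1] > 0))
        secant = np.full(k + 1, np.nan)
        secant[eligible] = F[eligible] / (d[eligible] - d0)
        reached = np.flatnonzero(secant >= 0.9 * stiffness)
        if len(reached) == 0:
            return float(F[k]), float(d[k]), True
        start = reached[0]
        after = np.flatnonzero(secant[start:] < 0.9 * stiffness)
        if len(after) == 0:
            return float(F[k]), float(d[k]), True
        i = start + after[0]
        return float(F[i]), float(d[i]), False
    if criterion == "offset":
        offset = offset_fraction * c.span
        line = stiffness * (d[: k + 1] - d0 - offset)
        diff = F[: k + 1] - line
        crossings = np.flatnonzero((diff[:-1] > 0) & (diff[1:] <= 0))
        if len(crossings) == 0:
            return float(F[k]), float(d[k]), True
        i = crossings[0] + 1
        return float(F[i]), float(d[i]), False
    raise BiomechError(f"unknown yield criterion {criterion!r}")


def post_yield_displacement(c: BendingCurve, yield_displacement: float, failure_index: int) -> float:
    """Displacement between yield and fracture; 0 (flagged brittle upstream)
    when failure precedes yield."""
    return max(float(c.displacement[failure_index] - yield_displacement), 0.0)


def work_to_fracture(c: BendingCurve, failure_index: int) -> float:
    """Trapezoidal integral of load over displacement up to failure (N*mm)."""
    return float(np.trapezoid(c.load[: failure_index + 1], c.displacement[: failure_index + 1]))


def analyze_tensile(c: TensileCurve, window_fraction: float = 0.20) -> TensileResult:
    """Complete tensile analysis of one specimen curve."""
    strain, stress = to_stress_strain(c)
    csa = cross_sectional_area(c.mass, c.length, c.density)
    u_stress, u_strain, detected = ultimate_point(strain, stress)
    return TensileResult(
        csa=csa,
        elastic_modulus=elastic_modulus(strain, stress, window_fraction),
        ultimate_stress=u_stress,
        ultimate_strain=u_strain,
        toughness=toughness(strain, stress),
        failure_detected=detected,
    )


def analyze_bending(
    c: BendingCurve, window_fraction: float = 0.20, yield_criterion: str = "secant10"
) -> BendingResult:
    """Complete three-point-bending analysis of one load-displacement curve."""
    stiffness = bending_stiffness(c, window_fraction)
    idx, detected = detect_failure(c.load)
    k = int(np.argmax(c.load[: idx + 1]))
    y_load, y_disp, brittle = yield_point(c, stiffness, yield_criterion)
    ultimate = float(c.load[k])
    return BendingResult(
        ultimate_load=max(ultimate, y_load),
        stiffness=stiffness,
        yield_load=min(y_load, ultimate),
        yield_displacement=y_disp,
        post_yield_displacement=post_yield_displacement(c, y_disp, k),
        work_to_fracture=work_to_fracture(c, k),
        yield_criterion=yield_criterion,
        brittle=brittle,
        failure_detected=detected,
    )
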