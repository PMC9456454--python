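"""Synthetic spectra and mechanical curves with fully known ground truth.

Generators are pure functions of (recipe, seed).  The cohort presets are
calibrated so that the *true* group effects equal the printed study values:

* ``paper-tendon-raman`` — tendon Raman ratio means per the published table
  (pentosidine 2.00 WT vs 2.39 oim, etc.), n = 6 WT / 8 oim, between-
  specimen SDs back-computed from the printed SEMs (sd = sem*sqrt(n)).
* ``paper-bone-ftir`` — bone FTIR percent effects (+13% phosphate/amide I,
  -4.6% crystallinity, +29% acid phosphate, -23% collagen maturity),
  n = 10 per group.
* ``paper-tensile`` — tendon mechanical effects (-60% elastic modulus,
  -39% ultimate stress, +27% ultimate strain), n = 9 WT / 7 oim.
* ``paper-bending`` — femoral bending effects (-64% ultimate load, -58%
  stiffness, -56% yield load, -71% post-yield displacement; the emergent
  work-to-fracture effect lands at the printed -84.4%), n = 10 WT / 8 oim.

Spectral specimens carry a 10% CV global intensity scale (section
thickness/focus; cancels in every ratio) plus small per-parameter
biological scatter; see docs/methods.md for the variability model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import material
from .bandfit import pseudo_voigt, pv_area
from .biomech import BendingCurve, TensileCurve, cross_sectional_area
from .spectra import Spectrum, average_replicates, write_spectrum

#: Replicate acquisitions per specimen; the protocol records several spectra
#: per sample and averages them before any ratio is computed.
N_REPLICATES = 3

__all__ = [
    "SpectrumRecipe",
    "MechRecipe",
    "CohortPreset",
    "Specimen",
    "PRESETS",
    "pmma_reference",
    "synth_spectrum",
    "synth_tensile",
    "synth_bending",
    "synth_cohort",
    "get_preset",
]

_GAUSS_AREA = 0.5 * math.sqrt(math.pi / math.log(2.0))


# ---------------------------------------------------------------------------
# recipes and elementary generators


@dataclass(frozen=True)
class SpectrumRecipe:
    """Generating parameters of one synthetic spectrum.

    ``subpeaks`` are (center, amplitude, fwhm, eta) tuples; ``baseline`` are
    polynomial coefficients (constant first) in the scaled coordinate
    x = (w - mid)/(range/2); ``mult_scale`` is a global multiplicative
    scale and ``mult_quad`` an out-of-model multiplicative quadratic (the
    harder Mie surrogate); ``pmma_scale`` adds that multiple of the pMMA
    reference before distortion; ``noise_sd`` is Gaussian noise as a
    fraction of the clean maximum.
    """

    grid: tuple[float, float, float]
    subpeaks: tuple[tuple[float, float, float, float], ...]
    baseline: tuple[float, ...] = (0.0,)
    mult_scale: float = 1.0
    mult_quad: float = 0.0
    pmma_scale: float = 0.0
    noise_sd: float = 0.0
    modality: str = "raman_fingerprint"
    label: str = ""

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        return np.arange(lo, hi + 0.5 * step, step)

    def clean(self, w: np.ndarray | None = None) -> np.ndarray:
        """Noise-, baseline- and distortion-free sum of subpeaks."""
        if w is None:
            w = self.wavenumbers()
        y = np.zeros_like(w, dtype=float)
        for center, amp, fwhm, eta in self.subpeaks:
            y += pseudo_voigt(w, center, amp, fwhm, eta)
        return y

    def clean_spectrum(self) -> Spectrum:
        w = self.wavenumbers()
        return Spectrum(w, self.clean(w), self.modality, label=self.label + "/clean")


def pmma_reference(grid: tuple[float, float, float] = (800.0, 1800.0, 2.0)) -> Spectrum:
    """Synthetic embedding-resin reference: strong carbonyl band at 1730
    cm^-1 plus a weak 1450 cm^-1 CH band.  A surrogate for a measured pure
    pMMA spectrum; user-replaceable."""
    w = np.arange(grid[0], grid[1] + 0.5 * grid[2], grid[2])
    y = pseudo_voigt(w, 1730.0, 1.0, 30.0, 0.0) + pseudo_voigt(w, 1450.0, 0.35, 25.0, 0.0)
    return Spectrum(w, y, "ftir", label="pmma_reference_synthetic")


def synth_spectrum(
    r: SpectrumRecipe, seed: int | np.random.Generator = 0
) -> tuple[Spectrum, dict]:
    """Generate one spectrum; returns (spectrum, truth record).

    Model: (clean + pmma_scale*pmma) * mult_scale * (1 + mult_quad*x^2)
    + baseline polynomial + white Gaussian noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = r.wavenumbers()
    clean = r.clean(w)
    signal = clean.copy()
    if r.pmma_scale > 0:
        signal = signal + r.pmma_scale * pmma_reference(r.grid).intensities
    x = (w - w.mean()) / ((w[-1] - w[0]) / 2.0)
    mult = r.mult_scale * (1.0 + r.mult_quad * x**2)
    y = signal * mult + np.polyval(list(reversed(r.baseline)), x)
    scale = float(np.max(np.abs(clean))) or 1.0
    if r.noise_sd > 0:
        y = y + rng.normal(0.0, r.noise_sd * scale, size=len(w))
    truth = {
        "recipe": r,
        "subpeak_areas": {c: pv_area(a, f, e) for c, a, f, e in r.subpeaks},
        "subpeak_fwhm": {c: f for c, a, f, e in r.subpeaks},
    }
    return Spectrum(w, y, r.modality, label=r.label), truth


@dataclass(frozen=True)
class MechRecipe:
    """Piecewise elastic-plastic curve: quadratic toe (slope-continuous),
    linear elastic segment, reduced-slope post-yield segment, instant
    fracture at the ultimate point.

    For tensile recipes x is fractional strain and y is stress (N/mm^2);
    for bending x is displacement (mm) and y is load (N).
    """

    kind: str  # "tensile" | "bending"
    elastic_slope: float  # E (N/mm^2 per unit strain) or stiffness (N/mm)
    yield_y: float  # stress/load at the elastic->plastic kink
    ultimate_y: float  # stress/load at fracture
    ultimate_x: float  # strain (fraction) / displacement (mm) at fracture
    toe_x: float = 0.0  # toe-region extent
    step: float = 2e-4
    noise_sd: float = 0.0
    # tensile specimen geometry
    mass: float = 1.0  # mg
    length: float = 5.0  # mm
    density: float = 1.12  # mg/mm^3
    span: float = 6.0  # mm, bending support span
    label: str = ""

    def __post_init__(self):
        y_toe = self.elastic_slope * self.toe_x / 2.0
        if not (self.yield_y > y_toe >= 0):
            raise ValueError("yield must exceed the toe-end value")
        if self.ultimate_y < self.yield_y or self.ultimate_x <= self.yield_x:
            raise ValueError("ultimate must lie beyond yield")
        if self.post_yield_slope >= self.elastic_slope:
            raise ValueError("post-yield slope must be below the elastic slope")

    @property
    def toe_y(self) -> float:
        return self.elastic_slope * self.toe_x / 2.0

    @property
    def yield_x(self) -> float:
        return self.toe_x + (self.yield_y - self.toe_y) / self.elastic_slope

    @property
    def post_yield_slope(self) -> float:
        return (self.ultimate_y - self.yield_y) / (self.ultimate_x - self.yield_x)

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.where(
            x < self.toe_x,
            self.elastic_slope * x**2 / (2.0 * max(self.toe_x, 1e-12)),
            np.where(
                x < self.yield_x,
                self.toe_y + self.elastic_slope * (x - self.toe_x),
                self.yield_y + self.post_yield_slope * (x - self.yield_x),
            ),
        )
        return np.where(x > self.ultimate_x, 0.0, y)

    def area_to_fracture(self) -> float:
        """Closed-form area under the curve from 0 to the ultimate point."""
        toe = self.elastic_slope * self.toe_x**2 / 6.0
        elastic = 0.5 * (self.toe_y + self.yield_y) * (self.yield_x - self.toe_x)
        plastic = 0.5 * (self.yield_y + self.ultimate_y) * (self.ultimate_x - self.yield_x)
        return toe + elastic + plastic

    def truth(self) -> dict:
        t = {
            "elastic_slope": self.elastic_slope,
            "yield_y": self.yield_y,
            "yield_x": self.yield_x,
            "ultimate_y": self.ultimate_y,
            "ultimate_x": self.ultimate_x,
            "post_yield": self.ultimate_x - self.yield_x,
            "area_to_fracture": self.area_to_fracture(),
        }
        if self.kind == "tensile":
            t["csa"] = cross_sectional_area(self.mass, self.length, self.density)
        return t


def _sampled_xy(r: MechRecipe, rng: np.random.Generator, tail: int = 4):
    x = np.arange(0.0, r.ultimate_x, r.step)
    if x[-1] < r.ultimate_x:
        x = np.append(x, r.ultimate_x)  # the curve always reaches its ultimate point
    y = r.evaluate(x)
    # instant fracture: a few near-zero samples past the ultimate point
    x = np.concatenate([x, r.ultimate_x + r.step * np.arange(1, tail + 1)])
    y = np.concatenate([y, np.zeros(tail)])
    if r.noise_sd > 0:
        y = y + rng.normal(0.0, r.noise_sd * r.ultimate_y, size=len(y))
    return x, y


def synth_tensile(r: MechRecipe, seed: int | np.random.Generator = 0) -> tuple[TensileCurve, dict]:
    """Tensile curve in instrument units (displacement mm, force N)."""
    if r.kind != "tensile":
        raise ValueError("recipe kind must be 'tensile'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    strain, stress = _sampled_xy(r, rng)
    csa = cross_sectional_area(r.mass, r.length, r.density)
    curve = TensileCurve(
        displacement=strain * r.length,
        force=stress * csa,
        mass=r.mass,
        length=r.length,
        density=r.density,
        label=r.label,
    )
    return curve, r.truth()


def synth_bending(r: MechRecipe, seed: int | np.random.Generator = 0) -> tuple[BendingCurve, dict]:
    """Three-point-bending load-displacement curve."""
    if r.kind != "bending":
        raise ValueError("recipe kind must be 'bending'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    disp, load = _sampled_xy(r, rng)
    return BendingCurve(displacement=disp, load=load, span=r.span, label=r.label), r.truth()


# ---------------------------------------------------------------------------
# cohort presets


@dataclass
class Specimen:
    id: str
    group: str
    spectra: dict = field(default_factory=dict)  # name -> Spectrum
    curve: object | None = None  # TensileCurve | BendingCurve
    truth: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CohortPreset:
    name: str
    kind: str  # "tendon_raman" | "bone_ftir" | "tensile" | "bending"
    n_per_group: dict
    make_specimen: Callable[[str, str, np.random.Generator], Specimen]
    description: str = ""


def synth_cohort(
    preset: "CohortPreset | str",
    seed: int,
    n_per_group: dict | None = None,
    outdir: str | Path | None = None,
) -> tuple[list[Specimen], pd.DataFrame]:
    """Generate a two-group cohort; returns (specimens, truth table).

    Deterministic per (preset, seed): every specimen draws from its own
    child of one ``SeedSequence``.  With ``outdir`` the per-specimen files
    and a ``truth.csv`` are also written.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    counts = n_per_group or preset.n_per_group
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(sum(counts.values())))
    specimens, rows = [], []
    for group in counts:
        for i in range(counts[group]):
            rng = np.random.default_rng(next(children))
            sp = preset.make_specimen(f"{group}_{i + 1:02d}", group, rng)
            specimens.append(sp)
            rows.append({"specimen": sp.id, "group": sp.group, **sp.truth})
    truth = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sp in specimens:
            for name, spec in sp.spectra.items():
                write_spectrum(spec, outdir / f"{sp.id}_{name}.csv")
            if sp.curve is not None:
                xcol, ycol = (
                    ("displacement_mm", "force_N")
                    if isinstance(sp.curve, TensileCurve)
                    else ("displacement_mm", "load_N")
                )
                x = sp.curve.displacement
                y = sp.curve.force if isinstance(sp.curve, TensileCurve) else sp.curve.load
                pd.DataFrame({xcol: x, ycol: y}).to_csv(outdir / f"{sp.id}.csv", index=False)
        truth.to_csv(outdir / "truth.csv", index=False)
    return specimens, truth


# -- bone FTIR preset -------------------------------------------------------

# WT cortical-bone subpeak areas (a.u.*cm^-1, relative) and FWHMs (cm^-1).
_BONE_PO4_WT = {960.0: (45.0, 20.0), 1030.0: (25.0, 28.0), 1058.0: (10.0, 24.0),
                1076.0: (8.0, 24.0), 1096.0: (7.0, 24.0), 1110.0: (4.0, 24.0),
                1127.0: (5.0, 26.0)}
_BONE_AMIDE_WT = {1610.0: (1.5, 25.0), 1630.0: (3.0, 25.0), 1660.0: (14.0, 26.0),
                  1678.0: (4.5, 25.0), 1690.0: (5.0, 24.0)}
_BONE_OTHER = {871.0: (1.5, 18.0), 1240.0: (2.0, 30.0), 1450.0: (1.5, 25.0),
               1550.0: (10.0, 45.0)}  # carbonate, amide III, CH, amide II

#: Injected bone FTIR group effects, percent (oim vs WT).
BONE_EFFECTS = {
    "phosphate_amide": +13.0,
    "crystallinity": -4.6,
    "acid_phosphate": +29.0,
    "collagen_maturity": -23.0,
}


def _bone_group_params(group: str) -> tuple[dict, dict, float]:
    """(po4 areas, amide areas, fwhm at 960) encoding the group effects.

    Ratio effects are split symmetrically between numerator and denominator
    subpeaks; the phosphate/amide effect is then imposed exactly by a
    closed-form rescale of the whole phosphate band.  Crystallinity is
    encoded in the 960 cm^-1 linewidth (crystallinity = 1/FWHM).
    """
    po4 = {c: list(v) for c, v in _BONE_PO4_WT.items()}
    amide = {c: list(v) for c, v in _BONE_AMIDE_WT.items()}
    fwhm960 = _BONE_PO4_WT[960.0][1]
    if group == "WT":
        return po4, amide, fwhm960
    r = math.sqrt(1.0 + BONE_EFFECTS["acid_phosphate"] / 100.0)
    po4[1127.0][0] *= r
    po4[1096.0][0] /= r
    m = math.sqrt(1.0 + BONE_EFFECTS["collagen_maturity"] / 100.0)
    amide[1660.0][0] *= m
    amide[1690.0][0] /= m
    wt_pa = sum(a for a, _ in _BONE_PO4_WT.values()) / sum(a for a, _ in _BONE_AMIDE_WT.values())
    target_pa = (1.0 + BONE_EFFECTS["phosphate_amide"] / 100.0) * wt_pa
    g = target_pa * sum(a for a, _ in amide.values()) / sum(a for a, _ in po4.values())
    for c in po4:
        po4[c][0] *= g
    fwhm960 = fwhm960 / (1.0 + BONE_EFFECTS["crystallinity"] / 100.0)
    return po4, amide, fwhm960


def _make_bone_specimen(
    sid: str,
    group: str,
    rng: np.random.Generator,
    pmma_scale: float = 0.3,
    mult_quad: float = 0.0,
    noise_sd: float = 0.004,
    variability: float = 1.0,
) -> Specimen:
    po4, amide, fwhm960 = _bone_group_params(group)
    v = variability
    scale = float(np.clip(rng.normal(1.0, 0.10 * v), 0.5, 1.5))  # section thickness/focus
    subpeaks, truth_po4, truth_amide = [], {}, {}
    fwhm960_i = fwhm960 * float(np.clip(rng.normal(1.0, 0.015 * v), 0.9, 1.1))
    for c, (a, f) in {**po4, **amide, **_BONE_OTHER}.items():
        a_i = a * float(np.clip(rng.normal(1.0, 0.02 * v), 0.8, 1.2))
        f_i = fwhm960_i if c == 960.0 else f * float(np.clip(rng.normal(1.0, 0.02 * v), 0.8, 1.2))
        if c in po4:
            truth_po4[c] = a_i
        elif c in amide:
            truth_amide[c] = a_i
        # Gaussian amplitude from area: area = amp * fwhm * (1/2)sqrt(pi/ln2)
        subpeaks.append((c, scale * a_i / (f_i * _GAUSS_AREA), f_i, 0.0))
    recipe = SpectrumRecipe(
        grid=(800.0, 1800.0, 2.0),
        subpeaks=tuple(subpeaks),
        baseline=(0.3 * scale, 0.08 * scale, 0.12 * scale),
        mult_scale=1.0,
        mult_quad=mult_quad,
        pmma_scale=pmma_scale * scale * float(np.clip(rng.normal(1.0, 0.15 * v), 0.0, 2.0)),
        noise_sd=noise_sd,
        modality="ftir",
        label=sid,
    )
    replicates = [synth_spectrum(recipe, rng)[0] for _ in range(N_REPLICATES)]
    spectrum = average_replicates(replicates)
    a_po4, a_amide = sum(truth_po4.values()), sum(truth_amide.values())
    truth = {
        "phosphate_amide": a_po4 / a_amide,
        "crystallinity": 1.0 / fwhm960_i,
        "crystal_size_index": truth_po4[1076.0] / truth_po4[1058.0],
        "acid_phosphate": truth_po4[1127.0] / truth_po4[1096.0],
        "collagen_maturity": truth_amide[1660.0] / truth_amide[1690.0],
        "beta_sheet_fraction": (truth_amide[1610.0] + truth_amide[1630.0]) / a_amide,
    }
    return Specimen(id=sid, group=group, spectra={"ftir": spectrum}, truth=truth)


# -- tendon Raman preset ----------------------------------------------------

# printed tendon ratio means (WT, oim) and SEMs with group sizes (6, 8)
TENDON_TABLE = {
    "enz_crosslink": ((1.36, 0.10), (1.60, 0.17)),
    "pentosidine": ((2.00, 0.10), (2.39, 0.07)),
    "beta_sheet": ((0.07, 0.01), (0.10, 0.01)),
    "hydroxyproline": ((0.91, 0.03), (0.85, 0.14)),
    "gag": ((0.08, 0.02), (0.06, 0.02)),
    "nanoporosity": ((8.85, 0.84), (12.53, 1.57)),
    "bound_water": ((0.040, 0.006), (0.026, 0.005)),
    "nh_stretch": ((0.035, 0.004), (0.022, 0.003)),
    "oh_stretch": ((0.0015, 0.003), (0.011, 0.003)),
}
TENDON_N = {"WT": 6, "oim": 8}

_TENDON_FP_PEAKS = {  # center -> (base amplitude, fwhm); 920 is the reference
    872.0: (0.9, 16.0), 920.0: (1.0, 16.0), 1004.0: (0.35, 10.0), 1033.0: (0.3, 14.0),
    1245.0: (1.2, 28.0), 1296.0: (8.0, 14.0), 1345.0: (2.0, 18.0), 1380.0: (0.2, 16.0),
    1450.0: (2.5, 24.0), 1610.0: (0.2, 22.0), 1640.0: (1.4, 26.0), 1670.0: (1.6, 22.0),
    1690.0: (1.0, 20.0),
}
_TENDON_HW_PEAKS = {
    2880.0: (0.7, 60.0), 2940.0: (1.0, 70.0), 3070.0: (0.10, 80.0),
    3243.0: (0.04, 90.0), 3330.0: (0.035, 100.0), 3457.0: (0.01, 110.0),
}


def _tendon_targets(
    group: str, rng: np.random.Generator | None, variability: float = 1.0
) -> dict:
    """Per-specimen true ratio targets: printed mean + N(0, sem*sqrt(n))."""
    gi = 0 if group == "WT" else 1
    n = TENDON_N[group]
    out = {}
    for name, groups in TENDON_TABLE.items():
        mean, sem = groups[gi]
        sd = sem * math.sqrt(n) * variability
        v = mean if rng is None or sd == 0 else float(rng.normal(mean, sd))
        out[name] = max(v, 0.05 * abs(mean) + 1e-4)
    return out


def _calibrate_fingerprint(targets: dict, n_iter: int = 25) -> SpectrumRecipe:
    """Iteratively adjust peak amplitudes so the *measurement operator*
    (rubber-band baseline + local-max intensity ratios) applied to the clean
    spectrum returns the target ratios exactly; the beta-sheet area fraction
    is imposed analytically."""
    peaks = {c: list(v) for c, v in _TENDON_FP_PEAKS.items()}
    ratio_peaks = {"pentosidine": 1345.0, "hydroxyproline": 872.0,
                   "nanoporosity": 1296.0, "gag": 1380.0}
    amide = (1610.0, 1640.0, 1670.0, 1690.0)
    for _ in range(n_iter):
        recipe = SpectrumRecipe(
            grid=(800.0, 1800.0, 1.0),
            subpeaks=tuple((c, a, f, 0.0) for c, (a, f) in sorted(peaks.items())),
            modality="raman_fingerprint",
        )
        measured = material._fingerprint_ratios(recipe.clean_spectrum())
        for name, center in ratio_peaks.items():
            peaks[center][0] *= targets[name] / measured[name]
        peaks[1670.0][0] *= targets["enz_crosslink"] / measured["enz_crosslink"]
        areas = {c: peaks[c][0] * peaks[c][1] for c in amide}
        frac = areas[1610.0] / sum(areas.values())
        t = targets["beta_sheet"]
        # closed-form update of the 1610 share keeping the rest fixed
        peaks[1610.0][0] *= (t / (1 - t)) / (frac / (1 - frac))
    return SpectrumRecipe(
        grid=(800.0, 1800.0, 1.0),
        subpeaks=tuple((c, a, f, 0.0) for c, (a, f) in sorted(peaks.items())),
        modality="raman_fingerprint",
    )


def _calibrate_highwave(targets: dict, n_iter: int = 20) -> SpectrumRecipe:
    """Same idea for the high-wavenumber window: the operator is peak
    scaling at 2940 cm^-1, rubber-band baseline, local-max ratios."""
    peaks = {c: list(v) for c, v in _TENDON_HW_PEAKS.items()}
    ratio_peaks = {"bound_water": 3243.0, "nh_stretch": 3330.0, "oh_stretch": 3457.0}
    for _ in range(n_iter):
        recipe = SpectrumRecipe(
            grid=(2700.0, 3800.0, 2.0),
            subpeaks=tuple((c, a, f, 0.0) for c, (a, f) in sorted(peaks.items())),
            modality="raman_highwave",
        )
        measured = _measure_highwave(recipe.clean_spectrum())
        for name, center in ratio_peaks.items():
            peaks[center][0] *= targets[name] / measured[name]
    return SpectrumRecipe(
        grid=(2700.0, 3800.0, 2.0),
        subpeaks=tuple((c, a, f, 0.0) for c, (a, f) in sorted(peaks.items())),
        modality="raman_highwave",
    )


def _measure_highwave(s: Spectrum) -> dict:
    from . import preprocess
    from .bandfit import intensity_at

    scaled, _ = preprocess.scale_to_peak(s, 2940.0, 15.0)
    corr = preprocess.baseline_correct(scaled, method="rubberband")
    i2940 = intensity_at(corr, 2940.0, 15.0)
    return {
        "bound_water": intensity_at(corr, 3243.0) / i2940,
        "nh_stretch": intensity_at(corr, 3330.0) / i2940,
        "oh_stretch": intensity_at(corr, 3457.0) / i2940,
    }


def _make_tendon_specimen(
    sid: str,
    group: str,
    rng: np.random.Generator,
    noise_fp: float = 0.003,
    noise_hw: float = 0.0015,
    variability: float = 1.0,
) -> Specimen:
    targets = _tendon_targets(group, rng, variability)
    scale = float(np.clip(rng.normal(1.0, 0.10 * variability), 0.5, 1.5))
    fp = _calibrate_fingerprint(targets)
    hw = _calibrate_highwave(targets)
    fp = replace(fp, mult_scale=scale, baseline=(0.4, 0.15, 0.1), noise_sd=noise_fp, label=sid)
    hw = replace(hw, mult_scale=scale, baseline=(0.1, 0.05), noise_sd=noise_hw, label=sid)
    fps = average_replicates([synth_spectrum(fp, rng)[0] for _ in range(N_REPLICATES)])
    hws = average_replicates([synth_spectrum(hw, rng)[0] for _ in range(N_REPLICATES)])
    return Specimen(
        id=sid, group=group,
        spectra={"fingerprint": fps, "highwave": hws},
        truth=dict(targets),
    )


# -- mechanical presets -----------------------------------------------------

#: Tendon tensile group truths: (modulus N/mm^2, ultimate stress N/mm^2,
#: ultimate strain fraction); effects -60% / -39% / +27% for oim.
TENSILE_GROUPS = {
    "WT": {"modulus": 250.0, "ultimate_stress": 20.0, "ultimate_strain": 0.12,
           "mass": (1.45, 0.08), "length": (5.5, 0.5)},
    "oim": {"modulus": 100.0, "ultimate_stress": 12.2, "ultimate_strain": 0.1524,
            "mass": (0.54, 0.04), "length": (4.6, 0.2)},
}
TENSILE_N = {"WT": 9, "oim": 7}

#: Femoral bending group truths: stiffness N/mm, yield/ultimate load N,
#: post-yield displacement mm; effects -58/-56/-64/-71% for oim.
BENDING_GROUPS = {
    "WT": {"stiffness": 60.0, "yield_load": 7.0, "ultimate_load": 10.0, "pyd": 0.35},
    "oim": {"stiffness": 25.2, "yield_load": 3.08, "ultimate_load": 3.6, "pyd": 0.1015},
}
BENDING_N = {"WT": 10, "oim": 8}


def _make_tensile_specimen(
    sid: str,
    group: str,
    rng: np.random.Generator,
    cv: float = 0.03,
    noise_sd: float = 0.003,
    variability: float = 1.0,
) -> Specimen:
    g = TENSILE_GROUPS[group]
    cv = cv * variability
    E = g["modulus"] * float(np.clip(rng.normal(1.0, cv), 0.8, 1.2)) if cv else g["modulus"]
    su = (g["ultimate_stress"] * float(np.clip(rng.normal(1.0, cv), 0.8, 1.2))
          if cv else g["ultimate_stress"])
    eu = (g["ultimate_strain"] * float(np.clip(rng.normal(1.0, 0.04 * variability), 0.8, 1.2))
          if variability else g["ultimate_strain"])
    n = TENSILE_N[group]
    mass = max(float(rng.normal(g["mass"][0], g["mass"][1] * math.sqrt(n) * variability)),
               0.2 * g["mass"][0])
    length = max(float(rng.normal(g["length"][0], g["length"][1] * math.sqrt(n) * variability)),
                 0.5 * g["length"][0])
    sy = 0.75 * su
    recipe = MechRecipe(
        kind="tensile", elastic_slope=E, yield_y=sy, ultimate_y=su, ultimate_x=eu,
        toe_x=0.02, step=2e-4, noise_sd=noise_sd,
        mass=mass, length=length, label=sid,
    )
    curve, truth = synth_tensile(recipe, rng)
    return Specimen(
        id=sid, group=group, curve=curve,
        truth={"elastic_modulus": E, "ultimate_stress": su, "ultimate_strain_pct": 100 * eu,
               "toughness": truth["area_to_fracture"], "csa": truth["csa"],
               "mass_mg": mass, "length_mm": length},
    )


def _make_bending_specimen(
    sid: str,
    group: str,
    rng: np.random.Generator,
    cv: float = 0.03,
    noise_sd: float = 0.003,
    variability: float = 1.0,
) -> Specimen:
    g = BENDING_GROUPS[group]
    cv = cv * variability

    def draw(mean, sd):
        return mean * float(np.clip(rng.normal(1.0, sd), 0.8, 1.2)) if sd else mean

    k = draw(g["stiffness"], cv)
    fy = draw(g["yield_load"], cv)
    fu = max(draw(g["ultimate_load"], cv), 1.05 * fy)
    pyd = draw(g["pyd"], 0.04 * variability)
    toe = 0.05
    dy = toe + (fy - k * toe / 2.0) / k
    recipe = MechRecipe(
        kind="bending", elastic_slope=k, yield_y=fy, ultimate_y=fu, ultimate_x=dy + pyd,
        toe_x=toe, step=5e-4, noise_sd=noise_sd, label=sid,
    )
    curve, truth = synth_bending(recipe, rng)
    return Specimen(
        id=sid, group=group, curve=curve,
        truth={"stiffness": k, "yield_load": fy, "ultimate_load": fu,
               "post_yield_displacement": pyd, "work_to_fracture": truth["area_to_fracture"]},
    )


PRESETS = {
    "paper-tendon-raman": CohortPreset(
        name="paper-tendon-raman", kind="tendon_raman", n_per_group=dict(TENDON_N),
        make_specimen=_make_tendon_specimen,
        description="Tendon Raman cohort; true ratio means per the printed table.",
    ),
    "paper-bone-ftir": CohortPreset(
        name="paper-bone-ftir", kind="bone_ftir", n_per_group={"WT": 10, "oim": 10},
        make_specimen=_make_bone_specimen,
        description="Bone FTIR cohort; injected effects +13/-4.6/+29/-23 percent.",
    ),
    "paper-bone-ftir-hard": CohortPreset(
        name="paper-bone-ftir-hard", kind="bone_ftir", n_per_group={"WT": 10, "oim": 10},
        make_specimen=lambda sid, group, rng: _make_bone_specimen(sid, group, rng, mult_quad=0.15),
        description="Same cohort with an out-of-model multiplicative quadratic "
                    "distortion; exercises the EMSC corrector beyond its model "
                    "class (no recovery guarantee).",
    ),
    "paper-tensile": CohortPreset(
        name="paper-tensile", kind="tensile", n_per_group=dict(TENSILE_N),
        make_specimen=_make_tensile_specimen,
        description="Tendon tensile cohort; effects -60% modulus, -39% ultimate stress.",
    ),
    "paper-bending": CohortPreset(
        name="paper-bending", kind="bending", n_per_group=dict(BENDING_N),
        make_specimen=_make_bending_specimen,
        description="Femoral bending cohort; effects -64/-58/-56/-71 percent.",
    ),
}


def get_preset(name: str) -> CohortPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
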