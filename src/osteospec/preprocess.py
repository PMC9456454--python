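"""Spectral conditioning: smoothing, baseline removal, EMSC-style Mie
correction, pMMA quantification/subtraction, and the two study
normalizations (vector normalization over the phosphate band for FTIR,
peak scaling at the ~2940 cm^-1 CH stretch for high-wavenumber Raman).

Every step returns a new :class:`~osteospec.spectra.Spectrum` and appends an
entry to a :class:`PreprocessReport` when one is passed, so a pipeline run
is fully auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra import Band, Spectrum, resample

__all__ = [
    "PreprocessReport",
    "smooth",
    "baseline_correct",
    "mie_correct",
    "subtract_pmma",
    "vector_normalize",
    "scale_to_peak",
    "PMMA_WINDOW",
]

#: Carbonyl window (cm^-1) over which the embedding-resin contribution is
#: quantified and removed.
PMMA_WINDOW = (1700.0, 1760.0)


class PreprocessError(ValueError):
    pass


class CorrectionFailedError(PreprocessError):
    """EMSC fit degenerate (non-positive scale or ill-conditioned design)."""


@dataclass
class PreprocessReport:
    steps: list = field(default_factory=list)
    pmma_contribution: float = 0.0
    normalization_constant: float = 1.0
    warnings: list = field(default_factory=list)

    def record(self, step: str, **params) -> None:
        self.steps.append({"step": step, **params})


def _log(report: PreprocessReport | None, step: str, **params) -> None:
    if report is not None:
        report.record(step, **params)


def smooth(
    s: Spectrum, window: int = 9, polyorder: int = 3, report: PreprocessReport | None = None
) -> Spectrum:
    """Savitzky-Golay polynomial smoothing; grid unchanged.

    ``window`` must be odd, between 5 and half the spectrum length, and
    strictly larger than ``polyorder``.
    """
    n = len(s)
    if window % 2 == 0 or window < 5 or window > n // 2:
        raise PreprocessError(f"window must be odd and in [5, {n // 2}], got {window}")
    if polyorder >= window:
        raise PreprocessError("polyorder must be < window")
    y = savgol_filter(s.intensities, window, polyorder)
    _log(report, "smooth", window=window, polyorder=polyorder)
    return s.with_intensities(y)


def _rubberband_baseline(w: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Lower convex hull baseline (Andrew monotone chain on the lower hull)."""
    pts = np.column_stack([w, y])
    hull: list[int] = []
    for i in range(len(pts)):
        while len(hull) >= 2:
            o, a = pts[hull[-2]], pts[hull[-1]]
            # keep only right turns -> lower hull
            if (a[0] - o[0]) * (pts[i][1] - o[1]) - (a[1] - o[1]) * (pts[i][0] - o[0]) <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(w, w[hull], y[hull])


def baseline_correct(
    s: Spectrum,
    method: str = "rubberband",
    degree: int = 2,
    report: PreprocessReport | None = None,
) -> Spectrum:
    """Estimate and subtract a slowly varying baseline.

    ``poly`` fits a polynomial (degree <= 5) by iterative reweighting that
    down-weights points above the current fit (so peaks do not pull the
    baseline up); ``rubberband`` uses the lower convex hull.  If the
    corrected minimum dips below -5% of the corrected maximum the clamp is
    *reported*, never silently applied.
    """
    w, y = s.wavenumbers, s.intensities
    if method == "rubberband":
        base = _rubberband_baseline(w, y)
    elif method == "poly":
        if degree > 5:
            raise PreprocessError("poly baseline degree must be <= 5")
        x = (w - w.mean()) / (w.max() - w.min())
        mask = np.ones(len(w), bool)
        coef = np.polyfit(x, y, degree)
        for _ in range(8):
            base = np.polyval(coef, x)
            mask = y <= base + 1e-12 + 0.02 * (y.max() - y.min())
            if mask.sum() <= degree + 1:
                break
            coef = np.polyfit(x[mask], y[mask], degree)
        base = np.polyval(coef, x)
    else:
        raise PreprocessError(f"unknown baseline method {method!r}")
    out = y - base
    peak = float(np.max(out)) if np.max(out) > 0 else 1.0
    if float(np.min(out)) < -0.05 * peak and report is not None:
        report.warnings.append(
            f"baseline_correct: corrected minimum {np.min(out):.3g} below -5% of max {peak:.3g}"
        )
    _log(report, "baseline_correct", method=method, degree=degree)
    return s.with_intensities(out)


def mie_correct(
    s: Spectrum,
    reference: Spectrum,
    cond_threshold: float = 1e10,
    report: PreprocessReport | None = None,
) -> Spectrum:
    """Extended multiplicative signal correction against a reference.

    Models ``s ~ a + b*reference + c1*x + c2*x^2`` (x = scaled wavenumber)
    by least squares and returns ``(s - a - c1*x - c2*x^2) / b``.  Removes
    the additive/multiplicative distortion family that Mie-type scattering
    imposes on transflection FTIR spectra of embedded sections.
    """
    if s.modality != "ftir":
        raise PreprocessError("mie_correct expects an FTIR spectrum")
    ref = reference
    if len(ref) != len(s) or not np.allclose(ref.wavenumbers, s.wavenumbers):
        ref = resample(reference, s.wavenumbers)
    w = s.wavenumbers
    x = (w - w.mean()) / ((w.max() - w.min()) / 2.0)
    design = np.column_stack([np.ones_like(x), x, x**2, ref.intensities])
    cond = np.linalg.cond(design)
    if cond > cond_threshold:
        raise CorrectionFailedError(f"EMSC design matrix ill-conditioned (cond={cond:.3g})")
    coef, *_ = np.linalg.lstsq(design, s.intensities, rcond=None)
    a, c1, c2, b = coef
    if b <= 0:
        raise CorrectionFailedError(f"EMSC multiplicative scale non-positive (b={b:.3g})")
    corrected = (s.intensities - a - c1 * x - c2 * x**2) / b
    _log(report, "mie_correct", a=float(a), b=float(b), c1=float(c1), c2=float(c2))
    return s.with_intensities(corrected, emsc_scale=float(b))


def subtract_pmma(
    s: Spectrum,
    pmma_ref: Spectrum,
    window: tuple[float, float] = PMMA_WINDOW,
    report: PreprocessReport | None = None,
) -> tuple[Spectrum, float]:
    """Quantify and remove the embedding-resin (pMMA) carbonyl contribution.

    The scale of ``pmma_ref`` is fitted by least squares over the
    1700-1760 cm^-1 carbonyl window, then reduced if needed so the window
    residual stays non-negative (within a small noise allowance estimated
    from the local high-frequency content) — over-subtraction is thereby
    prevented.  Returns the corrected spectrum and the subtracted area
    (a.u.·cm^-1), the numerator of the resin-porosity ratio.  A negative
    optimal scale means no detectable resin: the spectrum is returned
    unchanged with contribution 0 and a warning flag.
    """
    if s.modality != "ftir":
        raise PreprocessError("subtract_pmma expects an FTIR spectrum")
    ref = pmma_ref
    if len(ref) != len(s) or not np.allclose(ref.wavenumbers, s.wavenumbers):
        ref = resample(pmma_ref, s.wavenumbers)
    w = s.wavenumbers
    sel = (w >= window[0]) & (w <= window[1])
    if sel.sum() < 4:
        raise PreprocessError("pMMA window has too few points")
    r, y = ref.intensities[sel], s.intensities[sel]
    denom = float(np.dot(r, r))
    if denom <= 0:
        raise PreprocessError("pMMA reference is zero over the carbonyl window")
    scale = float(np.dot(r, y) / denom)
    if scale <= 0:
        if report is not None:
            report.warnings.append("subtract_pmma: negative optimal scale, nothing subtracted")
        _log(report, "subtract_pmma", scale=0.0)
        return s, 0.0
    # noise allowance: robust SD of the second difference in the window
    resid_noise = float(np.std(np.diff(y, 2))) / np.sqrt(6.0) if len(y) > 4 else 0.0
    sig = r > 0.05 * r.max()
    if np.any(sig):
        nonneg = np.min((y[sig] + 3.0 * resid_noise) / r[sig])
        scale = min(scale, max(0.0, float(nonneg)))
    corrected = s.intensities - scale * ref.intensities
    dw = np.gradient(w)
    contribution = float(np.trapezoid(scale * ref.intensities[sel], w[sel]))
    _log(report, "subtract_pmma", scale=scale, contribution=contribution)
    if report is not None:
        report.pmma_contribution = contribution
    return s.with_intensities(corrected, pmma_scale=scale), contribution


def vector_normalize(
    s: Spectrum, b: Band, report: PreprocessReport | None = None
) -> tuple[Spectrum, float]:
    """Divide by the Euclidean norm of the intensities inside band ``b``.

    After the call the within-band norm equals 1; the constant is returned
    (and logged) so absolute quantities can be recovered.
    """
    sl = s.band_slice(b)
    norm = float(np.linalg.norm(s.intensities[sl]))
    if norm == 0:
        raise PreprocessError(f"zero norm over band {b.name!r}")
    _log(report, "vector_normalize", band=b.name, constant=norm)
    if report is not None:
        report.normalization_constant = norm
    return s.with_intensities(s.intensities / norm), norm


def scale_to_peak(
    s: Spectrum,
    center: float = 2940.0,
    search_halfwidth: float = 15.0,
    report: PreprocessReport | None = None,
) -> tuple[Spectrum, float]:
    """Rescale so the local maximum near ``center`` equals 1.0.

    This is the study's high-wavenumber normalization at the collagen CH
    stretch (~2940 cm^-1); the window search tolerates small peak shifts.
    """
    if s.modality != "raman_highwave":
        raise PreprocessError("scale_to_peak expects a high-wavenumber Raman spectrum")
    w = s.wavenumbers
    sel = (w >= center - search_halfwidth) & (w <= center + search_halfwidth)
    if not np.any(sel):
        raise PreprocessError("peak search window outside the grid")
    idx = np.flatnonzero(sel)
    local = s.intensities[idx]
    k = int(np.argmax(local))
    # require an interior maximum or a positive peak value
    peak = float(local[k])
    if peak <= 0:
        raise PreprocessError("no positive local maximum in the scaling window")
    _log(report, "scale_to_peak", center=center, constant=peak)
    if report is not None:
        report.normalization_constant = peak
    return s.with_intensities(s.intensities / peak), peak
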