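"""Tendon Raman and bone FTIR material-property parameters.

Tendon (Raman): intensity ratios of collagen-quality markers against the
proline/hydroxyproline reference peaks, a fitted beta-sheet area fraction of
amide I, and three high-wavenumber water/NH/OH ratios against the ~2940
cm^-1 CH stretch.

Bone (FTIR): the fixed pipeline Mie(EMSC) correction -> pMMA quantification
and subtraction -> vector normalization over the v1,v3 phosphate band ->
second-derivative-seeded band fitting of the phosphate and amide I
envelopes, from which mineral and organic-matrix ratios are computed.

All parameters are dimensionless ratios and therefore invariant to a global
intensity rescaling of the input spectrum.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import bandfit, preprocess
from .bandfit import FitResult, band_area, fit_band, intensity_at, peak_fwhm, second_derivative_minima
from .preprocess import PreprocessReport
from .spectra import Band, Spectrum

__all__ = [
    "TendonRamanParams",
    "BoneFTIRParams",
    "tendon_raman_params",
    "bone_ftir_params",
    "secondary_structure",
    "PHOSPHATE_BAND",
    "AMIDE_I_BAND",
    "PO4_TEMPLATE",
    "AMIDE_I_TEMPLATE",
    "TENDON_AMIDE_TEMPLATE",
]

# Integration bands (cm^-1); standard bone-FTIR practice.
PHOSPHATE_BAND = Band("v1v3_PO4", 900.0, 1200.0)
AMIDE_I_BAND = Band("amide_I", 1600.0, 1720.0)
CARBONATE_BAND = Band("v2_CO3", 850.0, 900.0)

# Template subpeak centers used when second-derivative seeding is ambiguous.
PO4_TEMPLATE = (960.0, 1030.0, 1058.0, 1076.0, 1096.0, 1110.0, 1127.0)
AMIDE_I_TEMPLATE = (1610.0, 1630.0, 1660.0, 1678.0, 1690.0)
TENDON_AMIDE_TEMPLATE = (1610.0, 1640.0, 1670.0, 1690.0)

# Fit windows are wider than the integration bands and include the flanking
# bands (v2 carbonate, amide III, amide II) as explicit subpeaks: modelling
# the neighbours stops their tails from wobbling the fitted baseline, which
# otherwise dominates the error of the area partition.  Width inits are the
# template linewidths of the deconvolution protocol.
PO4_FIT_BAND = Band("v1v3_PO4_fit", 830.0, 1270.0)
PO4_FIT_SEEDS = (871.0, *PO4_TEMPLATE, 1240.0)
PO4_FIT_FWHM = (18.0, 20.0, 28.0, 24.0, 24.0, 24.0, 24.0, 26.0, 30.0)
AMIDE_FIT_BAND = Band("amide_I_fit", 1500.0, 1730.0)
AMIDE_FIT_SEEDS = (1550.0, *AMIDE_I_TEMPLATE)
AMIDE_FIT_FWHM = (45.0, 25.0, 25.0, 26.0, 25.0, 24.0)

#: Amide-I subband -> collagen secondary-structure label (center windows).
SECONDARY_STRUCTURE_MAP = (
    ((1605.0, 1635.0), "beta_sheet"),
    ((1635.0, 1655.0), "random_coil"),
    ((1655.0, 1665.0), "helix"),
    ((1665.0, 1685.0), "turns"),
    ((1685.0, 1720.0), "other"),
)


class MissingCoverageError(ValueError):
    """The spectrum does not cover a wavenumber region a parameter needs."""


def refine_seeds(
    s: Spectrum, band: Band, template: tuple[float, ...], match_distance: float = 5.0
) -> list[float]:
    """Seed centers for a band fit.

    The second-derivative minima are used as seeds only when they resolve
    the full expected subpeak set — one candidate within ``match_distance``
    cm^-1 of each template center, no extras unaccounted for.  Heavily
    overlapped envelopes rarely resolve completely, in which case the
    template centers stand (the documented fallback); mixing partially
    resolved candidates with template positions destabilizes the
    ill-conditioned area partition and is deliberately avoided.
    """
    try:
        candidates = second_derivative_minima(s, band)
    except bandfit.BandFitError:
        candidates = []
    if len(candidates) == len(template):
        matched = []
        remaining = list(candidates)
        for c in template:
            near = min(remaining, key=lambda x: abs(x - c), default=None)
            if near is None or abs(near - c) > match_distance:
                return list(template)
            matched.append(near)
            remaining.remove(near)
        return matched
    return list(template)


@dataclass(frozen=True)
class TendonRamanParams:
    enz_crosslink: float  # I1670/I1690, mature/immature enzymatic crosslinks
    pentosidine: float  # I1345/I920, advanced glycation end-products
    hydroxyproline: float  # I872/I920
    nanoporosity: float  # I1296/I920, unbound-water porosity
    gag: float  # I1380/I920, glycosaminoglycan content
    beta_sheet: float  # A1610/A(amide I), fitted
    bound_water: float  # I3243/I2940
    nh_stretch: float  # I3330/I2940
    oh_stretch: float  # I3457/I2940

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BoneFTIRParams:
    phosphate_amide: float  # A(v1,v3 PO4)/A(amide I), degree of mineralization
    crystallinity: float  # 1/FWHM(960 cm^-1) in cm
    crystal_size_index: float  # A1076/A1058
    acid_phosphate: float  # A1127/A1096, immature HPO4 mineral
    carbonate_phosphate: float  # I(v2 CO3)/I(960), intensity mode
    carbonate_phosphate_area: float  # area-mode alternative
    collagen_maturity: float  # A1660/A1690
    nanoporosity_pmma: float  # A(pMMA 1730)/A(v1,v3 PO4)
    secondary_structure: dict = field(default_factory=dict)
    converged: bool = True

    def as_dict(self) -> dict:
        d = asdict(self)
        ss = d.pop("secondary_structure")
        d.pop("converged")
        for k, v in ss.items():
            d[f"ss_{k}"] = v
        return d


def _fingerprint_ratios(fp: Spectrum) -> dict:
    """Intensity ratios on a baseline-corrected fingerprint spectrum."""
    corrected = preprocess.baseline_correct(fp, method="rubberband")
    i920 = intensity_at(corrected, 920.0)
    if i920 <= 0:
        raise MissingCoverageError("no positive 920 cm^-1 reference intensity")
    return {
        "pentosidine": intensity_at(corrected, 1345.0) / i920,
        "hydroxyproline": intensity_at(corrected, 872.0) / i920,
        "nanoporosity": intensity_at(corrected, 1296.0) / i920,
        "gag": intensity_at(corrected, 1380.0) / i920,
        "enz_crosslink": intensity_at(corrected, 1670.0) / intensity_at(corrected, 1690.0),
        "_corrected": corrected,
    }


def tendon_raman_params(
    fingerprint: Spectrum,
    highwave: Spectrum,
    amide_seeds: tuple[float, ...] = TENDON_AMIDE_TEMPLATE,
    amide_band: Band = Band("amide_I", 1580.0, 1720.0),
) -> TendonRamanParams:
    """All nine tendon Raman ratios from one specimen's averaged spectra.

    ``fingerprint`` must cover 850-1750 cm^-1 and ``highwave`` 2800-3600
    cm^-1 (the latter is peak-scaled to the 2940 CH stretch internally, an
    idempotent operation).  The beta-sheet fraction comes from a fitted
    amide I band; its numerator is the ~1610 cm^-1 subpeak area.
    """
    w = fingerprint.wavenumbers
    if w[0] > 850.0 or w[-1] < 1750.0:
        raise MissingCoverageError("fingerprint spectrum must cover 850-1750 cm^-1")
    hw = highwave.wavenumbers
    if hw[0] > 2800.0 or hw[-1] < 3600.0:
        raise MissingCoverageError("high-wavenumber spectrum must cover 2800-3600 cm^-1")

    ratios = _fingerprint_ratios(fingerprint)
    corrected = ratios.pop("_corrected")

    seeds = refine_seeds(corrected, amide_band, amide_seeds)
    amide_fit = fit_band(corrected, amide_band, seeds=seeds, fwhm_init=20.0)
    total = band_area(amide_fit)
    try:
        beta = amide_fit.nearest(1610.0).area / total if total > 0 else float("nan")
    except bandfit.BandFitError:
        beta = 0.0

    scaled, _ = preprocess.scale_to_peak(highwave, 2940.0, 15.0)
    hw_corr = preprocess.baseline_correct(scaled, method="rubberband")
    i2940 = intensity_at(hw_corr, 2940.0, 15.0)
    return TendonRamanParams(
        enz_crosslink=ratios["enz_crosslink"],
        pentosidine=ratios["pentosidine"],
        hydroxyproline=ratios["hydroxyproline"],
        nanoporosity=ratios["nanoporosity"],
        gag=ratios["gag"],
        beta_sheet=float(beta),
        bound_water=intensity_at(hw_corr, 3243.0) / i2940,
        nh_stretch=intensity_at(hw_corr, 3330.0) / i2940,
        oh_stretch=intensity_at(hw_corr, 3457.0) / i2940,
    )


def secondary_structure(
    amide_fit: FitResult,
    assignment=SECONDARY_STRUCTURE_MAP,
) -> dict:
    """Area fraction of each collagen secondary-structure subband.

    Each fitted amide-I subpeak area is divided by the total area of the
    assigned subpeaks (components outside the assignment windows, e.g. an
    amide II nuisance peak in a wide fit window, are excluded); fractions
    sum to 1.
    """

    def label_of(p):
        for (lo, hi), label in assignment:
            if lo <= p.center < hi:
                return label
        return None

    assigned = [(p, label_of(p)) for p in amide_fit.subpeaks]
    assigned = [(p, lab) for p, lab in assigned if lab is not None]
    total = sum(p.area for p, _ in assigned)
    if total <= 0:
        raise bandfit.BandFitError("amide I fit has zero total area")
    fractions = {label: 0.0 for _, label in assignment}
    for p, lab in assigned:
        fractions[lab] += p.area / total
    return fractions


def bone_ftir_params(
    raw: Spectrum,
    pmma_ref: Spectrum,
    emsc_reference: Spectrum | None = None,
    report: PreprocessReport | None = None,
    return_fits: bool = False,
):
    """Full bone FTIR pipeline on one spectrum.

    Steps, in fixed order: EMSC Mie correction (against ``emsc_reference``,
    or the spectrum itself — an exact identity — when none is supplied),
    pMMA quantification + subtraction, vector normalization over the v1,v3
    phosphate band, then constrained fits of the phosphate and amide I
    envelopes seeded by second-derivative minima with template fallback.
    """
    if raw.modality != "ftir":
        raise preprocess.PreprocessError("bone_ftir_params expects an FTIR spectrum")
    if raw.wavenumbers[0] > 850.0 or raw.wavenumbers[-1] < 1760.0:
        raise MissingCoverageError("FTIR spectrum must cover 850-1760 cm^-1")
    if report is None:
        report = PreprocessReport()

    # EMSC relative to the supplied reference (the spectrum itself — an
    # exact identity — when none is given), then explicit background
    # removal: EMSC only removes background *relative to the reference*.
    s = preprocess.mie_correct(raw, emsc_reference if emsc_reference is not None else raw, report=report)
    s = preprocess.baseline_correct(s, method="rubberband", report=report)
    s, pmma_area = preprocess.subtract_pmma(s, pmma_ref, report=report)
    # denominator of the resin-porosity ratio: raw-mode phosphate area on the
    # same (pre-normalization) intensity scale as the subtracted resin area
    po4_raw_area = band_area(s, PHOSPHATE_BAND, mode="raw")
    s, _ = preprocess.vector_normalize(s, PHOSPHATE_BAND, report=report)

    def fit_with_template(band: Band, template, fwhm_init) -> FitResult:
        seeds = refine_seeds(s, band, template)
        # tight center constraints plus soft width penalties: the subpeak
        # partition of these heavily overlapped envelopes is ill-conditioned,
        # and the regularization is what makes it comparable across specimens
        return fit_band(
            s, band, seeds=seeds, center_tolerance=3.0,
            fwhm_init=list(fwhm_init), fwhm_bounds=(10.0, 55.0),
            center_penalty=0.2, fwhm_penalty=0.4,
        )

    po4_fit = fit_with_template(PO4_FIT_BAND, PO4_FIT_SEEDS, PO4_FIT_FWHM)
    amide_fit = fit_with_template(AMIDE_FIT_BAND, AMIDE_FIT_SEEDS, AMIDE_FIT_FWHM)

    corrected = preprocess.baseline_correct(s, method="rubberband")
    i_carb = intensity_at(corrected, 875.0, 25.0)
    i_po4 = intensity_at(corrected, 960.0, 10.0)
    # integration restricted to the named bands: the flanking subpeaks in
    # the fit windows are nuisance components, not part of either envelope
    po4_area = band_area(po4_fit, PHOSPHATE_BAND)
    amide_area = band_area(amide_fit, AMIDE_I_BAND)

    params = BoneFTIRParams(
        phosphate_amide=po4_area / amide_area,
        crystallinity=1.0 / peak_fwhm(po4_fit, 960.0),
        crystal_size_index=po4_fit.nearest(1076.0).area / po4_fit.nearest(1058.0).area,
        acid_phosphate=po4_fit.nearest(1127.0).area / po4_fit.nearest(1096.0).area,
        carbonate_phosphate=i_carb / i_po4,
        carbonate_phosphate_area=band_area(corrected, CARBONATE_BAND, mode="raw") / po4_area,
        collagen_maturity=amide_fit.nearest(1660.0).area / amide_fit.nearest(1690.0).area,
        nanoporosity_pmma=(pmma_area / po4_raw_area) if po4_raw_area > 0 else 0.0,
        secondary_structure=secondary_structure(amide_fit),
        converged=po4_fit.converged and amide_fit.converged,
    )
    if return_fits:
        return params, {"po4": po4_fit, "amide": amide_fit, "report": report}
    return params
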