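"""Spectrum container, file I/O and grid manipulation.

A :class:`Spectrum` is a strictly increasing wavenumber grid (cm^-1) with
intensities in arbitrary units plus a modality tag.  The three modalities
mirror the acquisitions of the study: Raman fingerprint (800-1800 cm^-1),
Raman high-wavenumber (2700-3800 cm^-1) and FTIR (~800-1800 cm^-1).
Replicate spectra of one specimen are averaged on a common grid before any
ratio is computed; the averaging is recorded in the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "Band",
    "MODALITY_BOUNDS",
    "read_spectrum",
    "write_spectrum",
    "crop",
    "resample",
    "average_replicates",
    "infer_modality",
]

#: Tolerant grid bounds per modality (cm^-1), slightly wider than the
#: acquisition ranges so edge channels survive cropping.
MODALITY_BOUNDS = {
    "raman_fingerprint": (700.0, 1900.0),
    "raman_highwave": (2600.0, 3900.0),
    "ftir": (700.0, 1900.0),
}

MIN_POINTS = 16


class SpectrumError(ValueError):
    """Malformed spectrum input (parse failure, bad grid, wrong modality)."""


class Band(NamedTuple):
    """A named wavenumber interval [low, high] in cm^-1."""

    name: str
    low: float
    high: float

    def __post_init__(self):  # pragma: no cover - NamedTuple hook unused
        pass

    def validate(self) -> "Band":
        if not self.low < self.high:
            raise SpectrumError(f"band {self.name!r}: low {self.low} must be < high {self.high}")
        return self


@dataclass(frozen=True)
class Spectrum:
    wavenumbers: np.ndarray
    intensities: np.ndarray
    modality: str
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)
        if w.ndim != 1 or y.ndim != 1 or len(w) != len(y):
            raise SpectrumError("wavenumbers and intensities must be 1-D of equal length")
        if len(w) < MIN_POINTS:
            raise SpectrumError(f"spectrum too short: {len(w)} points (< {MIN_POINTS})")
        if not np.all(np.diff(w) > 0):
            raise SpectrumError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(y)):
            raise SpectrumError("intensities must be finite")
        if self.modality not in MODALITY_BOUNDS:
            raise SpectrumError(f"unknown modality {self.modality!r}")
        lo, hi = MODALITY_BOUNDS[self.modality]
        if w[0] < lo or w[-1] > hi:
            raise SpectrumError(
                f"grid [{w[0]:.1f}, {w[-1]:.1f}] outside {self.modality} bounds [{lo}, {hi}]"
            )

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def with_intensities(self, y: np.ndarray, **meta) -> "Spectrum":
        """Copy with new intensities; extra kwargs are merged into meta."""
        return replace(self, intensities=np.asarray(y, dtype=float), meta={**self.meta, **meta})

    def band_slice(self, b: Band) -> slice:
        i0 = int(np.searchsorted(self.wavenumbers, b.low, side="left"))
        i1 = int(np.searchsorted(self.wavenumbers, b.high, side="right"))
        return slice(i0, i1)


def infer_modality(w: np.ndarray) -> str:
    """Guess modality from the grid range (high-wavenumber vs fingerprint/FTIR)."""
    if w[0] >= 2600.0:
        return "raman_highwave"
    return "raman_fingerprint"


def read_spectrum(
    path: str | Path,
    format: str | None = None,
    modality: str | None = None,
    label: str | None = None,
) -> Spectrum:
    """Read a two-column (wavenumber, intensity) CSV/TSV file.

    An optional single header line is tolerated.  Rows are sorted by
    ascending wavenumber and duplicate wavenumbers are collapsed by the mean
    (instrument rescans).  Modality is inferred from the grid range unless
    given.  A ``<path>.json`` sidecar written by :func:`write_spectrum` is
    picked up as metadata when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    delim = "\t" if format == "tsv" else ","

    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    start = 0
    if lines:
        first = lines[0].split(delim)
        try:
            [float(v) for v in first[:2]]
        except ValueError:
            start = 1  # header line
    for lineno, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split(delim)]
        if len(parts) < 2:
            raise SpectrumError(f"{path.name}: line {lineno}: expected 2 columns, got {len(parts)}")
        try:
            rows.append((float(parts[0]), float(parts[1])))
        except ValueError as exc:
            raise SpectrumError(f"{path.name}: line {lineno}: malformed numeric row") from exc
    if len(rows) < MIN_POINTS:
        raise SpectrumError(f"{path.name}: only {len(rows)} points (< {MIN_POINTS})")

    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    # mean-collapse duplicate wavenumbers
    w, inv = np.unique(arr[:, 0], return_inverse=True)
    y = np.bincount(inv, weights=arr[:, 1]) / np.bincount(inv)

    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return Spectrum(
        wavenumbers=w,
        intensities=y,
        modality=modality or meta.get("modality") or infer_modality(w),
        label=label if label is not None else path.stem,
        meta=meta,
    )


def write_spectrum(s: Spectrum, path: str | Path, format: str = "csv") -> Path:
    """Write a two-column file plus a JSON metadata sidecar; returns the path."""
    path = Path(path)
    delim = "\t" if format == "tsv" else ","
    with open(path, "w") as fh:
        fh.write(f"wavenumber_cm-1{delim}intensity\n")
        for w, y in zip(s.wavenumbers, s.intensities):
            fh.write(f"{w:.6g}{delim}{y:.10g}\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"modality": s.modality, "label": s.label, **s.meta}, default=str))
    return path


def crop(s: Spectrum, b: Band) -> Spectrum:
    """Restrict to low <= w <= high; metadata preserved."""
    sl = s.band_slice(b)
    n = sl.stop - sl.start
    if n == 0:
        raise SpectrumError(f"band {b.name!r} [{b.low}, {b.high}] does not overlap the grid")
    if n < 8:
        raise SpectrumError(f"band {b.name!r} overlaps only {n} points (< 8)")
    return replace(s, wavenumbers=s.wavenumbers[sl], intensities=s.intensities[sl])


def resample(s: Spectrum, grid: Sequence[float]) -> Spectrum:
    """Linear interpolation onto ``grid``; extrapolation is refused."""
    grid = np.asarray(grid, dtype=float)
    if grid[0] < s.wavenumbers[0] - 1e-9 or grid[-1] > s.wavenumbers[-1] + 1e-9:
        raise SpectrumError(
            f"resample grid [{grid[0]}, {grid[-1]}] extends beyond spectrum "
            f"[{s.wavenumbers[0]}, {s.wavenumbers[-1]}]"
        )
    y = np.interp(grid, s.wavenumbers, s.intensities)
    return replace(s, wavenumbers=grid, intensities=y)


def average_replicates(spectra: Iterable[Spectrum]) -> Spectrum:
    """Average replicate spectra of one specimen.

    All replicates are resampled to the first replicate's grid (restricted to
    the common range), then averaged point-wise.  The study records three
    spectra per specimen; spectra are averaged first and ratios computed once.
    """
    spectra = list(spectra)
    if not spectra:
        raise SpectrumError("no spectra to average")
    lo = max(sp.wavenumbers[0] for sp in spectra)
    hi = min(sp.wavenumbers[-1] for sp in spectra)
    if lo >= hi:
        raise SpectrumError("replicates have no common wavenumber range")
    ref = spectra[0]
    grid = ref.wavenumbers[(ref.wavenumbers >= lo) & (ref.wavenumbers <= hi)]
    stack = np.vstack([resample(sp, grid).intensities for sp in spectra])
    return Spectrum(
        wavenumbers=grid,
        intensities=stack.mean(axis=0),
        modality=ref.modality,
        label=ref.label,
        meta={**ref.meta, "averaged_replicates": len(spectra)},
    )
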