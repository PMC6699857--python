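"""EI spectrum processing for saturated-hydrocarbon identification.

The 70 eV EI spectrum of an alkane is dominated by the alkyl cation series
CnH2n+1+ (nominal m/z = 14n + 1) whose intensities fall off roughly
exponentially with mass.  A methyl branch promotes cleavage of the two C-C
bonds flanking the branch carbon (the resulting cations are secondary), so
the corresponding series ions stand out above the smooth envelope.  This
module turns that physics into four steps: background subtraction, parent
(molecular) ion assignment, alkyl-envelope extraction, and an
exponential-decay fit whose positive outliers are the enhanced ions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np

from .errors import (
    DecayFitError,
    InsufficientEnvelopeError,
    NoParentError,
)
from .records import alkane_formula

__all__ = [
    "PeakSpectrum",
    "ParentAssignment",
    "DecayFit",
    "FitPoint",
    "subtract_background",
    "determine_parent",
    "extract_envelope",
    "fit_decay",
    "detect_enhanced",
    "alkyl_series",
]

#: lowest alkyl-series m/z used for envelope work.  CnH2n+1+ ions below C4H9+
#: (m/z 57) deviate from the exponential decay for every alkane and would
#: poison the fit, so the series starts at 57.
MZ_SERIES_MIN = 57

#: half-width (Da) of the molecular-ion region excluded from enhanced-ion
#: calls: M-15 (methyl loss) and M-29 are rearrangement-dominated.
PARENT_EXCLUSION_DA = 30


@dataclass(frozen=True)
class PeakSpectrum:
    """One background-subtracted, centroided EI spectrum tied to a peak."""

    peak_id: str
    retention_time: float  # minutes
    mz: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise ValueError("mz and intensities must be 1-D arrays of equal length")
        if mz.size and (np.any(np.diff(mz) <= 0) or mz[0] <= 0):
            raise ValueError("m/z values must be positive and strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensities", inten)

    @classmethod
    def from_pairs(cls, peak_id: str, retention_time: float,
                   ions: Sequence[tuple[float, float]]) -> "PeakSpectrum":
        ions = sorted(ions)
        return cls(peak_id, retention_time,
                   np.array([m for m, _ in ions], dtype=float),
                   np.array([i for _, i in ions], dtype=float))

    def __len__(self) -> int:
        return int(self.mz.size)


@dataclass(frozen=True)
class ParentAssignment:
    """Molecular-ion call: nominal mass, formula and carbon count.

    ``unsaturation`` 0 means the alkane series (M = 14C + 2), 1 the monoene
    series (M = 14C).  ``ambiguous`` marks calls made past more intense or
    off-series high-mass ions, mirroring the low-confidence cases where the
    molecular ion is weak or absent.
    """

    parent_mz: int
    molecular_formula: str | None
    carbon_count: int | None
    unsaturation: int | None
    ambiguous: bool = False


class FitPoint(NamedTuple):
    mz: int
    observed: float
    predicted: float
    residual_ratio: float  # observed / predicted


@dataclass(frozen=True)
class DecayFit:
    """A * exp(-lambda * m/z) fitted to the alkyl-ion envelope."""

    amplitude: float
    decay_constant: float  # per Dalton
    fitted_points: tuple[FitPoint, ...]
    parent_mz: int | None = None
    masked: tuple[int, ...] = field(default_factory=tuple)

    def predict(self, mz: float) -> float:
        return self.amplitude * math.exp(-self.decay_constant * mz)


def subtract_background(spectrum: PeakSpectrum,
                        background: PeakSpectrum | None,
                        mz_tolerance: float = 0.3) -> PeakSpectrum:
    """Subtract a background spectrum ion-by-ion (floor at zero).

    Signal ions with no background partner within ``mz_tolerance`` pass
    through unchanged; background-only ions are ignored.
    """
    if len(spectrum) == 0:
        raise ValueError("cannot background-subtract an empty spectrum")
    if background is None or len(background) == 0:
        return spectrum
    idx = np.searchsorted(background.mz, spectrum.mz)
    out = spectrum.intensities.copy()
    for i, m in enumerate(spectrum.mz):
        best = None
        for j in (idx[i] - 1, idx[i]):
            if 0 <= j < len(background):
                d = abs(background.mz[j] - m)
                if d <= mz_tolerance and (best is None or d < best[0]):
                    best = (d, j)
        if best is not None:
            out[i] = max(0.0, out[i] - background.intensities[best[1]])
    return replace(spectrum, intensities=out)


def _nominal(mz: float) -> int:
    return int(math.floor(mz + 0.5))


def determine_parent(spectrum: PeakSpectrum,
                     rel_intensity_floor: float = 0.005) -> ParentAssignment:
    """Assign the molecular ion after background subtraction.

    Scans credible ions (>= ``rel_intensity_floor`` of the base peak) from
    high to low m/z for the first one on the alkane (14C+2) or monoene (14C)
    nominal series.  When no credible ion is on either series the floor is
    relaxed and the highest on-series ion of any intensity is taken with
    ``ambiguous=True`` — the weak-molecular-ion case.  If the spectrum has
    no on-series ion at all, the top credible ion is returned ambiguous with
    no formula; the caller may then supply the parent manually.
    """
    if len(spectrum) == 0:
        raise NoParentError("empty spectrum")
    base = float(spectrum.intensities.max())
    if base <= 0:
        raise NoParentError("spectrum has no non-zero intensity")
    ions = sorted(
        ((_nominal(m), float(i)) for m, i in zip(spectrum.mz, spectrum.intensities)
         if i > 0),
        reverse=True,
    )
    credible = [(m, i) for m, i in ions if i >= rel_intensity_floor * base]
    if not credible:
        raise NoParentError(
            f"no ion above {rel_intensity_floor:.3%} of the base peak"
        )

    def _assign(m: int, ambiguous: bool) -> ParentAssignment | None:
        residue = m % 14
        if residue == 2:
            return ParentAssignment(m, alkane_formula((m - 2) // 14),
                                    (m - 2) // 14, 0, ambiguous)
        if residue == 0:
            return ParentAssignment(m, alkane_formula(m // 14, unsaturation=1),
                                    m // 14, 1, ambiguous)
        return None

    for rank, (m, _) in enumerate(credible):
        hit = _assign(m, ambiguous=rank > 0)
        if hit is not None:
            return hit
    for m, _ in ions:  # relaxed pass: molecular ion below the floor
        hit = _assign(m, ambiguous=True)
        if hit is not None:
            return hit
    return ParentAssignment(credible[0][0], None, None, None, ambiguous=True)


def alkyl_series(parent_mz: int, mz_min: int = MZ_SERIES_MIN) -> list[int]:
    """Nominal alkyl-cation m/z values (== 1 mod 14) in [mz_min, M-15]."""
    start = mz_min + ((1 - mz_min) % 14)
    return list(range(start, parent_mz - 15 + 1, 14))


def extract_envelope(spectrum: PeakSpectrum, parent: ParentAssignment,
                     mz_tolerance: float = 0.3) -> list[tuple[int, float]]:
    """Collect intensities at every alkyl-series nominal m/z up to M-15.

    Missing series ions are recorded as absent (omitted), not as zeros.
    """
    targets = alkyl_series(parent.parent_mz)
    out: list[tuple[int, float]] = []
    mzs = spectrum.mz
    for t in targets:
        idx = np.searchsorted(mzs, t)
        best = None
        for j in (idx - 1, idx):
            if 0 <= j < len(spectrum):
                d = abs(mzs[j] - t)
                if d <= mz_tolerance and (best is None or d < best[0]):
                    best = (d, j)
        if best is not None:
            out.append((t, float(spectrum.intensities[best[1]])))
    if len(out) < 4:
        raise InsufficientEnvelopeError(
            f"only {len(out)} alkyl-series ions found (need >= 4)"
        )
    return out


def _log_fit(mz: np.ndarray, inten: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(mz, np.log(inten), 1)
    return float(math.exp(intercept)), float(-slope)


def fit_decay(envelope: Sequence[tuple[int, float]],
              mask_threshold: float = 2.0,
              parent_mz: int | None = None) -> DecayFit:
    """Least-squares exponential fit of the envelope in log-intensity space.

    After a first pass, points whose observed/predicted ratio exceeds
    ``mask_threshold`` (candidate enhanced ions) are masked and the fit is
    redone once, so branch-enhanced ions do not drag the baseline upward.
    The returned fit reports every positive-intensity point against the
    final curve.
    """
    pts = [(int(m), float(i)) for m, i in envelope if i > 0]
    if len(pts) < 4:
        raise DecayFitError(
            f"need >= 4 positive-intensity envelope points, got {len(pts)}"
        )
    mz = np.array([m for m, _ in pts], dtype=float)
    inten = np.array([i for _, i in pts], dtype=float)
    amp, lam = _log_fit(mz, inten)
    ratios = inten / (amp * np.exp(-lam * mz))
    masked = ratios > mask_threshold
    masked_mz: tuple[int, ...] = ()
    if masked.any() and (~masked).sum() >= 4:
        amp, lam = _log_fit(mz[~masked], inten[~masked])
        masked_mz = tuple(int(m) for m in mz[masked])
    pred = amp * np.exp(-lam * mz)
    points = tuple(
        FitPoint(int(m), float(o), float(p), float(o / p))
        for m, o, p in zip(mz, inten, pred)
    )
    return DecayFit(amp, lam, points, parent_mz=parent_mz, masked=masked_mz)


def detect_enhanced(fit: DecayFit, ratio_threshold: float = 2.0) -> list[int]:
    """m/z of ions sitting >= ``ratio_threshold`` times above the envelope.

    The molecular-ion region (within ``PARENT_EXCLUSION_DA`` of the parent)
    is excluded: M-15 and M-29 are prominent for every alkane and carry no
    branch information.
    """
    out = []
    for p in fit.fitted_points:
        if p.residual_ratio < ratio_threshold:
            continue
        if fit.parent_mz is not None and p.mz > fit.parent_mz - PARENT_EXCLUSION_DA:
            continue
        out.append(p.mz)
    return sorted(out)
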