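"""Seed-controlled synthetic EI spectra, chromatograms and reference tables.

The generator inverts the identification model: alkyl-series ions
(m/z == 1 mod 14, from 57 up to M-15) fall off as A*exp(-lambda*m),
diagnostic branch-cleavage ions are multiplied by an enhancement factor
before noise, the molecular ion sits at nominal M, and additive Gaussian
noise is truncated at zero.  Retention times come from a monotone (by
default gently quadratic) map of true retention index, alongside a C8-C40
n-alkane ladder, so the piecewise-linear calibration is exercised against a
non-affine truth.

Everything here is synthetic test scaffolding with the statistical shape of
real cuticular-hydrocarbon runs; see the methods note for what it does and
does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ChcidError, UnsupportedStructureError
from .inference import (
    CandidateStructure,
    infer_branch_positions,
    make_structure,
    predict_diagnostic_ions,
)
from .refcurves import REFERENCE_COLUMNS
from .spectra import PeakSpectrum, alkyl_series

__all__ = [
    "SimSpectrumParams",
    "RetentionModel",
    "simulate_spectrum",
    "simulate_chromatogram",
    "generate_dataset",
    "make_reference_table",
    "structure_ri",
]


@dataclass(frozen=True)
class SimSpectrumParams:
    """Envelope and noise parameters for one simulated EI spectrum.

    Defaults reproduce the visual shape of real alkane spectra: steep
    exponential decay, a visible molecular ion, branch ions about three
    times the envelope, and ~1% additive noise.
    """

    envelope_amplitude: float = 1.0e6  # counts
    decay_constant: float = 0.012  # per Dalton
    enhancement_factor: float = 3.0  # applied to diagnostic ions, >= 1
    molecular_ion_rel_intensity: float = 0.5  # fraction of envelope at M
    noise_sd: float = 1.0e4  # counts, additive, truncated at 0 (= 1% of A)
    mz_min: int = 57
    seed: int = 0

    def __post_init__(self) -> None:
        if self.envelope_amplitude <= 0:
            raise ValueError("envelope amplitude must be positive")
        if self.decay_constant < 0:
            raise ValueError("decay constant must be non-negative")
        if self.enhancement_factor < 1:
            raise ValueError("enhancement factor must be >= 1")
        if self.noise_sd < 0 or self.molecular_ion_rel_intensity < 0:
            raise ValueError("noise sd and molecular-ion intensity must be >= 0")


@dataclass(frozen=True)
class RetentionModel:
    """Monotone map from true retention index to retention time (minutes).

    Quadratic in RI with a small curvature by default, standing in for the
    instrument's temperature program; defaults place C15 near 13 min and
    C38 near 50 min, as in typical CHC runs.
    """

    intercept: float = -7.2  # minutes
    slope: float = 0.0119  # minutes per RI unit
    curvature: float = 1.2e-6  # minutes per RI^2

    def __call__(self, ri: float) -> float:
        return self.intercept + self.slope * ri + self.curvature * ri * ri

    def check_monotone(self, ri_lo: float, ri_hi: float) -> None:
        # derivative slope + 2*c*ri must stay positive over the span
        for ri in (ri_lo, ri_hi):
            if self.slope + 2 * self.curvature * ri <= 0:
                raise ChcidError(
                    f"retention model not increasing at RI {ri:.0f}"
                )


def simulate_spectrum(structure: CandidateStructure,
                      params: SimSpectrumParams,
                      peak_id: str = "",
                      retention_time: float = 0.0) -> PeakSpectrum:
    """Simulate the centroided EI spectrum of a saturated alkane.

    Deterministic given ``params.seed``.  With ``noise_sd == 0`` every
    non-diagnostic series ion equals A*exp(-lambda*m) exactly.
    """
    if structure.unsaturation != 0:
        raise UnsupportedStructureError("simulator covers saturated alkanes only")
    m_parent = structure.molecular_mass
    if params.mz_min >= m_parent:
        raise ValueError(f"mz_min {params.mz_min} must be below M {m_parent}")
    diagnostics = set(predict_diagnostic_ions(structure).ions)
    series = alkyl_series(m_parent, mz_min=params.mz_min)
    a, lam = params.envelope_amplitude, params.decay_constant
    mz = np.array(series + [m_parent], dtype=float)
    base = a * np.exp(-lam * mz)
    base[-1] *= params.molecular_ion_rel_intensity
    with np.errstate(over="ignore"):
        for i, m in enumerate(series):
            if m in diagnostics:
                base[i] = base[i] * params.enhancement_factor
    if not np.all(np.isfinite(base)):
        raise ValueError("enhanced envelope overflowed to non-finite intensity")
    rng = np.random.default_rng(params.seed)
    if params.noise_sd > 0:
        base = np.maximum(0.0, base + rng.normal(0.0, params.noise_sd, base.size))
    return PeakSpectrum(peak_id, retention_time, mz, base)


def simulate_chromatogram(structures: Sequence[CandidateStructure],
                          ri_true: Sequence[float],
                          model: RetentionModel | None = None,
                          ladder_carbons: Iterable[int] = range(8, 41),
                          peak_ids: Sequence[str] | None = None,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stick retention times for compounds plus the n-alkane ladder.

    Returns (peak table, ladder table), both sorted by retention time.
    Compounds whose true RI falls outside the ladder span get an
    ``out_of_ladder`` warning flag rather than an error.
    """
    if len(structures) != len(ri_true):
        raise ValueError("structures and ri_true must have equal length")
    if any(r <= 0 for r in ri_true):
        raise ValueError("true RI values must be positive")
    model = model or RetentionModel()
    carbons = sorted(int(c) for c in ladder_carbons)
    if len(carbons) < 2:
        raise ChcidError("ladder needs at least two alkanes")
    lo, hi = 100.0 * carbons[0], 100.0 * carbons[-1]
    all_ri = list(ri_true) + [lo, hi]
    model.check_monotone(min(all_ri), max(all_ri))
    ladder = pd.DataFrame({
        "carbon_number": carbons,
        "retention_time_min": [model(100.0 * c) for c in carbons],
    }).sort_values("retention_time_min", ignore_index=True)
    ids = list(peak_ids) if peak_ids is not None else [
        f"P{i + 1:02d}" for i in range(len(structures))
    ]
    peaks = pd.DataFrame({
        "peak_id": ids,
        "retention_time_min": [model(r) for r in ri_true],
        "ri_true": list(map(float, ri_true)),
        "out_of_ladder": [not lo <= r <= hi for r in ri_true],
    }).sort_values("retention_time_min", ignore_index=True)
    return peaks, ladder


def _branch_ri_deficit(chain: int, locant: int) -> float:
    """RI lowering caused by one methyl at ``locant`` on a C``chain`` chain.

    Terminal-adjacent branches perturb retention least; the effect saturates
    around 60 RI units for internal positions, matching the magnitudes seen
    on apolar columns.
    """
    return 40.0 + 2.0 * min(locant, chain + 1 - locant, 10)


def structure_ri(structure: CandidateStructure) -> float:
    """Deterministic true retention index used throughout the simulator."""
    if structure.unsaturation != 0:
        raise UnsupportedStructureError("RI model covers saturated alkanes only")
    n = structure.parent_chain_length
    deficit = sum(_branch_ri_deficit(n, p) for p in structure.branch_positions)
    return 100.0 * structure.total_carbons - deficit


# locant patterns used to populate reference cells; truncated to the branch
# count and kept only when they fit on the chain
_REF_PATTERNS = (
    (4, 8, 12, 16, 20),
    (5, 9, 13, 17, 21),
    (7, 11, 15, 19, 23),
    (4, 7, 10, 13, 16),
)


def make_reference_table(carbon_range: tuple[int, int] = (15, 38),
                         max_branches: int = 5) -> pd.DataFrame:
    """Synthetic reference RI table emulating literature-database extracts.

    Several isomers per (carbon count, branch count) cell, with RIs from the
    same deterministic model the chromatogram simulator uses, so reference
    curves and simulated compounds are mutually consistent.  n-alkanes sit
    exactly at RI = 100*C.
    """
    rows = []
    for c in range(carbon_range[0], carbon_range[1] + 1):
        rows.append({"compound_name": make_structure(c).name, "carbon_count": c,
                     "branch_count": 0, "ri": 100.0 * c})
        for k in range(1, max_branches + 1):
            chain = c - k
            if chain < 7:
                continue
            seen = set()
            for pattern in _REF_PATTERNS:
                locs = pattern[:k]
                if locs[-1] > chain - 3:
                    continue
                s = make_structure(chain, locs)
                if s.branch_positions in seen:
                    continue
                seen.add(s.branch_positions)
                rows.append({"compound_name": s.name, "carbon_count": c,
                             "branch_count": k, "ri": structure_ri(s)})
    return pd.DataFrame(rows, columns=REFERENCE_COLUMNS)


def _sample_structure(rng: np.random.Generator, carbon_range: tuple[int, int],
                      branch_range: tuple[int, int],
                      max_tries: int = 200) -> CandidateStructure:
    kmin, kmax = branch_range
    for _ in range(max_tries):
        c = int(rng.integers(carbon_range[0], carbon_range[1] + 1))
        k = int(rng.integers(kmin, kmax + 1))
        chain = c - k
        # locants in [4, chain-3] keep every diagnostic ion inside the
        # observable window [71, M-30]; spacing >= 2 avoids quaternary-like
        # adjacency atypical of insect CHCs
        lo, hi = 4, chain - 3
        if k > 0 and (hi < lo or hi - lo + 1 < k):
            continue
        locs = tuple(sorted(rng.choice(np.arange(lo, hi + 1), size=k, replace=False))) if k else ()
        if any(b - a < 2 for a, b in zip(locs, locs[1:])):
            continue
        s = make_structure(chain, locs)
        if k:
            ions = predict_diagnostic_ions(s).ions
            res = infer_branch_positions(c, ions, k_hint=k)
            if res.top is None or res.ambiguous or res.top.branch_positions != s.branch_positions:
                continue  # ion set does not uniquely identify the isomer
        return s
    raise ChcidError(
        f"could not place {branch_range} branches on C{carbon_range} after "
        f"{max_tries} tries"
    )


def generate_dataset(n_compounds: int,
                     branch_count_range: tuple[int, int] = (0, 2),
                     seed: int = 0,
                     carbon_range: tuple[int, int] = (21, 31),
                     params: SimSpectrumParams | None = None,
                     model: RetentionModel | None = None,
                     ladder_carbons: Iterable[int] = range(8, 41),
                     ) -> tuple[list[PeakSpectrum], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full identification problem with known ground truth.

    Returns (spectra, peak table, ladder table, ground-truth table),
    reproducible bit-for-bit given ``seed``.  Structures are sampled so that
    their diagnostic ions fall in the observable window and identify the
    isomer uniquely, and so that retention times are distinct.
    """
    if n_compounds < 1:
        raise ValueError("n_compounds must be >= 1")
    kmin, kmax = branch_count_range
    if not 0 <= kmin <= kmax <= 5:
        raise ValueError("branch counts must lie in 0..5")
    params = params or SimSpectrumParams()
    model = model or RetentionModel()
    rng = np.random.default_rng(seed)
    structures: list[CandidateStructure] = []
    ris: list[float] = []
    for _ in range(n_compounds):
        for _ in range(200):
            s = _sample_structure(rng, carbon_range, branch_count_range)
            ri = structure_ri(s)
            if all(abs(ri - r) >= 2.0 for r in ris):
                structures.append(s)
                ris.append(ri)
                break
        else:
            raise ChcidError("could not sample compounds with distinct RIs")
    order = np.argsort(ris)
    structures = [structures[i] for i in order]
    ris = [ris[i] for i in order]
    ids = [f"P{i + 1:02d}" for i in range(n_compounds)]
    peaks, ladder = simulate_chromatogram(structures, ris, model,
                                          ladder_carbons, peak_ids=ids)
    spectra = []
    truth_rows = []
    for pid, s, ri in zip(ids, structures, ris):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sp = simulate_spectrum(s, replace(params, seed=sub_seed), peak_id=pid,
                               retention_time=float(model(ri)))
        spectra.append(sp)
        truth_rows.append({
            "peak_id": pid,
            "structure": s.name,
            "formula": s.formula,
            "mw": s.molecular_mass,
            "total_carbons": s.total_carbons,
            "branch_count": s.branch_count,
            "locants": ";".join(map(str, s.branch_positions)),
            "ri_true": ri,
            "retention_time_min": float(model(ri)),
        })
    truth = pd.DataFrame(truth_rows)
    return spectra, peaks, ladder, truth
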