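"""Compound-table assembly and the end-to-end identification pipeline.

``run_pipeline`` chains, per chromatographic peak: background subtraction,
parent-ion assignment, alkyl-envelope extraction, exponential-decay fit,
enhanced-ion detection, curve-based branch-count estimation and ion-based
branch-position inference, with the retention index computed against the
n-alkane ladder.  Per-peak failures downgrade to row status flags so a run
always produces a full table plus a structured decision log.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .calibration import fit_ladder, retention_index_flagged
from .config import PipelineConfig
from .errors import ChcidError
from .inference import resolve_compound
from .records import CompoundRecord, nominal_mass
from .refcurves import BranchCurves, build_curves
from .spectra import (
    PeakSpectrum,
    determine_parent,
    detect_enhanced,
    extract_envelope,
    fit_decay,
    subtract_background,
)

__all__ = ["assemble_table", "run_pipeline", "records_to_frame"]

TABLE_COLUMNS = ["peak_id", "rt_min", "mw", "formula", "structure", "ri",
                 "flags", "annotation"]


def records_to_frame(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    rows = [{
        "peak_id": r.peak_id,
        "rt_min": r.retention_time,
        "mw": r.nominal_mw,
        "formula": r.molecular_formula or "",
        "structure": r.structure_name,
        "ri": r.ri,
        "flags": ";".join(sorted(r.flags)),
        "annotation": r.annotation,
    } for r in records]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def assemble_table(records: Sequence[CompoundRecord],
                   coelution_window: float = 0.005) -> pd.DataFrame:
    """Sort records by retention time, validate them, and flag co-elution.

    Validation failures (formula/MW mismatch) become per-row flags; the
    table is always emitted.
    """
    recs = sorted(records, key=lambda r: r.retention_time)
    out = []
    for i, r in enumerate(recs):
        flags = set(r.flags)
        if r.molecular_formula and r.nominal_mw is not None:
            try:
                if nominal_mass(r.molecular_formula) != r.nominal_mw:
                    flags.add("mw-formula-mismatch")
            except ChcidError:
                flags.add("formula-unparseable")
        for j in (i - 1, i + 1):
            if 0 <= j < len(recs) and \
                    abs(recs[j].retention_time - r.retention_time) < coelution_window:
                flags.add("possible-coelution")
        out.append(r.with_flags(*flags))
    return records_to_frame(out)


def run_pipeline(spectra: Sequence[PeakSpectrum],
                 ladder: Sequence[tuple[int, float]],
                 reference_table: pd.DataFrame | None = None,
                 config: PipelineConfig | None = None,
                 background: PeakSpectrum | None = None,
                 curves: BranchCurves | None = None,
                 ) -> tuple[pd.DataFrame, list[dict]]:
    """Identify every peak spectrum against a ladder and reference curves.

    Returns the compound table (sorted by Rt) and a per-peak decision log.
    A missing/invalid ladder is fatal; everything else degrades to flags.
    """
    cfg = config or PipelineConfig()
    cal = fit_ladder(ladder)  # fatal on a bad ladder, by design
    if curves is None and reference_table is not None:
        curves = build_curves(reference_table)
    records: list[CompoundRecord] = []
    log: list[dict] = []
    for spec in spectra:
        entry: dict = {"peak_id": spec.peak_id, "rt_min": spec.retention_time}
        ri, extrapolated = retention_index_flagged(cal, spec.retention_time)
        entry["ri"] = ri
        try:
            clean = subtract_background(spec, background, cfg.mz_tolerance)
            parent = determine_parent(clean, cfg.parent_floor)
            entry["parent_mz"] = parent.parent_mz
            entry["formula"] = parent.molecular_formula
            enhanced: list[int] = []
            if parent.unsaturation == 0 and parent.carbon_count is not None:
                envelope = extract_envelope(clean, parent, cfg.mz_tolerance)
                fit = fit_decay(envelope, cfg.mask_threshold, parent.parent_mz)
                entry["decay_constant"] = fit.decay_constant
                enhanced = detect_enhanced(fit, cfg.ratio_threshold)
            entry["enhanced"] = enhanced
            rec = resolve_compound(parent, enhanced, ri, curves,
                                   retention_time=spec.retention_time,
                                   peak_id=spec.peak_id,
                                   penalty=cfg.score_penalty,
                                   ri_tolerance=cfg.ri_tolerance)
        except ChcidError as exc:
            entry["error"] = str(exc)
            rec = CompoundRecord(spec.retention_time, None, None, "unidentified",
                                 None, spec.peak_id,
                                 frozenset({f"stage-error:{type(exc).__name__}"}))
        if extrapolated:
            rec = rec.with_flags("ri-extrapolated")
        entry["structure"] = rec.structure_name
        entry["flags"] = sorted(rec.flags)
        records.append(rec)
        log.append(entry)
    return assemble_table(records, cfg.coelution_window), log
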