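"""Reading and writing the pipeline's exchange formats.

Spectra travel as NIST MSP text (read and written through matchms); tables
(ladder, peaks, reference RIs, compound output) are headered CSV with all
floats at full precision on the machine side.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from matchms import Spectrum as _MmsSpectrum
from matchms.exporting import save_as_msp
from matchms.importing import load_from_msp

from .errors import ChcidError
from .records import CompoundRecord
from .spectra import PeakSpectrum

__all__ = [
    "write_msp",
    "read_msp",
    "read_ladder_csv",
    "write_ladder_csv",
    "read_peak_table_csv",
    "write_compound_table",
    "read_compound_table",
]

COMPOUND_COLUMNS = ["peak_id", "rt_min", "mw", "formula", "structure", "ri",
                    "flags", "annotation"]


def write_msp(spectra: Sequence[PeakSpectrum], path) -> None:
    """Write spectra as NIST MSP text, one entry per peak."""
    out = []
    for s in spectra:
        out.append(_MmsSpectrum(
            mz=np.asarray(s.mz, dtype=float),
            intensities=np.asarray(s.intensities, dtype=float),
            metadata={"compound_name": s.peak_id or "peak",
                      "peak_id": s.peak_id,
                      "retention_time": float(s.retention_time)},
            metadata_harmonization=False,
        ))
    path = Path(path)
    if path.exists():
        path.unlink()  # matchms appends to existing files
    save_as_msp(out, str(path))


def read_msp(path) -> list[PeakSpectrum]:
    """Read MSP text into peak spectra (retention time from metadata)."""
    spectra = []
    for i, s in enumerate(load_from_msp(str(path), metadata_harmonization=False)):
        meta = {k.lower(): v for k, v in s.metadata.items()}
        rt = float(meta.get("retention_time", meta.get("retentiontime", "nan")))
        pid = str(meta.get("peak_id", meta.get("compound_name", f"peak{i}")))
        spectra.append(PeakSpectrum(pid, rt, s.peaks.mz, s.peaks.intensities))
    return spectra


def read_ladder_csv(path) -> list[tuple[int, float]]:
    frame = pd.read_csv(path)
    for col in ("carbon_number", "retention_time_min"):
        if col not in frame.columns:
            raise ChcidError(f"ladder CSV missing column {col!r}")
    return list(zip(frame["carbon_number"].astype(int),
                    frame["retention_time_min"].astype(float)))


def write_ladder_csv(ladder: Sequence[tuple[int, float]], path) -> None:
    pd.DataFrame(ladder, columns=["carbon_number", "retention_time_min"]) \
        .to_csv(path, index=False, float_format="%.6g")


def read_peak_table_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "peak_id" not in frame.columns or "retention_time_min" not in frame.columns:
        raise ChcidError("peak table CSV needs peak_id and retention_time_min")
    return frame


def write_compound_table(table: pd.DataFrame, path) -> None:
    """Write the compound table; Rt to 2 decimals, RI integer (report style)."""
    out = table.copy()
    out["rt_min"] = out["rt_min"].map(lambda v: f"{v:.2f}")
    out.to_csv(path, index=False)


def read_compound_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, keep_default_na=False,
                        dtype={"flags": str, "annotation": str, "peak_id": str})
    frame["rt_min"] = frame["rt_min"].astype(float)
    return frame


def records_from_frame(frame: pd.DataFrame) -> list[CompoundRecord]:
    """Rebuild records from a compound table read back from CSV."""
    recs = []
    for row in frame.itertuples(index=False):
        recs.append(CompoundRecord(
            retention_time=float(row.rt_min),
            nominal_mw=None if pd.isna(row.mw) else int(row.mw),
            molecular_formula=row.formula or None,
            structure_name=row.structure,
            ri=None if pd.isna(row.ri) else int(row.ri),
            peak_id=str(row.peak_id),
            flags=frozenset(f for f in str(row.flags).split(";") if f),
            annotation=str(row.annotation),
        ))
    return recs
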