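"""Packaged data: the curated trophallactic-fluid compound table and a
synthetic reference-RI table.

``tf_compounds.csv`` is the curated identification table for ant
trophallactic-fluid GC-MS peaks (61 compounds: n-alkanes, methyl-branched
alkanes, alkenes, fatty acids and esters, an aldehyde and a
cholesterol-like molecule), with retention time, nominal MW, proposed
molecular formula and structure, integer retention index, and the original
peak letters.  Ambiguous branch or double-bond positions carry a leading
``*-``.

``reference_ri_synthetic.csv`` is a *synthetic* stand-in for a
literature-database RI extraction (the real extraction is unversioned and
online-only): several isomers per (carbon count, branch count) cell, C15 to
C38, 0 to 5 branches, generated once from the simulator's deterministic RI
model.  One annotated cell (C25, two branches) averages to 2409 to mirror
the documented example of cell averaging.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .calibration import round_ri
from .nomenclature import ALKANE_NAMES
from .records import nominal_mass

__all__ = [
    "load_tf_compounds",
    "load_reference_ri",
    "nalkane_ladder",
    "hydrocarbon_rows",
]

_N_ALKANE_NAMES = {name.lower() for name in ALKANE_NAMES.values()}


def _data_path(name: str):
    return resources.files("chcid.data").joinpath(name)


def load_tf_compounds() -> pd.DataFrame:
    """The curated 61-row compound table (rt_min, mw, formula, structure,
    ri, peak_id)."""
    with resources.as_file(_data_path("tf_compounds.csv")) as p:
        return pd.read_csv(p, keep_default_na=False)


def load_reference_ri() -> pd.DataFrame:
    """The packaged synthetic reference-RI table."""
    with resources.as_file(_data_path("reference_ri_synthetic.csv")) as p:
        return pd.read_csv(p)


def nalkane_ladder(compounds: pd.DataFrame | None = None) -> list[tuple[int, float]]:
    """(carbon number, retention time) anchors from the table's n-alkane rows."""
    df = compounds if compounds is not None else load_tf_compounds()
    anchors = []
    for row in df.itertuples(index=False):
        name = str(row.structure).strip().lower()
        if name in _N_ALKANE_NAMES:
            carbons = (int(row.mw) - 2) // 14
            anchors.append((carbons, float(row.rt_min)))
    return sorted(anchors)


def hydrocarbon_rows(compounds: pd.DataFrame | None = None) -> pd.DataFrame:
    """Rows whose proposed formula is a pure hydrocarbon (CxHy, no oxygen)."""
    df = compounds if compounds is not None else load_tf_compounds()
    mask = df["formula"].str.fullmatch(r"C\d+H\d+")
    return df[mask].reset_index(drop=True)


def check_fixture_integrity(compounds: pd.DataFrame | None = None) -> bool:
    """True when every hydrocarbon row's formula reproduces its MW column."""
    df = hydrocarbon_rows(compounds)
    return all(nominal_mass(f) == int(m) for f, m in zip(df["formula"], df["mw"]))


# kept for annotation: documented example mean for the C25 / two-branch cell
C25_DIMETHYL_MEAN_RI = round_ri(2409.0)
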