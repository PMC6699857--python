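"""RI-vs-carbon-number reference curves stratified by methyl-branch count.

Each added methyl branch lowers the retention index of an alkane relative to
the n-alkane of the same carbon count (an internal monomethyl sits roughly
60 RI units low).  Averaging literature RI values per (carbon count,
branch count) cell therefore yields six well-separated curves for 0-5
branches; a measured RI plus a carbon count picks out the branch count as
the curve with the smallest residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ChcidError

__all__ = [
    "MAX_BRANCHES",
    "BranchCurves",
    "build_curves",
    "consistency_check",
    "estimate_branch_count",
    "load_reference_table",
    "curves_to_frame",
]

MAX_BRANCHES = 5

REFERENCE_COLUMNS = ["compound_name", "carbon_count", "branch_count", "ri"]

#: default tolerance (RI units) for calling a (RI, carbons, branches)
#: combination consistent with its reference curve.
DEFAULT_RI_TOLERANCE = 15.0


@dataclass(frozen=True)
class BranchCurves:
    """Per-branch-count cell means plus a linear fit over carbon number."""

    cell_means: dict[tuple[int, int], float]  # (carbon_count, k) -> mean RI
    lines: dict[int, tuple[float, float]]  # k -> (slope, intercept)

    def value(self, carbon_count: int, branch_count: int) -> float:
        """Curve value, preferring the exact cell mean over the fitted line."""
        key = (int(carbon_count), int(branch_count))
        if key in self.cell_means:
            return self.cell_means[key]
        if branch_count in self.lines:
            slope, intercept = self.lines[branch_count]
            return slope * carbon_count + intercept
        raise KeyError(
            f"no reference data for {branch_count} branches at C{carbon_count}"
        )

    def evaluable(self, carbon_count: int, branch_count: int) -> bool:
        return (carbon_count, branch_count) in self.cell_means or branch_count in self.lines


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REFERENCE_COLUMNS if c not in table.columns]
    if missing:
        raise ChcidError(f"reference table missing columns {missing}")
    t = table.copy()
    t["carbon_count"] = t["carbon_count"].astype(int)
    t["branch_count"] = t["branch_count"].astype(int)
    t["ri"] = t["ri"].astype(float)
    if (t["carbon_count"] < 8).any():
        raise ChcidError("reference carbon counts below C8")
    if ((t["branch_count"] < 0) | (t["branch_count"] > MAX_BRANCHES)).any():
        raise ChcidError(f"branch counts must lie in 0..{MAX_BRANCHES}")
    if (t["ri"] <= 0).any():
        raise ChcidError("reference RI values must be positive")
    return t


def load_reference_table(path) -> pd.DataFrame:
    """Read a reference RI CSV (compound_name, carbon_count, branch_count, ri)."""
    return _validate(pd.read_csv(path))


def build_curves(table: pd.DataFrame) -> BranchCurves:
    """Average reference RIs per (carbon count, branch count) cell and fit
    one least-squares line per branch count over the cell means.

    Branch counts with fewer than two carbon levels keep their cell means
    but get no fitted line.
    """
    t = _validate(table)
    if t.empty:
        raise ChcidError("reference table is empty")
    means = t.groupby(["carbon_count", "branch_count"])["ri"].mean()
    cell_means = {(int(c), int(k)): float(v) for (c, k), v in means.items()}
    lines: dict[int, tuple[float, float]] = {}
    for k in sorted(t["branch_count"].unique()):
        cells = sorted((c, v) for (c, kk), v in cell_means.items() if kk == k)
        if len(cells) >= 2:
            xs = np.array([c for c, _ in cells], dtype=float)
            ys = np.array([v for _, v in cells], dtype=float)
            slope, intercept = np.polyfit(xs, ys, 1)
            lines[int(k)] = (float(slope), float(intercept))
    return BranchCurves(cell_means=cell_means, lines=lines)


def consistency_check(curves: BranchCurves, ri: float, carbon_count: int,
                      branch_count: int,
                      tolerance: float = DEFAULT_RI_TOLERANCE) -> tuple[float, bool]:
    """Residual of a measured RI against the curve for the hypothesized
    (carbon count, branch count), and whether it passes ``tolerance``."""
    if not 0 <= branch_count <= MAX_BRANCHES:
        raise ChcidError(f"branch count {branch_count} outside 0..{MAX_BRANCHES}")
    residual = float(ri) - curves.value(carbon_count, branch_count)
    return residual, abs(residual) <= tolerance


def estimate_branch_count(curves: BranchCurves, ri: float,
                          carbon_count: int) -> tuple[int, dict[int, float]]:
    """Branch count whose curve lies closest to the measured RI.

    Ties break toward fewer branches (parsimony).  The full per-k residual
    vector is returned for transparency.
    """
    residuals: dict[int, float] = {}
    for k in range(MAX_BRANCHES + 1):
        if curves.evaluable(carbon_count, k):
            residuals[k] = float(ri) - curves.value(carbon_count, k)
    if not residuals:
        raise ChcidError(f"no reference curve evaluable at C{carbon_count}")
    k_best = min(residuals, key=lambda k: (abs(residuals[k]), k))
    return k_best, residuals


def curves_to_frame(curves: BranchCurves) -> pd.DataFrame:
    """Flatten curves to a tidy frame (for CSV export and plotting)."""
    rows = [
        {"carbon_count": c, "branch_count": k, "mean_ri": v}
        for (c, k), v in sorted(curves.cell_means.items())
    ]
    return pd.DataFrame(rows, columns=["carbon_count", "branch_count", "mean_ri"])
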