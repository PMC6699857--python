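"""Kovats/linear retention-index calibration from an n-alkane ladder.

Retention indices are computed by piecewise-linear interpolation between
the ladder anchors (the van den Dool & Kratz convention for
temperature-programmed GC): within the segment bounded by n-alkanes with
``n_lo`` and ``n_hi`` carbons eluting at ``t_lo`` and ``t_hi``,

    RI(t) = 100*n_lo + 100*(n_hi - n_lo) * (t - t_lo) / (t_hi - t_lo)

The ``100*(n_hi - n_lo)`` factor makes segments gap-aware: when an alkane is
missing from the ladder (e.g. C21 between C20 and C22) the single wider
segment still assigns RI = 100*n at both anchors.  Outside the ladder span
the terminal segment is extended linearly and the result is flagged as
extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .errors import InsufficientLadderError, LadderInversionError

__all__ = [
    "RICalibration",
    "RIValue",
    "fit_ladder",
    "retention_index",
    "retention_index_flagged",
    "round_ri",
]


class RIValue(NamedTuple):
    ri: float
    extrapolated: bool


@dataclass(frozen=True)
class RICalibration:
    """Validated, sorted (carbon_number, retention_time) anchors.

    By definition the retention index at an anchor is exactly
    ``100 * carbon_number``.
    """

    anchors: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise InsufficientLadderError(
                f"need >= 2 ladder anchors, got {len(self.anchors)}"
            )
        carbons = [c for c, _ in self.anchors]
        times = [t for _, t in self.anchors]
        for (c0, t0), (c1, t1) in zip(self.anchors, self.anchors[1:]):
            if c1 <= c0:
                raise LadderInversionError(
                    f"carbon numbers not strictly increasing: C{c0} before C{c1}"
                )
            if t1 <= t0:
                raise LadderInversionError(
                    "retention times not strictly increasing: "
                    f"C{c0} at {t0} min vs C{c1} at {t1} min"
                )
        object.__setattr__(self, "_carbons", np.asarray(carbons, dtype=float))
        object.__setattr__(self, "_times", np.asarray(times, dtype=float))

    @property
    def span(self) -> tuple[float, float]:
        """(first, last) anchor retention time in minutes."""
        return self.anchors[0][1], self.anchors[-1][1]

    def ri(self, rt: float) -> float:
        return self.ri_flagged(rt).ri

    def ri_flagged(self, rt: float) -> RIValue:
        rt = float(rt)
        if not math.isfinite(rt):
            raise ValueError(f"retention time must be finite, got {rt}")
        times: np.ndarray = self._times  # type: ignore[attr-defined]
        ris = 100.0 * self._carbons  # type: ignore[attr-defined]
        if rt < times[0]:
            slope = (ris[1] - ris[0]) / (times[1] - times[0])
            return RIValue(float(ris[0] + slope * (rt - times[0])), True)
        if rt > times[-1]:
            slope = (ris[-1] - ris[-2]) / (times[-1] - times[-2])
            return RIValue(float(ris[-1] + slope * (rt - times[-1])), True)
        return RIValue(float(np.interp(rt, times, ris)), False)


def fit_ladder(ladder: Iterable[tuple[int, float]]) -> RICalibration:
    """Validate and sort an n-alkane ladder into a calibration.

    Exact duplicate rows are collapsed; the same carbon number with two
    different retention times is rejected as contradictory.
    """
    entries = sorted({(int(c), float(t)) for c, t in ladder})
    seen: dict[int, float] = {}
    for c, t in entries:
        if c in seen:
            raise LadderInversionError(
                f"duplicate ladder carbon C{c} with conflicting times "
                f"{seen[c]} and {t} min"
            )
        seen[c] = t
    if len(entries) < 2:
        raise InsufficientLadderError(
            f"need >= 2 ladder anchors after de-duplication, got {len(entries)}"
        )
    return RICalibration(anchors=tuple(entries))


def retention_index(cal: RICalibration, rt: float) -> float:
    """Retention index of a peak at ``rt`` minutes (float, unrounded)."""
    return cal.ri(rt)


def retention_index_flagged(cal: RICalibration, rt: float) -> RIValue:
    """Like :func:`retention_index` but carries the extrapolation flag."""
    return cal.ri_flagged(rt)


def round_ri(ri: float) -> int:
    """Round a retention index half-up to the nearest integer.

    Reported RIs are integers; full precision is kept internally.
    """
    if not math.isfinite(ri):
        raise ValueError(f"retention index must be finite, got {ri}")
    return int(math.floor(ri + 0.5))


def ladder_from_frame(frame) -> Sequence[tuple[int, float]]:
    """Extract (carbon_number, retention_time_min) pairs from a ladder table."""
    return list(zip(frame["carbon_number"].astype(int), frame["retention_time_min"].astype(float)))
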