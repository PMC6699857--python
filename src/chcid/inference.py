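"""Methyl-branch position inference from enhanced EI fragment ions.

Cleavage of either C-C bond flanking a branch carbon yields a secondary
carbenium ion, so those alkyl-series ions are enhanced above the smooth
envelope.  For a methyl branch at locant p on a parent chain of n carbons
(molecule CnH2n+2 plus the methyl, M = 14*(n+1) + 2) the two
branch-retaining cleavage products are

    near-end ion:  carbons 1..p plus the methyl  -> m/z = 14*(p+1) + 1
    far-end ion:   carbons p..n plus the methyl  -> m/z = 14*(n-p+2) + 1

so the pair sums to M + 28.  With several branches each fragment also
carries every other methyl it contains, which the composition count below
accounts for.  Inference inverts this rule: enumerate candidate locant
sets, predict their diagnostic ions, and score them against the observed
enhanced ions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from . import refcurves as _rc
from .calibration import round_ri
from .errors import ChcidError, UnsupportedStructureError
from .nomenclature import alkene_name, branched_name, parse_name
from .records import CompoundRecord, alkane_formula
from .refcurves import BranchCurves
from .spectra import MZ_SERIES_MIN, ParentAssignment

__all__ = [
    "CandidateStructure",
    "DiagnosticPrediction",
    "ScoredCandidate",
    "InferenceResult",
    "make_structure",
    "predict_diagnostic_ions",
    "infer_branch_positions",
    "name_structure",
    "parse_structure_name",
    "resolve_compound",
]

#: score deducted per predicted-but-unobserved or observed-but-unpredicted ion.
DEFAULT_SCORE_PENALTY = 0.5


@dataclass(frozen=True)
class CandidateStructure:
    """A saturated linear or methyl-branched alkane (or a monoene shell).

    ``branch_positions`` are locants on the parent chain, stored in the
    lowest-locant numbering (renumbering from either chain end picks the
    lexicographically smaller set).
    """

    total_carbons: int
    parent_chain_length: int
    branch_positions: tuple[int, ...] = ()
    unsaturation: int = 0
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.total_carbons != self.parent_chain_length + len(self.branch_positions):
            raise ValueError(
                "total_carbons must equal parent_chain_length + number of branches"
            )
        locs = self.branch_positions
        if any(not 2 <= p <= self.parent_chain_length - 1 for p in locs):
            raise ValueError(
                f"locants {locs} outside [2, {self.parent_chain_length - 1}]"
            )
        if any(b <= a for a, b in zip(locs, locs[1:])):
            raise ValueError("locants must be strictly increasing")
        if locs and locs != _canonical_locants(self.parent_chain_length, locs):
            raise ValueError(
                f"locants {locs} are not in lowest-locant form on a "
                f"C{self.parent_chain_length} chain"
            )

    @property
    def branch_count(self) -> int:
        return len(self.branch_positions)

    @property
    def molecular_mass(self) -> int:
        """Nominal molecular mass (14C+2 saturated, 14C monoene)."""
        return 14 * self.total_carbons + 2 - 2 * self.unsaturation

    @property
    def formula(self) -> str:
        return alkane_formula(self.total_carbons, self.unsaturation)

    @property
    def name(self) -> str:
        return name_structure(self)


@dataclass(frozen=True)
class DiagnosticPrediction:
    structure: CandidateStructure
    ions: tuple[int, ...]


@dataclass(frozen=True)
class ScoredCandidate:
    structure: CandidateStructure
    score: float
    predicted: tuple[int, ...]


@dataclass(frozen=True)
class InferenceResult:
    """Ranked candidates for one peak, with the raw observed ions."""

    candidates: tuple[ScoredCandidate, ...]
    observed: tuple[int, ...]
    resolved: bool
    ambiguous: bool

    @property
    def top(self) -> CandidateStructure | None:
        if not self.candidates:
            return None
        return replace(self.candidates[0].structure, ambiguous=self.ambiguous)

    @property
    def top_score(self) -> float:
        return self.candidates[0].score if self.candidates else float("-inf")


def _canonical_locants(chain: int, locants: Sequence[int]) -> tuple[int, ...]:
    fwd = tuple(sorted(locants))
    rev = tuple(sorted(chain + 1 - p for p in locants))
    return min(fwd, rev)


def make_structure(parent_chain_length: int,
                   branch_positions: Iterable[int] = (),
                   unsaturation: int = 0) -> CandidateStructure:
    """Build a structure, applying lowest-locant renumbering."""
    locs = _canonical_locants(parent_chain_length, tuple(branch_positions))
    return CandidateStructure(
        total_carbons=parent_chain_length + len(locs),
        parent_chain_length=parent_chain_length,
        branch_positions=locs,
        unsaturation=unsaturation,
    )


def predict_diagnostic_ions(structure: CandidateStructure) -> DiagnosticPrediction:
    """Diagnostic (enhanced) ions from cleavage at each branch carbon.

    For every branch, both flanking C-C chain bonds are cleaved and the
    charge is retained on the branch-containing (secondary-cation)
    fragment; the fragment's carbon count includes every methyl it carries.
    Ions are merged, restricted to the observable alkyl series window
    (> 57, <= M-15), and sorted.  Linear alkanes predict no ions.
    """
    if structure.unsaturation != 0:
        raise UnsupportedStructureError(
            "diagnostic-ion rules cover saturated alkanes only"
        )
    n = structure.parent_chain_length
    locs = structure.branch_positions
    mmax = structure.molecular_mass - 15
    ions: set[int] = set()
    for p in locs:
        near_c = p + sum(1 for q in locs if q <= p)
        far_c = (n - p + 1) + sum(1 for q in locs if q >= p)
        for c in (near_c, far_c):
            mz = 14 * c + 1
            if MZ_SERIES_MIN < mz <= mmax:
                ions.add(mz)
    return DiagnosticPrediction(structure=structure, ions=tuple(sorted(ions)))


def _carbon_count(parent: ParentAssignment | int) -> int:
    if isinstance(parent, ParentAssignment):
        if parent.carbon_count is None:
            raise ChcidError("parent assignment carries no carbon count")
        if parent.unsaturation not in (0, None):
            raise UnsupportedStructureError(
                "branch inference requires a saturated parent"
            )
        return parent.carbon_count
    return int(parent)


def infer_branch_positions(parent: ParentAssignment | int,
                           enhanced: Sequence[int],
                           k_hint: int | None = None,
                           penalty: float = DEFAULT_SCORE_PENALTY,
                           max_branches: int = _rc.MAX_BRANCHES) -> InferenceResult:
    """Rank candidate branch locant sets against observed enhanced ions.

    Candidates are every lowest-locant set of ``k`` methyls on the
    C(total-k) parent chain, scored as ``|P & O| - penalty * |P ^ O|`` where
    P is the predicted and O the observed ion set.  ``k`` is ``k_hint`` when
    given, otherwise 0 for an empty observation and 1..``max_branches``
    otherwise.  The result is *ambiguous* when the top score is tied or the
    top prediction does not account exactly for the observed ions (partial
    evidence), and *unresolved* when no candidate scores positive.
    """
    total_c = _carbon_count(parent)
    observed = frozenset(int(m) for m in enhanced)
    ks = ([int(k_hint)] if k_hint is not None
          else [0] if not observed else list(range(1, max_branches + 1)))
    scored: list[ScoredCandidate] = []
    for k in ks:
        chain = total_c - k
        if chain < 3 or (k > 0 and chain - 2 < k):
            continue
        if k == 0:
            pools: Iterable[tuple[int, ...]] = [()]
        else:
            pools = (
                locs for locs in itertools.combinations(range(2, chain), k)
                if locs == _canonical_locants(chain, locs)
            )
        for locs in pools:
            s = CandidateStructure(chain + k, chain, locs)
            pred = set(predict_diagnostic_ions(s).ions)
            score = len(pred & observed) - penalty * len(pred ^ observed)
            scored.append(ScoredCandidate(s, score, tuple(sorted(pred))))
    scored.sort(key=lambda c: (-c.score, c.structure.branch_count,
                               c.structure.branch_positions))
    if not scored:
        return InferenceResult((), tuple(sorted(observed)), False, True)
    top = scored[0]
    exact = frozenset(top.predicted) == observed
    tied = len(scored) > 1 and abs(scored[1].score - top.score) < 1e-12
    resolved = top.score > 0 or (not observed and exact)
    ambiguous = tied or not exact
    return InferenceResult(tuple(scored[:50]), tuple(sorted(observed)),
                           resolved, ambiguous)


def name_structure(structure: CandidateStructure) -> str:
    """Field-style name: ``Hexacosane``, ``9-methylnonacosane``,
    ``5,9-dimethylhentriacontane``; ambiguous structures get ``*-``."""
    if structure.unsaturation == 1:
        return alkene_name(structure.total_carbons)
    if structure.unsaturation != 0:
        raise UnsupportedStructureError("only alkanes and monoenes are named")
    return branched_name(structure.parent_chain_length, structure.branch_positions,
                         ambiguous=structure.ambiguous)


def parse_structure_name(name: str) -> CandidateStructure:
    """Inverse of :func:`name_structure` for fully specified saturated names."""
    chain, locants = parse_name(name)
    return make_structure(chain, locants)


def resolve_compound(parent: ParentAssignment,
                     enhanced: Sequence[int],
                     ri: float,
                     curves: BranchCurves | None,
                     retention_time: float = float("nan"),
                     peak_id: str = "",
                     penalty: float = DEFAULT_SCORE_PENALTY,
                     ri_tolerance: float = _rc.DEFAULT_RI_TOLERANCE) -> CompoundRecord:
    """Compose one identification: curve-based branch count, ion-based
    locants, RI cross-check, and a named record with status flags.

    The reference curves supply a branch-count hypothesis; the enhanced
    ions decide the locants.  When unconstrained ion evidence scores
    strictly better at a different branch count, the ions win and a
    ``branch-count-conflict`` flag records the disagreement.  Errors are
    collected as flags, never raised, so a run always yields a table row.
    """
    flags: set[str] = set()
    ri_int = round_ri(ri)
    if parent.carbon_count is None:
        return CompoundRecord(retention_time, parent.parent_mz, None,
                              "unidentified", ri_int, peak_id,
                              frozenset({"no-molecular-series"}))
    if parent.unsaturation == 1:
        # double-bond position is out of reach of the branch-ion rules
        return CompoundRecord(retention_time, parent.parent_mz, parent.molecular_formula,
                              alkene_name(parent.carbon_count), ri_int, peak_id,
                              frozenset({"double-bond-position-unassigned"}))
    if parent.ambiguous:
        flags.add("weak-molecular-ion")
    total_c = parent.carbon_count
    k_hint: int | None = None
    if curves is not None:
        try:
            k_hint, _ = _rc.estimate_branch_count(curves, ri, total_c)
        except ChcidError:
            flags.add("no-reference-curve")
    else:
        flags.add("no-reference-curve")

    hinted = infer_branch_positions(total_c, enhanced, k_hint=k_hint, penalty=penalty)
    free = infer_branch_positions(total_c, enhanced, k_hint=None, penalty=penalty)
    result = hinted
    if k_hint is None or free.top_score > hinted.top_score + 1e-12:
        if k_hint is not None:
            flags.add("branch-count-conflict")
        result = free

    structure = result.top
    if structure is None or not result.resolved:
        annotation = f"enhanced ions: {list(result.observed)}" if result.observed else ""
        return CompoundRecord(retention_time, parent.parent_mz,
                              parent.molecular_formula,
                              f"unresolved C{total_c} alkane", ri_int, peak_id,
                              frozenset(flags | {"unresolved"}), annotation)
    if result.ambiguous:
        flags.add("position-ambiguous")
    annotation = ""
    if result.ambiguous and structure.branch_positions:
        annotation = f"possibly {','.join(map(str, structure.branch_positions))}-"
    if curves is not None and curves.evaluable(total_c, structure.branch_count):
        _, ok = _rc.consistency_check(curves, ri, total_c, structure.branch_count,
                                      tolerance=ri_tolerance)
        if not ok:
            flags.add("ri-branch-mismatch")
    return CompoundRecord(retention_time, structure.molecular_mass,
                          structure.formula, structure.name, ri_int, peak_id,
                          frozenset(flags), annotation)
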