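# Methods

## The identification model

The package targets saturated linear and methyl-branched hydrocarbons in
GC-EI-MS runs of insect-derived samples (cuticular washes, trophallactic
fluid), measured on a unit-resolution quadrupole with an apolar column and
a co-run C8–C40 n-alkane ladder. Identification of one chromatographic
peak proceeds through five stages, each with an explicit contract and
failure mode; per-peak failures become row status flags so a run always
produces a complete table.

### Retention index

Temperature-programmed (van den Dool & Kratz) linear interpolation between
ladder anchors, with the retention index at an anchor equal to 100 × carbon
number by definition. Segments scale by `100·Δcarbons`, so a ladder with a
missing alkane (for example no C21 between C20 and C22) still assigns both
anchors exactly; this gap handling is required to reproduce integer RIs of
peaks eluting inside such gaps. Outside the ladder span the terminal
segment is extended linearly and the value is flagged `extrapolated`.
Reported RIs are rounded half-up to integers; full precision is kept
internally. The isothermal logarithmic Kovats formula is deliberately not
used: the curated table's interpolated rows (1541, 1956, 1992, 2020)
reproduce exactly under linear interpolation. One row of that table (the
17.06-min methylheptadecane, printed RI 1742) interpolates to 1743 from
the in-table anchors; the discrepancy is consistent with the published
anchors coming from a separate ladder run and the row is documented as
out-of-tolerance evidence, not used as a reproduction target.

### Parent ion

After optional background subtraction (ion-by-ion within the m/z
tolerance, floored at zero), the molecular ion is the highest-m/z credible
ion (≥ 0.5% of the base peak by default) whose nominal mass lies on the
alkane (14C+2) or monoene (14C) series. Because the molecular ion of long
alkanes is genuinely weak — often below any sensible relative floor — the
floor is relaxed when no credible on-series ion exists, and the resulting
call is flagged ambiguous (`weak-molecular-ion`). A spectrum with no
on-series ion at all yields an ambiguous assignment with no formula, and
the row is reported unidentified rather than guessed.

### Envelope fit and enhanced ions

The alkyl series is read at every nominal m/z ≡ 1 (mod 14) from 57 to
M−15; ions below 57 (41/43/55) deviate from the exponential for every
alkane and are excluded by construction. Missing ions are recorded as
absent, not zero. The fit `I = A·e^(−λm)` is ordinary least squares on log
intensities — the estimator is linear in that space, so no iterative
nonlinear fitter is needed — followed by one mask-and-refit pass: points
with observed/predicted above the mask threshold (default 2, the same as
the detection threshold) are removed and the fit redone, so genuinely
enhanced ions do not lift the baseline they are measured against. Enhanced
ions are the points at or above the ratio threshold, excluding everything
within 30 Da of the parent (M−15 and M−29 are rearrangement-dominated and
carry no branch information, which also means branches at locants 2 and 3
are not ion-detectable; they surface only through the RI curves, flagged
low-confidence).

### Branch count from reference curves

Reference RIs are averaged per (carbon count, branch count) cell —
arithmetic means, exactly as a database extraction would be condensed —
and a least-squares line per branch count serves as fallback between
carbon counts with no cell. The estimated branch count is the argmin of
the absolute residual, ties broken toward fewer branches (parsimony). The
consistency band is 15 RI units by default: per-branch position effects
span roughly ±10 units around a cell mean while adjacent curves sit ~55
units apart, so 15 separates curves cleanly without rejecting ordinary
positional variation.

### Branch positions from diagnostic ions

For a branch at locant p on an n-carbon chain, cleavage of either C–C bond
flanking the branch carbon keeps the charge on the branch-containing
(secondary-cation) fragment. Counting the carbons of each cleavage product
(including every methyl the fragment carries) gives the near-end ion
`14(p+1)+1` and its far-side complement; for a monomethyl the pair sums to
M+28. Candidate locant sets of the hypothesized size are enumerated
exhaustively in lowest-locant canonical form and scored
`|P∩O| − 0.5·|PΔO|` against the observed ions. The reported structure is
ambiguous (leading `*-`, with a "possibly …" annotation) when the top
score is tied **or** when the top prediction does not account exactly for
the observed ions — a single enhanced ion is treated as partial evidence,
not proof. When no candidate scores positive the row is reported
unresolved, carrying the raw ion list.

Two structural facts of this ion algebra are worth knowing. First, the
ion set of a dimethyl {p, q} on an n-carbon chain is identical to that of
{p, n−q} whenever p + q < n, so many spread-out dimethyls are intrinsically
isobaric by ions alone; this is why real CHC tables carry so many
`*-dimethyl` entries. Second, ties can cross branch counts (e.g. the pair
{141, 309} on C30 fits both 9-methylnonacosane and
9,20-dimethyloctacosane); the RI-derived branch-count hint is what breaks
such ties. In the composed resolver the curves supply the hint, the ions
decide the positions, and when an unconstrained search scores strictly
better at a different branch count the ions win and a
`branch-count-conflict` flag records the disagreement — the curves are a
check, not a veto.

## Synthetic data: what it emulates and what it does not

The generator inverts the identification model: series intensities
`A·e^(−λm)` (defaults A = 10⁶ counts, λ = 0.012 /Da), diagnostic ions
multiplied by an enhancement factor ε = 3 before noise, a molecular ion at
half the envelope value at M, and additive Gaussian noise truncated at
zero (default SD 1% of A). Retention times come from a quadratic
RI→minutes map (slope 0.0119 min/RI, small positive curvature) so the
piecewise-linear calibration is exercised against a non-affine truth; the
defaults place C15 near 13 min and C38 near 50 min, matching typical CHC
temperature programs. True RIs follow a deterministic rule — each branch
lowers RI by 40 + 2·min(p, n+1−p, 10) units, saturating at 60 for internal
positions — and the generated reference table is built from the same rule,
so curves and compounds are mutually consistent in the way a good database
extraction would be.

Only the fitted 14n+1 alkyl series plus the molecular ion are simulated;
the odd-electron 14n series, isotope clusters, alkenes, oxygenates and
chromatographic peak shapes are not. Noise is additive and homoscedastic.
`generate_dataset` samples structures whose diagnostic ions fall inside
the observable window (locants in [4, chain−3], which keeps every ion in
[71, M−30]) and whose ion set identifies the isomer uniquely at its true
branch count, resampling otherwise, with carbon counts 21–31 by default —
the upper bound is where the simulated molecular ion stays findable under
the default envelope, and the range covers the ≥C27 window where the
abundant natural compounds sit. Passing tests on this generator therefore
demonstrate correctness of the algebra and the pipeline plumbing, not
robustness to co-elution, heteroscedastic noise, or ion-ambiguous isomers
— on real data those cases surface as flags and `*-` names rather than
wrong confident answers.

## Validation ensembles and problem sizes

The exhaustive prediction-vs-cleavage-oracle check covers every canonical
structure up to C33 with up to three branches (tens of thousands of
structures; the oracle enumerates bond cleavages on the molecular graph,
independently of the composition formula). End-to-end recovery uses 50
noise-free compounds with 0–2 branches, which must recover 100% exactly.
The noisy detection benchmark uses 200 monomethyl spectra at ε = 3 and
noise SD 2% of A, sizes C16–C20: at these settings every envelope ion
stays at or above twice the noise SD (a limit-of-quantification argument —
`A·e^(−0.012(M−15)) ≥ 2σ` requires M ≲ 283), so the benchmark measures the
detector rather than the physics of ions buried below the floor; required
recovery of the exact planted pair is ≥ 95%. For larger alkanes at that
noise level the far diagnostic ion drops below quantifiable intensity and
exact-pair recovery is information-theoretically impossible; realistic
instrument noise floors are far lower relative to the base peak.

## Numerical choices and degenerate inputs

Nominal (integer) masses throughout; centroids bind to nominal targets
within 0.3 Th. Fits require ≥ 4 positive envelope points; non-positive
intensities are dropped, a constant envelope legitimately fits λ = 0, and
the refit is skipped if masking would leave fewer than 4 points. Ladders
need ≥ 2 anchors after de-duplication; equal retention times or duplicate
carbon numbers with conflicting times are inversion errors naming the
offending pair. Rounding of reported RIs is half-up. All thresholds live
in `PipelineConfig` (YAML-loadable; CLI flags override).

## Known limitations

Double-bond positions in alkenes are never assigned (rows are named
`*-…ene`); 2- and 3-methyl branches are not ion-detectable by design of
the exclusion windows; co-eluting compounds are flagged by retention-time
proximity but not deconvolved; the packaged reference table is synthetic
and a user-supplied CSV of real literature values should replace it for
real analyses; mzML input is not supported (no reader available in the
supported dependency set) — spectra travel as NIST MSP text.
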