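# Methods

This note documents the models, parameters, numerical choices, and known
limitations behind `pyranoshift`.

## Data model

A compound is a set of `(label, δ/ppm, carbon_class)` records, tagged
`experimental` or `calculated`. Shifts are stored at the precision given
(typically one decimal); rounding to 0.1 ppm happens only at presentation.
Labels follow IUPAC xanthone numbering (C-1…C-8, C-4a, C-8a, C-9, C-9a,
C-10a) with pyran carbons C-1′/C-2′; an alias map collapses typographic
primes and double primes (C-1″ → C-1′), because literature sources disagree
on priming while the correction factors are keyed to these positions.
Structures are represented only by subtype codes — type letter A–D
(prenylation at C-1…C-4) plus two digits (pyran-oxygen carbon; position of
an additional oxygenated substituent, 0 = none); dual codes mark two pyran
rings. No connection tables or SMILES are in scope.

Solvent is recorded but not used in scoring; cross-solvent comparisons only
warrant caution, not rejection, and the reference data this targets are
dominated by CDCl₃.

Duplicate labels inside an entry are rejected unless flagged
`intensity_note="double"`: a double-intensity signal misread as one line is
represented as the same ppm value repeated under the two labels it actually
covers, which is sufficient for alignment without special matching
machinery.

## Boltzmann averaging

Calculated shifts for flexible molecules are conformer-population averages:
w_i ∝ exp(−(E_i − min E)/(R·T)), δ̄ = Σ w_i δ_i per label, with
R = 8.314 J mol⁻¹ K⁻¹, T = 298.15 K by default, and energies accepted in
kJ/mol only. Weights are computed from energy differences, so any constant
energy offset cancels; the exponentials are max-shifted before
normalization for stability. One conformer reproduces its table exactly;
T → ∞ recovers the unweighted mean.

## Empirical correction factors

GIAO predictions for pyranoxanthones carry systematic position-specific
errors: calculated values run high at the carbonyl-peri carbons C-1/C-8 and
at the pyran olefinic C-1′, and low at C-2′. Corrections are additive per
*correction class*:

    offset(class) = mean(δ_exp − δ_calc)   over matched carbons
    δ_corrected   = δ_calc + offset(class)

C-1 and C-8 are pooled into one class (`C1_C8`): they occupy symmetric peri
positions and show near-identical deviations. Because the record-level
carbon classes carry no peri category, the class key is derived from the
normalized label (C-1/C-8 → `C1_C8`; otherwise the spectral class). The
packaged defaults are the gathered-set values −2.9 / −3.7 / +2.8 ppm;
deriving fresh factors from user pairs overrides them, and per-type (A–D)
scopes are supported but not default — a single gathered scope is simpler
and more broadly applicable. The mean is untrimmed (no outlier rejection
before averaging); n and sd are reported per class, classes with no matched
carbons are omitted with a warning rather than zero-filled. Applying
factors to their own derivation set zeroes the class-wise mean residuals
identically, and the estimator is location-equivariant. No slope/intercept
rescaling of calculated shifts is performed in the default path (the
correction model is additive); a Goodman-style linear rescale is available
as an opt-in flag in ranking.

## Scoring and DP4

Deviations Δ = δ_corrected_calc − δ_exp are computed on shared labels after
alias normalization; unshared labels are listed as excluded. Corrections
are applied before DP4 by default (the workflow's convention; the rescaling
alternative is off by default). Per candidate:

* RMSD = √(mean Δ²) and max |Δ| with its label;
* DP4: P(c) ∝ Π_k S_t(|Δ_k|/σ; ν), Student-t survival function, defaults
  σ = 2.306 ppm and ν = 11.38 (the published ¹³C parameters of the method;
  both configurable). Likelihoods are summed as `t.logsf` terms and
  renormalized from log space, so products that underflow direct floating
  point are still ranked correctly; only if *all* candidates underflow even
  in log space is a numeric error raised.
* single-outlier flag: the max-|Δ| label is flagged iff max |Δ| ≥ t_major
  (default 5.0 ppm) and the second-largest |Δ| ≤ t_rest (default 3.0 ppm),
  with RMSD recomputed excluding it. The thresholds are heuristics chosen
  so that the narrated pattern — one ~8 ppm deviation against otherwise
  ≤3 ppm residuals, suggesting a typo, misread spectrum, or contamination —
  is flagged while ordinary error spread is not. At least 3 shared carbons
  are required for the pattern to be meaningful.

Ranking is deterministic: DP4 descending, then RMSD, then candidate id.

## Subtype markers and classification

The marker table (`markers.json`) assigns each subtype diagnostic ¹³C
expectations for carbons adjacent to the pyran ring (the pyran-bonded
oxygenated core carbon, both olefinic methines), the carbonyl, and one
subtype-characteristic aromatic CH. Narrative-anchored values (B31 methines
115.8/127.0; B13 CH-2 91.5 vs D31 ≈98; A20 core carbon 151.7 vs C40 ≈141;
carbonyl cases 176.1/180.5/183.0) are used verbatim; the remaining
complement is **curated by the package** for subtype separability — in
particular each subtype carries exactly five markers so that
fraction-matched comparisons across subtypes are like-for-like, and the
fifth (free aromatic CH) values are placed in spectral regions ≥3 ppm clear
of all other markers. These complements are stylized working values, not
literature transcriptions, and the same caveat applies to the generator
scaffold below. Subtypes lacking ¹³C data in the source classification
(B14, B30, C20, C42) are excluded from the table rather than given wide
tolerances, so claiming them raises a lookup error.

Classification greedily matches each marker to the nearest unconsumed shift
(ties toward the lower value) within tolerance — simple and adequate for
five markers per subtype — and ranks subtypes by (fraction matched
descending, mean absolute marker deviation ascending, code). Matching is
value-based, deliberately ignoring the literature labels under audit. The
default tolerance is ±1.5 ppm per marker (matching cases in the underlying
data agree to ~1 ppm; mismatches are ≥6 ppm), overridable per marker. No
subtype is asserted when the best fraction falls below 0.6. Entries with
two pyran rings are classified in two passes, removing consumed shifts
between passes. Tightening tolerances can only decrease match counts
(monotonicity), and classification is invariant to shift-row order.

The carbonyl doubles as an H-bond probe: <178 ppm → no intramolecular
H-bond, 178–184.5 → one, >184.5 → two. The interior boundaries interpolate
between the ~176 and ~186 ppm anchors using the narrated one-bond cases
(180.0, 183.1 ppm); both are configurable.

## Dereplication

Shift-multiset search uses an exact dynamic program over the two sorted
lists with a lexicographic objective: maximize pairs with |q − r| ≤
tolerance, then minimize Σ|q − r|. For points on a line an optimal matching
can be taken order-preserving (a crossing exchange never increases the
objective), so the DP is exact; tests verify it against an independent
Hungarian-assignment oracle. Default search tolerance is 0.5 ppm
(literature matches show sub-1-ppm deviations); hits below a configurable
matched fraction are dropped. Conflict auditing flags pairs whose spectra
match at ≥90% overlap with mean |diff| ≤ 1.0 ppm but whose structures
differ (class 1), and entries sharing a compound name whose spectra fail
that test (class 2). Swapped-assignment detection is label-aware and
searches only single transpositions — the narrated failure mode (reversed
C-8a/C-9a) — reporting pairs whose exchange improves Σ|δ_a − δ_b| by at
least 1.0 ppm. It is O(n²) and returns nothing for identical entries. The
matcher is a stated stand-in for external database scoring, whose internals
are not public; substructure search is approximated by subtype-code
filtering, since no molecular graphs are in scope.

## Synthetic data

The generator defines the study conditions under which the pipeline is
validated:

* an experimental compound of subtype S = S's five marker expectations, one
  prenylation-site quaternary carbon, and a fixed stylized xanthone
  scaffold (11 filler carbons: label → base ppm in
  `synthetic_scaffold.json`), each perturbed by independent Gaussian jitter
  (default σ = 0.8 ppm);
* its calculated counterpart adds the class offsets calc − exp = +2.9
  (C-1/C-8), +3.7 (C-1′), −2.8 ppm (C-2′) plus independent residual noise
  (default σ = 1.0 ppm, matching the scale of post-correction scatter the
  additive model assumes);
* a modeling set draws subtypes uniformly over the marker table, n = 76 by
  default — the modeling-set size of the underlying study;
* misassignment cases generate from one subtype and label with another,
  warning when the two marker sets are indistinguishable within tolerance.

Design choices worth flagging. Filler carbons use *fixed shared base
values* rather than per-entry uniform re-draws: experimental entries,
calculated candidates, and reference models must share a deterministic
baseline, or candidate deviations would be dominated by generator noise
instead of the subtype marker differences the workflow discriminates on.
Scaffold values are kept ≥3 ppm from every marker so filler signals cannot
satisfy foreign-subtype diagnostics. The per-subtype prenylation
quaternaries (e.g. B31: quaternary C-2 + methine C-4; D31 the reverse) make
regioisomer models differ where real regioisomers differ — without them,
DP4 between B31 and D31 candidates is capped near 0.9 even at zero noise —
but they are deliberately not diagnostic markers, so classification rests
on the marker table alone. Noise is independent Gaussian per carbon, the
simplest model consistent with a mean-offset correction; a heavier-tailed
Student-t option (ν = 11.38, matching the DP4 error model) is available.
No within-compound error correlation is modelled, and conformer ensembles
or realistic DFT error correlation beyond class offsets are out of scope.
Every generator is a pure function of (config, seed).

What passing synthetic tests do **not** show: performance on real spectra
with solvent/referencing shifts, overlapping signals, missing quaternary
carbons, or impurity peaks; nor fidelity of the stylized scaffold and
curated marker complements to any individual literature compound.

## Pipeline verdict rule

The underlying revision decisions were expert judgements without a stated
numeric cutoff; the pipeline makes the rule explicit (and configurable):

* **reassign** — a non-claimed candidate tops the DP4 ranking with P ≥ 0.95,
  or a dereplication hit matches at ≥ 0.9 overlap while the claimed subtype
  has ≥1 marker violation;
* **unresolved** — violations exist but nothing passes and the claimed
  candidate (if any) is not top-ranked;
* **consistent** — otherwise. Jitter-level single-marker misses with a
  top-ranked claimed candidate do not flip the verdict.

Dereplication runs even when the consistency check passes, since data
conflicts are found that way. Stage order is fixed; the pipeline is
deterministic, and a reassignment always cites its evidence (DP4 score or
hit id). Reports serialize losslessly to JSON with full provenance
(thresholds and correction offsets used).

## Validation problem sizes

The shipped checks use: 100 synthetic modeling sets of n = 76 with σ = 1.0
for correction-factor recovery (mean absolute error ≈ 0.08 ppm, bound
0.18 ≈ 1.5·σ/√76); 500 random ≤8-shift instances for matcher/oracle
agreement; 200 draws per subtype at 0.8 ppm jitter for classifier recovery
(≥95% required, ≥98% observed); and a 200-case benchmark (100 consistent
across all subtypes, 100 misassigned over ten strongly marker-distinct
subtype pairs, jitter 0.8 / noise 1.5) for verdict accuracy (≥90% required,
96–99% observed across seeds). These sizes keep the whole validation under
a minute on one CPU while leaving the statistical bounds comfortably
non-trivial.

## Known limitations

* The registry and modeling-set catalog are curated from running text; the
  catalog's 50 unnamed entries are subtype/sequence placeholders
  (`curation: "placeholder"`), and per-case RMSD values printed only in
  tabular figures of the source are not reproduced here.
* Marker complements and the generator scaffold are stylized (see above).
* No ¹H scoring, no DP4+/DP5 (would require shielding ensembles), no
  conformer generation — conformer energies and candidate shift sets are
  inputs, not products.
* Dual-pyran classification is a two-pass heuristic; overlapping marker
  windows between the two rings can shadow each other.
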