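# Methods

`repeatcc` analyses homopolymeric glutamine (polyQ), alanine (polyA) and
strictly alternating glutamine–alanine (polyQA) repeats in proteomes,
their statistical association with coiled-coil (CC) domains, and the
design and biophysical characterization of CC-forming repeat peptides.
This note records the models, conventions, parameter choices and known
limitations.

## Repeat detection

A protein is scanned for three kinds of maximal runs, each with a
minimum length `min_len` (default **4 residues**, the threshold defining
the Q4/A4/QA4 protein classes):

* **Q / A homopolymers** — maximal runs of a single letter; maximal
  runs of the same letter can neither overlap nor abut.
* **QA alternation** — maximal strictly alternating Q/A runs in either
  phase (`QAQA…` or `AQAQ…`) that contain both letters. The "tandem
  repeat" reading (at least four *QA units*) is recovered by setting
  `min_len = 8`; the default follows the at-least-four-*residues*
  convention used for the other two classes.

Coordinates are 0-based half-open everywhere; exporters add 1-based
columns only where a format dialect requires them. Ambiguity and rare
letters (X, U, B, Z) never match Q or A and always break runs — a
conservative choice, since treatment of such codes in low-complexity
scans is rarely specified. A residue may belong simultaneously to a
homopolymer run and a QA run (`QQQQAQA` is Q4 and, given length, QA4);
the class flags are independent memberships by design.

## Coiled-coil tracks and segments

CC evidence enters as per-residue P-score tracks (lower = stronger CC
prediction), the output format of pairwise-correlation CC predictors
such as Paircoil2. The predictor is **consumed, never called**: any tool
emitting `(position, residue, p_score)` rows can drive the pipeline.
Segments are maximal runs of residues with `P < p_threshold`
(default **0.05**, strict inequality, so `P = 0.05` is not CC);
unscored residues break segments, and proteins below a predictor's
minimum length simply carry all-missing tracks and count as non-CC. A
protein is a *CC protein* iff it has at least one called segment. No
minimum segment length is imposed beyond thresholding (predictor
windows already smooth the score); `min_seg_len` exists for sensitivity
analyses.

For self-contained testing a **naive heptad scorer** produces
pseudo-P-scores from windowed hydrophobic periodicity: within a
centered window (default 21 residues) every heptad frame is tried and
the fraction of a/d core positions occupied by {L, I, V, M, F, A, Q} is
taken; pseudo-P is one minus the best fraction. It is deliberately
crude plumbing — monotone in core occupancy, which is exactly what the
design-rule ordering tests need — and is not a substitute for a real
predictor on biological sequences (no pairwise residue correlations, no
solvent-face weighting, A/Q treated as core-compatible by construction).

## Enrichment statistics

All percentages are kept on the 0–100 scale.

* **Co-occurrence.** For classes A and B with counts `n_A`, `n_B` in a
  proteome of `N` proteins, the independence null expects
  `E = n_A·n_B/N` joint members; the reported enrichment is
  `ratio = n_AB/E`. Significance is a chi-squared test with Yates'
  continuity correction on the 2×2 membership table (df = 1,
  two-sided). Fisher's exact test is available (`method="fisher"`) for
  tiny fixtures where the chi-squared approximation is poor. Counts,
  not rounded percentages, feed every test. Zero margins yield a
  flagged result instead of an exception.
* **CC association** applies the same test with B = CC proteins.
* **Repeat/CC overlap.** Per protein, union residue masks of all called
  CC segments (length `cc_len`) and of repeat runs (length `rep_len`,
  all kinds combined or filtered to one kind) give the observed overlap
  `|CC ∩ repeat|`. The chance expectation uses relative lengths:
  `E_overlap = cc_len · rep_len / L` for a protein of `L` residues.
  Proteins are then dichotomized at an overlap of
  `overlap_threshold` (default **4**) residues, and the number of
  proteins with observed ≥ 4 is compared with the number expected ≥ 4
  by a Yates-corrected goodness-of-fit chi-squared. Proteins lacking
  either feature are excluded by default (an inclusion flag exists for
  sensitivity analysis); a dichotomy with zero or saturated expected
  counts is flagged undefined rather than tested.
* **Permutation oracle.** The relative-length expectation is validated
  by uniformly re-placing both segment sets at random non-overlapping
  integer positions and measuring mean overlap. For segments short
  relative to `L` the formula is unbiased within Monte-Carlo error
  (measured combined z ≈ 0 over 50 random configurations at 10⁵
  placements); for segments whose length is comparable to `L`, discrete
  edge effects make the true mean exceed `cc_len·rep_len/L` by
  a relative O((cc_len+rep_len)/L) — this divergence is a documented
  property, not an error, and the oracle exists precisely to quantify
  it.
* **Scalar metrics.** `%A4/%Q4` (the phylogenetic trend statistic) and
  the normalized co-occurrence `%(Q4∩A4)/(%A4)²`, both NaN-flagged when
  the denominator class is empty.
* **Phylogenetic correlation.** Pearson r (with r² and the two-sided
  p-value against zero correlation) of a per-species metric versus
  divergence time from *Homo sapiens* in millions of years. Divergence
  times are user configuration — the package ships an editable example
  table (`simulate.EXAMPLE_DIVERGENCE_MYA`, TimeTree-style values) that
  is input, not output. Constant inputs are flagged undefined.

## Synthetic data

Generators are pure functions of a spec plus a seed (bitwise-identical
reruns); a root seed fans out to stage seeds via `SeedSequence.spawn`.
Ground truth is always re-derivable by running the analysis stage on
the generated data, and the test suite enforces these closures.

* **Proteomes.** Protein count, a log-normal length law (default median
  ≈ 375 aa, clipped to [60, 5000]), SwissProt-like background residue
  frequencies, and planted per-protein repeat classes: P(Q4) = 0.0229
  and P(A4) = 0.0773 by default — the occurrences reported for the
  human proteome — with P(Q4 ∩ A4) = f·P(Q4)·P(A4) for a tunable
  co-occurrence factor f (default 2.0: a clear but moderate
  over-representation; the source screen reports significance, not an
  effect size) and P(QA4) = 0.02 independently (not printed either).
  Planted run lengths are 4 + (Geometric(0.35) − 1). Backgrounds are
  scrubbed of accidental Q4/A4/QA4 runs by targeted rejection
  (re-drawing a run-internal residue from non-Q/A letters), and planted
  runs get run-breaking flanks, so planted prevalences are *exact*
  ground truth at the cost of a slightly non-i.i.d. background — for
  calibration tests exactness beats distributional purity. A flags-only
  fast path (`draw_repeat_flags`) draws class memberships without
  sequence synthesis; it is exact for membership statistics and is what
  the type-I-error and factor-recovery calibrations use at
  n = 20 000 × 1000 replicates. Yates' correction is mildly
  conservative at these margins (measured type-I ≈ 0.04 at n = 20 000
  and ≈ 0.03 at n = 5 000), which is why calibration is run at the full
  proteome size rather than scaled down.
* **CC tracks.** Per protein, with probability `p_cc` one segment
  (uniform length 21–49 by default) receives P ~ U(0, 0.04) against a
  U(0.2, 1) background, so calling at 0.05 recovers planted boundaries
  exactly. With probability `overlap_bias` the segment is centered on a
  planted repeat run; bias 0 gives null placement, bias 1 maximal
  repeat/CC overlap. Segments longer than a protein are shrunk, never
  silently dropped.
* **Phylo series.** `value = intercept + slope·mya + N(0, noise_sd)`,
  for correlation fixtures with a closed-form target
  ρ = slope·sd(mya)/sd(value).
* **CD fixtures.** A basis combination, not a physical model: a
  two-Gaussian helix basis (minima at 208/222 nm, solved to hit a
  target 222/208 ratio at −30 000 deg·cm²·dmol⁻¹ depth) mixed with a
  coil basis (single 200-nm minimum) by a helix weight, converted to
  raw instrument millidegrees by inverting the MRE formula so that the
  reduction round-trips.

Because the generators plant clean repeats and rectangular CC segments,
passing tests demonstrate correctness of the *statistics and plumbing*,
not performance on real proteomes: real repeats are interrupted, real
P-score tracks are smooth and length-correlated, and real proteome
percentages depend on the database release. The headline numbers of the
original screen (e.g. 2.29 %/7.73 % Q4/A4 occurrence in human, A4/Q4
ratio rising 0.58 → 3.37 across six species, CC association 1.3–2.2×,
≥4-residue overlap 10–16×) therefore require the actual UniProt
proteomes plus a real CC predictor and are deliberately out of
desk-scale scope; the pipeline logs exactly those statistics so a
real-data run can be compared directly.

## Peptide design rules

The heptad register (positions a–g; a/d hydrophobic core) is anchored
on user-asserted core residues — canonically the valines immediately
flanking a polyQ/polyA region — by choosing, among the seven frames,
the one satisfying the most anchors (ties to the smallest frame);
unsatisfiable anchors are reported, not fatal. Variants:

* **cc+**: the first 2·n_heptads a/d positions inside the target
  region are substituted with CC-stabilizing hydrophobics, a → L and
  d → V by default. Published mutants whose exact per-site letters are
  known are reproduced via per-site overrides rather than guessed.
* **cc−**: prolines at the first n_sites a/d positions.
* **polyA length variants**: ±k alanines applied at the C-terminal end
  of a run (placement inside a homopolymer is unobservable in the
  product sequence); re-scanning the variant yields the base run length
  plus the delta.

Every variant records its substitutions/indels, and re-applying them to
the base must reproduce the variant exactly (enforced at construction).

## CD data reduction

Mean residue molar ellipticity uses the standard convention

    [θ] = θ · mw / (10 · (n − 1) · c · pl)

with θ in millidegrees, mw the peptide molecular weight (g/mol), n the
residue count (n − 1 peptide bonds), c in mg/ml and pl in cm; the
frequently typeset one-line form "θ × mw/10 × (n−1) × c × pl" is
dimensionally meaningful only with (n−1), c, pl in the denominator,
which is how it is implemented. The 222/208-nm ratio uses linear
interpolation to exactly 222 and 208 nm (grids with no sample within
1 nm of a target are flagged sparse). Classification: **CC-like** iff
ratio ≥ 1 with both values negative; **single-helix** for negative
minima with 0.25 ≤ ratio < 1 (dissociated helices, e.g. under TFE);
**non-helical** otherwise (the random-coil signature of a lone ~200-nm
minimum with negligible 222-nm signal — the 0.25 cut is a heuristic
chosen well below any helical spectrum's ratio). Thermal melts are
normalized by the 222-nm value at the point nearest the reference
temperature (default 5 °C, the folded baseline), making the reference
exactly 1.0; normalization is idempotent and scale-invariant.

## Numerical and degenerate-input conventions

Undefined statistics (zero margins, constant correlations, zero or
saturated expected dichotomies, θ₂₀₈ = 0) return NaN values with an
explanatory note instead of raising, so multi-species sweeps never die
on one degenerate proteome; malformed *inputs* (inconsistent counts,
out-of-range P-scores, invalid residues) raise with the offending
position or row named. Chi-squared corrections clip at zero
(`max(|O−E|−0.5, 0)`), matching the textbook definition.

## Problem sizes

Default verification sizes were chosen so the whole suite runs in well
under a minute of statistics: oracle-equivalence sweeps use 1000 random
sequences/tracks; the overlap null model uses 50 configurations × 10⁵
placements (vectorized interval arithmetic, no masks); calibrations use
1000 replicates (type-I) and 200 replicates per factor (recovery) at
n = 20 000 via the flags-only path; end-to-end screens use six species
of several hundred proteins with full sequence synthesis. These sizes
are the package's own verification defaults; nothing in the statistics
depends on them.

## Known limitations

* Interrupted/imperfect repeats, non-Q/A homopolymers and DNA-level
  triplet structure are out of scope.
* The naive heptad scorer is a test harness, not a predictor;
  oligomeric state and parallel/antiparallel topology are never
  inferred.
* The relative-length overlap expectation ignores edge effects (see
  above) and within-protein positional structure (real CC domains and
  repeats are not uniformly placed).
* CD reduction performs no secondary-structure deconvolution, melting
  temperature fitting or instrument smoothing.
* The study-peptide sequences bundled for worked examples are
  reconstructions from the published textual description (module
  `peptides_synthetic`); their repeat composition is exact, their
  flanking residues are a faithful but synthetic reconstruction.
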