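# Methods

## Model

`loopcomp` treats CTCF-mediated loop formation as the outcome of four
independent requirements, multiplied into a per-pair probability
`p_ij = w_ij · p_i · p_j · D_ij · LC_ij`.

**Binding occupancy.** CTCF binding at site *i* follows the chemical
equilibrium `p_i = [CTCF] / ([CTCF] + K_d,i)`. The local dissociation
constant is not observable directly, so the ChIP-seq intensity `x`
(local signal divided by the genome-average signal) is taken as inversely
proportional to `K_d,i`, giving `p_i = x / (x + a)` with a single
dimensionless scale `a`, interpretable as the genome-average
`K_d/[CTCF]`. Fitted values near 8.5 are consistent in magnitude with the
in-vitro anchor `370 nM / 144 nM = 2.6` (affinity at the H19/Igf2 site
over nuclear CTCF concentration), allowing for weaker average affinity on
chromatin. A saturating alternative `p_i = tanh(a'·x)` is provided
(`binding_kind="tanh"`); its scale `a'` (default 0.1, chosen so a
mean-enrichment site gets a comparable occupancy) is fit independently of
`a` because the two parameterizations are not nested.

**Orientation.** Loop anchors prefer convergent motifs. Each "non-inward"
motif destabilizes the anchor complex by a factor `w > 1`:
weights 1, `1/w`, `1/w²` for convergent, tandem, divergent pairs.
The generalized form with independent weights `(w1, w2)` is supported and
reduces to the one-parameter model when unset.

**Distance.** A constant per-bp dissociation rate of translocating Cohesin
yields `D_ij = exp(−d_ij/λ)`, with `λ` the processivity (the expected loop
length, ~300 kb in imaging-based estimates; the default here is 3 Mb
because fits on interaction data push `λ` upward until the term is inert).
A power-law alternative `D_ij = (d_ij/kb)^−k` is included for comparison;
distances enter it in kb so the term stays ≤ 1 over the modelled range
(pairs are ≥ 1 kb apart in practice; the unit choice is a convention the
data does not pin down). `lam=None` disables the term.

**Loop competition (LC).** A formed loop blocks Cohesin translocation, so
any loop overlapping a formed one is suppressed. Two pairs compete when
their *open* midpoint intervals intersect — nested loops compete, loops
sharing only an anchor do not. This convention keeps the full model
consistent with its internal-site approximation (which counts strictly
internal sites) and resolves the boundary ambiguity deterministically.
The full term `LC_ij = Π_{mn∩ij≠∅}(1 − p_mn)` makes the model a fixed
point, solved by damped iteration (below). The approximation
`LC_ij = Π_{i<m<j}(1 − p_m)` — all sites strictly inside the loop are
unoccupied, regardless of their orientation, since occupancy rather than
loop geometry is what stalls Cohesin — avoids iteration and ranks pairs
nearly identically (Spearman ρ ≈ 0.98 on default landscapes; the two
agree within the acceptance threshold ρ > 0.9).

**Pass-through (WAPL knockout).** With Cohesin unloading impaired, Cohesin
resides longer and traverses boundaries with probability `s`; every
competition factor becomes `1 − (1−s)·p`. `s = 0` recovers complete
blocking, `s = 1` removes competition; `p_ij` is nondecreasing in `s`, so
called-loop counts and lengths grow with `s`, the knockout phenotype.
`s ≈ 0.4` is the regime reported to match knockout data.

## Fixed-point solver

The coupled system `p_ij = q_ij · Π_{mn∩ij≠∅}(1 − (1−s)·p_mn)` (with
`q_ij = w_ij p_i p_j D_ij`) is solved by successive over-relaxation:
`p_(k+1) = (p'_(k+1) + b·p_k) / (1 + b)` with relaxation rate `b`
(default 1.0), initialized at the base term `q`, converging when
`max|Δp| < tol` (default 1e-6, cap 500 iterations; non-convergence is
flagged, never silent). Convergence is insensitive to `b` over at least
`0.1–10`. Each sweep evaluates all per-pair competition products in
`O(P log P)` via prefix sums over endpoint-sorted pairs:
`log LC_ij = S_total − S[right ≤ left_ij] − S[left ≥ right_ij] − own term`,
exploiting the complement of the open-interval overlap relation. Products
of many `(1 − p)` factors are accumulated in log space with factors
floored at 1e-12 to avoid underflow on long ranges. Unit tests pin the
solver to the analytic two-pair solution `p = q/(1+q)` and to an
independent dense `O(P²)` enumeration oracle run to 1e-12 from multiple
initializations.

## Calibration

Parameters `(a, w, λ)` are fit by exhaustive grid search maximizing AUPRC
(average precision, step interpolation — the appropriate metric at class
imbalances of 1:20 and beyond; the model's nonlinear coupling makes
likelihood-based fitting impractical). Default grids bracket the reported
optima: `a ∈ {2, 3.5, 5, 6.5, 8, 8.5, 10, 12, 15}`,
`w ∈ {1, 1.5, 2, 2.5, 3, 3.5, 4, 5}`,
`λ ∈ {100 kb, 300 kb, 1 Mb, 3 Mb, none}`. Exact metric ties break toward
the smallest parameter values (disabled decay ordered last) so fits are
deterministic. Cross-validation partitions by chromosome (5 folds by
default) so training and test pairs never share a competition
neighborhood; besides per-fold argmaxes, the procedure reports a
**consensus optimum** — the argmax of the mean held-out metric surface
across folds (the aggregate optimization curve) — which is the stable
quantity to compare against the full-data fit when positives number in
the hundreds rather than tens of thousands.

## Synthetic data generator

The generator emulates one chromosome arm's worth of CTCF landscape per
"chromosome": geometric inter-site spacing (mean 25 kb, matching ~40
sites/Mb in site-dense regions), log-normal raw intensities (σ = 1.0),
i.i.d. strand orientations, and 10 chromosomes × 5 Mb × 200 sites by
default. Intensities are scaled so that mean `x` equals a configurable
peak enrichment over the genome-average signal (default 30; real ChIP
tracks are background-dominated, so site-level `x` far exceeds 1 and
occupancies at `a = 8.5` are substantial). Labels are drawn from the model
itself, by either of two mechanisms:

* `bernoulli_closed_form` — independent Bernoulli draws from the
  approximate-LC probabilities (a population-average picture; default).
* `occupancy_then_extrude` — a single-cell realization: occupancy sampled
  per site, then a left-to-right walk accepts candidate loops between
  occupied sites with probability `w_ij·D_ij` unless blocked by an
  overlapping accepted loop. `brute_force_pij` enumerates this process
  exactly (occupancy configurations × acceptance branches) on ≤ 12 sites
  and anchors the sampler's correctness; hand enumeration on a three-site
  chain is reproduced in the tests.

Positive PET counts are `1 + Poisson(25·p_ij)`, putting the median
positive near the count filters used on real data (≥ 4 supporting
read pairs). The default landscape yields ~600 positives of ~75,000
candidate pairs (≈ 1:120). This is intentionally *sparser* than the
1:20–1:40 ratios of deep ChIA-PET: model-consistent labels are bounded by
occupancy (the summed loop probability anchored at one site cannot exceed
its binding probability), whereas a sequenced cell population reports the
union of alternative loops across cells, so one site can appear in
several measured loops at once. Passing tests on this generator therefore
demonstrate internal consistency, parameter recoverability and the
direction of every perturbation effect — not the absolute AUPRC or class
ratio attainable on real interaction data. Other real-data features the
generator omits: clustered/correlated site spacing, orientation bias near
domain boundaries, technical noise in anchor coordinates, and
inter-chromosomal signal.

## Evaluation and analyses

* **Metrics.** AUPRC = average precision; AUROC via the rank statistic
  (ties averaged, equal to the normalized Mann–Whitney U, brute-force
  checked). Subsampling CIs: 10 repeats of 10% down-sampling, percentile
  interval. Predicted probabilities are also correlated (Pearson) with
  `log(1 + PET count)`; negatives enter with count 0.
* **Matched sampling.** For each positive, one negative with identical
  orientation class and `p_i·p_j` within a factor of 2, plus either
  `D_ij` (distance-matched, leaving competition free) or `LC_ij`
  (competition-matched, leaving distance free) within the same factor;
  sampling is seeded and without replacement, unmatched positives are
  dropped and counted, and every emitted pair's constraints are asserted
  post hoc. Distance-matching is meaningful only when scoring uses a
  live distance term (the analyses use λ = 300 kb for this purpose).
* **Enhancer–promoter constraints.** A link's span runs between element
  midpoints; a loop's span between anchor midpoints. A link *crosses* a
  loop when exactly one loop anchor midpoint lies strictly inside the
  link span ("crossing" has no standard formal definition; this
  operationalization is symmetric and translation-invariant) and is
  *contained* when both link endpoints lie strictly inside the loop span.
  True/false ratios per group use a Haldane +0.5 pseudo-count when a raw
  count is zero, reported alongside raw counts. Predicted-loop sets
  require an explicit probability threshold (no universal value exists;
  0.1 is the package default for loop calling).
* **Cell-type comparison.** Top-N loops by PET count per set
  (sequencing-depth control, N = 10,000 by default); a loop is shared iff
  both anchors overlap (≥ 1 bp) a loop of the other set.
* **Perturbations.** Deletion zeroes `x` but keeps the site row so
  competition bookkeeping stays explicit; inversion flips orientation
  only (unless a measured post-edit intensity is supplied); weakened-motif
  genotypes are modelled as intensity scaling (default factor 0.5 — real
  variant effects on binding are heterogeneous and not quantified here).
  The crossing/outside contact-ratio map bins predicted contact in 40 kb
  bins over ±800 kb; bin pairs flanking the target from both sides are
  "crossing", same-side pairs "outside", bins containing the target are
  excluded from both classes. Under the approximate-LC scoring used for
  these reports, deletion strictly increases every crossing pair with
  nonzero prior competition and leaves disjoint pairs exactly unchanged
  (the full fixed point adds small second-order ripples).

## Genomic I/O conventions

Coordinates are 0-based half-open (BED) everywhere; all distances are
motif-midpoint to motif-midpoint (anchors and peaks are ~1 kb, so
midpoints are adequate and unambiguous). Peaks come from narrowPeak/BED6+
(signal column selectable — which intensity statistic is best is
data-dependent), loops from BEDPE with the PET count in the score column,
and a headered TSV pair table is the exchange format between stages.
Signal normalization defaults to the retained-site mean (mean `x` = 1
exactly) with an optional genome-average override. Orientation is
annotated as the strand of the best log-odds PWM hit within the peak
(JASPAR-format matrices, uniform background, pseudocount 0.8); hits below
80% of the maximum achievable score, or with tied strands, are ambiguous
and excluded from pairing, mirroring the removal of loops whose anchors
cannot be oriented. Loop labelling requires each anchor to overlap
exactly one retained peak (≥ 1 bp); anchors hitting more than one peak
are ambiguous and dropped with a count, and PET-count filters default to
4 (deep datasets) or 3.

## Known limitations

* Cohesin loading is assumed uniform along the genome; compartments,
  nucleosome context and loading hotspots are out of scope, as is polymer
  dynamics of the extrusion trajectory itself.
* The model's probabilities are calibrated for ranking, not for absolute
  loop frequency in a cell population (see the generator note above).
* The exclusion mechanism's left-to-right acceptance walk is one concrete
  realization of "first loop formed blocks the rest"; marginals from the
  mean-field fixed point and from the exclusion process differ at second
  order, and only the fixed point is used for scoring.
* PWM orientation annotation is a clean-room stand-in for motif tools
  whose exact scoring is not bit-reproducible; thresholds are exposed.
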