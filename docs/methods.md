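# Methods

This note documents the statistical model, the numerical choices behind the
variational fit, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the problem was genuinely open.

## Read counting at breakends

A structural variant is a pair of single-base breakends (l, u), each with a
direction: `+` when the junction attaches to the sequence left of the locus
(supporting reads align up to the position and are soft-clipped on the
right), `-` for the mirror case. Directionality matters because only reads on
one side of each locus belong to a given junction — inversions and reciprocal
translocations place genuine supporting reads of *other* breakpoints on the
opposite side, and counting them would double-count evidence. The counter
therefore only accepts split reads whose clip side matches the breakend
direction, and treats opposite-direction support as anomalous.

Fragments are classified per breakend as split (clip boundary within 6 bp of
the locus, clip length above 10 for 100 bp reads, scaled as 10% of the read
length otherwise), spanning (mates flanking the junction, both facing it,
adjusted insert — the sum of each mate's outer-end distance to its breakend —
under μ_ins + 3σ_ins), normal (read or insert crossing the locus with ≥ 10 bp
on each side and ≤ 6 bp of soft-clip), anomalous (boundary crossers fitting
no category), or irrelevant. Split and spanning reads are pooled into a
single supporting count b shared by both ends, with side-specific normal
counts o_l, o_u giving per-end binomial trials d_i = b + o_i.

The field notation writes the per-end support as b_ij = s_ij + c_ij while
also treating spanning reads as breakpoint-level, which leaves ambiguous
whether a side's trials should use only its own split reads. We adopt the
shared-total convention as the default because a spanning pair genuinely
supports both ends of the same junction; a `per_side` support mode
(b_i = s_i + c) is available on `ReadCounts` for sensitivity analyses.

Duplication-class SVs (tandem and interspersed duplications) gain DNA: the
duplicated allele keeps its reference-supporting reads, so raw normal counts
overestimate the reference depth and raw VAFs are biased low. Normal counts
of DNA-gain events are multiplied by `AF_norm = 1 − t/n_p` (purity over
ploidy); adjusted normal counts are carried as reals and rounded only at
reporting. Breakends whose mean depth exceeds `expected_depth × max_cn`
(defaults 50 × 10) are flagged as likely repeat artefacts and excluded.

## Filtering

Conservative by design, since samples typically carry tens to low hundreds of
SVs and every variant carries weight in clustering. Hard filters: at least
one split and one spanning read; per-end depth strictly greater than 2;
intra-chromosomal size (u − l) greater than the fragment size (taken as
μ_ins, since no separate fragment-size parameter exists in the sample
metadata); no germline support (a germline breakpoint matching both ends
within 6 bp with matching directions and ≥ 1 supporting read); a valid
copy-number state (major + minor ≥ 1) at l or u when a segmentation is
supplied. Optional filters restrict to copy-number-neutral (1/1) or clonal
copy-number backgrounds, and a BED blacklist rejects on any overlap. An SV
with exactly one valid copy-number end is kept; the invalid end falls back to
the normal-ploidy default annotation rather than discarding the variant.

Background copy number is the state *before* the SV occurred: for
intra-chromosomal events the segment upstream of l and downstream of u (never
the rearranged interval itself); for inter-chromosomal breakends the segment
on the side opposite the breakend direction, i.e. where reference-supporting
reads come from. Copy-number segments are half-open [start, end) in 1-based
coordinates so boundary bases have a unique owner. For subclonal segments the
total tumour copy number is the clone-fraction-weighted sum over the (at
most two) states.

## The mixture model and its variational fit

Given per-end counts (b_i, d_i), purity t, error constant ε (default 1e-3)
and per-end copy-number annotations, the likelihood of an SV in cluster k is
the product of two binomials with success probability f_ik = w_i φ_k + ε.
Multiplicity candidates are {1..n_maj} for clonal backgrounds and all
fraction-weighted sums Σ_r ρ_r x_r, x_r ∈ {0..n_maj_r}, for subclonal ones;
in the weight, subclonal n_tot_t is the weighted average total.

Priors: φ_k ~ Normal(1, 1) — centred on clonality, weakly informative on the
[0, 2] CCF range; mixing weights ~ Dirichlet(0.01) per component, sparsity-
inducing so surplus components empty out and quality control can prune them.
Both are configurable on `ModelConfig`.

The binomial is not conjugate to the Gaussian prior, so expectations over
q(φ_k) = N(μ_k, s_k²) are evaluated by Gauss–Hermite quadrature (12 nodes).
The quadrature rule *defines* the surrogate ELBO that every update
maximises:

* q(Z) and q(π) have exact coordinate-ascent solutions (softmax of expected
  log-likelihood plus E[log π_k]; Dirichlet with counts added);
* (μ_k, log s_k) are updated by damped coordinate Newton steps with
  numerical derivatives and backtracking, accepting a step only if it
  improves the objective;
* multiplicities are per-end argmaxes of the responsibility-weighted
  expected binomial log-likelihood over the candidate set, with ties broken
  toward the smallest candidate (the conservative, lower-CCF choice).

Because every update is an exact maximiser or explicitly guarded, the ELBO
trace is non-decreasing by construction; the test suite asserts this at
tolerance 1e-8 on every fit. Success probabilities are clipped away from
{0, 1} at 1e-12 inside logarithms; responsibilities are computed in
log-space with max-subtraction. Convergence is declared at relative ELBO
change below 1e-6, with a 1000-iteration cap (tens of iterations in
practice). A breakend with d = 0 contributes exactly zero log-likelihood, so
the dual-end model degenerates to the single-end model when one end is
masked.

Initialisation: per restart, cluster means start at the K-quantiles of the
empirical per-variant CCFs (unit multiplicity), jittered by N(0, 0.05) for
restarts after the first; posterior s.d. starts at 0.1. Restart seeds derive
deterministically from (seed, K, restart) via `numpy.random.SeedSequence`.
The best-ELBO solution across K = 1..6 × 5 restarts is selected, then
quality-controlled: empty clusters removed, clusters holding under 1% of
variants removed (smallest first), clusters with means closer than 0.10
merged (closest pair first, responsibility-weighted mean); the variational
updates are re-run to convergence after each step.

Post-assignment freezes the reference q(φ) and iterates only assignments and
mixing weights — re-estimating the weights prevents the result from simply
mimicking the reference's mixing proportions. During post-assignment the
merge step of quality control merges assignment labels only: reference CCFs
are never re-estimated, and a merged cluster reports the weight-averaged
mean, flagged in the QC log. Post-assignment is the recommended route when a
sample yields fewer than about 10 filtered SVs.

## Clonality statistics

Variants with representative CCF (mean of the two end CCFs, capped at 2)
below 0.7 are subclonal; the boundary value is clonal. Enrichment of
balanced rearrangements (inversions, inter-chromosomal translocations) among
subclonal SVs is a one-sided hypergeometric test P(X ≥ x).

The dispersion test asks whether a binomial adequately models supporting
counts of copy-number-neutral variants: null Binomial(d_j, t/2) against a
beta-binomial alternative whose β comes from the closed-form moment match
(verified algebraically against a numerical method-of-moments solver) with
sample-level mean μ = μ_d·t/2 and σ the s.d. of the observed counts, and
per-variant α = −μβ/(μ − d_j); the per-variant statistic 2(ℓ₁ − ℓ₀) is
referred to χ²(1). Two properties follow from this construction and are
asserted as such: each "test" has a single observation and the alternative's
parameters are moment-estimated sample-wide, so under binomial data the test
is strongly conservative (measured null rejection ≈ 0, not the nominal α —
for roughly half of null samples the moment fit is infeasible, σ² below the
binomial variance, and the statistic is zero by definition); under genuine
overdispersion outlying variants reject readily. A `per_variant_depth` flag
estimates μ from each variant's own depth instead of the sample mean.

## Benchmarking

True and inferred cluster means are matched alternating from the extremes:
highest-with-highest, then lowest-with-lowest, then second-highest, and so
on until either list is exhausted (highest-first claims the middle when the
paired count is odd). Errors are signed (inferred − true): cluster-number
error, mean cluster CCF error over matched pairs, mean variant CCF error,
and mean multiplicity error against the multiplicity implied by the true
cluster mean (brute-force binomial maximisation at φ_true — the "optimal"
oracle, which is also how optimal per-variant CCFs are computed).
Subclonal sensitivity/specificity use the truth clonality labels against
inferred CCF < 0.7. In two-sample mixtures a variant is clonal when shared
by both samples and subclonal when private to one.

## Synthetic data

The generator draws from the model's own forward process at the count level:
clone CCFs and sizes, purity, Poisson depth per breakend (fixed-depth mode
available), multiplicity uniform over the positive candidate set, and
independent binomial draws at both ends sharing one φ. Duplication-class
variants additionally emit inflated raw normal counts (adjusted count
divided by AF_norm) so the counting-step correction can be exercised.
Two-sample mixtures re-draw counts at CCF 1 for shared variants and at
p_A / 1 − p_A for private ones, reproducing the branching truth of mixing
two clonal samples. Copy-number perturbation modes (major − 1 with the 1-0
guard, major + 1, fraction ± 0.3 capped at 0.9) support robustness
experiments.

Default study conditions follow the validation experiments: two-clone runs
use 50 + 50 SVs at CCFs 1.0/0.4, depth 100, purity 0.75; duplication
adjustment runs use 200 SVs at purity 0.6, depth 200; mixtures use a 70–30
split with shared clonal variants. Problem sizes in the acceptance script
(20 seeds for recovery, 200 replicates for test calibration, 25–50
closed-loop configurations) were chosen as the smallest that make the
stochastic checks stable.

What the generator does **not** emulate: actual read sequences and
alignment noise (no reference rearrangement or read simulation — the
alignment-fixture generator produces geometrically exact reads for testing
the counter, not realistic ones), mapping ambiguity in repeats, micro-
homologies longer than the 6 bp positional tolerance, correlated noise
between breakends, or real subclonal copy-number segmentation error.
Passing tests therefore demonstrate correctness of the inference given the
model's noise assumptions, not robustness to alignment artefacts in real
tumours.

## Known limitations

* Multiplicity is a point estimate (maximum pseudo-marginal likelihood), not
  integrated over; uncertainty in m does not propagate into cluster CCFs.
* The binomial likelihood ignores residual overdispersion; the variational
  assignment partially mitigates this by integrating over the CCF posterior,
  and the dispersion test lets users check the assumption per sample.
* Model selection by surrogate ELBO across K is heuristic; quality control
  (not the ELBO alone) is what keeps the effective cluster number honest.
* Directionality inference from soft-clips is deliberately basic (no local
  realignment); caller-provided directions are preferred and override
  inference by default.
* Complex events (more than two mutually matching breakpoints) are flagged
  and excluded rather than resolved.
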