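# Methods

This note records the statistical model behind `splicefit`, the numerical
choices made where the design was genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Model

A locus is represented by a splicing graph G over S exonic segments with
edge set E (introns from spliced reads or annotation, plus adjacencies
between genomically contiguous segments).  Transcripts are source-to-sink
paths; a candidate set of k transcripts is a binary matrix U (k×S) with
derived intron-usage indicators u_{t,e}.  Sample r contributes observed
per-base segment counts V_obs_r (aligned bases / segment length), intron
confirmation counts I_obs_r (spliced alignments matching the edge exactly;
boundary-spanning alignments for adjacency edges), and read-pair links P_r.

Abundances are normalized: W ∈ [0, w_max]^{k×R}, expected counts
V_exp_r = c·UᵀW_r with c = max observed segment count (so a transcript
explaining the deepest segment alone has W ≈ 1; w_max = 2 leaves slack).
The fitted objective is

    Σ_r [ L(V_obs_r, V_exp_r) + w_intron·L(I_obs_r, I_exp_r) + w_pair·pp_r ]
      + w_sparsity·(#novel + w_known_discount·#known)

with pp_r = Σ_{(s1,s2)} P_r(s1,s2)·[no selected transcript contains both].
The sparsity term is Occam's razor over transcripts; annotated transcripts
pay a discounted price, so novel rows appear only when the annotation
cannot explain the coverage.

### Count likelihood

Counts are modelled per segment as independently distributed around the
expected coverage:

    L(v | μ) = max{ P_Poisson(v; λ_bg), P_NB(v; μ, Var = μ + α·μ²) }.

The NB component captures overdispersion that grows with expression; the
Poisson background (mean λ_bg, in reads/base) models false alignments and
unprocessed RNA, and the max-combination means any observation can be
attributed to noise at the bounded cost −log P_Poisson(v; λ_bg).  The
combination rule is a design choice (the alternative, a fixed-weight
mixture, is available via `LossModel(combine="mixture")`); the max form
was chosen because it caps the penalty for segments a selected transcript
set leaves unexplained, which is what lets the optimizer discard
information context-dependently instead of requiring pre-filtering.
Non-integer counts are handled by the log-gamma continuous extension of
both pmfs.  Dispersions below 1e-9 short-circuit to the Poisson (the
log-gamma difference loses precision there, and the distributions are
numerically identical).

Parameterization: Var(μ) = μ + α·μ² with a single scalar α (default 0.1, a
mid-range bulk RNA-Seq value); an additive offset β (Var += β) is accepted
in config but defaults to 0.  λ_bg defaults to 0.1 reads/base.
`estimate_noise_params` fits α by method-of-moments on single-isoform
loci — all segments of such a locus share one expected coverage, so the
cross-segment variance at each locus mean identifies the variance
function; α solves the least-squares fit of (s² − m) against m² through
the origin, and λ_bg is the mean intronic/intergenic coverage.  Fewer than
10 usable loci triggers a warning and the shipped defaults.

### Convex proxy

The NB NLL is not convex in μ (logarithmic right tail, −v·log μ divergence
at 0, and the background cap flattens both tails), so the optimizer uses a
convex piecewise-quadratic surrogate per observed count v:

* the *gradient* is piecewise linear over breakpoints spanning
  [0, max(4v, 20)], non-decreasing (convexity), anchored at exactly 0 at
  μ = v (minimum at the observation);
* the curve's value at v equals the true NLL there, and values elsewhere
  follow by exact integration, giving per-piece quadratic coefficients;
* slope increments are fitted by non-negative least squares against the
  true NLL on a dense grid — NNLS makes the convexity and anchor
  constraints structural rather than penalized;
* 6 pieces by default: left of v the knots crowd geometrically toward 0
  (ratio 0.3) where curvature is largest; right of v the gaps double.

Two guards matter in practice.  The fit target is capped at its value at
μ = 0.05·v: chasing the −v·log μ singularity otherwise drags the whole
fit and makes the curve sag *below* the truth just right of zero, which
manifested as spurious quantification minima at small expected counts.
And a minimum slope step of 1e-8 on the pieces flanking the anchor keeps
the minimizer unique.  `ProxyCurve.max_abs_deviation` reports the fit
error over the uncapped region; for v = 10 at default parameters it is a
few NLL units, concentrated where the true NLL is concave (tails) — near
the minimum (0.5v–2v) the deviation stays below ~0.75.  Consequences of
proxy error are confined to selection margins; the statistical tests
evaluate the exact NLL (below).

## Solver

Exact mode is a best-first branch-and-bound over *path-inclusion
indicators*: candidate transcripts are the graph's enumerated paths
(capped, default 64) plus any annotated rows.  A node fixes some
candidates in/out; its lower bound is the convex quantification with all
undecided candidates admitted, plus pair penalty on that widest support,
plus sparsity charged only for decided inclusions.  Admitting transcripts
can only lower the loss and pair terms and sparsity is undercounted, so
the bound is valid; leaves are scored exactly, giving an optimality
certificate.  Branching picks the undecided candidate with the largest
fitted abundance in the node relaxation (most load-bearing first);
subproblem quantifications are cached by candidate subset.

This differs from branching on raw U entries with a [0,1] MIQP relaxation:
that design needs a quadratic-programming backend with McCormick
linearization of the U·W products, and no open MIQP solver is available
here.  Branching on whole-path indicators keeps every node a small smooth
convex problem (L-BFGS-B over W ≥ 0 with analytic gradients) at the cost
of enumerating candidates up front — acceptable because loci beyond the
enumeration cap are served by iterative mode.  The linear validity
constraint system over raw U entries is still provided
(`build_validity_constraints`) and is tested to carve out exactly the
valid paths plus the zero row; it is the contract an external MIQP
backend would plug into.

Iterative mode seeds the annotated rows, then repeatedly adds the single
best new path, freezing accepted rows; a candidate is kept only if its
loss reduction exceeds its sparsity price times (1 − 1e-6).  This is a
greedy descent (the objective never increases) without a certificate;
status is reported as `approximate`.

Determinism: among objective ties (tolerance 1e-9) the solver prefers
fewer transcripts, then the lexicographically smallest U (rows compared
in sorted order).  Node limit 1e5; hitting it returns the best incumbent
with status `time-capped`.

Default weights (w_sparsity = w_intron = w_pair = 1, discount 0.1,
k_max = 12) are shipped as usable mid-scale settings; they are in NLL
units, so analyses at very low coverage (e.g. the normalized toy
instances, where all counts are ≤ 1) should scale w_sparsity down
accordingly, as the tests do.

## Statistical tests

Transcript confidence: the quantification (regularizers zeroed) is
re-solved with transcript t's abundance fixed to zero in every sample;
the statistic is 2·[NLL_restricted − NLL_full], referred to χ² with
df = R — zeroing the transcript removes one free abundance per sample.
The df is configurable and reported in the output.  Differential
expression between two samples compares free per-sample abundances with
abundances tied across the samples (optionally only for a subset of
transcripts, the rest staying free under the null); df = number of tested
transcripts.

Both tests *fit* with the convex proxy but *evaluate* the exact NB NLL at
the proxy-optimal abundances, so calibration does not inherit proxy
fitting error.  The residual effect (the exact NLL is evaluated slightly
off its own optimum) biases statistics downward, i.e. conservatively;
the simulated null puts the type-I error at α = 0.05 near 0.04.
Statistics are clipped at 0 (the restricted model can appear marginally
better through this evaluation asymmetry).  P-values are per-locus;
multiple-testing correction across loci is left to the caller.

## Multi-mapper optimization

Each multi-mapping read carries candidate locations (segments covered,
junction hits, coordinate).  A round visits reads in fixed id order and
moves a read to the candidate minimizing the exact NLL of the count terms
any of its candidates touch, accepting only strict improvements; ties
break to the lowest coordinate and never flip an assignment.  The loop
alternates rounds with per-region re-fitting, accepting a region's new
model only if it lowers that region's exact NLL — both steps monotonically
decrease one objective, so the loop terminates (an assignment-signature
guard additionally stops any residual cycling).  Reassignment is integral
(whole reads), so the loop converges to a coordinate-descent fixpoint that
can sit one read away from the planted optimum; the tests assert recovery
to within that granularity.  With no multi-reads the loop reduces exactly
to the plain per-region pipeline.

## Graph construction

Coordinates are 0-based half-open internally; GTF I/O converts to/from
1-based closed.  Boundaries: splice sites from spliced-read gap endpoints
and internal annotated exon ends; TSS/TTS from annotated transcript ends
and from coverage-island edges, where an island ends after ≥ 20 uncovered
bases (read-length-scale gaps merge; the island-joining support threshold
is config).  Candidate segments between boundaries are kept iff (i) more
than 5% of their bases are covered (multi-mapped reads included — the
filter runs before MMO), (ii) they lie inside an annotated exon, or
(iii) removing them would disconnect two segments linked by read pairs.
Intron edges require exact junction coordinates (no fuzz; mismatches are
logged and skipped).  A segment is flagged initial if a TSS labels its
start or nothing leads into it, terminal symmetrically — so annotated
ends and island edges open/close paths, while intron-separated segments
do not.  Graphs are per strand, built in genomic order; for minus-strand
annotation the TSS/TTS labels swap ends.  The construction is biased
toward completeness: adding reads can split segments and add edges but
never removes annotated structure, and enumeration over a graph built
from annotation alone reproduces exactly the annotated intron chains on
non-recombining gene structures (with shared internal segments between
transcripts carrying distinct ends, path closure can exceed the
annotated set — by design).

## Identifiability toy

The cassette graph with n skips has 2n+1 segments, 3n junction edges and
2ⁿ paths.  Observations are *exact expectations* (no sampling noise):
segment coverage and junction support are linear in the abundances, so a
candidate transcript set is consistent with a sample iff strictly
positive abundances (threshold 1e-8) reproduce the observations exactly
(tolerance 1e-8).  Candidate sets are restricted to the minimal
consistent cardinality: without that restriction every strict superset of
a consistent set is also consistent and uniqueness would be vacuous (the
1/C(8,3) guessing baseline presumes size-restricted candidates).
Full-rank subset systems are decided by pseudo-inverse plus residual and
positivity checks; rank-deficient ones fall back to LP feasibility.
Per-sample abundances are independent uniform(0,1) renormalized to sum 1
(total expression fixed), redrawn per sample; multi-sample consistency
intersects the per-sample sets.

The acceptance script runs 2000 Monte-Carlo trials per experiment (vs. 50
in the original desk experiment) so the reported fractions estimate the
simulation's stable values with ~1 pp standard error; the trial count is
a precision choice and does not alter the experimental conditions.

## Synthetic data generator

`splicefit.simulate.make_fixture` plants transcripts with per-sample
abundances and emits coordinate-sorted SAM plus GTF: fragment counts per
transcript are NB-dispersed around abundance·(effective positions)/read
bases, start positions are uniform along the transcript, reads crossing
introns carry N CIGAR operations, and paired mode emits proper mate pairs.
Deterministic per seed (byte-identical regeneration).  It emulates
uniform, bias-free sampling at desk scale; it does *not* model positional
or sequence bias, indels, sequencing error, mapping ambiguity or
fragment-length variability.  Tests passing on these fixtures therefore
demonstrate correctness of counting, graph construction and inference
under the stated model, not robustness to real-library biases — which the
loss's background floor and the confidence test are designed to absorb,
but which are not validated here.

## Known limitations

* The convex proxy cannot follow the NB NLL's concave tails; deviations
  there are reported per curve but not eliminated.
* Exact mode requires enumerable candidate paths (cap 64 by default);
  beyond that, iterative mode gives no optimality certificate.
* MMO's integral reassignment converges to a fixpoint within one read of
  the optimum; fractional (rescue-style) assignment is out of scope.
* The differential test handles exactly two samples; replicate designs
  and cross-locus multiple-testing correction are left to the caller.
* Unstranded libraries are assigned by overlap; splice-dinucleotide
  strand inference requires a genome and is not bundled.
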