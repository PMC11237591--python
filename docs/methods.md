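# Methods

This note documents the models, null models, numerical choices and known
limitations of `nichevol`.  Nothing stated here is an empirical claim
beyond what the test suite and `scripts/acceptance.py` compute.

## Niche-breadth classification

Three indices are computed per taxon.  Levins' breadth `B = 1/Σ p_i²`
and Shannon breadth `H = −Σ p_i ln p_i` are evaluated with **samples as
resource states**: `p` is the taxon's vector of per-sample relative
abundances normalised to sum to one, so `B ∈ [1, n_samples]`.  This is
the convention of the niche-width tooling commonly used for this
analysis (spaa/EcolUtils).  We deliberately do not aggregate to
per-habitat means first: at habitat-mean grain a maximally even taxon
and every read-redistribution null sit at the same evenness ceiling, so
the classification rule "observed above the 95% envelope on all three
indices" could never fire for true generalists.  At sample grain the
envelope and the observations separate cleanly.  Occurrence frequency
`F` is the fraction of samples with a nonzero count.

**Null model.**  The default null permutes the whole abundance table by
2×2 count swaps (rows i,j × columns k,l; move d reads along one
diagonal), with a Metropolis correction that makes the stationary
distribution uniform over all non-negative integer tables with the
observed row and column margins.  Taxon totals and sample depths are
therefore preserved exactly while habitat association and occupancy are
randomised; the null envelope reflects the clumpiness a taxon of that
abundance would have in a margin-matched random table.  One chain is
run with a burn-in of 20× the thinning interval; the thinning default
(~30 swap proposals per row between snapshots) was set so that data
generated by the null itself are called non-opportunist at well under
the 10% envelope tail mass (measured ~1–5%).  A simpler alternative
null ("multinomial": each taxon's reads redistributed independently,
proportional to sample totals) is available via `scheme=`; it is
markedly more even than real tables and is kept for comparison only.
A taxon is a generalist iff observed `B`, `H` **and** `F` all exceed the
97.5% null quantile, a specialist iff all three fall below the 2.5%
quantile, otherwise an opportunist.  Strict generalists additionally sit
at or above the 90th percentile (among generalists, ties inclusive) of
all three indices; strict specialists have more than 50 total reads.

## Synthetic data

The generator emulates the post-processing products of a multi-habitat
amplicon survey: 5 habitats × 6 parks × 3 replicates (90 samples),
rarefied depth 10,000, with 10% planted generalists (symmetric Dirichlet
habitat preferences, concentration 50), 30% specialists (concentration
0.05) and background taxa.  Parks sit on a fixed 2-D grid with unit
spacing; each non-background taxon has a home park from which its
abundance decays as `exp(−spatial_decay × distance)` (default 0.3,
per-class overrides available for distance-decay experiments).  Counts
are one multinomial draw per sample (columns sum to depth exactly); an
overdispersed per-sample lognormal noise term (σ = 0.3) represents
unexplained environmental variation between replicates.

Two defaults deserve justification:

- **Background taxa are "null-typical" by construction.**  Their
  per-sample weights are iid Gamma draws (shape =
  `niche_concentration_background`, default 1) — a symmetric simplex
  draw across the 90 samples.  At shape 1 this equals the flat
  composition, which is also the row distribution of the
  margin-uniform permutation null, so background taxa are opportunists
  in the exact sense the classifier tests for.  This is the natural
  definition of an "intermediate" class: habitat-indifferent taxa whose
  sample-to-sample variation carries no spatial or environmental
  signal.
- **Baseline abundances are lognormal with σ = 0.5.**  Real amplicon
  surveys are far heavier-tailed; the narrower spread keeps every
  planted taxon inside the abundance range where a permutation
  classifier has statistical power.  Consequently the planted-label
  recovery tests demonstrate correctness of the machinery, not
  classifier performance on rare taxa — a taxon with a few dozen reads
  is undetectable by any envelope test, in real data as here.

Trees come from a Gillespie birth–death simulation (retry cap on full
extinction; tips extended to the next event time so branch lengths are
strictly positive).  BiSSE simulation couples a binary state to the
same process with state-specific rates.  Correlation-structured
compositions exponentiate a multivariate normal with the requested
basis correlation, close to fractions and sample multinomially.

## Beta diversity and distance decay

Bray-Curtis is `Σ|x−y| / Σ(x+y)`; weighted UniFrac is the normalised
variant (scikit-bio), bounded in [0,1] for comparability.  The decay
fit is OLS of `log(dissimilarity)` on `log(D+1)` with natural logs
(slope comparisons are base-invariant); identical pairs (dissimilarity
0) are dropped with a logged count because the model is undefined
there.  `within_habitat=True` restricts to same-habitat pairs so the
slope measures spatial turnover uncontaminated by habitat turnover.

## Community assembly

βMNTD is the abundance-weighted mean, over taxa of each community, of
the patristic distance to the nearest taxon of the other community
(averaged symmetrically).  βNTI standardises it against 999 tip-label
shuffles across the pool's tips.  Pairs sharing their full taxon
support have βMNTD ≡ 0 under every labelling; with `degenerate="zero"`
such pairs return βNTI = 0 (no selection signal) instead of raising —
the pipeline uses this because dense synthetic subtables hit the case
routinely.  RC draws null communities preserving each community's
richness (membership ∝ pool occupancy) and abundance (∝ pool mean
relative abundance), and maps the observed Bray-Curtis quantile to
[−1, 1] with ties counted half.  Arguments are ordered canonically so
both statistics are exactly symmetric.  The decision rule uses strict
inequalities at ±2 and ±0.95; boundary values fall through to the next
rule.  Process fractions are kept as exact rationals.  The
phylogenetic-bin refinement used by some pipelines is intentionally not
implemented; classification is whole-community and flagged as such.

## Networks

SparCC estimates basis variances from the log-ratio variance matrix
`t_ij = var(log x_i/x_j)` under the sparsity approximation, solving
`[(n−2)I + J] ω = t·1` and excluding the strongest correlated pair
(|r| > 0.1) from the system for up to 10 rounds; fractions are drawn
per sample from Dirichlet(counts+1) (the standard zero treatment) and
the median over 20 such draws is returned, clipped to [−1,1].
Negative basis variances from sparsity violations are clamped to a
small positive floor.  Edge p-values come from a sample bootstrap:
columns resampled with replacement, SparCC re-run (5 inner iterations
for speed), two-sided "crosses zero" convention with the (b+1)/(B+1)
correction.  No multiple-testing correction is applied to edges (raw
p < 0.05, as in standard practice for this threshold pair); edges
additionally need |R| ≥ 0.6.  Modularity uses greedy agglomeration on
the unsigned graph (edge sign kept as an attribute); modules are
labelled by their lowest node id for determinism.  Rewired nulls use
degree-preserving double-edge swaps (≥10× edge count per replicate).
Zi uses the module's population standard deviation (sd = 0 ⇒ zi = 0).
Stability metrics follow the definitions in the README; the removal
experiment counts a surviving node only if it retains at least one
edge (secondary extinctions count as losses) with the original node
count as denominator.  Functional complementarity is the total branch
length of an average-linkage dendrogram on Jaccard distances between
interaction-partner sets; niche overlap is the mean Morisita-Horn
similarity of partner profiles.

## BiSSE

The likelihood integrates the coupled extinction/data ODEs tip-to-root
per branch with fixed-step RK4 (step ≤ 0.02 / total-rate, capped at
10⁵ steps per branch) and renormalises D after every branch,
accumulating the log scale.  At internal nodes (root included) D values
multiply with the state's speciation rate; the root combines states
with weights proportional to their conditional likelihoods.  There is
no conditioning on survival: the reported comparisons are between
nested fits on the same tree, for which the conditioning constant
cancels qualitatively and the convention is configurable in principle.
The equal-rate limit factorises into a constant-rate birth–death tree
likelihood times a symmetric two-state Markov character likelihood;
both closed forms are implemented (`bd_mk2_loglik`) under identical
root conventions and the pruning agrees with them to better than 1e-6
on trees up to 50 tips — this is the module's primary correctness
anchor.  The kernel is numba-jitted with a pure-Python fallback.

Fitting is two-step: step 1 constrains λ_g = λ_s, μ_g = μ_s and
symmetric transitions (3 parameters) starting from a constant-rate
birth–death maximum-likelihood fit of the tree alone (q₀ = λ̂/10);
step 2 frees all six rates from step 1's optimum with two additional
jittered restarts (Nelder-Mead in log-rate space, xatol 1e-5).  The
nested fits are compared by a χ² likelihood-ratio test with 3 degrees
of freedom.  Diversification potential is `DP = λ + t − μ` with `t`
the transition rate **into** the focal state (a transition adds to the
focal state's standing diversity); the rate-out convention is reported
alongside (`dp_*_tout`) since the choice is interpretive.

Root-to-tip branch-length comparisons are meaningful only on
non-ultrametric trees (e.g. sequence-divergence phylogenies); on the
generator's ultrametric trees all depths are equal by construction, and
the test suite checks exactly that invariant.

## Pipeline and reproducibility

One master seed feeds named substreams (CRC32 of the stage name mixed
into a `SeedSequence`), so stages are independently reproducible and
every derived seed stays below 2³¹.  The demo configuration scales
stages down (300 permutations, 199 assembly nulls with 120 sampled
pairs per group, 50 bootstrap draws) so the whole two-domain pipeline
runs in tens of seconds; the manifest stores a SHA256 per output and
reruns are byte-identical.  The evo stage fits the BiSSE model to a
simulated state tree, because classification labels carry no
phylogenetic signal on the independently simulated taxon tree; on real
data the stage accepts any Newick tree plus a tip-state table.

## Known limitations

- The permutation classifier has no power for rare taxa; synthetic
  designs keep planted taxa abundant (see above).
- Real amplicon tables are sparser, heavier-tailed and
  taxonomically structured in ways the generator does not emulate
  (no phylogenetic signal in abundances, no taxon–taxon interactions
  except through compositional closure); passing tests demonstrate
  the estimators' correctness and calibration under the stated
  models, not field performance.
- Whole-community βNTI/RC classification approximates, but does not
  reproduce, bin-refined assembly partitions.
- SparCC assumes a sparse true correlation network; dense correlation
  structures bias the basis-variance solution.
- The BiSSE fit, like all state-dependent diversification models, has
  limited power on small trees and can hit boundary optima (μ → 0);
  the likelihood-ratio test remains calibrated (measured type-I error
  ~3–5% at 200 tips) but point estimates on <100-tip trees are noisy.
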