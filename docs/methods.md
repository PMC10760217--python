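# Methods

This note records the statistical model behind `expressbn`, the defaults
and why they are what they are, what the synthetic cohorts do and do not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer from the code.

## Data model

The unit of analysis is a cohort: a samples × transcripts matrix of
covariate-adjusted expression values plus integer-coded phenotype columns,
of which `DX` (diagnosis, 0/1) and `APOE_Genetic` (risk-haplotype carrier
status, 0/1) are required.  Adjustment for biological and technical
covariates is assumed to have happened upstream; the package never touches
raw intensities.  Missing expression values are handled at load time, by
default by dropping the affected sample (a per-transcript drop policy is
available); downstream code may assume a complete matrix.

## Maximum-entropy discretization

Every continuous variable is reduced to k ordered bins (default k = 3,
"low / medium / high") before any information-theoretic or network
computation, giving one multinomial representation shared by all stages.
The criterion is marginal and unsupervised: among all contiguous
partitions of the sorted values that keep tied values in one bin, pick the
one maximizing the Shannon entropy of bin occupancy.  For tie-free data
this is equal-frequency binning; entropy is strictly concave in the size
vector, so the optimum there is the balanced split and is computed
directly.  With ties the optimizer enumerates every tie-respecting
partition exhaustively whenever C(u−1, k−1) ≤ 4·10⁶ candidates (u = number
of distinct values; always true at cohort scale, since u ≤ n); beyond that
a dynamic program maximizes entropy exactly but applies the tie-break only
locally.

Deterministic tie-breaks: among equal-entropy partitions, prefer the
lexicographically most balanced size multiset, then the smallest first cut
point.  Cut points are stored as midpoints between the adjacent distinct
values across each boundary, so out-of-sample values code stably and
codes are a monotone function of the raw value (any strictly increasing
transform of a variable leaves its codes unchanged).  Variables with fewer
than k distinct values are dropped with a warning by default.

## Mixed mutual information

Dependence between a (discretized) transcript and a discrete phenotype is
measured by the plug-in mutual information on their joint count table, in
bits.  Discretize-then-plug-in keeps the ranking exactly consistent with
the multinomial model the network stage fits, and makes the estimator
exactly testable against brute-force summation.  No binless (kernel or
k-NN) estimator is offered.  The plug-in estimator is biased upward by
roughly (r−1)(s−1)/(2N ln 2) bits under independence, which at N ≈ 300–500
is two orders of magnitude below planted-signal MMI values; the ranking,
not the absolute value, is what downstream stages consume.  Ties rank
lexicographically by name, so rankings are deterministic.  The default
pre-selection keeps the top 2000 transcripts, and the phenotype nodes are
always appended to the network's variable set regardless of their rank.

## Network model and score

Structures are scored by a two-part MDL code length per node, in bits:

    score(X | Pa) = Σ_{j,k} −N_jk log2(N_jk / N_j·)
                    + (log2 N)/2 · q · (r − 1)

with r the arity of X, q the product of parent arities (counting the full
configuration space, observed or not), and N_jk the count of samples with
parent configuration j and X = k.  Lower is better; the total score is the
sum over nodes (decomposable, so a single-edge move touches one term).
Penalizing (log2 N)/2 per free parameter is the standard two-part code;
score equivalence holds (X→Y and Y→X tie exactly on two variables).

Search is hybrid.  A constraint phase keeps only variable pairs whose
G-statistic 2N ln2 · MI exceeds the χ² critical value with
(r_x−1)(r_y−1) degrees of freedom at α = 0.01 (configurable); the score
phase is greedy hill climbing over add / delete / reverse restricted to
those pairs under the acyclicity constraint.  Climbing is
first-improvement over the candidate-pair order: each restart shuffles
that order and also randomizes which direction of a new edge is evaluated
first, then applies the best strictly-improving move per pair until a full
pass changes nothing.  Both randomizations matter: with a deterministic
best-move rule every restart walks the same trajectory, and with a
deterministic direction tie-break, collider-generated data always orients
its first (score-equivalent) edge out of the collider node and no single
strict-improvement move crosses the score plateau into the v-structure
class.  Twenty restarts (default) from the empty graph are run and the
best-scoring network wins, earliest restart on ties; results are
bit-identical given the seed.  After convergence, edges whose removal
would not worsen the score are pruned, so every retained edge has strictly
positive strength.

Edge strength — the "explanatory weight" printed on network figures — is
the MDL improvement attributable to one edge given the child's other
parents: score(child | Pa∖{p}) − score(child | Pa).  Because the
likelihood term grows linearly in N at fixed distributions while the
penalty grows only logarithmically, strengths scale approximately linearly
with sample size; the acceptance suite checks R² ≥ 0.95 for that
regression.  Strengths are comparable within a network, not across
differently-sized cohorts, and no constraint is placed on the position of
`DX` in the graph: edge directions encode the best-scoring factorization,
not causal claims.

The Markov neighborhood of a target is its adjacent nodes with their edge
strengths; the Markov blanket adds co-parents of its children.
Dependency paths are shortest paths in the undirected skeleton, with the
lexicographically smallest node sequence on ties — used to show how a hit
that is absent from the neighborhood still reaches the diagnosis through
an intermediate.

## CPTs and risk statistics

A two-level conditional probability tree stratifies P(DX = 1) first by
carrier status, then by a transcript's bin, exposing raw counts at every
node; probabilities are exact count ratios, so count consistency and the
law of total probability hold identically, and empty strata report `null`
rather than an imputed 0.  Leaves are ordered by increasing risk.

High-vs-low contrasts (the medium bin is dropped) are summarized by the
2×2 odds ratio with a Wald 95% interval on the log scale and a two-sided
normal p-value.  The Wald choice is verifiable from published output: a
Wald interval is log-symmetric about the OR, and the printed triple
(2.2810; 1.2217–4.2588) satisfies the log-midpoint identity to four
decimals.  When a single cell is zero the Haldane–Anscombe 0.5 correction
is applied to all cells and flagged; a fully zero row or column is an
error.  The table orientation is fixed as exposed = high expression,
outcome = case; swapping strata reciprocates the OR and mirrors the CI.

## Cross-cohort similarity

For each cohort the transcripts above the p-th percentile of its MMI
distribution (strict inequality; linear-interpolation percentiles) form a
set; the two sets, restricted to the shared transcript universe G, are
compared by Jaccard index across a percentile grid (default 0, 5, …, 95).
Significance is the hypergeometric upper tail P(overlap ≥ t_obs) for two
random subsets of the observed sizes drawn from G — with sizes fixed,
"Jaccard at least as observed" is equivalent to "overlap at least t_obs".
Tails are computed in log space, so vanishing p-values at high cutoffs
report a finite log₁₀ p instead of underflowing to zero.

## Synthetic cohorts

The generator emulates the statistical shape of the two cohorts the
pipeline targets, and its defaults are those study conditions: n = 475
with 218 cases and carrier frequency 206/475 (kronos-like), n = 306 with
144 cases and carrier frequency 79/306 (rush-like).  The genotype→DX link
is logistic with the odds ratio implied by each cohort's printed
carrier-by-diagnosis counts ((150·201)/(56·68) ≈ 7.92 and
(57·140)/(22·87) ≈ 4.17); the intercept is solved by bisection so the
marginal case fraction is hit in expectation.  Transcripts are Gaussian
with unit within-group standard deviation: signal transcripts shift their
mean by Δ (default 1.5σ) with diagnosis, genotype, or both; chain children
regress on a parent transcript with correlation 0.8; the rest are pure
noise.  The default preset plants three diagnosis-shifted hits, one
genotype-shifted transcript and one chain child among 200 transcripts —
200 keeps full-pipeline recovery experiments at 20 seeds comfortably
inside a desktop minute while preserving a realistic multiplicity burden.

A deliberate omission: the flagship preset plants no *joint*
diagnosis+genotype child.  An additive joint child with comparable
coefficients induces explaining-away cancellation — conditioning on the
child, the direct genotype–diagnosis dependence almost vanishes, and the
minimum-MDL structure genuinely routes the genotype through the child
rather than keeping the direct edge.  That is a property of that
generative configuration, not of the cohorts being emulated, where the
genotype–diagnosis edge is the strongest and most reproducible feature.
The `joint_signal` role remains implemented and unit-tested for
sensitivity experiments.

What the generator does *not* emulate: microarray intensity distributions,
residual covariate structure, correlated null transcripts (co-expression
blocks), or linkage between the genotype and transcript noise.  Passing
recovery tests therefore demonstrate that the pipeline finds the planted
dependency structure under clean Gaussian noise at realistic sample sizes
— not that it would be equally specific on real arrays.

## Calibration behavior on null data

With all-null transcripts and the genotype unlinked, the learned blanket
of `DX` should ideally be empty.  Per candidate pair, a spurious
dependence survives only if it clears both the skeleton G-test and the
MDL penalty — at n = 475 and 3×2 tables that is ≈ 0.002 per pair, far
stricter than the nominal α = 0.01.  But with ~200 candidate transcripts
the familywise probability of at least one spurious DX-adjacent edge is
≈ 0.3, so the empty-blanket rate sits near 0.7, not above 0.9; the
measured rate varies between 0.5 and 0.8 across seed batches.  This is a
multiplicity property of any fixed-threshold selection at this scale, not
an implementation artifact; neither the skeleton test nor the MDL score
applies a familywise correction, by design.  Practical reading: a
borderline blanket member with an edge strength of a few bits should be
treated as unreplicated until the CPT and a univariate test corroborate
it.  Null-data *similarity* is well calibrated: hypergeometric p-values
across independent null cohorts are non-significant at ≥ 95% of grid
points.

## Problem sizes and determinism

Defaults reproduce the reference settings (top 2000 transcripts, 3 bins,
20 restarts, α = 0.01).  The test and acceptance suites run the full
pipeline at 200 transcripts × 475 samples (seconds per seed), exhaustive
DAG enumeration at 3 variables, and estimator oracles at N ≤ 30 — sizes
chosen so every check is exact or highly replicated while the whole suite
stays desktop-fast.  Every stochastic component (generator, restart
shuffles) is driven by explicit integer seeds; identical seeds give
byte-identical run directories (manifests contain no timestamps).

## Known limitations

- Structure search is greedy; restarts mitigate but do not eliminate
  local optima (measured ≥ 95% agreement with exhaustive search on three
  variables at n = 500).
- The plug-in MMI is upward-biased at small N; rankings are fine, absolute
  bit values should not be over-interpreted.
- Edge strengths depend on N; compare them only within one network.
- The Wald interval degrades for very sparse 2×2 tables even with the
  Haldane correction; exact intervals are out of scope.
- No inference engine (belief propagation) and no linear-Gaussian mode:
  the package is structure + local tables only, by design.
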