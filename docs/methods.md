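# Methods

This note documents the models, estimators, numerical choices and
limitations behind phylotherm, in the spirit of a package methods appendix.

## The scientific question and the data model

Given a rooted phylogeny of a genus's type strains (one genome per species,
branch lengths in arbitrary time or substitution units) and each strain's
minimum growth temperature `t_min` (°C), the package quantifies whether cold
adaptation (`t_min ≤ 5 °C`, inclusive; the threshold is configurable)
evolved gradually within a conserved lineage or sporadically across the
tree. Three complementary lenses are used: continuous-trait evolution model
selection on `t_min`, phylogenetic signal of the binary cold state, and
genome-composition corroboration via the Arg/(Arg+Lys) ratio.

Trees are consumed, never inferred. Multifurcations are accepted on input
and resolved deterministically (first two children joined under a
zero-length node, repeatedly) before any binary-only algorithm; zero-length
branches are floored at 1e-8 × tree height inside likelihood computations
only, so contrast weights stay finite. Trees are taken as rooted as
written; ultrametricity is never assumed — operations that require it
(OU, early-burst and Pagel-δ transforms, OU trait simulation) test for it
explicitly and refuse otherwise.

## REML contrast likelihood

All thirteen trait models share one likelihood currency: restricted maximum
likelihood on phylogenetic independent contrasts. The pruning recursion at
an internal node with daughters (x_i, t_i), (x_j, t_j) produces contrast
c = x_i − x_j with effective time T = t_i + t_j, node value
x̂ = (x_i/t_i + x_j/t_j)/(1/t_i + 1/t_j), and extends the node's parent
branch by t_i·t_j/(t_i + t_j). A binary n-tip tree yields exactly n − 1
contrasts and the root state is eliminated, never counted as a parameter —
this keeps AIC comparable across Gaussian and jump families.

**Gaussian families.** BM, OU (stationary), early burst, a linear rate
trend through time, and Pagel's λ, κ, δ are implemented as branch-length
transforms followed by the BM contrast likelihood
Σ ln N(c; 0, σ²T′). The transforms: λ scales internal edges and restores
original tip heights (λ = 0 is the star phylogeny); κ raises each branch
length to the power κ; δ, EB, OU and the rate trend are monotone node-depth
maps — d ↦ h^{1−δ} d^δ, d ↦ (e^{ad} − 1)/a, d ↦ e^{−2αh}(e^{2αd} − 1)/(2α)
(the stationary OU tip covariance written as a height map, numerically
stable as α → 0), and d ↦ d + b d²/2 with 1 + b·h > 0 enforced. σ² is
profiled analytically (σ̂² = mean(c²/T′)), so each Gaussian fit is a
bounded one-dimensional search over the shape parameter, run over
`restarts` bracketed sub-intervals plus the interval endpoints (the
BM-identity points λ=κ=δ=1, a=0 sit on the boundary and must be reachable).
The test suite verifies every Gaussian likelihood against a dense-matrix
MVN REML oracle (root profiled out) to 1e-8 on random trees, and the OU
transform against the closed-form stationary covariance directly.

**Lévy jump families.** Pure jump-normal (compound Poisson with normal
jumps), variance-gamma, normal-inverse-Gaussian, and their three Brownian
mixtures are defined by characteristic exponents ψ(k) (table in
`levy.py`). Contrasts are treated as independent increments over their
effective times T, scored with

    f(x; T) = (1/π) ∫₀^∞ exp(T·ψ(k)) cos(kx) dk.

This independent-increment treatment of contrasts is an approximation (for
non-Gaussian processes the pruning node estimates are no longer exact
conditional means); it is the established pulsed-evolution device, and its
consequences here are validated by simulation (model-selection and
calibration tests) rather than assumed. Within-branch jump history is
integrated out exactly by the characteristic function.

Numerics of the inversion:

* substitution u = k√T lets one frequency grid serve contrasts whose T
  spans orders of magnitude; trapezoid quadrature converges
  super-algebraically for these even, smooth integrands;
* the truncation point is where the integrand drops below e^{−40}, or — for
  slowly (polynomially) decaying cases such as variance-gamma with small
  T/ν — where an analytic tail bound val(U)·U/((p−1)π) with local decay
  exponent p falls below tolerance;
* pure-jump processes carry an atom at x = 0 (probability e^{−λT} of no
  jump for JN). A Gaussian "nugget" variance convolved into the density
  (default 1e-6 × tip-trait variance during fitting; a config knob)
  regularizes the atom, mirroring measurement-error handling — real
  contrasts are never exactly zero. Grid-density evaluation with nugget 0
  raises a numerical-support error for atom-bearing settings instead of
  returning garbage;
* the pointwise likelihood evaluator defaults to ~6 quadrature points per
  oscillation period (relative density error ≈ 1e-4 in the worst
  short-branch tail cases — immaterial for optimization); the grid
  evaluator is reference-grade (≤ 1e-6 absolute against closed forms, and
  integrates to 1 ± 1e-6);
* negative ringing values are clipped (to 0 on grids; densities floored at
  1e-300 before logs).

Jump fits run multi-start L-BFGS-B on log-parameters (5 restarts by
default, seeded; first start at data-scaled heuristics — jump rate ≈
2/tree-height, total variance matched to the BM REML rate — remaining
starts log-normal perturbations). AIC ties below 1e-6 break by smaller k,
then family name; non-converged fits are excluded from ranking.

## Ancestral state reconstruction

Marginal (not joint) reconstruction under BM with a flat root prior:
downpass conditional means/variances (the contrast recursion), an uppass
carrying the rest-of-tree message, inverse-variance pooling at each node.
Node means are invariant to σ²; variances scale linearly in it. σ²
defaults to the BM REML fit. The implementation is checked against the
flat-prior MVN conditional (means and variances) on random trees. Lineage
trends report the estimate sequence along the root → clade-MRCA path;
monotonicity is reported, never assumed. ASR under OU or jump models is
deliberately out of scope — reconstruction is a descriptive companion to
the model ranking, not an inference engine of its own.

## Fritz–Purvis D

d_obs sums |v(parent) − v(child)| over all edges, with nodal values v the
Felsenstein branch-length-weighted downpass averages of the 0/1 tip states.
Published variants differ in branch-length handling, and the original
formulation used equal lengths; both are available
(`equal_branch_lengths=True` replicates the unit-length variant), with
real branch lengths the default. Two seeded null ensembles scale d_obs:
tip shuffles (anchor D = 1) and Brownian-threshold simulations conditioned
on the observed prevalence by rank (anchor D = 0). The minority state
count is what gets thresholded — distributionally identical (the Brownian
liability is sign-symmetric) but it makes D exactly invariant to swapping
the 0/1 labels, a property the tests assert. Both p-values use the add-one
estimator (p_random = Pr*(d_r ≤ d_obs), p_brownian = Pr*(d_b ≥ d_obs)), so
the smallest reportable p at 1000 permutations is 1/1001 ≈ 0.001. Both
p-values are always reported; which null a published "P" refers to is often
ambiguous, so no single value is privileged.

The distance–trait test correlates patristic distance with |Δt_min| over
unordered tip pairs (Pearson default, Spearman available), with one-sided
significance from joint row/column label permutations and the add-one
estimator.

## Composition, clades, gene families

A genome's Arg/(Arg+Lys) value is the mean of per-protein ratios
nR/(nR+nK) over its core proteins (proteins with no R and no K are excluded
and tallied); the pooled-count variant total-R/(total-R+K) is available
behind a flag since published arithmetic varies. "Core proteins" are
whatever FASTA set the user supplies — core-genome construction is an
upstream concern. Counting is case-insensitive; non-R/K residues are
ignored; sequences > 95% ACGTNU trigger a nucleotide-contamination warning.

Cold-clade detection returns maximal monophyletic clades whose analyzed
tips are all cold, sorted by size (ties by first tip label). Unclassified
tips (missing t_min) break exclusivity by default — a conservative call —
or can be treated as transparent with `ignore_unclassified`. Output is
verified against exhaustive clade enumeration. The broader "near-clade"
grouping (an L′-style margin) must be user-supplied: no automatic heuristic
is offered because any such boundary is a judgment call.

Clade-specific families require in-clade presence ≥ 0.9 and out-clade
presence ≤ 0.05 (both configurable); the score is the frequency
difference. Group comparisons are nonparametric throughout
(Kruskal–Wallis for ≥ 3 groups, Mann–Whitney pairwise, Benjamini–Hochberg
across pairs), with all-tied inputs reported at the null center with
p = 1 rather than erroring.

## Synthetic data: what it emulates, and what it does not

Generators draw Yule (pure-birth) trees — ultrametric, minimal-parameter —
and traits by exact per-branch transition sampling for all 13 families
(Poisson-mixed normals for JN, gamma- and inverse-Gaussian-subordinated
normals for VG/NIG, exact OU transitions, Gaussian increments on the
transformed tree for the Pagel/EB/trend families; no Euler discretization
anywhere). Binary states come from rank-thresholded Brownian liabilities
(exact prevalence) or uniform placement; proteomes from i.i.d. residue
draws with controlled R/K frequencies; presence/absence matrices from
Bernoulli backgrounds with planted clade-specific families. A single seed
expands into per-generator substreams (SeedSequence spawn keys), so adding
a generator never perturbs existing streams.

The demo dataset ("clustered" vs "sporadic" genus) maps a standardized
Brownian liability to °C as t_min = 9 + 6·z, putting roughly a quarter of
tips at or below the 5 °C threshold — prevalence comparable to a genus rich
in psychrotrophs; the sporadic variant permutes the same temperatures
across tips. Cold strains in the clustered genus get Arg frequency 0.040
vs 0.050 (Lys 0.060 vs 0.050), a composition skew of realistic size.

What passing tests on these data do **not** show: real core-gene trees are
non-ultrametric and non-Yule; real t_min is interval-censored lab data with
measurement error; real proteome composition varies per protein family, not
i.i.d.; and gene-family presence is phylogenetically autocorrelated rather
than Bernoulli. The oracle tests establish numerical correctness of the
estimators; the calibration tests establish statistical behavior only under
these idealized generating processes.

## Problem sizes and defaults

Calibration and recovery runs use the sizes the analyses are designed for:
rate recovery and jump-model selection on 200-tip Yule trees (50 and 25
replicates), D calibration on 500-tip trees (200 replicates, 150-sample
null ensembles per replicate; the 1/1001 p-floor is checked at 1000
permutations), composition round trips with 100 proteins × 300 residues
and 2000-family matrices, and the two-genus contrast on 200-tip fixtures
with 1000-sample D nulls. `scripts/acceptance.py` re-runs all of these
from a single seed.

## Known limitations

* The Lévy REML-contrast likelihood is approximate (see above); absolute
  lnL values for jump families should be compared within this package, not
  across implementations with different conventions.
* Jump-parameter point estimates (rate vs jump size) are weakly identified
  on single trees — the product λσ_J² is what the data pin down — so model
  *selection* is reliable where parameter recovery is noisy.
* Asymmetric jump distributions, branch-specific rates, per-tip
  measurement-error models and Bayesian fitting are out of scope.
* OU is fitted in its stationary, single-optimum form on ultrametric trees
  only.
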