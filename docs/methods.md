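# Methods

This note documents the models implemented in `basecomp`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the problem sizes used by the test suite.

## The scientific setting

Synonymous codon usage in *Drosophila* is GC-biased: preferred codons end in
G or C ("strong", S, bases), unpreferred ones in A or T ("weak", W).  A
population-scaled force gamma = 4\*Ne\*s — directional selection on codon
usage, GC-biased gene conversion, or both; the package does not attempt to
distinguish them — favors S alleles at 4-fold degenerate third positions.
Positions 8–30 of introns shorter than 66 bp (SI sites) serve as the
putatively neutral reference class.  The package asks how the intensity of
this force has changed along the *D. melanogaster* and *D. simulans*
lineages, using *D. yakuba* as the outgroup, by combining divergence-based
statistics (substitution counts from a reconstructed ancestor) with two
polymorphism-based estimators sensitive to different timescales.

## Closed-form substitution theory (`popgen`)

Under reversible two-allele mutation (u: S→W, v: W→S, kappa = u/v) and genic
selection gamma, the per-site fixation-flux rates are

    r_SW = u * gamma / (e^gamma − 1),     r_WS = v * gamma / (1 − e^−gamma),

so R = r_SW / r_WS = kappa e^−gamma, the equilibrium GC content is
Q = 1 / (1 + kappa e^−gamma), and gamma can be read off a measured R once
kappa is known from a neutral class: gamma = ln(kappa / R).  For a lineage
that starts at equilibrium for gamma and then has its force reduced to
p\*gamma, the expected ratio of substitution *counts* is

    N_WS / N_SW = e^−(1−p) gamma,

which is < 1 whenever a GC-favoring force weakened — the signature of an
AT-biased substitution pattern without any change in mutation bias.

The skew statistic delta_pi is implemented as k · a\_{n−1} / S − 1 with
a\_{n−1} = Σ\_{i<n} 1/i.  The trailing −1 is fixed by the requirement that
the statistic be zero at the neutral equilibrium expectation k = S/a and
share Tajima's D's sign (negative under an excess of rare variants);
expressions near gamma = 0 are evaluated by series below |gamma| < 1e−8 to
avoid cancellation.

## Site extraction and binning (`extraction`)

4-fold sites are third codon positions whose codon prefix belongs to one of
the eight fully degenerate families, required in all three references and
every sample haplotype; codons with two or more segregating positions are
excluded, as are genes contributing fewer than ten qualifying sites.  Sample
prefixes containing N are treated as uninformative rather than
disqualifying.  SI positions 8–30 are counted 1-based inclusive on the
gap-stripped focal reference (23 positions for an intron of length ≥ 30);
the < 66 bp length test also excludes alignment gaps.  Sites with more than
two distinct non-N sample alleles are dropped (biallelic restriction); N
calls are excluded from allele counts but do not remove the site.

Genes are ranked by the GC fraction of their qualifying focal-reference
sites (not whole-gene GC) and split into bins of near-equal gene counts
(difference ≤ 1), 20 autosomal and 4 X-linked by default, with SI sites
binned separately.  Ties are broken by gene id for determinism.

## Ancestral reconstruction (`ancestry`)

The *ms* ancestor (the mel–sim common ancestor) is inferred on the rooted
tree ((mel, sim) ms, yak).  The branch-nonstationary GTR gives each of the
four branches its own five free exchangeabilities and three free base
frequencies, plus three free root frequencies and four branch lengths:
3 + 4(5+3) + 4 = 39 free parameters.  The stationary comparator is a single
GTR on an unrooted star (5 + 3 + 3 = 11 parameters); the root is
unidentifiable in the stationary case, which is why the star is used there
and the rooted tree only for the nonstationary model.  The two are nested,
giving a chi-squared LRT with 28 df.

Likelihoods are computed over the 64 site-pattern counts; transition
matrices come from a symmetrized eigendecomposition (each branch's rate
matrix is reversible with respect to its own frequencies).  Optimization is
multi-start L-BFGS-B on log/softmax-transformed parameters; the
nonstationary fit always includes a start that embeds the stationary
solution, which guarantees the nesting inequality and makes the LRT
well-defined.  Ancestral-state posteriors marginalize the root analytically;
AWP is the full posterior vector per pattern, SBR its argmax (ties broken
A<C<G<T), and parsimony is the majority base with fully ambiguous patterns
(three distinct bases) flagged and excluded downstream.

Parsimony's bias matters in exactly the regime this package targets: when
both descendant lineages drift toward AT, parallel G→A changes produce
(A, A, G)-type patterns that majority rule polarizes wrongly.  In such
simulations the posterior-weighted expected substitution counts track the
planted truth to within sampling noise while parsimony misstates them by
tens of percent.

## Substitution statistics (`substitution`)

Expected counts compare the (possibly probabilistic) ancestor with the
extant reference per lineage; N_WS, N_SW, the within-class N_neu, and the
ancestral site totals L_W, L_S are accumulated per bin, with AWP totals
rounded to integers once at the aggregate level.  Rates are r_WS = N_WS/L_W
and r_SW = N_SW/L_S.  Test conventions: 2×2 contingency comparisons use
Pearson chi-squared with Yates continuity correction; 1:1 goodness-of-fit
uses the uncorrected (n1−n2)²/(n1+n2); 2×k heterogeneity tests use
uncorrected Pearson with k−1 df.  This specific combination reproduces the
published values of both test families from the printed count tables, which
is how it was pinned down.  Polymorphism-to-divergence ratios are reported
relative to the neutral class with a Yates-corrected 2×2 association test by
default and Fisher's exact test as an option (the choice is exposed because
no single convention is canonical).

## Spectra (`sfs`)

Polarity comes from the ancestral posterior restricted to the two observed
alleles and renormalized, so each SNP contributes fractionally to
(category, derived-count) cells; a hard argmax assignment is available for
parity with parsimony/SBR.  Sites whose posterior puts zero mass on both
observed alleles are flagged unpolarizable and excluded.  Categories are
W→S, S→W and neutral (A↔T, G↔C); monomorphic sites fill the fixed-W/fixed-S
classes used by the long-timescale model.  Rows with missing calls are
hypergeometrically projected down to a common sample size (default: the
minimum complete count; dropping is available), because both estimators
need a single frequency-class dimension.  Tajima's D follows the 1989
variance normalization and is validated against tskit on coalescent
simulations; per-gene statistics are averaged per bin.

## Short-timescale estimator (`glemin`)

An infinite-sites Poisson-field model for the three polarized spectra with
expected class counts theta_cat · r_i · I_i(gamma_cat), gamma_cat = +gamma,
−gamma, 0 for W→S, S→W, neutral.  The integral has the closed form
I_i(gamma) = C(n,i) B(i, n−i) (1 − e^−gamma · 1F1(i; n; gamma)) /
(1 − e^−gamma), evaluated with Kummer's function (adaptive quadrature is the
test oracle only); I_i(0) = 1/i.  The distortion factors r_i (r_1 ≡ 1) are
shared across the three categories, which is both what makes them a
demography correction rather than extra per-category freedom and what gives
the documented free-parameter counts: M0 = 3 + (n−2), M1 adds gamma, and
the starred variants add exactly two polarization-error rates — one shared
by the two selected categories and one for the neutral class (25 parameters
at n = 21, 21 at n = 17).  The alternative error split is configurable but
not the default.  Error mixing replaces class i with a (1−e, e) blend of
itself and the reverse class of the opposite category.

The likelihood is an independent-Poisson quasi-likelihood (x log mu − mu;
the x! term is dropped so fractional AWP counts are handled consistently —
all comparisons are within a dataset, where the omitted term is common).
Fitting profiles out theta and r by coordinate ascent — every mean is linear
in each coordinate, so each update is a closed form or a short concave
Newton solve — leaving a 1-D search over gamma (M1) or a 3-D Nelder-Mead
over (gamma, e_sel, e_neu) (M1*), multi-started.  This keeps a full M0+M1
fit near 0.3 s at n = 20, which is what makes 100-replicate calibration
tests affordable.

## Long-timescale estimator (`zc`)

A two-allele Wright-Fisher model for the *unpolarized* S-allele count
spectrum including the fixed classes, with reversible mutation
(theta = 4 N0 v, kappa = u/v), selection gamma = 4 N0 s (semidominant;
the heterozygote-disadvantage scaling is folded into gamma), and one
instantaneous size change: equilibrium at N1 = g·N0, then tau·2N0
generations at N0 before sampling.  Because monomorphic sites carry
information about base composition, gamma is informed by the long-term
history, not just current segregation.

Equilibrium sampling probabilities are exact: Wright's density
e^{gamma x} x^{4Nv−1} (1−x)^{4Nu−1} integrated against the binomial kernel
has the closed form C(n,i) B(a+i, b+n−i) 1F1(a+i; a+b+n; gamma), evaluated
in logs with the Kummer transform for gamma < 0.  The non-equilibrium phase
uses a discretized Wright-Fisher chain on a rescaled population of size
n_grid (default 200; floor 100), with per-generation increments chosen so
theta, kappa, gamma and tau are invariant under the rescaling; the
propagator is applied by binary powering (a dozen small matrix products
instead of thousands of vector products).  tau = 0 returns the ancestral
stationary form exactly; tau ≥ 10 returns the current-epoch stationary form
(the chain has mixed; this also caps the cost of likelihood evaluations).
The effective selection argument inside the stationary quadrature is
clipped at |gamma·g| = 100 to keep 1F1 finite; fits never approach this.

The likelihood is multinomial over classes 0..n.  ZC1 has 5 free parameters
(gamma, theta, kappa, g, tau), ZC0 fixes gamma = 0 (4), and the
constant-size variants ZC1c/ZC0c drop g and tau (3/2).  Fitting is
multi-start bounded L-BFGS-B in transformed coordinates; the step-change
variants warm-start from the corresponding constant-size fit (cheap, since
it only touches the closed-form stationary path), which both guarantees the
nesting inequality and avoids a slow-manifold local optimum near the
ergodic-tau boundary that pure random starting points can fall into.
Identifiability: for tau beyond a few units of 2N0 generations the data
carry no information about g; profile flatness there is expected and the
tau ≥ 10 cap makes it explicit.  Default restarts are 50 (configurable);
the tests use 2–3 with the warm start, which recovers the same optima on
the simulated problem sizes.

## Synthetic data (`simulate`)

* **Toy genomes**: genes of ATG + 4-fold codons + a short intron + codons +
  TAA on alternating strands, with planted reference substitutions and
  sample polymorphism, one over-long intron and one doubly-segregating
  codon to exercise the exclusion rules; the truth sidecar lists the exact
  extraction results.
* **Triplet alignments**: sites evolved down the rooted tree with the true
  *ms* state retained; the "gc-shift" scenario moves the target frequencies
  of both post-*ms* branches toward AT (root GC 0.6–0.7 → 0.3 by default),
  the regime where parsimony is misled by parallel changes.
* **Forward Wright-Fisher**: discrete binomial resampling at 2N copies with
  the same deterministic selection+mutation map as the estimator's grid;
  burn-in 10·2N1 generations at the ancestral size, instantaneous change,
  tau·2N0 further generations, binomial subsampling.  Sites are initialized
  *fixed*, Bernoulli at the Li-Bulmer composition for the locally scaled
  force: an interior initialization would bias the fixed-class composition
  (selection fixes S from frequency x with probability above Q), and
  composition relaxes only on the substitution timescale, far beyond any
  affordable burn-in.  N0 defaults to 500; the tests use N0 = 100 so that
  2e5-site runs finish in tens of seconds.
* **Poisson-field spectra**: independent Poisson draws around the
  short-timescale expectations, including polarization-error mixing.
* **Origination-fixation lineages**: ancestors drawn at the equilibrium GC
  for (kappa, gamma), then a two-state Markov chain with the *reduced*
  fixation rates; because both directions share the same time factor, the
  expected count ratio equals e^−(1−p) gamma at any elapsed time.
* **Admixture-bottleneck**: a two-deme mixture of equilibrium spectra with
  a growth-like singleton excess — explicitly a qualitative testbed, not a
  calibrated demographic model.

What the generators do *not* emulate: linkage (all sites independent, no
Hill-Robertson interference), alignment error, repeat content, orthology
mistakes, base-calling error beyond missingness, and context-dependent
mutation.  Passing tests therefore demonstrate correctness of the inference
machinery under the stated models, not robustness to every artifact of real
resequencing data.

## Problem sizes and tolerances used by the tests

Chosen once as desk-scale versions of the study conditions:

* Short-timescale recovery: n = 20, ~50k SNPs, 20 seeds, gamma = 2,
  each estimate required within ±20%.
* Long-timescale recovery: 200k forward-simulated equilibrium sites
  (N0 = 100), gamma = 1, kappa = 2; fits on a 100-point grid.
* Type-I error: 100 neutral replicates per estimator, rejection rate ≤ 7%
  at alpha = 0.05.  The neutral ZC datasets are multinomial draws from the
  model's exact stationary distribution (100k sites each); forward
  simulation remains the oracle elsewhere.
* Transient propagator vs forward simulation: 3×3 grid of gamma ∈ {0,1,2},
  tau ∈ {0.1, 0.5, 2}, g = 2, 50k sites per point; total-variation
  distance required < 0.015, i.e. Monte-Carlo noise (~0.005 at 50k sites
  over 21 classes) plus an O(1/N) allowance for the diffusion-scale
  rescaling between the simulator's literal population sizes and the
  estimator's rescaled grid.
* Reconstruction comparison: 500k sites under the parallel AT-shift; AWP
  must match or beat parsimony on expected sitewise accuracy (parsimony's
  no-calls score zero) and beat it on substitution-count error.
* The nonstationarity LRT null calibration uses 10 replicates at 30k sites
  with a ≤ 3/10 rejection bound (the 100-replicate version lives with the
  estimator calibrations, which are much cheaper per replicate).

## Known limitations

* The 39-parameter nonstationary GTR is fit to 63 free pattern frequencies;
  parameters sit on ridges (root frequencies trade off against the two
  root-adjacent branches) even though the likelihood, the LRT and the
  posteriors are stable.  Only the latter are consumed downstream.
* The grid propagator and a literal finite-N population differ at O(1/N);
  estimates are insensitive to n_grid above ~200 (probability-level
  agreement between 200 and 300 is ~1e−4), but very small real populations
  would need the literal chain.
* The Glemin-style distortion factors absorb demography only to the extent
  a shared per-class multiplier can; strong recent growth plus polarization
  error can still shift gamma estimates, which is precisely why the
  long-timescale model is fit alongside.
* No multi-epoch demographies beyond the one-step change; no
  distribution-of-fitness-effects extensions; no folded-spectrum analyses.
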