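# Methods

## Model

Observed data are read counts $W_{ij}$ for samples $i = 1..n$ and taxa
$j = 1..m$, with sequencing depths $N_i = \sum_j W_{ij}$.  The generative
model is

$$
\delta_{ij} \sim \mathrm{Bernoulli}(\pi_j), \qquad
X_i \mid \delta_i \sim \mathrm{Dirichlet}(\alpha_{1,\delta_{i1}}, \dots,
\alpha_{m,\delta_{im}}), \qquad
W_i \mid X_i \sim \mathrm{Multinomial}(N_i, X_i),
$$

so each taxon's Dirichlet shape is a two-point mixture: a low mode
$\alpha_{j,0}$ and a high mode $\alpha_{j,1}$ selected per sample by the
indicator $\delta_{ij}$.  Equivalently, absolute abundances are independent
gamma mixtures $Y_{ij} \sim (1-\delta_{ij})\,\Gamma(\alpha_{j,0}, \rho) +
\delta_{ij}\,\Gamma(\alpha_{j,1}, \rho)$ normalised by the total load; the
composition is independent of the scale $\rho$, which therefore appears
nowhere in the package.  A low mode far below 1 concentrates mass near
zero, which is how the model captures excess zeros; modes in proximity
recover an ordinary (unimodal) Dirichlet component.

Assumptions worth stating: taxa are conditionally independent given the
mode indicators (inter-taxon correlation is not modelled — the fit borrows
strength across *samples* of the same taxon, not across taxa); counts are
multinomial given the composition (no extra-multinomial technical noise);
samples are i.i.d.

## Inference

The posterior over $(X, \delta)$ is intractable (a sum over $2^m$ mode
configurations per sample), so it is approximated by the mean field
$\prod_i \mathrm{Dirichlet}(\beta_i) \prod_{ij}
\mathrm{Bernoulli}(\gamma_{ij})$, fitted by variational EM.

**E-step (coordinate ascent).**  The optimal Dirichlet factor is
$\beta_{ij} = W_{ij} + \gamma_{ij}\alpha_{j,1} +
(1-\gamma_{ij})\alpha_{j,0}$.  The Bernoulli factor requires
$E_q[\log\Gamma(\sum_k \alpha_{k,\delta_{ik}})]$, which is intractable;
by convexity of $\log\Gamma$ it is bounded below by
$\log\Gamma(\alpha_{j,\delta_{ij}} + s_{i,-j})$ with
$s_{i,-j} = \sum_{k \ne j} [\gamma_{ik}\alpha_{k,1} +
(1-\gamma_{ik})\alpha_{k,0}]$, giving the closed-form update
$\gamma_{ij} = \sigma(\mathrm{logit}\,\pi_j + h_{ij}(1) - h_{ij}(0))$ with

$$
h_{ij}(d) = \log\Gamma(\alpha_{j,d} + s_{i,-j})
 + (\alpha_{j,d}-1)\,(\psi(\beta_{ij}) - \psi(\textstyle\sum_k \beta_{ik}))
 - \log\Gamma(\alpha_{j,d}),
$$

computed in log space through the numerically stable logistic.  Updates
cycle over taxa with $\beta$ refreshed column-by-column until
$\max|\Delta\gamma| < 10^{-6}$ or 50 sweeps; rows (samples) are independent,
so the result does not depend on any parallel partitioning over samples.
A Monte-Carlo estimate of the intractable expectation would be possible but
is much slower and is not used for fitting.

**M-step.**  $\pi_j$ is the column mean of $\gamma$, clamped to
$[10^{-4}, 1-10^{-4}]$.  The shapes maximise

$$
F(\alpha) = \sum_i \log\Gamma\Big(\sum_j \bar\alpha_{ij}\Big)
 + \sum_{ij} (\bar\alpha_{ij}-1)\, t_{ij}
 - \sum_{ij} \big[\gamma_{ij}\log\Gamma(\alpha_{j,1}) +
   (1-\gamma_{ij})\log\Gamma(\alpha_{j,0})\big],
$$

$\bar\alpha_{ij} = \gamma_{ij}\alpha_{j,1} + (1-\gamma_{ij})\alpha_{j,0}$,
$t_{ij} = \psi(\beta_{ij}) - \psi(\sum_k \beta_{ik})$, via L-BFGS-B with
analytic gradients, box constraints $[10^{-6}, 10^{6}]$ and a warm start at
the previous shapes; all $2m$ components are optimised jointly because the
$\log\Gamma(\sum_j \bar\alpha_{ij})$ term couples taxa.  If the optimiser
fails to improve $F$, the previous shapes are kept.

**Surrogate ELBO and monotonicity.**  The recorded objective replaces the
intractable expectation by the same Jensen bound
$\log\Gamma(\sum_j \bar\alpha_{ij})$, so it (a) lower-bounds the exact log
marginal likelihood — verified against $2^m$ enumeration in the tests —
and (b) is provably non-decreasing under the $\beta$ update, the $\pi$
update and the $\alpha$ ascent.  The $\gamma$ update optimises the
per-coordinate chord bound rather than this surrogate, so its monotonicity
is not a theorem; it is instead property-tested (tolerance $10^{-8}$
relative) and has never been violated on tested instances.  Outer EM stops
when the relative surrogate change drops below $10^{-6}$ or after 100
iterations (typical fits take a few tens).

**Identifiability.**  Labels are fixed by the convention
$\alpha_{j,0} \le \alpha_{j,1}$; a violation after the M-step is repaired
by swapping the pair together with $\gamma_{\cdot j} \to 1-\gamma_{\cdot j}$
and $\pi_j \to 1-\pi_j$, which leaves the likelihood unchanged.  When the
data are genuinely single-mode the mixture collapses
($\alpha_{j,1} \to \alpha_{j,0}$) and $\pi_j$ becomes arbitrary; the
identifiable quantity is then the effective shape
$\pi_j\alpha_{j,1} + (1-\pi_j)\alpha_{j,0}$, and the tests assert exactly
that.

**Initialisation** (deterministic): responsibilities from a per-taxon
median split of log relative abundance (pseudocount 0.5) at 0.8/0.2;
shapes from a method-of-moments Dirichlet fit, split into
$0.1\hat\alpha$ / $2\hat\alpha$; $\pi$ from the initial column means.
All-zero taxa are retained (their imputation is prior-driven); zero-depth
samples are rejected at load; single-sample tables are refused.

## Imputation outputs

The imputed composition is the variational posterior mean
$\hat X_{ij} = \beta_{ij} / \sum_k \beta_{ik}$ — strictly positive, so
log-scale analyses need no pseudocount.  Multiple imputations draw
$X_i \sim \mathrm{Dirichlet}(\beta_i)$ per sample; the mode indicators are
already marginalised into $\beta$ through $\gamma$, so no $\delta$ is
sampled.  An exact-oracle routine enumerates all $2^m$ configurations
(refused above $m = 15$) with log-space weight accumulation; it exists for
validation, not production use.

## Simulators

The well-specified generator draws from the model above.  Default study
design: 80 samples, 100 taxa, depths log-uniform on [5000, 50000] — a
typical genus-level cross-sectional study.  The `combo-like` preset mixes
the three archetypes seen when the model is fitted to real gut data: 40%
zero-spike taxa ($\alpha_0 \sim U(0.001, 0.05)$,
$\alpha_1 \sim \mathrm{LogU}(0.5, 20)$), 30% bimodal
($\alpha_0 \sim \mathrm{LogU}(0.1, 1)$, ratio $\mathrm{LogU}(5, 50)$), 30%
near-unimodal (ratio $U(1, 2)$), $\pi \sim U(0.2, 0.8)$.  The `separated`
preset makes every taxon strongly bimodal with $\pi = 1/2$ and is used for
parameter-recovery checks.

Misspecified generators draw absolute abundances from gamma or log-normal
marginals coupled by a Gaussian copula with exchangeable correlation 0.4
inside consecutive blocks of 10 taxa (one shared factor per block), then
multinomial counts; or build a correlated log-normal count-mean matrix and
draw Poisson / negative-binomial (dispersion 5) counts directly, in which
case row totals are random with the requested depth as expectation.
Marginal choices — gamma shape $U(0.5, 2)$, per-taxon mean
$\mathrm{LogNormal}(0,1)$, log-normal $\sigma = 1$ — were fixed once as a
realistic genus-level spread (two orders of magnitude between common and
rare taxa, overdispersed within taxon).  These generators emulate
inter-taxon correlation and model misspecification; they do **not** emulate
real-data features such as phylogenetic structure, batch effects, varying
library-preparation biases or taxon-specific detection efficiencies, so
passing benchmarks here demonstrates robustness to the stated
misspecifications only.

`spike_signal` splits samples into two balanced groups and multiplies the
absolute abundance (or count mean) of a 10% subset of taxa in group 1 by
$e^{\pm U(\log 2, \log 4)}$ with random sign — a moderate, mixed-direction
signal — then regenerates compositions and counts.

## Recovery metrics

Fifteen metrics in three categories; the aggregation rules are this
package's own fixed definitions (standard forms, stated in
`bmdd.metrics`): mean squared error over entries; mean Euclidean row /
column distance; mean over samples of |Shannon or Simpson difference| and
of Bray-Curtis, KL (truth as reference, $10^{-12}$ guard), base-2
Jensen-Shannon and Hellinger divergences; mean over rows of |Gini
difference|; Euclidean distance between concatenated per-taxon (mean, sd)
vectors; mean over taxa of |CV difference|, of two-sample KS and of
Wasserstein distances across samples; mean absolute difference of
taxon-taxon correlation upper triangles (constant taxa contribute 0).
Baselines: do nothing, add pseudocount 1, zeros→0.5, and a depth-ratio
zero replacement $N_i / \max\{N_k : W_{kj} = 0\}$.

## Multiple-imputation differential abundance

Per posterior draw, each taxon's log abundance is regressed on the
covariate by closed-form OLS.  The sum-to-one constraint shifts all slopes
by a common nuisance constant; with sparse signal the mode of the slope
vector estimates it, located by a Gaussian-KDE argmax (Silverman
bandwidth, 2048-point grid) — a simplified mode-centring correction, not a
reproduction of any published tool.  Draws are pooled by Rubin's rule
($\bar q$, $T = \bar U + (1+1/M)B$) with Barnard-Rubin degrees of freedom
(complete-data df $n-2$), followed by Benjamini-Hochberg.  Winsorization
at an upper quantile (0.97 conventionally) is available and off by default
in simulations.  100 imputations are a sensible production default; the
benchmark harness uses 20.

## Problem sizes and numerical choices

Test-suite and acceptance-script workloads: oracle agreement at $n=20,
m=5$, depth 500; ELBO bound on 20 random instances with $m \le 6$;
recovery over 20 seeds at $n=500, m=10$, depth $10^4$; imputation
benchmark over 10 replicates of the 80×100 default design; DAA benchmark
under the gamma model at $n=100, m=50$, 10% differential taxa, 20
imputations, 50 replicates, nominal FDR 0.05.  These sizes keep every run
in the minutes range on a single core while leaving the Monte-Carlo error
well below the margins being asserted.

Tie-break: when $h_{ij}(1) = h_{ij}(0)$ (e.g. equal modes),
$\gamma_{ij} = \pi_j$ exactly.  Standard errors of constant taxa are
floored at $10^{-12}$.  All randomness flows from one seed through
`numpy` `SeedSequence` substreams; fits are deterministic given data and
configuration.

## Limitations

The mean-field posterior underestimates joint uncertainty (intervals are
approximate — empirical 95% coverage on zero cells is near but below
nominal); inter-taxon correlation is ignored by design, trading power for
robustness against signal leakage between correlated taxa; the ELBO
surrogate's monotonicity under the $\gamma$ update is empirical, not
proven; covariate- or phylogeny-informed priors and mixed-effects pooling
of imputations are out of scope.
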