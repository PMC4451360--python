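# Methods

## Scope and model

`instmfa` estimates steady-state carbon fluxes in photoautotrophic central
carbon metabolism from isotopically non-stationary 13CO2 labeling data.
After a switch to 13CO2, the fraction of each metabolite pool that is still
fully unlabeled decays from 1 toward a plateau; the shape and delay of that
decay carry information about fluxes and pool sizes.  The package simulates
exactly this mass-zero layer — for every simulated pool the unlabeled
fraction x_n(t), equivalently the mass-state-zero EMU / weight-n cumomer
variable — and fits the model to observed unlabeled fractional contents.

### Network

The reference network covers the Calvin–Benson cycle (CBC) boundary, a
simplified photorespiratory pathway and the starch, sucrose and trehalose
synthesis chains, with 18 simulated pools:

3PGA, DHAP, FBP(pl), F6P(pl), G6P(pl), G1P(pl), ADPG, FBP(cyt), F6P(cyt),
G6P(cyt), G1P(cyt), UDPG, Suc6P, Tre6P, Gly, Ser, glycerate (Glyc), 2PGA.

CBC intermediates between 3PGA/DHAP and RuBP are not state variables: the
labeling state of the system is driven entirely by RuBP (through measured
cumomer input functions) and CO2 (whose unlabeled fraction is taken as zero
from the start of labeling).  RuBisCO carboxylation produces two 3PGA per
event, one from the RuBP C1–C3 fragment (unlabeled with probability y_3)
and one containing the fixed CO2 (never unlabeled), so the unlabeled
production fraction is y_3 / 2.  Oxygenation yields 3PGA (y_3) and a
2-carbon unit entering Gly (y_2).  Two Gly condense to Ser with one carbon
released; an unlabeled Ser requires both glycines unlabeled (x_Gly^2).
Condensations are bilinear in the same way for FBP (x_DHAP^2, both
compartments draw on the one simulated triose pool), Suc6P
(x_UDPG · x_F6Pcyt) and Tre6P (x_UDPG · x_G6Pcyt).  The exact
reaction-level stoichiometry of this model family is not available in a
redistributable form; the reaction list used here is this
repository's documented convention, chosen to reproduce the known structure
(7 reversible reactions, 4 net termini, photorespiratory re-entry of Glyc
into 3PGA) exactly.

All fluxes and contents are carried in carbon-atom units (nmol C gFW^-1
s^-1 and nmol C gFW^-1), which makes the time constant k_n = F_n / p_n
unit-consistent without molecule/carbon conversion factors.

### Flux parameterization

The steady-state flux space is parameterized by 11 modes: 4 elementary flux
modes (EFMs) of the net system — terminating in starch, sucrose, trehalose,
and photorespiratory CO2 release — plus 7 futile exchange cycles, one per
reversible reaction.  EFMs are enumerated by a double-description
computation of the extreme rays of {v >= 0, S v = 0}, with RuBP balanced by
a lumped CBC-regeneration reaction (which is what forces carboxylation and
oxygenation to appear in the correct 6:10 carbon proportions inside the
photorespiration mode) and the pure-exchange 2PGA appendage excluded.  Each
net mode is normalized so its weight equals its terminal carbon rate; gross
carbon fixation is then exactly the sum of the four weights, and net
fixation is gross minus the photorespiration weight — which is what makes
the reference flux tables additive.

Exchange fluxes are optimized through the hyperbolic transform
f = scale · θ / (1 − θ) with θ in [0, 1).  The exact form of the transform is
not standardized beyond its name; this form is the package's convention.
`scale` defaults to the current gross fixation, and f is capped at
10^4 × scale — effectively irreversible mixing — and printed as "Inf.".

### RuBP inputs

Measured RuBP mass-isotopomer fractions are converted to unlabeled cumomer
fractions y_s with hypergeometric weights θ_s^i = C(N−s, i)/C(N, i)
(exact when label is uniformly distributed within each mass isotopomer; on
binomial labeling data the conversion reproduces y_s = u^s exactly, which
the tests exploit).  Each y_s series is condensed into a two-exponential
input model A e^{-a t} + B e^{-b t}, A + B = 1, fitted by bound-constrained
least squares over (A, log a, log b) from 10 log-spaced rate starts.  The
network references sizes s = 2 (oxygenation fragment) and s = 3
(carboxylation fragment).

### Simulation

The ODE system dx_n/dt = (1/p_n)[Σ_r F_in,r,n h_r,n(t) − F_n x_n] is
assembled into a dense linear matrix, a short list of bilinear terms and
exponential forcing vectors, with an analytic Jacobian.  Integration uses
stiff implicit multistep methods: scipy's BDF at rtol 1e-8 / atol 1e-10 by
default, or the Fortran LSODA stiff path at rtol 1e-6 / atol 1e-8 inside
fitting loops (the two agree to ~1e-6 on the reference system, well below
measurement noise).  States are clipped to [0, 1] only on output.  The
stiffness is real: capped exchange fluxes produce time constants up to
~1e5 s^-1 against observation times of 3600 s.

### Observation model

A metabolite measured as one pool predicts z = (1−φ) x + φ; plastid/cytosol
pairs (FBP, F6P, G6P, G1P) predict the active-pool-size-weighted mean of
the two trajectories before the same offset.  Compartment twins share one
inactive fraction φ because fractionation data cannot split an inactive
pool.  The inactive fraction of Tre6P is fixed to zero: the trehalose
branch shows no plateau, and fixing its observed intermediate keeps 13 free
inactive fractions, consistent with the 24-parameter accounting of
Scenario A.  (Whether the zero-plateau constraint belongs to Tre6P or to a
separately observed trehalose content is ambiguous in the source
description; the Tre6P reading keeps 14 observed metabolites × 7 times =
98 data points and is configurable.)

## Fitting

Scenario A fixes all 18 contents at their measured values and minimizes
VWSS_t (98 points, 24 parameters, 73 degrees of freedom by the
N − P − 1 convention that reproduces the reference 98/24 → 73 and
116/42 → 73 counts).  Scenario B frees the contents inside
[max(ε, mean − 4σ), mean + 4σ] and minimizes VWSS_all = VWSS_t + VWSS_c.
Scenario C frees 15 contents in [1e-5, 4e4] nmol C gFW^-1, pins 3PGA, DHAP
and 2PGA at their measured values with their mutual exchange at the cap
(one combined pool of fixed size, which anchors the otherwise
scale-invariant problem), and minimizes VWSS_t; its reference df = 59 is
taken as configuration since the exact parameter accounting behind it is
not reconstructable.  Time-course residuals are weighted by the
metabolite-mean variance rather than per-point variances to avoid
over-fitting single points.

Optimization is multistart local search: starts are drawn log-uniformly for
mode weights (1e-3 to 1e2) and contents (within bounds), uniformly for
exchange parameters and inactive fractions, plus one data-informed start
(plateau-level inactive fractions, measured contents).  Each start gets a
short derivative-free screening search (Powell, bounded); the best
candidates are refined by a bounded trust-region least-squares pass on the
variance-scaled residual vector, and the winner alternates full Powell and
least-squares rounds until the objective stops improving.  The screening
stage preserves the multistart robustness of a Subplex-style protocol while
the least-squares polish supplies the deep local convergence (to ~1e-9 in
the objective on noise-free data) that a simplex-family method alone
reaches only with very large evaluation budgets.  Default restarts: 100;
the recovery tests use 6–20, which the noise-free round trip shows to be
sufficient on synthetic data.

Confidence intervals are a parametric Monte-Carlo bootstrap: observations
are resampled as model prediction at the optimum plus Gaussian noise with
the observed variances, and each replicate is refitted warm-started from
the optimum (reduced budget).  Intervals use the pivotal (basic) bootstrap
construction — the 2.5/97.5 percentiles of the replicate deviations from
the optimum, reflected about the optimum — rather than raw replicate
percentiles: the replicate distribution approximates the distribution of
the estimation error, and reflecting it preserves nominal coverage when
the estimator is biased (which the weakly identified sucrose/starch split
visibly is on noisy synthetic data).  Replicate failures are excluded;
more than 20% failures aborts.

## Sensitivity analysis

Each optimized content is scaled over the grid 50, 60, 70, 80, 90, 95, 99,
101, 105, 110, 120, 130, 140, 150% of its optimum (the unperturbed 100%
point is not part of the regression), held fixed while everything else is
re-optimized (3 warm-started restarts by default), and the sensitivity is
the OLS slope of relative response against relative perturbation, with a
free intercept.  If |r| < 0.5 the sensitivity is reported as zero.  The
k·p structure of the model makes the trehalose-synthesis flux respond
one-to-one to the Tre6P content — the observed Tre6P delay pins
k = F/p, so F scales with p — and the tests verify a slope of 1 ± 0.2.

## Synthetic data

The generator emulates the study conditions: sampling at 5 s, 10 s, 1, 3,
10, 20, 60 min; 14 observed metabolites; contents drawn at the reference
means (or within ±2σ for the random preset); RuBP labeling per-carbon
exponential, u(t) = φ_R + (1−φ_R) e^{−λt} with λ = 0.02 s^-1 and
φ_R = 0.05, chosen so the 3-carbon cumomer halves within about a minute
(CBC intermediates label fast); binomial mass isotopomers realize the
uniform-labeling assumption exactly.  Time-course noise is Gaussian with
sd = max(cv · value, 0.005) at cv = 0.05 by default (the floor also keeps
variance weights finite); content "measurements" are perturbed by the
reference standard deviations.  The default inactive fractions (0.1–0.4,
zero for Tre6P) are round plateau levels in the range real rosette data
show.  Because the generator runs the same forward model the estimator
inverts — including the same fitted two-exponential input models — a
noise-free dataset is an exact round trip; passing recovery tests therefore
demonstrate the correctness and identifiability structure of the pipeline,
not robustness to model misspecification (channeling, unmodeled glycolate
pools, slow quenching or natural-abundance artifacts of real data).

## Numerical choices and limitations

* Degenerate inputs: constant cumomer series return the a = b = 0 input
  model with a warning; pools with influx but zero active size are rejected
  with the pool named; integration failures and non-finite states raise.
* Objective evaluations that fail inside a fit return a large penalty, and
  the least-squares polish treats them as saturated residuals.
* The combined-pool cap makes exchange parameters beyond the cap
  non-identifiable by construction; capped values are reported as "Inf.".
* Problem sizes in the shipped tests and acceptance script (restarts 6–20,
  8–10 Monte-Carlo replicates, 2–4 sensitivity levels) are reduced relative
  to the defaults (100 restarts, 100 replicates, 14 levels); they are the
  sizes at which the synthetic recovery results stabilize.
* Scenario C deliberately reports an unidentifiable starch/sucrose/
  trehalose split; only the photorespiration-to-gross-fixation ratio (and
  flux/pool-size ratios generally) is meaningful there, and the CLI prints
  a warning to that effect.
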