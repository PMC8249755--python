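# Methods

`megdcm` implements a complete, testable analysis chain for evoked
magnetoencephalographic (MEG) responses in a four-region emotional-face
network: a conductance-based neural-mass generative model, variational
Bayesian inversion, Bayesian model selection between two message-passing
architectures, a second-level parametric-empirical-Bayes (PEB) analysis of
group/drug effects, and the accompanying clinical/behavioral statistics.
Because the kind of source-level dataset this pipeline consumes is rarely
shareable, the package ships a synthetic-study generator with known ground
truth; every quantitative claim made by the test suite is a statement
about this generator's output, not about any particular empirical
recording.

## Generative model

Each region contains four populations — spiny stellate cells (ss),
superficial pyramidal cells (sp), inhibitory interneurons (ii), deep
pyramidal cells (dp). Population membranes integrate leak, AMPA, GABA and
NMDA conductance currents,

    Cm dV/dt = g_L (V_L − V) + g_ampa (V_E − V) + g_gaba (V_I − V)
             + g_nmda m(V) (V_E − V) + C u(t),

with a voltage-dependent magnesium-block gate on the NMDA channel,
`m(V) = 1/(1 + 0.2 exp(−a_mg V))`, evaluated at the postsynaptic membrane
potential. Each dimensionless channel conductance relaxes toward its
presynaptic drive at the receptor rate constant κ (the inverse of the
channel time constant):

    dg_k/dt = κ_k ( Σ_pre γ_pre σ(V_pre) − g_k ),

where `σ(V) = 1/(1 + exp(−(V − V_thr)/s))` is the population firing-rate
sigmoid. Intrinsic excitatory connections (ss→sp, ss→ii, sp→dp, dp→ii)
are carried by AMPA and NMDA; intrinsic inhibition (ii→ss, ii→sp, ii→dp
plus an inhibitory self-gain on every population) by GABA. Between
regions, superficial pyramidal cells project forward onto spiny stellate
cells and deep pyramidal cells project backward onto superficial pyramidal
cells and inhibitory interneurons, each projection carrying separate AMPA
and NMDA drive gains. A Gaussian "thalamic" input bump (default onset
64 ms, width 16 ms) drives the spiny stellate cells of early visual
cortex. The observed evoked response per region is a fixed mixture
J = (0.2, 0.8, 0, 0.2) of (ss, sp, ii, dp) depolarizations about the
resting state, scaled by a per-region gain.

Two architectures are compared: Model 1, a serial hierarchy
EV → Fusi → Amy → IFG with reciprocal backward connections, and Model 2,
which adds a direct reciprocal EV ↔ IFG pathway. Face emotion (happy vs.
the angry reference) scales both receptor components of every
region-to-region connection by exp(B_edge), with a per-edge modulator B.

All tunable quantities are log-scalings of shipped defaults, so a
parameter vector of zeros is the default model and priors are zero-mean
Gaussians on log-scalings.

### Fixed constants and default magnitudes

Membrane/gating constants: V_L = −70, V_E = 60, V_I = −90, V_thr = −40 mV,
s = 8 mV, a_mg = 0.06 mV⁻¹, g_L = 1, Cm = 32 ms (lumped membrane time
constant). Receptor time constants: AMPA 2.2 ms, GABA 5 ms, NMDA 100 ms.

The coupling magnitudes were chosen, with the constants above fixed, so
that (a) the default fixed point is stable under log-perturbations of at
least ±0.5 on the free parameters, (b) the dominant network response
peaks at ~100–130 ms (the early-visual source necessarily peaks slightly
earlier, input-locked at ~85 ms), and (c) the receptor rate constants —
particularly NMDA — are identifiable from a single evoked dataset at the
study's noise level (linearized Fisher-information analysis). The last
point drives the one unusual-looking choice: the granular-to-superficial
(ss→sp) projection is NMDA-dominated (NMDA:AMPA weight ratio 8), giving
every region a pronounced slow response component whose kinetics carry
the local NMDA rate constant. With a uniformly small NMDA ratio the NMDA
rate constants are nearly unidentifiable at realistic SNR.

## Numerics

* Fixed points: the channel equilibria are eliminated analytically
  (g*_k = drive at V*), leaving a 16-dimensional membrane balance solved
  by damped Newton with a finite-difference Jacobian; elements that stall
  are settled by 3 s of input-free integration and re-solved. The
  residual tolerance is 1e−8 on the state derivatives.
* Integration: fixed-step RK4, 1 ms by default (2 ms for study-scale
  fitting), starting at the steady state at the epoch start. Step-halving
  agreement of the observed response is verified to <1e−3 of peak.
* All simulation paths (including the fitter's finite-difference sweeps)
  run through one compiled, batched kernel; a plain NumPy reference
  implementation of the derivative field is kept as the public `dstates`
  and cross-checked to 1e−12 against an independent loop-based
  re-implementation in the tests.
* Divergent parameter proposals (possible during optimization) are frozen
  by the integrator and surface as enormous residuals, so the optimizer
  simply rejects them.

## Variational inversion

Inversion maximizes the free-energy bound
F = E_q[log p(y|θ)] − KL(q‖prior) with Gaussian q, by Gauss–Newton ascent
with Levenberg–Marquardt damping on the log-scaling parameters. A step
whose re-evaluated F falls below the best value so far is reverted and
the damping increased, making the accepted-step F sequence non-decreasing
by construction. Observation noise is independent Gaussian per region
with its own precision, updated by EM between parameter steps; no
temporal autocorrelation is modeled (a declared simplification — the
zero-phase 50 Hz low-pass applied identically to data and predictions
leaves residuals mildly correlated, so first-level posterior variances
are optimistic; the second level's between-subject variance component
absorbs this on average). The likelihood window is 1–500 ms peristimulus.
Sensitivities are numerical central differences (step 1e−3) batched
through the compiled integrator; the sensitivity matrix is reused across
damping retries within an iteration. On linear-Gaussian problems the
procedure reproduces the conjugate posterior and the exact log evidence
to machine precision (tested at 1e−4/1e−6).

Following the two-pass procedure, each dataset is inverted from the prior
mean and then re-inverted from the first posterior mean, keeping
whichever pass attains the higher F.

Prior variances: 1/8 for connection gains and emotion modulators, 1/16
for rate constants, input and observation parameters. Default
convergence: ΔF < 1e−2 nats, 64-iteration budget (study-scale batteries
use 10 + 4 sweeps; truth-initialized control fits reach the same optima).

## Model comparison

Fixed-effects: softmax of column-summed free energies. Random-effects:
the variational Dirichlet scheme over per-subject model evidences
(subject evidence = sum of session free energies), with exceedance
probabilities estimated from 1e5 seeded Dirichlet draws. α₀ = 1.

## Second level (PEB)

The design has four columns — mean, group (TRD +½ / HV −½), drug
(ketamine +⅔, baseline/placebo −⅓) and their product — over
subject-session fits. Two refinements over the most naive per-parameter
scheme are applied by default, both motivated by the structure of the
default injected effects:

1. **Shrinkage removal.** First-level posteriors are deflated to
   data-only estimates (prior precision subtracted in the full parameter
   space); directions the data do not inform get enormous variance and
   thus no second-level weight. Without this, rows with large true
   parameter excursions are differentially shrunk and within-design
   contrasts are biased toward zero.
2. **Joint GLS across parameters.** The second-level model is fit jointly
   over all first-level parameters using each fit's full posterior
   covariance, because estimation errors of kinetically similar
   parameters (e.g. NMDA rates of successive regions) are strongly
   correlated; modeling those correlations is what allows
   opposite-signed effects on collinear parameters to be separated.
   Effects are then assessed by rank-one Bayesian model reduction
   (prior variance of one coefficient shrunk to 1e−8), reported as
   Pp = σ(F_full − F_reduced) with a 0.95 reporting threshold.

The per-parameter independent model (analytic, conjugate-checkable)
remains available via `PebPriors(multivariate=False)`; the two coincide
for a single parameter. Between-subject variance is estimated per
parameter by EM with a 1e−6 floor; the β prior variance is ¼.

## Synthetic studies

A study draws per-subject-session log-scalings λ = Xβ_true + b_subject +
e_session with b ~ N(0, 0.02²) shared across a subject's sessions and
e ~ N(0, 0.02²) per session — deliberately tight parameter homogeneity so
that the printed group-level effect magnitudes (0.13–0.53) dominate
individual variability. Default injected effects: group×drug on the EV
GABA rate (−0.1274) and the EV/Fusi/Amy NMDA rates (+0.1994, −0.1723,
+0.1502), plus a drug effect on the Amy NMDA rate (+0.5303). Evoked
responses are simulated from Model 2 for both conditions on a
−100…500 ms, 2 ms grid, and i.i.d. Gaussian observation noise is added
per region at SNR 4 (each region's own noiseless RMS over 1–500 ms
divided by 4 — source-level time series are conventionally scaled per
source, and a global SNR would leave deep weak sources far below the
nominal level).

What the generator does **not** emulate: single-trial variability and
trial averaging (cells are condition-average traces by construction),
temporally correlated sensor noise, source-leakage/cross-talk between
regions, latency jitter between subjects, and any model mismatch — the
fitted model family contains the generating model. Passing recovery
tests therefore demonstrate internal consistency of the pipeline at
realistic noise, not robustness to the mismatches real MEG data add.

The linked clinical tables draw TRD MADRS scores from the configured
session distributions and construct the ketamine-session improvement as
a linear combination of the standardized true baseline-minus-ketamine
changes of the coupled parameters (EV AMPA rate, target r = 0.4917; EV
spiny-stellate self-gain, target r = −0.6545) plus calibrated Gaussian
noise. With a single coupling and zero noise the empirical correlation
is exactly ±1. Dot-probe behavior is generated per trial with
group/session accuracy offsets and a configurable congruency RT bias
(0 by default).

## Known limitations

* First-level noise is modeled as white after low-pass filtering;
  posterior variances are therefore optimistic by a roughly constant
  factor (absorbed, on average, by the second-level variance component).
* The NMDA rate constants of successive regions remain partially
  collinear (a cascade of similar low-pass kernels); at the scaled-down
  replicate size (8+8 subjects) the weakest injected interaction effects
  sit near the detection boundary, and individual replicates can fail to
  flag them.
* Per-parameter PEB reports are exact only under the independent model;
  the default joint model's per-row covariances come from the Laplace
  approximation at the posterior mode.
* The pipeline starts at source-level time series; sensor-space
  processing, source localization and lead fields are out of scope.
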