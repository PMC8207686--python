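# Methods

## Models

### Two-variable effective-regulation models

The variables B and W are the *total* BRAVO and WOX5 expressions integrated
over the stem cell niche — there is no spatial structure and no separation
of transcription from translation; every intermediate step is absorbed into
the promoter-activity functions. Both models share

    dB/dt = alpha*A0 + P_B(B, W) - d_B*B
    dW/dt = gamma*G0 + P_W(B, W) - d_W*W

with P_B(B, W) = alpha * [1 + eps_B (K_B B)^2]/[1 + (K_B B)^2]
                       * [1 + eps_W (K_W W)^2]/[1 + (K_W W)^2].

Hill exponents are fixed at 2 and are not configurable: the exponent is part
of the model definition, not a tuning knob. The constraint eps_B < 1
(self-inhibition) and eps_W > 1 (activation by WOX5) is enforced at
construction; parameter sets violating it are rejected.

The WOX5 promoter defines the variant:

* **alleviation** — P_W = gamma*W0^2 / (W0^2 + W^2*[B1*B0^2/(B^2+B0^2)+1]^2).
  The bracket is the self-repression strength: (1+B1) with no BRAVO, decaying
  to 1 at saturating BRAVO, so B1 is the maximum alleviation and B0 its BRAVO
  threshold. The squared bracket is the reading consistent with the
  bravo-knockout limit P_W(0, W) = gamma*W0^2/(W0^2 + W^2 (1+B1)^2) and with
  B1 as "maximum alleviation" semantics; the alternative (square only on part
  of the bracket) reproduces neither.
* **activation** — P_W = gamma * W0^2/(W0^2+W^2) * [1 + B1*B^2/(B^2+B0^2)]:
  WOX5 self-repression times a WOX5-independent activation by BRAVO of
  maximum strength B1.

The comparable quantity is the *stationary promoter activity* (pB, pW): at
steady state expression is proportional to promoter activity (B = pB/d_B),
and reporter GFP intensity has an arbitrary scale, so only mutant/WT
fold-changes of pB and pW are meaningful.

### Genotypes

Knockouts clamp the mutated expression to zero at all times; the promoter
functions are still evaluated (at the clamped state) because the reporter
remains active in the mutants. Parameter values are never altered in
mutants. Overexpression adds alpha*A0 (BRAVO) or gamma*G0 (WOX5) to the
production term; A0 = G0 = 100 by default, with an optional saturation check
that escalates the extent tenfold until the regulated read-out moves by less
than 1% (error after six escalations). The overexpression read-outs pB, pW
are the *endogenous* promoter activities, excluding the transgene term.

### Complex-formation model

Six species: free B, W, S and heterodimers C_BW, C_BS, C_WS with mass-action
binding lambda_XY, unbinding mu_XY and complex decay d_XY. Production of B
follows P_B on the free proteins, production of W carries only WOX5
self-repression (gamma*W0^2/(W0^2+W^2)), S is produced at constant beta.
Complexes are transcriptionally inert and only pairwise (no higher-order
species). In knockouts the free protein and every complex containing it are
clamped (their only source vanishes). S has no knockout/overexpression
genotype; beta is a sweep axis.

A structural redundancy worth knowing: at stationarity C_XY =
lambda*X*Y/(mu+d), so each complex drains the free proteins at net rate
lambda*d_XY/(mu_XY+d_XY)*X*Y — free-protein steady states depend on the
complex parameters only through that combined factor. This is why the
exploration freezes all decay rates and unbinding coefficients (varying them
alongside the lambdas would sample redundant directions).

## Parameter defaults

* alpha = 0.3 and gamma = 25 everywhere: the control-medium values of the
  medium parameterization alpha = 0.3/x, gamma = 250x/(x+9) at x = 1. Larger
  x (Brassinolide-like media) lowers alpha and raises gamma.
* The shipped two-variable defaults (`data/alleviation_calibrated.yaml`,
  `data/activation_calibrated.yaml`) are produced by the calibration
  pipeline (below), not hand-picked.
* The complex-model defaults (`data/complex_default.yaml`) are
  implementer-chosen: a grid search selected a regime where the BRAVO-WOX5
  heterodimer is a non-trivial fraction (~10%) of total WOX5 in the WT,
  free BRAVO *decreases* in the wox5 knockout (the competitor, freed from
  WOX5, sequesters BRAVO more) and free WOX5 barely changes in the bravo
  knockout. That regime needs a long-lived BRAVO-WOX5 dimer
  (mu_BW = d_BW = 0.2) with lambda_BW = 5, moderate competitor coupling
  (lambda_BS = lambda_WS = 2, beta = 10) and W0 = 1. These are stand-ins for
  unpublished constants and carry no empirical weight.

## Stationary solving

Two independent routes:

1. **Root-finding** on the algebraic stationary system (scipy's `hybr`, a
   modification of Powell's hybrid method), on the unclamped variables only.
   Negative trial points are evaluated at the clipped state with a linear
   push-back so no root sits at negative values.
2. **Time integration** (LSODA, rtol 1e-10) from the all-zero state in
   geometrically growing chunks until max |dX/dt| < 1e-8 * max(|X|, 1)
   per component. Failure to settle raises (oscillation or slow mode), it is
   never silently accepted.

The canonical solution is the basin of the all-zero initial condition — a
developmental "switch-on" reading. `solve_stationary` integrates, polishes
with the root-finder, and if the polished root drifts from the endpoint
beyond 1e-4 on the state scale the endpoint wins and a warning is recorded.
Stability is classified by the eigenvalues of a central finite-difference
Jacobian (step 1e-6 * max(|X|, 1), clamped variables excluded); seeded
multistart (8 random starts by default) reports multistability rather than
hiding it. In the default and calibrated regimes all solves are monostable.

For the two-variable models a fast bracketed path exploits monotonicity: at
fixed W the BRAVO balance is strictly decreasing in B (eps_B < 1), so B(W)
is a unique `brentq` root, and substituting it leaves one bounded scalar
equation in W. The calibration and exploration loops use this path; tests
pin it against the canonical solver at 1e-7 relative.

## Calibration

Free parameters: eps_B, eps_W, K_B, K_W, W0, B0, B1, d_B, d_W (alpha, gamma
fixed). Objective: weighted squared error on log fold-change ratios for the
two equality targets (pB^wox5/pB^WT = 0.5, weight 10; pW^bravo/pW^WT = 0.8,
weight 10) plus hinge penalties (margin 0.05 in log space) for the
direction-only constraints — pB up in bravo, pW up in wox5 and the double
mutant, pB down in the double mutant, pB up under WOX5 overexpression, pW
not below WT under BRAVO overexpression — and for the WT ordering B < W.
The directions carry no printed numbers, hence inequalities, not equalities.

Optimizer: Nelder-Mead on log-parameters, multistart (default 8 seeded
starts: one neutral center plus log-uniform draws over broad positive
ranges), max 600 iterations per start. Derivative-free because the
objective is cheap and mildly rugged while the parameter count is small.
The winning set is re-verified on the canonical (integration-anchored)
solver and the fit fails loudly unless every equality target is within 10%
relative; in practice the optimum reproduces both targets to ~1e-10. With
two equality constraints and nine free parameters the solution manifold is
high-dimensional — the shipped set is *a* calibrated point, not a unique
estimate, which is exactly the regime the robustness exploration probes.

## Exploration and medium sweep

Each non-frozen parameter is drawn uniformly in [P0/2, 2P0]; the eps_B and
eps_W ranges are intersected with their validity domains (eps_B < 1,
eps_W > 1) so no draw violates the model class. Sampling is on the
dimensional parameters; distributional read-outs are therefore qualitative
(side-of-1 patterns, spread), not exact reproductions of any particular
non-dimensional sampling scheme. Per draw the full six-genotype panel is
solved with the same parameter values; failed draws are excluded and
counted, and a failure rate above 5% aborts the run. Summaries report
median, quartiles, Tukey whiskers (Q1 − 1.5 IQR, Q3 + 1.5 IQR) and the
fraction of draws above 1 per ratio. The default exploration size is
N = 1000 draws. `compare_model_robustness` reports (never asserts) the
fraction of draws in which each two-variable model shows the observed
pW increase in the double mutant; for alleviation that fraction is 1 by
construction (pW^dm = gamma is the promoter's maximum), for activation it
is not.

The medium sweep overrides (alpha, gamma) through the x-parameterization per
grid point, keeps everything else fixed, and flags whether each ratio stays
on the same side of 1 across the sweep.

## QC-division contribution decomposition

F = F0/(1 + sum of active contributions); positive contributions repress
division. The divisive form is the only reading under which the closed
forms T_B = (1/qB)(d/c − 1), T_W = (1/qW)(d/b − 1), T_BW = d/a − 1 − T_B −
T_W are consistent with F^dm = F0 = d. In a single knockout the remaining
factor's contribution is attenuated: T_W^bravo = qW_bravo * T_W^WT (default
0.8, from the pWOX5 fold-change in bravo) and T_B^wox5 = qB_wox5 * T_B^WT
(default 0.5, from the pBRAVO fold-change in wox5; swept over a 50-point
log grid in [0.05, 1.5] by default because the molecular estimate is the
least certain). Negative contributions are meaningful (induction of
division), never an error; the decomposition and the forward model are exact
algebraic inverses.

Frequency errors are Bernoulli standard deviations sqrt(p(1−p)/N) at a
deliberately conservative N_eff = 15 per genotype, and are propagated to
the contributions by first-order (delta-method) formulas assuming
independence. The Monte-Carlo cross-check draws Gaussian perturbations in
the linear-response regime (deltas scaled by 0.01, spreads rescaled), where
it matches the analytic deltas to ~0.2%. **Limitation:** at the full
N_eff = 15 deltas the exact distribution of T_BW departs from first order
by roughly 10% — the WT frequency (0.394) sits close enough to zero, in
units of its delta, that d/a is visibly non-linear. The reported deltas are
first-order propagation, as defined; envelopes near the small-qB end of the
sweep should be read with that in mind. No significance threshold is
asserted anywhere — the sweep reports whether each envelope excludes zero
and leaves the judgement to the reader.

## Synthetic data

The generators emulate the *statistical structure* of the measurements, not
the measurements themselves:

* GFP intensities are lognormal per (genotype, reporter) group — positive
  support, multiplicative biological scatter — with group mean
  wt_mean × fold-change and coefficient of variation cv. Defaults
  wt_mean = 100 (arbitrary units; only ratios matter) and cv = 0.3 are
  implementer-chosen stand-ins: the per-root dispersion of the real
  quantification is not published. n = 30 roots per group by default.
* Divided-QC observations are binomial draws per genotype.

Fold-changes are estimated from synthetic samples exactly as from the real
data: ratio of group means, error by propagation of the group standard
deviations. Pipeline-closure tests (model panel → synthetic GFP → estimated
fold-changes; printed frequencies → binomial counts → decomposition) show
the analysis is consistent with its own assumptions. They do *not* show the
assumptions hold for real roots: lognormality, independence across roots
and the absence of segmentation/imaging artefacts are modelling choices.

## Reported problem sizes

The shipped analyses use N = 1000 exploration draws, 8 calibration starts,
1e6 Monte-Carlo draws for the error-propagation check, and 200 replicates
at n = 200 roots/group (GFP) and n = 500 roots/genotype (divisions) for the
recovery experiments.

## Known limitations

* Single-cell/spatial structure, mRNA dynamics and additional partners are
  out of scope by construction; conclusions concern niche-total expressions.
* The calibrated parameter set is one point on a solution manifold; only
  the fold-change ratios it was fitted to, and the direction constraints,
  are identified.
* Multistability outside the explored parameter ranges is reported when
  found but not systematically mapped (no bifurcation analysis).
* First-order error propagation under-represents the T_BW uncertainty at
  the conservative N_eff = 15 (see above).
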