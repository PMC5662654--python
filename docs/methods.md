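# Methods

## The model

`atranet` implements an effective kinetic model of all-trans retinoic acid
(ATRA)-induced differentiation of HL-60 myeloblastic leukemia cells. The
model is deliberately coarse: it does not resolve individual signaling
cascades, but captures the architecture that produces the experimentally
observed behaviour — a bistable, self-sustaining MAPK module upstream of a
transcription-factor program that drives differentiation markers and G0
arrest.

The model has three coupled layers:

1. **Signal initiation.** ATRA above a critical threshold activates the
   Trigger species (the ligand-bound RAR/RXR complex):
   `x_a = x_u * alpha*A/(1 + alpha*A)`, with gain `alpha = 0.1 uM^-1` above
   the threshold and 0 below it. The signalsome — the membrane complex that
   drives MAPK activation — is tracked by BLR1 (CXCR5) protein abundance
   (formation first order in BLR1 protein, `k_s = 0.0385 hr^-1`, chosen so
   the signalsome pseudo-steady state equals the BLR1 protein level).
   cRaf-pS621, the readout of sustained MAPK activity, is generated at rate
   `k+ * x_s * x_cRaf/(K+ + x_cRaf)` times an inhibitor factor
   `1 - I/(K_D + I)`. Activated species are removed only by dilution `mu`
   and non-specific decay `k_d = 0.1 mu` (deactivation/phosphatase
   reactions are neglected). The positive feedback closes through the BLR1
   promoter, which is activated by both activated Trigger and cRaf-pS621;
   this closure (which regulators, which Hill parameters) is effective
   plumbing — the biology motivating it is that BLR1/signalsome expression
   is MAPK-dependent while MAPK activation is signalsome-dependent.

2. **Signal integration.** Eleven myelomonocytic transcription factors
   (PPARgamma, PU.1, C/EBPalpha, IRF-1, Oct1, Oct4, AP-1, E2F, Egr-1, AhR,
   Gfi-1) wired by a curated signed connectivity table (52 edges over 17
   species counting Trigger/RARalpha), plus the reciprocal Gfi-1 -| Egr-1
   and Gfi-1 -| PU.1 repressions that complete the classical
   Gfi-1/Egr-1 counter-antagonistic switch (tagged `curated` in the
   configuration; the table lists Gfi-1 only as a target, which would make
   it inert as a regulator).

3. **Phenotype.** Differentiation markers CD38, CD14, CD11b, p21 and
   p47Phox, driven by the integration layer.

Every gene j carries an mRNA and a protein balance:

    dm_j/dt = rT_j * u_j + lambda_j - (mu + theta_m) m_j
    dp_j/dt = rX_j - (mu + theta_p) p_j

with length-corrected kinetic limits

    rT_j = kT * R1 * (L_T0/L_Tj) * G_j/(K_T + G_j)
    rX_j = kX * R2 * (L_X0/L_Xj) * m_j/(K_X + m_j)

and the promoter-occupancy control law

    u_j = (W0_j + sum_n W_nj f_nj) / (1 + W0_j + sum_n W_nj f_nj
                                        + sum_d W_dj f_dj)

where `f = x^eta/(K^eta + x^eta)` are Hill transfer functions of regulator
protein concentrations (nM), activation edges appear in numerator and
denominator, repression edges in the denominator only, and an unregulated
gene has `u_j = 1`. The constitutive rate is
`lambda_j = rT_j * W0_j/(1 + W0_j)`.

Note an internal labeling quirk of the characteristic parameter table the
defaults derive from: the transcription equation's saturation constant is
95,000 copies/cell and the translation equation's is 600 copies/cell,
although the table's labels attach those names the other way around. The
equations as written govern the implementation.

## Units and characteristic parameters

Time in hours; mRNA and protein states in copies/cell; regulator and
signaling concentrations in nM (conversion through the cytoplasmic volume
of a 12.4-um HL-60 cell with cytoplasmic fraction 0.51: 1 copy/cell =
3.26e-3 nM); ATRA in uM. Characteristic constants: `theta_m = 0.34 hr^-1`
(2-hr mRNA half-life), `theta_p = 0.07 hr^-1` (10-hr protein half-life),
`mu = 0.035 hr^-1` (19.5-hr doubling time), `kT = 1.44 hr^-1`,
`kX = 3.60 hr^-1`, `R1 = 85,000`, `R2 = 1e6` copies/cell, characteristic
gene/transcript lengths 44,192 / 1,374 nt. Sequence lengths follow RefSeq;
per the configuration convention the transcribed length equals the gene
length (the RNA read length is the total distance of transcription), except
CD38 where the two differ. The ATRA threshold is not fixed by theory; the
default 0.25 uM comes from the morphology dose series and is configurable.

Promoter-logic bounds: `W in [0, 100]`, `eta in (0, 4]`, `K in (0, 1000]`
nM. The shipped default configuration *is* the ground truth used by the
synthetic-data generator. Its promoter parameters were chosen once so that
the model reproduces the qualitative behaviour reported for this system —
bistability below the ATRA threshold, a single activated state above it,
washout memory carried by BLR1, >8-fold PU.1 de-repression in Gfi-1
knockouts, >8-fold loss of CD38/p21/IRF-1/Oct1 in PPARgamma knockouts with
p47Phox untouched, p21 up / E2F down under ATRA — and are not data in any
statistical sense.

## Simulation

Two evaluation modes. The default `pss` mode closes the activated species
algebraically at `x* = r+/(mu + k_d)`; because the closure is an acyclic
cascade (Trigger protein -> activated Trigger; BLR1 protein -> signalsome
-> cRaf-pS621), the fixed point is explicit and the ODE state is the 38
mRNA/protein balances. `full_ode` mode integrates the three activated
species explicitly (41 states). With `k_d = 0.1 mu` the activated-species
relaxation time is `1/(mu + k_d) ~ 26 hr`, which is *not* fast relative to
protein turnover (~10 hr); the two modes therefore agree only after
transients (the dual-route test checks long-time agreement to 0.5%), and
the PSS closure should be read as the model definition rather than as an
approximation theorem.

Integration uses LSODA at rtol 1e-6 / atol 1e-9; piecewise-constant
ATRA/inhibitor schedules restart the integrator at switch times. The
pre-treatment state is found by integrating 500 hr from small positive
seeds at ATRA = 0 and refining with a Powell-hybrid root solve; from
near-zero initial expression this lands on the inactive branch.

Phase-plane analysis reduces to the (signalsome, cRaf-pS621) plane with
gene expression at quasi-steady state. The signalsome nullcline is an
explicit function x_s(x_cRaf-pS621) (BLR1 expression does not depend on
x_s), and the cRaf nullcline is a line through the origin, so all
intersections — including the saddle — are bracketed by a scalar scan and
polished by root-finding; stability comes from central finite-difference
Jacobians (relative step 1e-6) of the reduced vector field. Duplicate roots
merge at relative distance 1e-4.

## Synthetic data

The generator emulates fold-change-normalized densitometry: sparse sampling
times {0, 4, 8, 16, 24, 48, 72} hr, three biological replicates,
multiplicative lognormal noise with sigma = 0.1 (strictly positive,
constant CV), and normalization to the simulated pre-treatment level.
Three treatment panels are produced, mirroring the experimental panels this
class of data comes from: continuous 1 uM ATRA (time courses of BLR1 mRNA,
cRaf-pS621, CD38 and CD11b protein, plus a 12-protein transcription-factor
panel at 48 hr), a 24-hr pulse followed by washout (BLR1 mRNA and
cRaf-pS621 to 144 hr), and ATRA plus 90 nM MAPK inhibitor. The washout and
inhibitor panels are not decoration: the washout plateau isolates the
cRaf->BLR1 feedback term from the Trigger->BLR1 term (ATRA off removes the
Trigger input), and the inhibitor panel samples the feedback transfer
function at a partially inhibited operating point. G0-arrest fractions are
produced from the simulated p21/E2F trajectory through the arrest
polynomial with known coefficients (0.10, 0.04, 0.025, 0.001) plus additive
Gaussian noise (sd 0.03, truncated to [0, 1]).

What the generator does *not* emulate: blot saturation and background
subtraction artifacts, correlated replicate errors, loading-control error,
biological heterogeneity between cultures, or any misspecification between
the fitted model class and reality (the truth lives inside the model
class). Passing estimation tests therefore demonstrate correctness of the
machinery and identifiability under the stated noise model — not that real
Western-blot data would constrain the parameters equally well.

## Estimation

For each observable j the residual is

    E_j = (M_j(t-) - y_j(t-))^2                      (absolute scale)
        + sum_i (M_ij - y_ij)^2                      (fold change)
        + sum_i (M'_ij - y'_ij)^2                    (min-max-scaled shape)

summed over observables and treatment panels (one simulation per panel per
candidate). Min-max scaling maps a constant series to zeros, which keeps
the shape term finite and penalizes flat simulations against varying data.
Failed simulations receive a finite penalty of 1e9 and are never archived.

Minimization uses an in-package (mu/mu_w, lambda) covariance matrix
adaptation evolution strategy: population `4 + floor(3 ln d)`, initial step
0.25 of the box width, box constraints enforced by reflection, random
in-box initialization, fully seeded. Every strictly improving evaluation is
archived together with the identification run that produced it. Point
estimates come from the best run on the original data; the *ensemble* is
drawn with at most one (best) parameter set per run (`select_ensemble`).
Because a converged search on a single noise realization collapses to a
point — its top entries differ by fractions of a percent, far less than the
noise-induced bias of the optimum — the fitter can run additional
identification runs on replicate-resampled data (`n_bootstrap`): each point
of the replicate-averaged series is perturbed multiplicatively by the
standard error of its replicate mean (parametric bootstrap under the
lognormal noise model). The resulting run-ensemble spreads like the
sampling distribution of the estimator, and its 99% confidence band covers
the noise-free truth trajectory — the property the ensemble bands are used
to convey. Restart counts and iteration budgets are configuration, not
science: the shipped defaults (2 search runs plus 8 bootstrap runs of
60-150 generations) reach the noise floor of the synthetic data on the
initiation subsystem in a few minutes on one core.

When every observable and free parameter lies in the signal-initiation
subsystem, candidates are simulated on that 3-gene subsystem alone; its
trajectories are identical to the full model's because no downstream
transcription factor feeds back into the initiation layer (this is checked
by a test, and the reduction refuses configurations that wire downstream
effectors into initiation promoters).

The default free set is the Hill parameterization (W, K, eta) of the two
activating edges on the BLR1 promoter. The promoter's constitutive weight
W0 is deliberately *not* estimated: in fold-change data it acts purely as a
normalization of the pre-treatment baseline, and freeing it opens a sloppy
ridge — W0 rescales every fold change and absorbs genuine promoter-weight
differences, so the feedback weight was recovered only to within roughly an
order of magnitude even at the noise floor. With W0 held at its configured
value, the three-panel design identifies both the feedback weight and its
cooperativity (the washout plateau reads the cRaf edge's occupancy term
directly once the Trigger input is withdrawn, and the inhibitor panel
samples the transfer curve at a second operating point). Identifiability
also requires the feedback weight itself to sit on the sensitive part of
the occupancy curve: the ground truth uses W = 8 (u ~ 0.89), where a
two-fold change in W moves the plateau by several times the replicate
noise; at the saturated top of the curve (W of order 10^2, u -> 1) no
design of this kind can distinguish weights. This sloppiness is the reason
ensemble spread — rather than point estimates — is the right summary of
such fits.

## Arrest model

G0-arrest is a black-box cubic polynomial in the combined coordinate
`x = t/T + p21/E2F` (protein levels): `A = a0 + a1 x + a2 x^2 + a3 x^3`,
fitted by ordinary least squares with replicates as independent rows and
predictions clamped to [0, 1]. Taken literally, the basis family
`phi_i = x^(i-1), i = 1..N-1` would duplicate the intercept
(`phi_1 = 1`), leaving three distinct columns for four coefficients; the
implementation uses the non-degenerate reading [1, x, x^2, x^3]. The
horizon T defaults to the final measurement time so t/T is in [0, 1]. The
design-matrix condition number is reported and a warning is issued above
1e8; a rank-deficient design (e.g. a constant combined coordinate) raises
an error naming the collinear columns rather than silently returning a
minimum-norm solution.

## Knockout analysis

Perturbations are unordered pairs — including self-pairs, so single
mutants come from the same machinery — of either genes of the connectivity
table (17 species, 153 perturbations) or table edges (52 edges, 1378
deletions; weight set to zero, edge kept in the roster so matrices keep
fixed shape). Each perturbed model is settled to its own ATRA-free
steady state (root refinement from the nominal baseline, which stays on the
inactive branch because knockouts only weaken expression) and driven with
1 uM ATRA for 72 hr at 1-hr output resolution. The displacement row is the
per-state relative l2-norm over the trajectory, ||x_pert - x_nom|| /
||x_nom|| (absolute norm for zero-baseline states); an endpoint-only mode
is available behind a flag. Matrices are averaged element-wise over the
top-10 ensemble and decomposed by thin SVD; mode variance is the squared
singular-value (energy) fraction, and loading signs are fixed so each
mode's largest state loading is positive.

A structural observation: marker genes with no outgoing edges (Oct4, CD38,
CD14, CD11b, p21, p47Phox, and E2F with only a self-loop) contribute
near-orthogonal self-deletion directions — their own mRNA/protein
displacement is exactly 1 and nothing else moves — which forms an
irreducible tail of the spectrum. The dominant modes are the shared
response programs of the master regulators (Gfi-1/PU.1, the
Trigger-dependent program, and the PPARgamma arm).

The mutant fold-change table reports mutant/wild-type protein ratios at
48 hr binned at >2, >4, >8 in either direction (reciprocal ratio for
down-regulation), with zero wild-type levels flagged unbounded.

## Problem sizes used by the default test run and the acceptance script

Ensemble fits run on the initiation subsystem (2 restarts x 100-150
generations, population 9; a few minutes on one core). The test suite
averages the edge-deletion scan over five ensemble members and the gene
scan over ten; the acceptance script averages both scans over the full
top-10 ensemble (about 15,000 trajectory integrations in total). The
recovery experiment uses ten seeds at 2 x 60 generations each. These sizes
were chosen so the whole pipeline reruns from scratch in well under half an
hour on a single core; all results quoted in the README come from these
runs.

## Known limitations

- The model does not describe program shutdown: sustained activation
  persists indefinitely, whereas BLR1 message is known to decline after
  ~48 hr in cells. Nothing in the package models the decline.
- The activated-species balances are not fast relative to gene expression
  under the default decay constants, so `pss` and `full_ode` modes disagree
  during transients (by design of the closure; see above).
- The connectivity is the curated table plus two documented curated edges;
  no automatic edge curation, no SBML import/export, no stochastic
  (Gillespie) simulation, no delay or chromatin-state terms.
- Absolute concentration scales are effective: activated cRaf-pS621 is not
  bounded by total cRaf (no substrate conservation in the effective
  generation law), and promoter half-saturations span the full allowed
  range rather than measured affinities.
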