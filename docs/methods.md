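# Methods

## The hybrid model

The model predicts batch-culture dynamics for a panel of monitored species
(medium components plus biomass) from the initial composition alone. Its
state is the monitored concentration vector C(t) on a uniform grid with
spacing dt (0.25 h by default). Internal metabolites never appear in the
state: under the intracellular steady-state assumption S V = 0 their
concentrations are constant, which is what reduces the full stoichiometric
update to the transport form C(t) = C(t-1) + r(t) T V(t) dt.

Two feedforward networks supply the quantities the stoichiometry cannot:

* **Lag network** (default one hidden layer of 16 tanh units): maps the
  standardized C(0) to (tlag, klag) through softplus heads, with a floor
  of 1e-3 1/h on klag. A zero-weight network returns configurable
  defaults (3.0 h, 1.0 1/h) through the output bias.
* **Flux network** (default two hidden layers of 64 tanh units): maps the
  standardized state C(t-1), augmented with a standardized log-biomass
  feature, to per-biomass specific rates g; the flux vector is
  V = X g(C) with X the biomass component of the state. Both choices are
  pure reparameterizations of a map from C(t-1) to V(t): growth is
  exponential in biomass, so the log coordinate separates lag-phase from
  exponential-phase states that are nearly identical on a linear scale,
  and scaling by X makes the biomass dependence of volumetric fluxes
  structural, so simulations extrapolate correctly to biomass densities
  outside the training range. The output is linear (fluxes may be
  negative; the positivity loss discourages it) with an optional softplus
  that enforces nonnegativity exactly.

The lag gate r(t) = 1 - e^(-klag t) for t <= tlag and 1 afterwards is
applied exactly as written, including its (usually small) jump at t = tlag.
The rollout is a residual network in time: with zero fluxes the state stays
at C(0), and the networks only learn corrections.

### Loss

Four per-time terms, each weighted by w_i(t) = lambda_i e^(-k_i t) with t
the integer step index, summed over t = 1..tmax/dt:

1. masked mse between C(t) and the replicate-mean observations on the
   measured channels (initial concentrations enter through the hard
   assignment C(0) = C_true(0), not through the loss);
2. mse(relu(X(t-1) - X(t)), 0): batch biomass cannot decrease. The
   equation can also be read with the opposite sign (penalizing
   increases); `loss2_sign="printed"` selects that variant, the default
   follows the stated intent;
3. mse(S V(t), 0) over the internal-metabolite rows of the expanded
   stoichiometric matrix (toy networks have no exchange pseudo-reactions,
   so extracellular rows are governed by the transport update rather than
   by a steady state; for genome-scale models with exchange reactions the
   two readings coincide);
4. mse(relu(-V(t)), 0): all reactions are irreversible after expansion,
   so fluxes should be nonnegative.

Defaults: lambda = (1, 1, 1, 1), k = (0, 0, 0, 0); the random-search
module explores lambda over {0.001, 0.01, 0.1, 1} and k over
{0, 0.25, 0.5, 0.75, 1}, ranking candidates by mean (tie: median)
held-out R^2 under 3-fold cross-validation over media.

Numerical choices inside the training loss:

* the steady-state penalty uses row-normalized stoichiometry (same zero
  set): raw biomass coefficients of ~40 mmol C/gDW give the penalty a
  curvature ~1600x larger than the data term and stall optimization;
* fit residuals of non-biomass channels are scaled by
  sqrt(sd_bio/sd_channel) — a compromise between raw units (a 20 mM
  substrate channel numerically drowns a 1 g/L biomass channel) and full
  standardization (under which small unphysical substrate excursions
  become nearly free);
* uptake reactions of a **measured** substrate are masked (zeroed) at
  steps where its predicted concentration is <= 0: continued uptake from
  an empty, observed pool is an unphysical escape route that the squared
  data term does not punish strongly enough. Unmeasured channels keep the
  plain residual dynamics.

### Gradients

The backward pass through the rollout (up to ~100 Euler steps) is written
out explicitly in numpy: per-step vector-Jacobian products through the
flux network, the skip connection, the gate, and all four loss terms, with
Adam as the optimizer. A finite-difference test validates the gradients to
1e-4 relative error. The exact gate has zero derivative with respect to
tlag almost everywhere, so the training rollout uses a straight-through
estimator: exact forward values, and for tlag the derivative of a sigmoid
blend of width tau = 0.5 h (the jump's point-mass influence spread over a
~tau window); klag keeps its exact ramp derivative.

### Lag-parameter estimation

Jointly with the fluxes, the gate is only weakly identified: the flux
network can rescale its output to absorb almost any gate error (observed
failure mode: klag collapses to its floor while tlag drifts hours away,
with unchanged fit quality but order-of-magnitude substrate overdrafts).
Training therefore proceeds in two stages:

1. **Warm start.** For every training curve, (tlag, klag) are estimated by
   least squares on ln X(t) = ln X(0) + mu E(t), where E is the integrated
   gate and mu is profiled out in closed form; the grid search runs over
   onset times paired with klag = 3/tlag — the package's gate convention
   that a lag gate "completes" (r = 1 - e^-3 ~ 95%) at its onset, which is
   the regime in which tlag is the observable lag duration. Only points
   below half the curve maximum enter the fit (before depletion bends the
   exponential). The lag network is then regressed onto these estimates
   (600 epochs, lr 1e-2, light weight decay to pool noisy single-curve
   fits across media).
2. **Joint phase.** Both networks train on the full objective; the lag
   network continues at a much smaller rate (3e-5 versus 1e-3) so the
   flux network cannot drag the gate back into the degenerate trade-off.

Early stopping monitors one minus the mean R^2 on a validation slice
(10% of training media when there are at least ten; otherwise trailing
time points, or the training loss itself via `val_mode`): R^2 is
amplitude-invariant, whereas a plain mse signal favors flat predictions
for small-amplitude media. The best parameters are restored; the epoch cap
is 1000.

### Simulation modes

The default `simulate` applies the plain residual update (exact Euler
identity; concentrations may drift slightly negative, which evaluation
reports as a flag). `simulate(..., clamp=True)` is the physical mode used
for forward simulation beyond the observation window: concentrations are
floored at zero, fluxes at zero (irreversibility), and uptake from any
exhausted pool is switched off. Without these guards an extended rollout
can wander into states far outside anything seen in training and either
manufacture carbon (uptake from an empty clamped pool) or destroy biomass.

## Synthetic data generator

The generator integrates a true kinetic ODE — not the hybrid model's own
update rule — so recovery tests are non-circular:

    dX/dt   = r(t) X sum_j Y_j v_j(C)
    dC_j/dt = -r(t) X v_j(C),        v_j = vmax_j C_j / (Km_j + C_j)

with scipy's adaptive integration (internal steps capped at dt/10,
terminal depletion events, substrates clipped at zero). Yields follow
carbon bookkeeping: Y_j = efficiency * carbon_j / gamma with efficiency
0.6 (fraction of assimilated carbon fixed into biomass) and gamma = 40
mmol C per gDW, giving e.g. 0.09 gDW per mmol glucose (~0.5 g/g).

Study conditions (defaults, chosen once): a six-substrate panel (glucose,
xylose, succinate; alanine, glutamate, serine) with vmax 5-10 mmol/gDW/h
and Km 0.1-0.5 mM; inoculum X(0) = 0.002 gDW/L (a ~1:500 dilution);
dt 0.25 h; horizon 24 h; three replicates with multiplicative lognormal
noise of sd 0.02 (plate-reader-style heteroscedasticity). Lag times are
drawn per medium from the nutrient class of its primary carbon source
(largest carbon-weighted concentration): mean 1.5 h (sd 0.3) for
amino-acid-primary media, 5.6 h for sugar-primary, and klag = 3/tlag by
the same completeness convention the estimator uses — under this gate
family the ramp timescale must scale with the onset time, otherwise tlag
is not the lag duration an experimenter would read off the curve.

An overflow variant (glucose/acetate) diverts a fixed carbon fraction
(0.3) of glucose uptake to acetate secretion and re-consumes acetate only
once glucose is nearly gone (inhibition constant 0.05 mM), producing
classical diauxic curves.

Media-design schemes: `single` (one component each), `single-levels`
(each component at 5/10/20 mM), `pairwise`, `random-k` (random subsets of
k components at random levels), and `random-k-pure` (like random-k but
class-pure — the design used to probe class-dependent lag times, since a
mixed medium near the carbon-parity boundary has an irreducibly ambiguous
primary class).

What the generator does **not** emulate: stationary-phase death or drift,
measurement-specific artifacts (well evaporation, saturation of optical
density), temperature or pH effects, regulatory hierarchies beyond the
single overflow pair, and between-replicate biological variability (noise
is purely observational). Tests passing on these data therefore show that
the machinery works under the model's own assumptions plus Monod kinetics;
they do not certify performance on real plate-reader data.

## Experiments wired into the acceptance suite

* **Media generalization** (the headline number): 60 `random-k` media,
  train on 40, mean biomass R^2 on the held-out 20; reproduced from
  scratch by `scripts/acceptance.py`.
* **Lag recovery**: 48 `random-k-pure` media, 32/16 split; held-out
  per-medium tlag within +-0.5 h for >= 80% of media and class means
  within +-0.5 h of 1.5/5.6 h.
* **Forecast**: a one-substrate glucose network at eight concentrations,
  16 h horizon, training on the chronological first two-thirds of each
  curve and scoring full-curve R^2. The horizon is set so every curve
  saturates within the training window; the score then measures whether
  the model holds amplitude and plateau through the held-out final third.
  Media whose first approach to stationary phase lies wholly in the
  held-out window would require out-of-distribution state generalization
  the architecture does not provide — a known limitation: temporal
  forecasting is reliable where the forecast states are covered by the
  training states (which is the situation in densely overlapping
  combinatorial panels).
* **dFBA contrast**: the LP baseline grows at full specific rate from the
  first Euler step on every substrate-positive medium; the trained hybrid
  suppresses first-step growth through its gate.
* **Diauxic forward simulation**: trained only on glucose and biomass
  channels of the overflow dataset, the physical-mode rollout past
  glucose depletion shows the never-observed acetate channel rising
  during the glucose phase and falling afterwards while biomass still
  increases.

R^2 between a predicted and a measured curve is 1 - SS_res/SS_tot. A
window whose observations carry no dynamics beyond measurement noise
(coefficient of variation below `min_cv`) has SS_tot at the noise floor;
such scores are reported as undefined rather than as noise ratios.

## Known limitations

* Per-substrate attribution is not identified when only biomass is
  observed on multi-substrate media: any consumption mix satisfying the
  carbon balance fits equally well, so individual substrate trajectories
  (and small negative excursions, which evaluation flags) should not be
  over-interpreted in that regime.
* The gate decomposition (tlag, klag) is conventional: without the
  completeness convention the two parameters trade off along a ridge that
  growth curves alone barely constrain.
* Default optimization settings are tuned for desk-scale networks
  (tens of reactions, tens of media); genome-scale training would at
  minimum need minibatching and a sparse-aware backward pass.
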