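# Methods

## The model in brief

`cannet` implements, side by side, the two faces of one object:

* a **canonical neural network**: a two-layer recurrent rate-coding
  network with a sigmoid activation.  The middle layer `x` receives
  binary sensory input `o` through an excitatory/inhibitory weight pair
  `W1, W0` and its own one-step-delayed activity through `K1, K0`; the
  output layer `y` reads the middle layer through `V1, V0` and drives
  decisions (`Prob[delta_i = 1] = y_i`).  Firing thresholds adapt with the
  weights and carry perturbation terms `phi, psi`.  Activity and
  plasticity both descend a single cost function `L`; the plasticity that
  results is Hebbian with an activity-dependent homeostatic term, and the
  output-layer Hebbian term is scaled by `1 - 2*Gamma(t)`, where the
  modulator `Gamma(t)` in [0, 1] reports, with a delay, the risk
  attributable to recent decisions (`Gamma < 0.5`: Hebbian; `> 0.5`:
  anti-Hebbian).

* a **discrete active-inference agent**: variational Bayes under a POMDP
  whose observations, hidden states and decisions are vectors of binary
  factors.  The likelihood `A`, decision-conditioned transition `B` and
  policy mapping `C` factorize into 2x2 column-stochastic submatrices
  (outer-product structure); `D` and `E` are fixed state and decision
  priors; mapping posteriors are Dirichlet.  The generative model
  conditions *past* decisions on the *current* binarized risk (a fictive,
  postdictive causality): a decision believed good is one that would have
  been sampled from `C` when the risk came out low, and from its
  elementwise reciprocal when high.  Minimizing variational free energy
  filter-style (only the newest beliefs are updated; past beliefs are
  frozen) gives per-factor softmax updates for states and decisions and
  risk-modulated pseudo-count accumulation for the mappings.

The dictionary between the two (module `equivalence`) binds
`sig(W_l) = ` likelihood mean columns, `sig(K_l)/sig(V_l) = ` inverse
transition/policy means (conditionals of the previous state given the
current state/decision), `phi = ln D`, `psi = ln E`, `Gamma(t) = Gamma_t`,
and initial weights scaled by inverse learning rates = Dirichlet prior
concentrations.  Under this dictionary the sigmoid activity fixed point
*is* the softmax posterior update (verified to 1e-12 on thousands of
random instances) and the cost `L` equals the free energy `F` step by
step, after removing three residuals that are constant in the optimized
activity: the Dirichlet parameter complexity (which grows only
logarithmically with history length), an order-one weight-dependent term,
and — on risk-modulated past steps — a modulated-threshold cross term
(the modulation multiplies the inverse-policy log-evidence on the Bayes
side but not the threshold's weight part on the network side).  The
residual is computed in closed form and verified, not assumed.

Expectations of log-mappings come in two modes: exact `digamma`
differences, and the large-concentration `logratio` approximation
(`ln(theta/sum)`).  The network correspondence is exact in `logratio`
mode; in `digamma` mode the gap is bounded by the reciprocal of the
smallest concentration involved (note: it is the *smallest*
concentration, not the pair total, that controls the gap, since
`psi(z) - ln z ~ -1/(2z)`), and the verification reports the bound
decaying as concentrations grow.

## Numerical choices

* Probability floor `1e-9` before every logarithm; ratio clip `1e-6`
  before every inverse sigmoid (both global constants).
* Dirichlet concentrations are floored at `1e-6` when anti-Hebbian
  decrements would drive them nonpositive (logged); the generative model
  does not define this case.
* Per-factor softmax over a {1, 0} pair is evaluated as a sigmoid of the
  logit difference; block vectors store the "= 1" components first.
* The activity simulator uses the fixed-point form; the explicit Euler
  integrator of the rate equations is retained for the gradient tests
  (and verified to converge to the same point to 1e-8).

## The maze task

The agent navigates a 21 x 41 grid from the left edge to any pathway cell
in the rightmost column, within `T = 20 000` steps per session.  It
observes the surrounding 11 x 11 binary window (out-of-grid cells read as
wall); a decision is a four-step action sequence over (up, down, left,
right) — 256 options, base-4 coded with the first step as the most
significant digit; a move into a wall is rejected but consumes its step.
After each four-step period the environment emits the delayed risk:
`Gamma = 0` if the agent moved rightwards by at least `d* = 2` cells
during the period, `0.45` if it moved rightwards but fell short, `0.55`
if it did not.  The likelihood is (near-)identity — the middle layer
tracks the observed window — so hidden-state inference is sharp and the
interesting learning is the policy.

**Maze family.**  The task needs mazes that an unbiased random walker
typically cannot cross within `T` but a rightward-biased policy can.
Randomized depth-first corridor carving does not separate these regimes
at this size: sparse mazes defeat biased walkers too (dead-end traps),
and densities at which biased walkers pass also let unbiased walkers
through about half the time.  The default generator therefore builds
"baffle" mazes: every second interior column is a wall pierced by one
randomly placed gap, one gap per wall is chained by a protected vertical
corridor (solvable by construction), and remaining compartment cells are
blocked with probability 0.3.  Measured across seeds, unbiased walkers
fail 10/10 of these mazes while a walker with a 0.4 rightward step bias
succeeds 10/10 (median ~8 000 steps).  DFS carving remains available as
`style="dfs"`.

**Learning phase.**  Training alternates action and learning phases.
The network dynamics are computed in belief space (the cheaper of the two
equivalent faces): the agent carries Dirichlet pseudo-counts and the synaptic
matrices are rebuilt from count ratios through the dictionary after each
update.  Policy counts pair the *realized* one-hot decision of each
period with the middle-layer state that produced it, weighted by
`1 - 2*Gamma` of that period (delayed modulation; the ablation applies
the previous period's risk instead).  Statistics enter as session
averages with a fixed per-session weight, so long failed sessions and
short successful ones count equally — without this, a single 5 000-period
failure outweighs ten short successes and training collapses.  Sensory
and recurrent counts use a much smaller weight ("small learning rate"),
keeping the focus on policy learning.

## Implicit-prior estimation

When threshold adaptation is slow relative to the recording, `phi` and
`psi` are estimated as logs of time-averaged rates, pooled across (by
default ten) distinct mazes; `exp(psi1) + exp(psi0) = 1` holds by
construction and the one-hot decision block is renormalized to sum to 1
for reporting.  Standard errors use the binomial approximation.  A
reconstructed agent is built from the estimated decision perturbation
alone (state perturbation available behind a flag), with standard weight
initializations, and trained with the standard protocol on fresh mazes;
its failure-probability trajectory is the prediction for the original
agent.  The prediction consumes no activity or behaviour of the original.

## What the synthetic task does and does not show

The generative process is fully synthetic and deliberately small: binary
windows, deterministic movement with wall rejection, a three-level risk
signal, and stationary mazes.  Passing tests show that the network/Bayes
equivalence holds exactly at the stated tolerances, that delayed
risk-modulated plasticity learns the navigation task where immediate
modulation does not, and that priors implicit in thresholds are
recoverable from activity and sufficient to predict learning.  They do
not show robustness to non-stationary environments, graded observations,
model mismatch in `A`/`B`, or biological noise; and the maze family is
calibrated for the stated walker separation, not for realism.

## Problem sizes used in the checks

Equivalence and gradient identities run on thousands of small random
instances (2-4 factors).  Behavioural comparisons use 21 x 41 mazes,
`T = 20 000` steps, 100 sessions.  The delayed-vs-immediate comparison
runs 10 seed replicates per arm in the test suite (8 in the acceptance
script).  The prior-sensitivity and reconstruction analyses use the three
decision-prior conditions `E_right = 0.0023, 0.0039, 0.0055`
(`E_left = 0.0078 - E_right`, `E_up = E_down = 0.0039`), 10 seeds per
condition per arm in the test suite (5 in the script), training on pools
of 20 distinct mazes with estimation activity pooled over 10 further
mazes.  Condition orderings are compared tie-aware: condition pairs whose
original late-training failure probabilities differ by less than the
pooled standard error are treated as ties (empirically, the two lower
`E_right` conditions are statistically indistinguishable late in
training, while the 0.0055 condition is distinguishably worse — it keeps
pressing rightward into walls).

## Known limitations

* The Bayesian filter uses mean-field geometric averaging over the frozen
  previous belief; it coincides with the exact Bayes filter only when the
  previous belief is one-hot (sharp likelihoods make this near-exact in
  the maze).
* With the decision prior fixed, the policy pathway expresses preferences
  only through state-profile matching (plus the anti-Hebbian suppression
  of punished decisions); a marginal "always right" preference is not
  representable without threshold adaptation.
* Eqs. of the count form and the raw gradient plasticity coincide at
  their fixed points only for unmodulated synapses (and for the modulated
  ones when the risk is constant at zero); the package verifies exactly
  these cases and documents the divergence.
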