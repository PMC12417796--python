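# Methods

`kinetransfer` adapts the *structure* of a kinetic batch-bioprocess model —
not just its parameters — to a related target process, using a pipeline of
hybrid neural correction, variance pruning, attribution-guided symbolic
regression, sparse fine-tuning and model-based design of experiments
(MbDoE). This note records the model assumptions, the conventions and
numerical choices the implementation makes where more than one reading was
defensible, and what the shipped synthetic study does and does not probe.

## The model class and the case study

A kinetic model is a system of ODEs dy/dt = f(y, θ) over species
concentrations y (g/L) with rate/yield constants θ. Expressions are
rational: trees over {+, −, ×, ÷} with variable, parameter and constant
leaves; *complexity* is the total node count. Auxiliary *shared rates*
(the specific growth rate μ) are named expressions referenced by several
balances and treated as additional equations during structure adaptation.

The shipped case study is a batch fermentation of biomass X, glucose S and
product P. The source model uses Monod growth
μ = μ_m·S/(S+K_S) with growth-associated and growth-independent product
formation (μ_m = 0.1 h⁻¹, K_S = 10 g/L, Y_S = 1 g/g, Y_P = 0.5 g/g,
β = 0.003 h⁻¹). The target-domain ground truth differs structurally:
Contois growth μ = μ_m·S/(S+K_S·X) with K_S = 5, endogenous biomass decay
−μ_d·X (μ_d = 0.1 h⁻¹), β = 0.05 h⁻¹, and product reversal −k_d·X²
(k_d = 0.07 L/(g·h)). A consequence worth stating explicitly: because
Contois growth is strictly below μ_m and μ_d = μ_m, the target biomass
decays monotonically from t = 0 in every batch; tests assert this actual
behavior. A low-prior source (dX/dt = μX, dS/dt = −Y_S μX, dP/dt = Y_P μX,
μ = μ_m·S) is included for the minimal-knowledge scenario.

## Synthetic data

Batches run 144 h from initial conditions drawn uniformly over
X₀ ∈ [0.1, 0.5], S₀ ∈ [1, 10], P₀ = 0 g/L; states are sampled on the grid
t = 0, 14, …, 140 h (11 samples — 144 is not a multiple of 14; the horizon
is integrated but the last sample falls at 140 h). Observations carry
multiplicative Gaussian noise, s.d. 5 % of the true value, independent per
state and time, clipped at zero. Generation is bit-reproducible from an
integer seed. The generator emulates the in-silico study design only: no
fed-batch feeding, no temperature/pH inputs, no autocorrelated or
state-dependent measurement error, and initial conditions are known exactly
(real assays would measure them with error). Passing tests therefore
demonstrate correct mechanics and recoverability under these idealized
conditions, not performance on real plant data.

Reference integration is adaptive RK45 (rtol 1e-8, atol 1e-10, scipy);
training uses fixed-step classic RK4 (below). MAPE uses a per-state
denominator floor of 1 % of that state's maximum over the dataset so that
early-batch P ≈ 0 cannot dominate the metric. When a candidate model's
prediction is scored over held-out batches, a batch the model cannot
integrate (a pole inside the trajectory) contributes a finite failure
ceiling of 1000 % rather than an infinity, keeping aggregate statistics
well defined.

## Correction embedding

Corrections φ_j are placed at the leaves of each equation's expression tree
truncated at depth D_max (default 3): every *sum level* reachable within
the budget — the top of each equation, and the numerator and denominator of
any quotient entered within the budget — receives one multiplicative slot
per summand and one trailing additive slot. A sum level that is exactly one
entered quotient gets no trailing slot of its own (the numerator's additive
slot already provides that freedom), and parameter-only factors share their
term's slot (a slot on a lone constant is unidentifiable against θ). These
rules give the Monod source 12 slots and the low-prior source 8 with μ
treated as a fourth equation. Multiplicative slots have baseline 1,
additive slots baseline 0; at baseline the hybrid model is exactly the base
model. Additive slots at the top of a state equation are tagged
*growth-independent* (decay, maintenance, reversal) for the optional
early-batch regularizer.

### Correction scale convention

The training problem is nondimensionalized: states by their dataset maxima
y_max, time by the horizon T. The published description leaves the
correction scale implicit, so the package fixes one: an additive slot's
corrector output is multiplied by the characteristic magnitude of its host
sum level — y_max/T at the top of a state equation, 1/T at the top of a
shared rate, and quotient numerator/denominator levels anchored to the
denominator's magnitude at the state maxima. With this convention a needed
correction (e.g. −μ_d·X in the biomass balance) corresponds to a corrector
output of order 10, a do-nothing slot to order 0, and the variance
threshold V_min = 0.1 acts as a lenient floor that removes unused slots
rather than a demanding bar that true corrections must clear.
Multiplicative slots are dimensionless and unscaled.

## One-step hybrid training

A single tanh network (5 hidden neurons, linear output, one output per
active slot) maps normalized states to all corrections. Output biases are
initialized at the slot baselines with small random weights, so training
starts at the unmodified mechanistic model; fixed per-output gains (10 on
additive outputs) let the network reach order-10 values without leaving the
small-weight regime. θ uses a signed log-magnitude parameterization
(θ = sign·eˢ with signs fixed at the warm start, so steps act
multiplicatively and inherited negative correction coefficients are
handled); ω and s are updated jointly by Adam (lr 0.01, exponential decay
0.999/epoch, up to
3000 epochs with early stopping at 1e-6 relative improvement per 100
epochs), gradient-norm clipping at 1, and decoupled weight decay 0.001 on
W₁/W₂ only. θ takes steps scaled by 0.2 relative to ω: the correction
locations are the quantity of interest, and slowing θ keeps model–data
mismatch from being silently absorbed into parameter drift before the
corrections can express it.

Since no automatic-differentiation framework is used, gradients are exact
discrete adjoints: the normalized system is integrated by fixed-step RK4
(4 substeps per 14 h sampling interval), and the adjoint is propagated
backward through every RK4 stage using sympy-generated Jacobians of the
slotted right-hand side chained with the network's analytic backward pass.
Finite-difference checks in the test suite verify the gradient to ~1e-8
relative.

During training integration, rate and Jacobian evaluations at a pole are
sanitized to large finite values and the normalized states are clipped to
|u| ≤ 100, so a parameter excursion across a singularity produces a large
finite loss whose (clipped) gradient pushes the parameters back out, rather
than a NaN that aborts the fit.

The objective is the mean squared normalized residual over all samples,
experiments and states, plus n_φ·P with
P = λ₁·mean‖∂φ/∂ŷ‖² + λ₂·mean‖φ−b‖², evaluated at the fitted trajectory's
measurement support. The penalty's gradient is taken with respect to ω at
those (detached) states — the cheap and stable choice; its indirect
dependence through the trajectory is deliberately not differentiated.
λ₁ = 1e-6 and λ₂ = 1e-4 were calibrated once on the planted-correction
suite (ground-truth data, source skeleton restricted to a true slot plus a
decoy): at these values the true slot's output variance is 0.7–1.4 versus
≤ 0.18 for decoys across all seeds, while larger λ₁ visibly suppresses
genuine state-dependence (corrections of slope ~10 cost λ₁·n_φ·J² ≈ 0.24 at
λ₁ = 1e-4 — larger than any attainable fit improvement). An optional
growth-independent regularizer (weight 0 by default, window = first 20 % of
the batch) pins tagged corrections to zero early in the batch.

## Pruning and attribution

Slot importance is the population variance of its fitted output over the
(experiment × time) sample grid. One slot — the least variable — is removed
per warm-started refit until at most U_max = 3 remain (one per dynamic
state, to limit structural nonidentifiability); the survivors are then
refitted to full convergence *from a fresh initialization* before the
V_min = 0.1 variance cut is applied: an under-trained corrector
under-expresses exactly the signal being judged, and the warm state
inherited from the pruning phase can sit in a baseline-collapsed local
minimum with the same effect.
An empty survivor set is a valid outcome ("no correction needed"). Pruning
is monotone; slots are never reactivated.

Integrated Gradients attributes each surviving correction to its input
features: the straight-line path integral from the per-feature mean of the
fitted states, midpoint rule (64 segments in the pipeline; completeness
holds to 1e-3 at 256). Feature weights π are mean absolute attributions
normalized to sum one; features below 0.05 are hard-excluded from that
slot's symbolic search.

## Symbolic regression

An in-package genetic-programming engine searches trees over {+,−,×,÷} with
complexity cap C_max = 7: steady-state tournament selection (size 5),
subtree crossover and subtree/point/insert/delete/constant-jitter mutation.
Variable leaves are always sampled with probability proportional to π, so
excluded features never appear. Division by |denominator| < 1e-9 returns a
large finite sentinel, making such candidates uncompetitive. Variable-free
subtrees are folded to single constants before archive entry, so complexity
measures structure rather than the spelling of constants. Each structurally
new candidate (constants masked) gets one Levenberg–Marquardt constant
refinement — otherwise a good structure born with poor constants can never
displace an entrenched archive entry — except that newcomers whose raw loss
exceeds 100× the best candidate so far are parked until a better-constant
copy appears. Three independent islands are evolved and their archives
merged, which guards against a single population converging prematurely
onto one structural basin (without islands the hardest planted correction,
the Contois saturation 1/(S+K_S·X), is recovered in only ~6/10 seeds; with
them, 10/10). The merged front is dominance-filtered (loss strictly
decreasing in complexity) and scored by S_k = −Δlog L/ΔC (S₁ = 0, zero
losses floored at 1e-12); ties favor lower complexity. Search defaults are
population 1200 / 1000 generations per island; the test and acceptance runs
use population 150–300 for 20–30 generations.

## Substitution, fine-tuning, passes

Discovered expressions (functions of normalized states) are substituted at
their slots with the slot scale applied, states mapped back to physical
units, and the equations canonically simplified (sympy together/cancel);
surviving numeric coefficients become named parameters c₁, c₂, …
Fine-tuning minimizes the normalized trajectory MSE over all parameters
(scipy least squares on fixed-step RK4 trajectories) with an L2 penalty
(weight 1e-3) on the new parameters. A new parameter is then *dropped* when
removing it and refitting the rest raises the normalized RMS residual by
less than 0.01 — a dispensability test chosen over a raw magnitude
threshold because correlated parameters make the magnitude of a redundant
coefficient meaningless (a planted spurious term fitted to ≈ −0.0005 still
changed trajectories noticeably until the remaining parameters were allowed
to compensate).

Passes repeat — embed (same D_max) into the updated model, prune, attribute,
search, substitute, fine-tune — until no slot survives V_min or two
consecutive passes produce structurally matching models (max 5 by default).
Within a pass only the top-1 expression per slot is substituted; the top-2
alternatives feed MbDoE candidate enumeration.

## Structural equivalence

Two models "match" when they describe the same parametric family of rate
laws. The test is numeric and bidirectional: jitter one model's parameter
values by ~5 % (seeded — this breaks accidental coincidences such as
μ_d = μ_m, which otherwise cancels a monomial of the ground truth's
canonical form), least-squares refit the other model's parameters to
reproduce it exactly at 50 log-uniform state points, require relative
residuals below 1e-6, and repeat with the roles swapped. The reverse
direction is what rejects over-parameterized candidates: X + c can imitate
X, but X cannot chase a jittered X + 0.4. Algebraically different but
equivalent forms (e.g. Monod times (S+K_S)/(S+K_S·X)) match, as they
should.

## MbDoE

Candidates are the cartesian product of the top-2 expressions per surviving
slot, substituted and fine-tuned with sparsity off (structures are compared
at their best fit), deduplicated by structural match. The Hunter–Reiner
objective J(z) sums squared differences of candidate trajectories over
sample times and unordered pairs, on states normalized by the candidates'
own maxima so all three species contribute comparably (σ² = 1). J is
maximized over the initial-condition box by a 16-point Latin-hypercube
start set with Nelder–Mead refinement of the best three starts. Each loop
iteration re-runs structure adaptation on the cumulative data, enumerates
candidates, designs z*, simulates the designed batch against the
ground-truth oracle with a freshly spawned noise seed, and stops on budget
exhaustion, structural fixity, or an indistinguishable candidate set.

## Problem sizes used by the shipped tests and acceptance script

The study conditions (3 initial experiments, 5 % noise, 14 h sampling,
D_max 3, U_max 3, V_min 0.1, C_max 7) are never changed. What is reduced in
the test suite and `scripts/acceptance.py` relative to the full design is
compute scale: training runs 300–1500 epochs instead of 3000, warm-started
pruning refits 100–250, symbolic regression 150–300 population over 30–60
generations instead of 1200/1000, end-to-end studies 3 repetitions with at
most 2 passes instead of 10 repetitions, design campaigns a budget of 2,
and prediction scoring 10 held-out noise-free batches. At these sizes the
planted-correction and self-transfer checks are already stable; the
end-to-end structure-discovery rates are noisier than a 10-repetition
study and are asserted only as an ordering (multi-pass ≥ single-pass).

## Known limitations

* With μ_d = μ_m the target trajectories are smooth monotone decays, and
  three noisy batches often admit constant-correction explanations that fit
  at the noise floor; full-structure discovery in a single pass is
  therefore seed-dependent, with the biomass-decay location the most
  reliably identified and the Contois denominator the least — the
  structural-nonidentifiability effect that motivates multiple passes and
  MbDoE in the first place.
* The variance threshold acts on the package's own correction-scale
  convention; a different nondimensionalization would shift what V_min=0.1
  means.
* The GP engine is deliberately minimal (no dimensional constraints, no
  alternative search strategies); history-dependent kinetics and
  non-constant design-uncertainty models σ²(z) are out of scope.
* Repetition studies parallelize trivially but are run serially here.
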