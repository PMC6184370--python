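# Methods

## The generative model

The agent's world is a discrete partially observed Markov decision process
with two independent hidden-state factors, flattened wealth-major into a
joint space of `n_wealth_levels × 2` states (default 16). All likelihoods
and transitions are column-stochastic matrices; joint matrices are exact
Kronecker products of the factor matrices, which is both the modeling
assumption (the factors evolve and emit independently given the action) and
a tested invariant.

**Likelihood (A).** The wealth cue is an identity mapping on the wealth
factor — wealth is observed exactly. The approval cue depends only on
self-worth through a symmetric logistic mapping with
`P(approval | charitable) = P(disapproval | mean) = e^α/(e^α+1)`. This
one-parameter bridge was chosen so that α = 0 gives exactly the
uninformative 50-50 mapping, the mapping is strictly increasing and smooth
in α, and the deterministic limit is approached asymptotically. α is the
*subject's* sensory precision; it does not alter the world (below).

**Transitions (B).** Self-worth: donating sustains *charitable* with
certainty and converts *mean* with probability 1 − β; keeping is the exact
mirror image. β is parameterized as the stay-probability of the
action-disfavored state because that single choice satisfies the three
constraints the dynamics must meet: identity matrices (full decoupling of
choices from self-worth) at β = 1, maximal 50-50 imprecision at β = ½, and
strong action sensitivity at low β. Values below ½ are accepted by the
type but excluded from default sweeps, since below that point β no longer
acts as a precision. Wealth: a deterministic one-level shift (down for
donate with a floor, up for keep with a ceiling) composed with a one-level
decay applied with probability `attrition` (default 0.10; the broke level
is exempt). Decay is applied after the shift within a trial; the order is a
convention, exposed as `decay_before_shift` for sensitivity checks.

**Preferences (C) and initial prior.** Log preferences rise linearly from
0 to `preference_span` (default 4.0 nats) across wealth levels, and
approval is preferred to disapproval by the same span. The initial prior
is an exact point mass on (broke, charitable).

## Inference and action selection

With at most 16 joint states, exact Bayesian filtering is used: one-step
prediction through the action's joint transition matrix, then a
multiplicative update with both modality likelihoods and renormalization.
A variational scheme would converge to the same posterior here; exactness
makes the filter testable against a brute-force enumeration over all joint
state trajectories, which the test suite does at tolerance 1e-10.

Policies are the `2^policy_depth` action sequences of length
`policy_depth` (default 1). Each is scored by expected free energy: per
step and modality, the KL divergence from the predicted outcome
distribution to the preference distribution (preferences exponentiated and
normalized per modality) plus the belief-weighted likelihood-column
entropy. Actions are drawn from the softmax policy posterior with inverse
temperature `policy_precision` (γ, default 8.0); an `argmax` mode with a
donate-first tie-break exists for deterministic tests. Neither γ nor the
planning depth is intrinsic to the game; both are exposed configuration
with the defaults frozen into the package's standard conditions.

During belief updates a probability floor (default 1e-10) is mixed into
the approval likelihood columns so that no observation carries exactly
zero evidence; without it, a maximally confident agent observing
disconfirming feedback from a disagreeing environment would make the
posterior undefined. Genuine zero-evidence observations (impossible wealth
cues) still raise an error deliberately, surfacing model/environment
mismatches rather than silently renormalizing.

## The environment (generative process)

The manipulated precisions are the subject's confidence, so by default the
world itself is honest: the approval cue is fully veridical (approval iff
truly charitable), the true self-worth dynamics use the agent's own β, and
the true attrition equals the agent's. Each can be overridden
(`env_alpha`, `env_beta`, `attrition`), and `share_with_model` forces the
environment matrices identical to the agent's. The wealth cue is noiseless
by construction, so the only possible observation-model mismatch is in the
approval modality, which the likelihood floor absorbs.

## Simulated experiments and problem sizes

A game is 16 choices from (broke, charitable). The sweep evaluates a
17 × 11 grid (α from 0 to 4 in steps of 0.25; β from 0.5 to 1.0 in steps
of 0.05) with 32 independently seeded replicates per cell — the grid spans
the two quoted likelihood regimes (50-50 at α = 0, ≈98% veridical at
α = 4) and the valid precision range of β; replicate seeds are derived
per-cell from the base seed so results are independent of evaluation
order. The full sweep takes well under a minute on one CPU. Summary
metrics per cell are the replicate means (and SDs) of the final-trial
posterior P(charitable), the final-trial true wealth level, and the
donation fraction; time-averaged wealth is also recorded per trajectory.

The developmental scenario chains three stages with carried-over beliefs
and true states, 16 trials each: (α = 4, β = 0.55) altruistic baseline,
(α = 0, β = 0.55) loss of likelihood precision, (α = 0, β = 1.0) maximal
prior precision — the fully decoupled self-aggrandizing limit, matching
the sweep's extreme corner cell.

### A structural note on the third stage

Raising β to its maximum *preserves* the carried-over self-worth belief
exactly (identity transitions, uninformative likelihood at α = 0) — it
does not restore it. More generally, at low α the self-worth belief under
sustained keeping has fixed point q* equal to the per-trial donation
probability, independent of β (β only sets the convergence rate), so once
the belief has collapsed in stage 2, no increase of prior precision can
systematically raise it in stage 3; and for α > 0 recovery is *easier* at
low β because a single donation lifts the belief by 1 − β. High prior
precision protects an intact positive self-image from uncharitable
choices (the static sweep shows exactly this at the (α = 0, β = 1) cell,
where the initial prior survives 16 keeps untouched); it cannot rebuild
one already lost. The package reports this as entrenchment: the
stage-3 self-worth expectation equals stage-2's exactly under the default
scenario, rather than exceeding it.

## Gaussian self-appraisal

Conscious self-valence is modeled as a single conjugate update on a signed
valence axis (roughly [−2, 2] by convention): posterior precision is the
sum of prior and likelihood precisions, the posterior mean their
precision-weighted average. Scenario presets share one negative affective
likelihood (mean −1.5) and differ only in message precisions and the prior
mean: *undefended* (prior 0.5, precision 1; likelihood precision 4) yields
a negative posterior; *self-aggrandizing* (prior 1.5, precision 16) a
positive one; *lacks remorse* (neutral prior, likelihood precision
attenuated to 0.05) a near-zero one. The presets are conventions chosen to
realize these qualitative patterns and are fully overridable; the valence
classifier uses a closed neutral band of ±0.25.

## What the simulations do and do not show

Everything here is self-generated: there is no fit to human choices, no
learning of A/B/C over trials, no second inferring agent behind the
approval feedback, and no mapping of valence units onto clinical
instruments. Passing tests show that the stated precision manipulations
are *sufficient* to produce the qualitative behavioral and self-appraisal
signatures inside this model family — not that they occur in patients.
Heat maps are directional patterns over replicate means, not calibrated
cell values.

## Numerical conventions

- Stochasticity tolerance 1e-12 on column sums; filter-vs-enumeration
  tolerance 1e-10; belief normalization drift bounded at 1e-9 over 10^4
  predict/update cycles.
- KL terms use the convention 0·log 0 = 0; preference distributions are
  softmax-normalized per modality, so risk is invariant to adding a
  constant to a preference vector.
- Argmax action selection breaks exact G ties toward donate (first policy
  in donate-first enumeration order).
- All random draws flow through `numpy.random.Generator` seeded explicitly;
  sweep cells use `SeedSequence(base_seed, spawn_key=(i, j, replicate))`.
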