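# repgame

Discrete active-inference simulation of a donate/keep **reputation game**,
built to study how aberrant *precision* — the confidence assigned to sensory
evidence and to prior beliefs — can produce psychopathic-trait-like patterns
of behavior and self-appraisal in an otherwise normal Bayesian agent. The
package targets computational-psychiatry researchers who want a small,
fully-inspectable agent model rather than a large toolbox.

## The model

An agent repeatedly (T = 16 trials) chooses to **donate** an offer to
charity or **keep** it. Its generative model has two hidden-state factors:

- **wealth** — 8 ordered levels, *broke* to *wealthy*;
- **self-worth** — *charitable* vs *mean*.

Two outcome modalities are observed each trial: an exact wealth cue, and a
binary **approval** cue whose reliability is set by the likelihood precision
**α**:

```
P(approval | charitable) = P(disapproval | mean) = e^α / (e^α + 1)
```

so α = 0 is an uninformative 50-50 mapping and large α approaches a
deterministic one. Action-conditioned transitions **B** encode the game:
donating steps wealth down one level (floor at broke) and sustains a
charitable self-worth; keeping steps wealth up (ceiling at wealthy) and
erodes it. The transition precision **β ∈ (0, 1]** is the per-trial
persistence of the action-disfavored self-worth state: β = 1 yields identity
transitions (choices decoupled from self-worth), β = ½ is maximally
imprecise. A constant attrition decays wealth one level with probability
0.10 per trial. Log prior preferences **C** rise log-linearly over wealth
and favor approval, both with a span of 4 nats.

Beliefs are updated by exact Bayesian filtering on the 16-state joint space,
and actions are scored by expected free energy

```
G(π) = Σ_τ Σ_m  KL( A_m q_τ(π) ‖ σ(C_m) )  +  E_{q_τ}[ H(A_m) ]
```

(risk plus ambiguity per modality), with a softmax policy posterior
`p(π) ∝ exp(−γ G(π))`. Sweeping (α, β) reproduces the characteristic
pattern: precise-likelihood agents donate and stay poor but believe
themselves charitable; attenuating α (*lacks remorse*) switches behavior to
wealth accumulation; and maximal β (*self-aggrandizing*) decouples
self-worth beliefs from choices, so an uncharitable agent retains a high
posterior expectation of being charitable.

A companion module implements the conceptual **Gaussian self-appraisal**
model: conscious self-valence as the precision-weighted fusion of a Gaussian
prior (top-down self-beliefs) and a Gaussian likelihood (bottom-up affective
evidence), with presets for *undefended*, *self-aggrandizing* and
*lacks-remorse* appraisal patterns.

## Worked example

```sh
$ repgame appraisal --scenario self_aggrandizing
scenario: self_aggrandizing
belief          mean  precision
prior          1.500     16.000
likelihood    -1.500      4.000
posterior      0.900     20.000
posterior valence: positive
```

The negative affective evidence (mean −1.5) is overridden by the elevated,
over-precise prior (mean +1.5, precision 16): the fused posterior mean
(16·1.5 + 4·(−1.5)) / 20 = +0.9 stays positive — an inflated self-appraisal
despite underlying shame signals.

```sh
$ repgame run --alpha 4 --beta 0.55 --seed 7 --out demo_run
```

writes `trajectory.json`, `trials.csv` and a `manifest.json` with config and
checksums. With a precise approval likelihood (α = 4) and action-sensitive
self-worth transitions (β = 0.55) the agent donates on 15 of 16 trials,
ends broke (final wealth level 0), and holds a final posterior
P(charitable) ≈ 1.000 — the altruistic regime.

Library use mirrors the CLI:

```python
import repgame as rg

traj = rg.run_game(rg.GameConfig(alpha=0.0, beta=1.0), seed=7)
print(traj.summary)   # keeps every offer, yet P(charitable) stays 1.0

result = rg.run_sweep(rg.SweepGrid(base_seed=0))   # full (α, β) heat maps
rg.export_heatmaps(result, "sweep_out", plot=True)
```

The sweep CSV (`sweep_long.csv`) is long-format with columns
`alpha, beta, metric, mean, sd`, one row per cell and metric
(`p_charitable`, `final_wealth`, `donation_fraction`), alpha varying
slowest.

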