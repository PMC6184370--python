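"""Complete games: a generative process emits true states and cues, the
agent infers and acts, and every trial is recorded.

The environment mirrors the structure of the agent's generative model but
is configured independently (:class:`~repgame.config.EnvironmentSpec`): by
default the approval cue is veridical and the true self-worth dynamics use
the agent's own beta, so the manipulated precisions are purely the
subject's confidence in an otherwise honest world.  The wealth cue is
always the exact true wealth level.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (ACTIONS, CHARITABLE, DONATE, MEAN, SELFWORTH_LABELS,
                     EnvironmentSpec, GameConfig, config_to_json)
from .inference import (BeliefState, EFEBreakdown, predict_states,
                        select_action, update_beliefs)
from .model import (GenerativeModel, assemble_model,
                    build_approval_likelihood, build_selfworth_transition,
                    build_wealth_transition)


@dataclass(frozen=True)
class EnvironmentMatrices:
    """Materialized generative process: factor transitions and the approval
    emission, all column-stochastic."""

    b_wealth: dict[str, np.ndarray]
    b_selfworth: dict[str, np.ndarray]
    approval: np.ndarray  # (2 outcomes, 2 true self-worth states)


def build_environment(config: GameConfig, env: EnvironmentSpec,
                      model: GenerativeModel | None = None
                      ) -> EnvironmentMatrices:
    """Resolve an :class:`EnvironmentSpec` against the agent's config."""
    if env.share_with_model:
        model = model if model is not None else assemble_model(config)
        return EnvironmentMatrices(
            b_wealth=model.transitions.b_wealth,
            b_selfworth=model.transitions.b_selfworth,
            approval=model.likelihood.a_approval_factor,
        )
    attrition = config.attrition if env.attrition is None else env.attrition
    beta = config.beta if env.env_beta is None else env.env_beta
    if env.env_alpha is None:
        approval = np.eye(2)  # veridical: approval iff truly charitable
    else:
        approval = build_approval_likelihood(env.env_alpha)
    return EnvironmentMatrices(
        b_wealth={a: build_wealth_transition(a, attrition,
                                             config.n_wealth_levels,
                                             config.decay_before_shift)
                  for a in ACTIONS},
        b_selfworth={a: build_selfworth_transition(a, beta) for a in ACTIONS},
        approval=approval,
    )


def env_step(true_state: tuple[int, int], action: str,
             env: EnvironmentMatrices, rng: np.random.Generator
             ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Sample one environment transition and the resulting cues.

    Returns ``((next_wealth, next_selfworth), (wealth_cue, approval_cue))``;
    the wealth cue equals the true next wealth level, the approval cue is
    drawn from the environment's approval mapping given the next self-worth.
    """
    wealth, selfworth = true_state
    next_wealth = int(rng.choice(env.b_wealth[action].shape[0],
                                 p=env.b_wealth[action][:, wealth]))
    next_selfworth = int(rng.choice(2,
                                    p=env.b_selfworth[action][:, selfworth]))
    approval_cue = int(rng.choice(2, p=env.approval[:, next_selfworth]))
    return (next_wealth, next_selfworth), (next_wealth, approval_cue)


@dataclass(frozen=True)
class TrialRecord:
    trial: int                      # 1-based
    action: str
    true_wealth: int
    true_selfworth: int
    obs_wealth: int
    obs_approval: int
    p_charitable: float             # posterior, after this trial's update
    expected_wealth: float
    G: tuple[float, ...]            # per policy, donate-first order


@dataclass(frozen=True)
class Summary:
    final_p_charitable: float
    final_wealth: int
    mean_wealth: float
    donation_fraction: float
    empty: bool = False


@dataclass(frozen=True)
class Trajectory:
    config: GameConfig
    env: EnvironmentSpec
    seed: int | None
    records: tuple[TrialRecord, ...]
    summary: Summary

    def to_dataframe(self) -> pd.DataFrame:
        rows = [dataclasses.asdict(r) for r in self.records]
        frame = pd.DataFrame(rows, columns=[f.name for f in
                                            dataclasses.fields(TrialRecord)])
        if len(frame):
            frame["G"] = [list(g) for g in frame["G"]]
        return frame

    def to_json(self, path=None, indent: int = 2) -> str:
        payload = {
            **config_to_json(self.config, self.env),
            "seed": self.seed,
            "records": [dataclasses.asdict(r) for r in self.records],
            "summary": dataclasses.asdict(self.summary),
        }
        text = json.dumps(payload, indent=indent, sort_keys=True)
        if path is not None:
            from pathlib import Path
            Path(path).write_text(text)
        return text

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _initial_state(config: GameConfig) -> tuple[int, int]:
    s0 = CHARITABLE if config.initial_selfworth == "charitable" else MEAN
    return (config.initial_wealth_index, s0)


def play_trials(model: GenerativeModel, env_mats: EnvironmentMatrices,
                belief: BeliefState, true_state: tuple[int, int],
                n_trials: int, rng: np.random.Generator,
                start_trial: int = 1
                ) -> tuple[list[TrialRecord], BeliefState, tuple[int, int]]:
    """Advance the agent/environment loop by ``n_trials`` trials, starting
    from the given belief and true state.  Used by both single games and
    multi-stage scenarios where beliefs and states carry over."""
    records: list[TrialRecord] = []
    for t in range(n_trials):
        action, breakdown = select_action(belief, model, rng)
        true_state, observation = env_step(true_state, action, env_mats, rng)
        belief = predict_states(belief, action, model)
        belief = update_beliefs(belief, observation, model)
        records.append(TrialRecord(
            trial=start_trial + t,
            action=action,
            true_wealth=true_state[0],
            true_selfworth=true_state[1],
            obs_wealth=observation[0],
            obs_approval=observation[1],
            p_charitable=belief.p_charitable,
            expected_wealth=belief.expected_wealth,
            G=tuple(float(g) for g in breakdown.G),
        ))
    return records, belief, true_state


def summarize(records, config: GameConfig,
              initial_belief: BeliefState | None = None) -> Summary:
    """Summary metrics of a trial sequence: final posterior P(charitable),
    final true wealth, mean true wealth over trials, donation fraction.
    An empty sequence reports the initial conditions, flagged."""
    if not len(records):
        belief = initial_belief
        if belief is None:
            belief = BeliefState(assemble_model(config).initial_prior.d_joint)
        return Summary(final_p_charitable=belief.p_charitable,
                       final_wealth=config.initial_wealth_index,
                       mean_wealth=float(config.initial_wealth_index),
                       donation_fraction=0.0, empty=True)
    wealth = [r.true_wealth for r in records]
    donations = sum(r.action == DONATE for r in records)
    return Summary(
        final_p_charitable=records[-1].p_charitable,
        final_wealth=records[-1].true_wealth,
        mean_wealth=float(np.mean(wealth)),
        donation_fraction=donations / len(records),
    )


def run_game(config: GameConfig,
             env: EnvironmentSpec | None = None,
             seed: int | np.random.SeedSequence | None = 0,
             model: GenerativeModel | None = None) -> Trajectory:
    """Play one full game of ``config.horizon`` trials.

    Bit-reproducible for a fixed seed and selection mode; ``model`` may be
    passed to amortize model construction across replicates with identical
    configs.
    """
    env = EnvironmentSpec() if env is None else env
    if model is None:
        model = assemble_model(config)
    elif model.config != config:
        raise ValueError("provided model was built from a different config")
    env_mats = build_environment(config, env, model)
    rng = np.random.default_rng(seed)
    belief = BeliefState(model.initial_prior.d_joint)
    records, belief, _ = play_trials(model, env_mats, belief,
                                     _initial_state(config),
                                     config.horizon, rng)
    seed_repr = seed if (seed is None or isinstance(seed, int)) else None
    return Trajectory(config=config, env=env, seed=seed_repr,
                      records=tuple(records),
                      summary=summarize(records, config))
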