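"""Construction and validation of the reputation-game generative model.

The agent's world has two hidden-state factors — wealth (``n_wealth_levels``
ordered levels, broke to wealthy) and self-worth (charitable vs mean) — and
two outcome modalities: an exact wealth cue and a binary approval cue whose
reliability is governed by the likelihood precision ``alpha``.  Transitions
are action-conditioned (donate/keep): donating steps wealth down and
sustains a charitable self-worth, keeping steps wealth up and erodes it,
with the coupling strength set by the transition precision ``beta`` and a
constant attrition of wealth.

Joint states are flattened wealth-major: joint index = ``wealth * 2 +
selfworth`` with charitable = 0, so the joint matrices are Kronecker
products of the wealth factor (left) and the self-worth factor (right).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .config import (ACTIONS, APPROVAL_LABELS, CHARITABLE, DONATE, KEEP,
                     MEAN, SELFWORTH_LABELS, GameConfig, ParameterError)

_ATOL = 1e-12


@dataclass(frozen=True)
class LikelihoodModel:
    """Outcome likelihoods on the joint state space (columns = states)."""

    a_wealth: np.ndarray       # (n_wealth, n_joint) — exact wealth cue
    a_approval: np.ndarray     # (2, n_joint) — approval cue, alpha-precise
    a_approval_factor: np.ndarray  # (2, 2) — approval | self-worth


@dataclass(frozen=True)
class TransitionModel:
    """Action-conditioned column-stochastic transitions, per factor and joint."""

    b_wealth: dict[str, np.ndarray]     # action -> (n_wealth, n_wealth)
    b_selfworth: dict[str, np.ndarray]  # action -> (2, 2)
    b_joint: dict[str, np.ndarray]      # action -> (n_joint, n_joint)


@dataclass(frozen=True)
class PreferenceModel:
    """Log prior preferences (natural-log units) per outcome modality."""

    c_wealth: np.ndarray    # (n_wealth,), nondecreasing, span preference_span
    c_approval: np.ndarray  # (2,), approval preferred by preference_span


@dataclass(frozen=True)
class InitialPrior:
    """Prior belief over joint states at trial 0."""

    d_joint: np.ndarray


@dataclass(frozen=True)
class GenerativeModel:
    config: GameConfig
    likelihood: LikelihoodModel
    transitions: TransitionModel
    preferences: PreferenceModel
    initial_prior: InitialPrior
    action_set: tuple[str, ...] = ACTIONS

    @property
    def n_joint(self) -> int:
        return self.config.n_joint

    def joint_index(self, wealth: int, selfworth: int) -> int:
        return wealth * 2 + selfworth

    def effective_a_approval(self) -> np.ndarray:
        """Approval likelihood with the configured probability floor mixed
        in, used during belief updates so no observation carries exactly
        zero evidence."""
        f = self.config.likelihood_floor
        return (1.0 - 2.0 * f) * self.likelihood.a_approval + f


def build_approval_likelihood(alpha: float) -> np.ndarray:
    """2x2 approval-cue likelihood factor (outcome x self-worth state).

    ``P(approval | charitable) = P(disapproval | mean) = e^alpha /
    (e^alpha + 1)``: 0.5 (uninformative) at alpha = 0, approaching the
    identity mapping as alpha grows.
    """
    if not (np.isfinite(alpha) and alpha >= 0):
        raise ParameterError("alpha: likelihood precision must be >= 0")
    p = float(expit(alpha))
    return np.array([[p, 1.0 - p],
                     [1.0 - p, p]])


def build_selfworth_transition(action: str, beta: float) -> np.ndarray:
    """2x2 self-worth transition factor (next x previous state).

    Donating keeps a charitable state with certainty and converts a mean
    state with probability ``1 - beta``; keeping is the mirror image (mean
    absorbing).  ``beta = 1`` gives the identity for either action,
    ``beta = 0.5`` is maximally imprecise.
    """
    if action not in ACTIONS:
        raise ParameterError(f"action: unknown action {action!r}")
    if not (0.0 < beta <= 1.0):
        raise ParameterError("beta: transition precision must lie in (0, 1]")
    if action == DONATE:
        return np.array([[1.0, 1.0 - beta],
                         [0.0, beta]])
    return np.array([[beta, 0.0],
                     [1.0 - beta, 1.0]])


def _shift_matrix(action: str, n: int) -> np.ndarray:
    shift = np.zeros((n, n))
    for level in range(n):
        if action == DONATE:
            shift[max(level - 1, 0), level] = 1.0
        else:
            shift[min(level + 1, n - 1), level] = 1.0
    return shift


def _decay_matrix(attrition: float, n: int) -> np.ndarray:
    decay = np.zeros((n, n))
    decay[0, 0] = 1.0
    for level in range(1, n):
        decay[level - 1, level] = attrition
        decay[level, level] = 1.0 - attrition
    return decay


def build_wealth_transition(action: str, attrition: float, n: int,
                            decay_before_shift: bool = False) -> np.ndarray:
    """n x n wealth transition factor: the action shift (down one for
    donate with a floor, up one for keep with a ceiling) composed with a
    one-level decay applied with probability ``attrition`` (level 0
    exempt).  Default order is shift then decay."""
    if action not in ACTIONS:
        raise ParameterError(f"action: unknown action {action!r}")
    if not (0.0 <= attrition <= 1.0):
        raise ParameterError("attrition: must be a probability")
    if not (int(n) == n and n >= 2):
        raise ParameterError("n: wealth level count must be an integer >= 2")
    shift = _shift_matrix(action, n)
    decay = _decay_matrix(attrition, n)
    return shift @ decay if decay_before_shift else decay @ shift


def build_preferences(config: GameConfig) -> PreferenceModel:
    """Log-linear wealth preferences from 0 up to ``preference_span`` and a
    ``preference_span`` log-preference for approval over disapproval."""
    c_wealth = np.linspace(0.0, config.preference_span,
                           config.n_wealth_levels)
    c_approval = np.array([config.preference_span, 0.0])
    return PreferenceModel(c_wealth=c_wealth, c_approval=c_approval)


def _joint_wealth_likelihood(n: int) -> np.ndarray:
    # Wealth cue is exact: identity on the wealth component, independent of
    # self-worth.
    return np.kron(np.eye(n), np.ones((1, 2)))


def assemble_model(config: GameConfig) -> GenerativeModel:
    """Build the full generative model from a validated config."""
    n = config.n_wealth_levels
    a_factor = build_approval_likelihood(config.alpha)
    likelihood = LikelihoodModel(
        a_wealth=_joint_wealth_likelihood(n),
        a_approval=np.kron(np.ones((1, n)), a_factor),
        a_approval_factor=a_factor,
    )
    b_wealth = {a: build_wealth_transition(a, config.attrition, n,
                                           config.decay_before_shift)
                for a in ACTIONS}
    b_selfworth = {a: build_selfworth_transition(a, config.beta)
                   for a in ACTIONS}
    b_joint = {a: np.kron(b_wealth[a], b_selfworth[a]) for a in ACTIONS}
    transitions = TransitionModel(b_wealth=b_wealth, b_selfworth=b_selfworth,
                                  b_joint=b_joint)
    d = np.zeros(config.n_joint)
    s0 = CHARITABLE if config.initial_selfworth == "charitable" else MEAN
    d[config.initial_wealth_index * 2 + s0] = 1.0
    return GenerativeModel(
        config=config,
        likelihood=likelihood,
        transitions=transitions,
        preferences=build_preferences(config),
        initial_prior=InitialPrior(d_joint=d),
    )


def _check_stochastic(name: str, matrix: np.ndarray, report: list[str]) -> None:
    sums = matrix.sum(axis=0)
    bad = np.where(np.abs(sums - 1.0) > _ATOL)[0]
    for col in bad:
        report.append(f"{name}: column {col} sums to {sums[col]!r}, not 1")
    if (matrix < -_ATOL).any():
        report.append(f"{name}: negative entries")


def validate_model(model: GenerativeModel) -> list[str]:
    """Return a list of invariant violations (empty iff the model is valid)."""
    report: list[str] = []
    cfg = model.config
    n = cfg.n_wealth_levels

    _check_stochastic("a_wealth", model.likelihood.a_wealth, report)
    _check_stochastic("a_approval", model.likelihood.a_approval, report)
    if not np.array_equal(model.likelihood.a_wealth,
                          _joint_wealth_likelihood(n)):
        report.append("a_wealth: not the identity on the wealth component")

    for action in ACTIONS:
        _check_stochastic(f"b_wealth[{action}]",
                          model.transitions.b_wealth[action], report)
        _check_stochastic(f"b_selfworth[{action}]",
                          model.transitions.b_selfworth[action], report)
        _check_stochastic(f"b_joint[{action}]",
                          model.transitions.b_joint[action], report)
        kron = np.kron(model.transitions.b_wealth[action],
                       model.transitions.b_selfworth[action])
        if not np.allclose(model.transitions.b_joint[action], kron,
                           atol=_ATOL, rtol=0):
            report.append(f"b_joint[{action}]: does not factorize as the "
                          "tensor product of the factor transitions")

    c_w = model.preferences.c_wealth
    if abs((c_w.max() - c_w.min()) - cfg.preference_span) > _ATOL:
        report.append("c_wealth: max - min does not equal preference_span")
    if (np.diff(c_w) < -_ATOL).any():
        report.append("c_wealth: not nondecreasing in wealth level")
    c_a = model.preferences.c_approval
    if abs((c_a[0] - c_a[1]) - cfg.preference_span) > _ATOL:
        report.append("c_approval: approval margin does not equal "
                      "preference_span")

    d = model.initial_prior.d_joint
    if abs(d.sum() - 1.0) > _ATOL or (d < 0).any():
        report.append("d_joint: not a probability vector")
    if d.shape != (cfg.n_joint,):
        report.append("d_joint: wrong dimension")
    return report


def export_matrices(model: GenerativeModel, directory) -> list[str]:
    """Write each model matrix to a labelled CSV under ``directory``;
    returns the file names written."""
    import pandas as pd
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = model.config.n_wealth_levels
    joint = [f"w{w}_{SELFWORTH_LABELS[s]}" for w in range(n) for s in (0, 1)]
    wealth = [f"w{w}" for w in range(n)]
    written = []

    def _write(name: str, matrix: np.ndarray, index, columns) -> None:
        frame = pd.DataFrame(np.atleast_2d(matrix), index=index,
                             columns=columns)
        frame.to_csv(directory / f"{name}.csv")
        written.append(f"{name}.csv")

    _write("a_wealth", model.likelihood.a_wealth, wealth, joint)
    _write("a_approval", model.likelihood.a_approval,
           list(APPROVAL_LABELS), joint)
    for action in ACTIONS:
        _write(f"b_wealth_{action}", model.transitions.b_wealth[action],
               wealth, wealth)
        _write(f"b_selfworth_{action}",
               model.transitions.b_selfworth[action],
               list(SELFWORTH_LABELS), list(SELFWORTH_LABELS))
        _write(f"b_joint_{action}", model.transitions.b_joint[action],
               joint, joint)
    _write("c_wealth", model.preferences.c_wealth, ["log_preference"], wealth)
    _write("c_approval", model.preferences.c_approval, ["log_preference"],
           list(APPROVAL_LABELS))
    _write("d_joint", model.initial_prior.d_joint, ["probability"], joint)
    return written
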