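"""Exact state inference, expected free energy, and action selection.

The joint hidden-state space is small (``n_wealth_levels * 2`` states), so
the posterior is computed by exact Bayesian filtering: a one-step prediction
through the action's transition matrix followed by a multiplicative
likelihood update over both outcome modalities.  Policies (action sequences
of length ``policy_depth``) are scored by expected free energy

    G(pi) = sum_tau sum_m [ KL( A_m q_tau || sigma(C_m) )      (risk)
                          + sum_s q_tau(s) H(A_m[:, s]) ]      (ambiguity)

where ``q_tau`` is the predicted state distribution at step tau under the
policy, ``sigma(C_m)`` the preference distribution obtained by
exponentiating and normalizing the log preferences of modality ``m``, and
``H`` the column entropy of the likelihood.  Actions come from a softmax
policy posterior ``p(pi) ∝ exp(-gamma * G(pi))`` (sampled or argmax).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .config import ACTIONS, DONATE, GameConfig
from .model import GenerativeModel

#: A policy is an ordered tuple of actions, length >= 1.
Policy = tuple[str, ...]

MODALITIES = ("wealth", "approval")


class InferenceError(RuntimeError):
    """Degenerate inference: an observation with zero total evidence."""


@dataclass(frozen=True)
class BeliefState:
    """Normalized posterior over joint hidden states, with factor marginals."""

    q_joint: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q_joint, dtype=float)
        object.__setattr__(self, "q_joint", q)
        if q.ndim != 1 or q.size % 2:
            raise ValueError("q_joint must be a flat vector over "
                             "(wealth x self-worth) joint states")

    @property
    def n_wealth(self) -> int:
        return self.q_joint.size // 2

    @property
    def q_wealth(self) -> np.ndarray:
        return self.q_joint.reshape(self.n_wealth, 2).sum(axis=1)

    @property
    def q_selfworth(self) -> np.ndarray:
        return self.q_joint.reshape(self.n_wealth, 2).sum(axis=0)

    @property
    def p_charitable(self) -> float:
        return float(self.q_selfworth[0])

    @property
    def expected_wealth(self) -> float:
        return float(self.q_wealth @ np.arange(self.n_wealth))

    @classmethod
    def point_mass(cls, wealth: int, selfworth: int, n_wealth: int
                   ) -> "BeliefState":
        q = np.zeros(n_wealth * 2)
        q[wealth * 2 + selfworth] = 1.0
        return cls(q)


@dataclass(frozen=True)
class EFEBreakdown:
    """Per-policy expected-free-energy decomposition and policy posterior."""

    policies: tuple[Policy, ...]
    risk: np.ndarray        # (n_policies, n_modalities), nats
    ambiguity: np.ndarray   # (n_policies, n_modalities), nats
    G: np.ndarray           # (n_policies,), total per policy
    posterior: np.ndarray   # (n_policies,), softmax(-gamma * G)


def predict_states(belief: BeliefState, action: str,
                   model: GenerativeModel) -> BeliefState:
    """One-step prior: push the belief through the action's joint
    transition matrix."""
    b = model.transitions.b_joint[action]
    if b.shape[1] != belief.q_joint.size:
        raise ValueError("belief dimension does not match the model")
    return BeliefState(b @ belief.q_joint)


def update_beliefs(prior_belief: BeliefState,
                   observation: tuple[int, int],
                   model: GenerativeModel) -> BeliefState:
    """Exact Bayes on the joint space given a (wealth cue, approval cue)
    pair; the approval likelihood carries the configured probability floor."""
    o_wealth, o_approval = observation
    a_wealth = model.likelihood.a_wealth
    a_approval = model.effective_a_approval()
    if not (0 <= o_wealth < a_wealth.shape[0]):
        raise ValueError(f"wealth cue index {o_wealth} out of range")
    if o_approval not in (0, 1):
        raise ValueError(f"approval cue index {o_approval} out of range")
    post = prior_belief.q_joint * a_wealth[o_wealth] * a_approval[o_approval]
    evidence = post.sum()
    if evidence <= 0.0:
        raise InferenceError(
            f"observation {observation} has zero evidence under the prior")
    return BeliefState(post / evidence)


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * (np.log(p[mask]) - np.log(q[mask]))))


def _column_entropies(a: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(a > 0, np.log(np.where(a > 0, a, 1.0)), 0.0)
    return -(a * logs).sum(axis=0)


def expected_free_energy(belief: BeliefState, policy: Policy,
                         model: GenerativeModel
                         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Risk and ambiguity (per modality, summed over policy steps) and the
    total G for one policy, starting from ``belief``."""
    if len(policy) < 1:
        raise ValueError("policy must contain at least one action")
    a_mats = (model.likelihood.a_wealth, model.likelihood.a_approval)
    c_vecs = (model.preferences.c_wealth, model.preferences.c_approval)
    pref_dists = [_softmax(c) for c in c_vecs]
    entropies = [_column_entropies(a) for a in a_mats]

    risk = np.zeros(len(a_mats))
    ambiguity = np.zeros(len(a_mats))
    q = belief.q_joint
    for action in policy:
        q = model.transitions.b_joint[action] @ q
        for m, a in enumerate(a_mats):
            predicted = a @ q
            risk[m] += _kl(predicted, pref_dists[m])
            ambiguity[m] += float(q @ entropies[m])
    return risk, ambiguity, float(risk.sum() + ambiguity.sum())


def enumerate_policies(depth: int) -> tuple[Policy, ...]:
    """All action sequences of the given depth, donate-first order."""
    return tuple(itertools.product(ACTIONS, repeat=depth))


def evaluate_policies(belief: BeliefState, model: GenerativeModel,
                      gamma: float | None = None) -> EFEBreakdown:
    """Score every policy of the configured depth and form the policy
    posterior ``softmax(-gamma * G)``."""
    cfg: GameConfig = model.config
    gamma = cfg.policy_precision if gamma is None else gamma
    policies = enumerate_policies(cfg.policy_depth)
    risk = np.zeros((len(policies), len(MODALITIES)))
    ambiguity = np.zeros_like(risk)
    G = np.zeros(len(policies))
    for i, policy in enumerate(policies):
        risk[i], ambiguity[i], G[i] = expected_free_energy(belief, policy,
                                                           model)
    posterior = _softmax(-gamma * G)
    return EFEBreakdown(policies=policies, risk=risk, ambiguity=ambiguity,
                        G=G, posterior=posterior)


def select_action(belief: BeliefState, model: GenerativeModel,
                  rng: np.random.Generator | int | None = None,
                  mode: str | None = None) -> tuple[str, EFEBreakdown]:
    """Choose the next action: enumerate policies, score them, then either
    sample from the policy posterior or take its mode (ties resolve to the
    first policy in donate-first enumeration order).  Returns the first
    action of the chosen policy together with the full breakdown."""
    cfg = model.config
    mode = cfg.selection_mode if mode is None else mode
    breakdown = evaluate_policies(belief, model)
    if mode == "argmax":
        choice = int(np.argmin(breakdown.G))
    else:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        choice = int(rng.choice(len(breakdown.policies),
                                p=breakdown.posterior))
    return breakdown.policies[choice][0], breakdown
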