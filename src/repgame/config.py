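"""Configuration objects shared by all subcommands.

Three dataclasses describe a complete experiment: :class:`GameConfig` (the
agent's generative model and decision settings), :class:`EnvironmentSpec`
(the generative process that actually emits states and cues) and
:class:`SweepGrid` (the (alpha, beta) grid and replicate seeding for heat-map
experiments).  All are immutable; invalid values raise
:class:`ParameterError` naming the offending field.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Action labels, in canonical enumeration order (donate first; ties in
#: deterministic action selection resolve to the earlier action).
DONATE = "donate"
KEEP = "keep"
ACTIONS = (DONATE, KEEP)

#: Self-worth factor levels (index into the 2-level factor).
CHARITABLE = 0
MEAN = 1
SELFWORTH_LABELS = ("charitable", "mean")

#: Approval modality outcomes.
APPROVAL = 0
DISAPPROVAL = 1
APPROVAL_LABELS = ("approval", "disapproval")


class ParameterError(ValueError):
    """An invalid parameter value, reported with its field name."""


def _require(cond: bool, key: str, msg: str) -> None:
    if not cond:
        raise ParameterError(f"{key}: {msg}")


@dataclass(frozen=True)
class GameConfig:
    """Parameters of the reputation-game agent.

    Parameters
    ----------
    n_wealth_levels
        Number of wealth states, from broke (0) upward.
    alpha
        Likelihood (sensory) precision of the approval cue, ``>= 0``.
        ``P(approval | charitable) = e^alpha / (e^alpha + 1)``: 0 gives an
        uninformative 50-50 mapping, large values approach a deterministic
        one.
    beta
        Transition (prior) precision of the self-worth dynamics, in
        ``(0, 1]``: the probability that the action-disfavoured self-worth
        state persists for one trial.  1 yields identity transitions
        (choices decoupled from self-worth); 0.5 is maximally imprecise.
    attrition
        Per-trial probability of losing one wealth level, applied on top of
        the action-driven shift.
    preference_span
        Max-minus-min of the log prior preferences (natural-log units), for
        both the wealth and the approval modality.
    horizon
        Number of choices per game.
    policy_depth
        Planning depth; all ``2**policy_depth`` action sequences are scored.
    policy_precision
        Inverse temperature (gamma) of the softmax over negative expected
        free energy.
    selection_mode
        ``"sample"`` draws the policy from its posterior; ``"argmax"`` takes
        the posterior mode (ties resolve to donate-first policies).
    initial_wealth_index
        True and believed starting wealth level.
    initial_selfworth
        Starting self-worth, ``"charitable"`` or ``"mean"``; the initial
        prior is a point mass on ``(initial_wealth_index, initial_selfworth)``.
    likelihood_floor
        Probability floor mixed into the approval likelihood columns during
        belief updates, guarding against zero-evidence observations when
        alpha is extreme and the environment disagrees.
    decay_before_shift
        If true, wealth attrition is applied before the action shift within
        a trial instead of after (sensitivity check; default order is
        shift-then-decay).
    """

    n_wealth_levels: int = 8
    alpha: float = 4.0
    beta: float = 0.9
    attrition: float = 0.10
    preference_span: float = 4.0
    horizon: int = 16
    policy_depth: int = 1
    policy_precision: float = 8.0
    selection_mode: str = "sample"
    initial_wealth_index: int = 0
    initial_selfworth: str = "charitable"
    likelihood_floor: float = 1e-10
    decay_before_shift: bool = False

    def __post_init__(self) -> None:
        _require(int(self.n_wealth_levels) == self.n_wealth_levels
                 and self.n_wealth_levels >= 2,
                 "n_wealth_levels", "must be an integer >= 2")
        _require(math.isfinite(self.alpha) and self.alpha >= 0,
                 "alpha", "likelihood precision must be >= 0")
        _require(0.0 < self.beta <= 1.0,
                 "beta", "transition precision must lie in (0, 1]")
        _require(0.0 <= self.attrition <= 1.0,
                 "attrition", "must be a probability")
        _require(self.preference_span >= 0,
                 "preference_span", "must be >= 0")
        _require(int(self.horizon) == self.horizon and self.horizon >= 0,
                 "horizon", "must be an integer >= 0")
        _require(int(self.policy_depth) == self.policy_depth
                 and self.policy_depth >= 1,
                 "policy_depth", "must be an integer >= 1")
        _require(self.policy_precision > 0,
                 "policy_precision", "must be > 0")
        _require(self.selection_mode in ("sample", "argmax"),
                 "selection_mode", "must be 'sample' or 'argmax'")
        _require(0 <= self.initial_wealth_index < self.n_wealth_levels,
                 "initial_wealth_index", "out of range")
        _require(self.initial_selfworth in SELFWORTH_LABELS,
                 "initial_selfworth", "must be 'charitable' or 'mean'")
        _require(0 <= self.likelihood_floor < 0.5,
                 "likelihood_floor", "must lie in [0, 0.5)")

    @property
    def n_joint(self) -> int:
        return self.n_wealth_levels * 2

    def replace(self, **kw: Any) -> "GameConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class EnvironmentSpec:
    """The generative process emitting true states and cues.

    By default the approval cue is veridical (approval iff the true
    self-worth is charitable) and the true self-worth dynamics use the
    agent's own beta — the manipulated precisions are the subject's
    confidence, not properties of the world.

    Parameters
    ----------
    env_alpha
        Approval veridicality of the world.  ``None`` (default) means fully
        precise; a float builds the same logistic mapping used by the agent.
    env_beta
        True self-worth persistence; ``None`` copies the agent's beta.
    attrition
        True wealth attrition; ``None`` copies the agent's rate.
    share_with_model
        Force all environment matrices identical to the agent's (overrides
        the three fields above).
    """

    env_alpha: float | None = None
    env_beta: float | None = None
    attrition: float | None = None
    share_with_model: bool = False

    def __post_init__(self) -> None:
        if self.env_alpha is not None:
            _require(self.env_alpha >= 0, "env_alpha", "must be >= 0")
        if self.env_beta is not None:
            _require(0.0 < self.env_beta <= 1.0, "env_beta",
                     "must lie in (0, 1]")
        if self.attrition is not None:
            _require(0.0 <= self.attrition <= 1.0, "attrition",
                     "must be a probability")

    def replace(self, **kw: Any) -> "EnvironmentSpec":
        return dataclasses.replace(self, **kw)


def _default_alphas() -> tuple[float, ...]:
    return tuple(i * 0.25 for i in range(17))  # 0, 0.25, ..., 4


def _default_betas() -> tuple[float, ...]:
    return tuple(0.5 + i * 0.05 for i in range(11))  # 0.5, 0.55, ..., 1.0


@dataclass(frozen=True)
class SweepGrid:
    """(alpha, beta) grid with per-cell replicate seeding."""

    alpha_values: tuple[float, ...] = field(default_factory=_default_alphas)
    beta_values: tuple[float, ...] = field(default_factory=_default_betas)
    n_replicates: int = 32
    base_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha_values",
                           tuple(float(a) for a in self.alpha_values))
        object.__setattr__(self, "beta_values",
                           tuple(float(b) for b in self.beta_values))
        _require(len(self.alpha_values) >= 1, "alpha_values", "empty")
        _require(len(self.beta_values) >= 1, "beta_values", "empty")
        _require(all(a >= 0 for a in self.alpha_values),
                 "alpha_values", "all values must be >= 0")
        _require(all(0 < b <= 1 for b in self.beta_values),
                 "beta_values", "all values must lie in (0, 1]")
        _require(self.n_replicates >= 1, "n_replicates", "must be >= 1")
        _require(self.base_seed >= 0, "base_seed", "must be >= 0")

    def replace(self, **kw: Any) -> "SweepGrid":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Config file I/O

_SECTIONS = {"game": GameConfig, "environment": EnvironmentSpec,
             "sweep": SweepGrid}


def _from_mapping(cls: type, mapping: dict[str, Any], section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ParameterError(
            f"{section}.{sorted(unknown)[0]}: unknown configuration key")
    coerced = {}
    for key, value in mapping.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    try:
        return cls(**coerced)
    except ParameterError as err:
        raise ParameterError(f"{section}.{err}") from err
    except TypeError as err:
        raise ParameterError(f"{section}: {err}") from err


def load_config(path: str | Path) -> tuple[GameConfig, EnvironmentSpec, SweepGrid]:
    """Read a YAML or JSON config file with ``game`` / ``environment`` /
    ``sweep`` sections; absent sections and keys take their defaults,
    unknown keys are rejected with their dotted path."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterError("top level: config must be a mapping")
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ParameterError(f"{sorted(unknown)[0]}: unknown section")
    out = []
    for name, cls in _SECTIONS.items():
        section = data.get(name) or {}
        if not isinstance(section, dict):
            raise ParameterError(f"{name}: section must be a mapping")
        out.append(_from_mapping(cls, section, name))
    return tuple(out)  # type: ignore[return-value]


def dump_config(game: GameConfig, env: EnvironmentSpec, grid: SweepGrid,
                path: str | Path | None = None) -> str:
    """Serialize the three config objects to YAML; optionally write to
    ``path``.  ``load_config(dump_config(...))`` round-trips semantically."""
    data = {
        "game": dataclasses.asdict(game),
        "environment": dataclasses.asdict(env),
        "sweep": {**dataclasses.asdict(grid),
                  "alpha_values": list(grid.alpha_values),
                  "beta_values": list(grid.beta_values)},
    }
    text = yaml.safe_dump(data, sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def config_to_json(game: GameConfig, env: EnvironmentSpec) -> dict[str, Any]:
    """JSON-ready snapshot used in trajectory serializations and manifests."""
    return {"game": dataclasses.asdict(game),
            "environment": dataclasses.asdict(env)}
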