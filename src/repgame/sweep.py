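"""Parameter sweeps over (alpha, beta) and the developmental-trajectory
scenario.

``run_sweep`` replays the heat-map experiment: for every grid cell the game
is repeated across independently seeded replicates and summarized by the
mean final posterior P(charitable) and mean final true wealth (plus SDs and
the mean donation fraction).  Replicate seeds are derived per cell from the
grid's base seed, so results do not depend on cell evaluation order.

``developmental_trajectory`` chains game stages with different (alpha,
beta) while carrying beliefs and true states across stage boundaries — the
staged decline from an altruistic regime (precise approval likelihood)
through attenuated likelihood precision to inflated prior precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import EnvironmentSpec, GameConfig, ParameterError, SweepGrid
from .inference import BeliefState
from .model import assemble_model
from .simulate import (Summary, build_environment, play_trials, run_game,
                       summarize)

METRICS = ("p_charitable", "final_wealth", "donation_fraction")

#: Default developmental stages (alpha, beta, n_trials): an altruistic start
#: with precise approval likelihood and action-sensitive transitions, then
#: loss of likelihood precision, then maximal transition-prior precision
#: (the fully decoupled self-aggrandizing limit).
DEFAULT_STAGES: tuple[tuple[float, float, int], ...] = (
    (4.0, 0.55, 16),
    (0.0, 0.55, 16),
    (0.0, 1.0, 16),
)


@dataclass(frozen=True)
class SweepResult:
    """Per-cell summary statistics on an |alpha| x |beta| grid."""

    grid: SweepGrid
    config: GameConfig
    env: EnvironmentSpec
    mean_p_charitable: np.ndarray
    sd_p_charitable: np.ndarray
    mean_final_wealth: np.ndarray
    sd_final_wealth: np.ndarray
    mean_donation_fraction: np.ndarray

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (alpha, beta, metric)."""
        rows = []
        for i, a in enumerate(self.grid.alpha_values):
            for j, b in enumerate(self.grid.beta_values):
                cells = {
                    "p_charitable": (self.mean_p_charitable[i, j],
                                     self.sd_p_charitable[i, j]),
                    "final_wealth": (self.mean_final_wealth[i, j],
                                     self.sd_final_wealth[i, j]),
                    "donation_fraction": (self.mean_donation_fraction[i, j],
                                          np.nan),
                }
                for metric, (mean, sd) in cells.items():
                    rows.append({"alpha": a, "beta": b, "metric": metric,
                                 "mean": mean, "sd": sd})
        return pd.DataFrame(rows)


def cell_seed(base_seed: int, i: int, j: int, replicate: int
              ) -> np.random.SeedSequence:
    """Deterministic, order-independent seed for one replicate of one cell."""
    return np.random.SeedSequence(entropy=base_seed,
                                  spawn_key=(i, j, replicate))


def run_sweep(grid: SweepGrid, config: GameConfig | None = None,
              env: EnvironmentSpec | None = None) -> SweepResult:
    """Aggregate ``grid.n_replicates`` independent games per (alpha, beta)
    cell."""
    config = GameConfig() if config is None else config
    env = EnvironmentSpec() if env is None else env
    shape = (len(grid.alpha_values), len(grid.beta_values))
    mean_p = np.zeros(shape)
    sd_p = np.zeros(shape)
    mean_w = np.zeros(shape)
    sd_w = np.zeros(shape)
    mean_d = np.zeros(shape)
    for i, alpha in enumerate(grid.alpha_values):
        for j, beta in enumerate(grid.beta_values):
            cell_cfg = config.replace(alpha=alpha, beta=beta)
            model = assemble_model(cell_cfg)
            p, w, d = [], [], []
            for r in range(grid.n_replicates):
                try:
                    traj = run_game(cell_cfg, env,
                                    seed=cell_seed(grid.base_seed, i, j, r),
                                    model=model)
                except Exception as err:
                    raise RuntimeError(
                        f"sweep cell (alpha={alpha}, beta={beta}, "
                        f"replicate={r}) failed: {err}") from err
                p.append(traj.summary.final_p_charitable)
                w.append(traj.summary.final_wealth)
                d.append(traj.summary.donation_fraction)
            mean_p[i, j], sd_p[i, j] = np.mean(p), np.std(p)
            mean_w[i, j], sd_w[i, j] = np.mean(w), np.std(w)
            mean_d[i, j] = np.mean(d)
    return SweepResult(grid=grid, config=config, env=env,
                       mean_p_charitable=mean_p, sd_p_charitable=sd_p,
                       mean_final_wealth=mean_w, sd_final_wealth=sd_w,
                       mean_donation_fraction=mean_d)


# ---------------------------------------------------------------------------
# Developmental trajectory (staged precision changes with carried-over state)

@dataclass(frozen=True)
class StageSummary:
    stage: int                 # 1-based
    alpha: float
    beta: float
    n_trials: int
    summary: Summary


def developmental_trajectory(stages, config: GameConfig | None = None,
                             seed: int | np.random.SeedSequence | None = 0,
                             env: EnvironmentSpec | None = None
                             ) -> list[StageSummary]:
    """Play consecutive stages with different (alpha, beta); beliefs and
    true states carry over between stages.

    ``stages`` is an ordered sequence of ``(alpha, beta, n_trials)``
    triples, at least two entries except when explicitly replaying a single
    game.
    """
    stages = tuple(stages)
    if len(stages) < 1:
        raise ParameterError("stages: at least one stage is required")
    config = GameConfig() if config is None else config
    env = EnvironmentSpec() if env is None else env
    rng = np.random.default_rng(seed)

    first_cfg = config.replace(alpha=stages[0][0], beta=stages[0][1])
    model0 = assemble_model(first_cfg)
    belief = BeliefState(model0.initial_prior.d_joint)
    s0 = 0 if config.initial_selfworth == "charitable" else 1
    true_state = (config.initial_wealth_index, s0)

    out: list[StageSummary] = []
    trial = 1
    for k, (alpha, beta, n_trials) in enumerate(stages, start=1):
        stage_cfg = config.replace(alpha=alpha, beta=beta)
        model = assemble_model(stage_cfg)
        env_mats = build_environment(stage_cfg, env, model)
        records, belief, true_state = play_trials(
            model, env_mats, belief, true_state, int(n_trials), rng,
            start_trial=trial)
        trial += int(n_trials)
        out.append(StageSummary(stage=k, alpha=alpha, beta=beta,
                                n_trials=int(n_trials),
                                summary=summarize(records, stage_cfg,
                                                  initial_belief=belief)))
    return out


def developmental_trajectory_ensemble(stages=DEFAULT_STAGES,
                                      config: GameConfig | None = None,
                                      base_seed: int = 0,
                                      n_replicates: int = 32,
                                      env: EnvironmentSpec | None = None
                                      ) -> pd.DataFrame:
    """Replicate-averaged stage summaries: one row per stage with the mean
    (over seeds) of each summary metric."""
    stages = tuple(stages)
    acc: dict[int, list[Summary]] = {k: [] for k in range(len(stages))}
    for r in range(n_replicates):
        seed = np.random.SeedSequence(entropy=base_seed, spawn_key=(r,))
        for k, st in enumerate(developmental_trajectory(stages, config,
                                                        seed, env)):
            acc[k].append(st.summary)
    rows = []
    for k, (alpha, beta, n_trials) in enumerate(stages):
        sums = acc[k]
        rows.append({
            "stage": k + 1, "alpha": alpha, "beta": beta,
            "n_trials": n_trials,
            "mean_p_charitable": float(np.mean(
                [s.final_p_charitable for s in sums])),
            "mean_wealth": float(np.mean([s.mean_wealth for s in sums])),
            "mean_final_wealth": float(np.mean(
                [s.final_wealth for s in sums])),
            "mean_donation_fraction": float(np.mean(
                [s.donation_fraction for s in sums])),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Export

def export_heatmaps(result: SweepResult, path, plot: bool = False
                    ) -> list[Path]:
    """Write the sweep to a long-format CSV (and optionally PNG heat maps)
    under ``path``; returns the files written.  Cell ordering is row-major
    in (alpha, beta)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = path / "sweep_long.csv"
    result.to_long_frame().to_csv(csv_path, index=False)
    written.append(csv_path)
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        panels = {"p_charitable": result.mean_p_charitable,
                  "final_wealth": result.mean_final_wealth}
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, (name, values) in zip(axes, panels.items()):
            im = ax.imshow(values, origin="lower", aspect="auto",
                           extent=(min(result.grid.beta_values),
                                   max(result.grid.beta_values),
                                   min(result.grid.alpha_values),
                                   max(result.grid.alpha_values)))
            ax.set_xlabel("beta (transition precision)")
            ax.set_ylabel("alpha (likelihood precision)")
            ax.set_title(name)
            fig.colorbar(im, ax=ax)
        fig.tight_layout()
        png_path = path / "sweep_heatmaps.png"
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
        written.append(png_path)
    return written


def load_heatmaps(csv_path) -> pd.DataFrame:
    """Re-import the long-format sweep CSV written by ``export_heatmaps``."""
    return pd.read_csv(csv_path)
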