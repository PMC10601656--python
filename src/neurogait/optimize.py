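"""CMA-ES solution of the walking MDP.

The search vector has 49 entries: the 37 reflex-controller parameters
followed by the 12 initial-state parameters.  Optimization runs in a
normalized [0, 1]^49 box mapped affinely onto physical bounds; CMA-ES
(covariance matrix adaptation evolution strategy, the standard
(mu/mu_w, lambda) formulation with rank-1 and rank-mu covariance updates and
cumulative step-size adaptation) maximizes the episode reward.

Candidate evaluation is deterministic given the parameter vector and the
experiment configuration, so parallel evaluation cannot change the result
stream; a diverging simulation scores a large negative sentinel so the
search continues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import controller as ctl
from .environment import (InitialStateParams, N_INIT, RewardWeights,
                          WalkingEnv, rollout)
from .muscle import MuscleSet
from .skeleton import SimulationDiverged, SkeletonModel

N_SEARCH = ctl.N_PARAMS + N_INIT  # 49
DIVERGENCE_SENTINEL = -1.0e6

#: physical bounds for the 37 controller parameters, canonical order
CONTROLLER_BOUNDS = {
    "theta_tgt_trunk": (-0.2, 0.4),
    "theta_tgt_knee_swing": (0.0, 1.5),
    "theta_tgt_ankle_swing": (-0.5, 0.5),
    "g_f_sol": (0.0, 3.0), "g_f_gas": (0.0, 3.0), "g_f_vas": (0.0, 3.0),
    "g_f_ham_stance": (0.0, 3.0), "g_f_gmax_stance": (0.0, 3.0),
    "g_f_ham_swing": (0.0, 3.0),
    "g_l_ta": (0.0, 3.0), "l_off_ta": (0.5, 1.5), "g_solta": (0.0, 3.0),
    "g_l_ilpso_swing": (0.0, 3.0), "l_off_ilpso": (0.5, 1.5),
    "g_v_bfsh_swing": (0.0, 3.0), "g_v_knee_stance": (0.0, 3.0),
    "k_overext": (0.0, 3.0), "phi_knee_off": (0.0, 0.3),
    "kp_trunk": (0.0, 3.0), "kd_trunk": (0.0, 3.0),
    "w_ham": (0.0, 1.0), "w_gmax": (0.0, 1.0), "w_ilpso": (0.0, 1.0),
    "c0_ilpso": (0.0, 0.3), "c0_gmax": (0.0, 0.3), "c0_ham": (0.0, 0.3),
    "c0_rf": (0.0, 0.3), "c0_vas": (0.0, 0.3), "c0_bfsh": (0.0, 0.3),
    "c0_gas": (0.0, 0.3), "c0_sol": (0.0, 0.3), "c0_ta": (0.0, 0.3),
    "kp_ankle_swing": (0.0, 3.0), "kd_ankle_swing": (0.0, 3.0),
    "kp_knee_swing": (0.0, 3.0), "kd_knee_swing": (0.0, 3.0),
    "e_ds": (0.0, 0.5),
}

#: physical bounds for the 12 initial-state parameters
INIT_BOUNDS = {
    "forward_speed": (0.5, 2.0), "rightward_speed": (-0.5, 0.5),
    "pelvis_height": (0.85, 1.05), "trunk_lean": (-0.3, 0.3),
    "hip_abduction_R": (-0.2, 0.2), "hip_abduction_L": (-0.2, 0.2),
    "hip_flexion_R": (-0.5, 0.8), "hip_flexion_L": (-0.5, 0.8),
    "knee_flexion_R": (0.0, 1.2), "knee_flexion_L": (0.0, 1.2),
    "ankle_R": (-0.5, 0.5), "ankle_L": (-0.5, 0.5),
}


def search_bounds() -> np.ndarray:
    """(49, 2) array of physical (lo, hi) bounds in canonical order."""
    lo_hi = [CONTROLLER_BOUNDS[n] for n in ctl.PARAM_NAMES]
    lo_hi += [INIT_BOUNDS[n] for n in
              InitialStateParams.__dataclass_fields__]
    return np.array(lo_hi, dtype=float)


def unit_to_physical(x_unit: np.ndarray) -> np.ndarray:
    b = search_bounds()
    return b[:, 0] + np.clip(x_unit, 0.0, 1.0) * (b[:, 1] - b[:, 0])


def physical_to_unit(x_phys: np.ndarray) -> np.ndarray:
    b = search_bounds()
    return np.clip((x_phys - b[:, 0]) / (b[:, 1] - b[:, 0]), 0.0, 1.0)


def split_candidate(x_unit: np.ndarray):
    """Unit 49-vector -> (ControllerParams, InitialStateParams)."""
    x = np.asarray(x_unit, dtype=float).ravel()
    if x.shape != (N_SEARCH,):
        raise ValueError(f"candidate must have length {N_SEARCH}, got {x.shape}")
    phys = unit_to_physical(x)
    params = ctl.unpack_params(ctl.project_params(phys[:ctl.N_PARAMS]))
    init = InitialStateParams.from_array(phys[ctl.N_PARAMS:])
    return params, init


@dataclass(frozen=True)
class EvalConfig:
    """Everything one candidate evaluation needs (picklable)."""

    horizon: float = 10.0
    v_tgt: float | None = 1.3
    weights: RewardWeights = field(default_factory=RewardWeights)
    weakness_muscle: str | None = None   # e.g. "SOL"
    mif_scale: float = 1.0

    def build_env(self) -> WalkingEnv:
        muscles = MuscleSet()
        if self.weakness_muscle is not None:
            muscles = muscles.scaled(self.weakness_muscle, self.mif_scale)
        return WalkingEnv(SkeletonModel(), muscles, self.weights,
                          horizon=self.horizon, v_tgt=self.v_tgt)


def evaluate_candidate(x_unit: np.ndarray, cfg: EvalConfig) -> float:
    """Deterministic episode reward of one (controller, initial-state)
    candidate; divergence returns the sentinel instead of raising."""
    params, init = split_candidate(np.clip(x_unit, 0.0, 1.0))
    env = cfg.build_env()
    try:
        trace = rollout(params, init, env)
    except SimulationDiverged:
        return DIVERGENCE_SENTINEL
    return trace.total_reward


def rollout_candidate(x_unit: np.ndarray, cfg: EvalConfig):
    """Full trace for a candidate (analysis / reporting)."""
    params, init = split_candidate(np.clip(x_unit, 0.0, 1.0))
    env = cfg.build_env()
    return rollout(params, init, env)


# ---------------------------------------------------------------------------
# CMA-ES core
# ---------------------------------------------------------------------------

@dataclass
class OptConfig:
    popsize: int = 16
    generations: int = 1000
    sigma0: float = 0.25
    seed: int = 0
    n_workers: int = 1
    horizon: float = 10.0
    v_tgt: float | None = 1.3
    bounds: tuple[float, float] = (0.0, 1.0)  # normalized box per coordinate

    def __post_init__(self):
        if self.popsize < 4:
            raise ValueError("popsize must be at least 4")
        if self.generations < 1:
            raise ValueError("generations must be at least 1")


@dataclass
class OptResult:
    best_params: np.ndarray            # unit-box vector
    best_reward: float
    reward_history: list               # per generation: (best, mean, best_ever)
    evaluations: int
    seed_provenance: str = "cold"

    def to_json(self, path) -> None:
        payload = {
            "best_params_unit": [float(v) for v in self.best_params],
            "best_reward": float(self.best_reward),
            "reward_history": [[float(a), float(b), float(c)]
                               for a, b, c in self.reward_history],
            "evaluations": int(self.evaluations),
            "seed_provenance": self.seed_provenance,
        }
        if len(self.best_params) == N_SEARCH:
            params, init = split_candidate(self.best_params)
            payload["best_controller_named"] = {
                n: float(getattr(params, n)) for n in ctl.PARAM_NAMES}
            payload["best_initial_state"] = {
                n: float(getattr(init, n))
                for n in InitialStateParams.__dataclass_fields__}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "OptResult":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.array(payload["best_params_unit"]),
                   payload["best_reward"],
                   [tuple(g) for g in payload["reward_history"]],
                   payload["evaluations"],
                   payload.get("seed_provenance", "cold"))


class CMAES:
    """(mu/mu_w, lambda) CMA-ES maximizer with box repair."""

    def __init__(self, x0: np.ndarray, sigma0: float, popsize: int,
                 seed: int, bounds: tuple[float, float] | None = (0.0, 1.0)):
        self.n = len(x0)
        self.mean = np.asarray(x0, dtype=float).copy()
        self.sigma = float(sigma0)
        self.lam = int(popsize)
        self.bounds = bounds
        self.rng = np.random.default_rng(seed)

        n, lam = self.n, self.lam
        self.mu = lam // 2
        w = np.log((lam + 1) / 2.0) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights ** 2)
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2.0 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((n + 2) ** 2 + self.mueff))
        self.damps = (1 + 2 * max(0.0, np.sqrt((self.mueff - 1) / (n + 1)) - 1)
                      + self.cs)
        self.chi_n = np.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))

        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self._decompose()
        self.generation = 0

    def _decompose(self):
        self.C = (self.C + self.C.T) / 2
        d, B = np.linalg.eigh(self.C)
        d = np.maximum(d, 1e-20)
        self.B = B
        self.D = np.sqrt(d)
        self.inv_sqrt_C = B @ np.diag(1.0 / self.D) @ B.T

    def ask(self) -> np.ndarray:
        z = self.rng.standard_normal((self.lam, self.n))
        y = (self.B * self.D) @ z.T          # (n, lam)
        x = self.mean[None, :] + self.sigma * y.T
        if self.bounds is not None:
            x = np.clip(x, self.bounds[0], self.bounds[1])
        return x

    def tell(self, x: np.ndarray, rewards: np.ndarray):
        order = np.argsort(-np.asarray(rewards, dtype=float), kind="stable")
        elite = x[order[:self.mu]]
        y_elite = (elite - self.mean) / self.sigma
        y_bar = self.weights @ y_elite
        self.mean = self.mean + self.sigma * y_bar

        self.ps = ((1 - self.cs) * self.ps
                   + np.sqrt(self.cs * (2 - self.cs) * self.mueff)
                   * (self.inv_sqrt_C @ y_bar))
        self.generation += 1
        denom = np.sqrt(1 - (1 - self.cs) ** (2 * self.generation))
        hsig = (np.linalg.norm(self.ps) / denom / self.chi_n
                < 1.4 + 2 / (self.n + 1))
        self.pc = ((1 - self.cc) * self.pc
                   + hsig * np.sqrt(self.cc * (2 - self.cc) * self.mueff) * y_bar)
        rank_mu = (y_elite.T * self.weights) @ y_elite
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (1 - hsig) * self.cc * (2 - self.cc) * self.C)
                  + self.cmu * rank_mu)
        self.sigma *= np.exp((self.cs / self.damps)
                             * (np.linalg.norm(self.ps) / self.chi_n - 1))
        self._decompose()


def _parallel_map(objective, xs: np.ndarray, n_workers: int,
                  args: tuple = ()) -> np.ndarray:
    """Order-preserving candidate evaluation; identical results for any
    worker count because each evaluation is deterministic in x."""
    if n_workers <= 1:
        return np.array([objective(x, *args) for x in xs], dtype=float)
    from joblib import Parallel, delayed
    res = Parallel(n_jobs=n_workers)(delayed(objective)(x, *args) for x in xs)
    return np.array(res, dtype=float)


_USE_CFG = object()


def run_cmaes(objective, x0: np.ndarray, cfg: OptConfig,
              bounds: tuple[float, float] | None = _USE_CFG,
              objective_args: tuple = (),
              callback=None,
              seed_provenance: str = "cold",
              checkpoint_path=None, checkpoint_every: int = 10) -> OptResult:
    """Maximize ``objective(x, *objective_args)`` with CMA-ES.

    Best-ever bookkeeping is elitist: the reported best reward is monotone
    non-decreasing across generations.  With ``checkpoint_path`` the
    best-so-far result is persisted every ``checkpoint_every`` generations
    (and at the end), so an interrupted run can be resumed warm-started.
    """
    if bounds is _USE_CFG:
        bounds = cfg.bounds
    es = CMAES(x0, cfg.sigma0, cfg.popsize, cfg.seed, bounds)
    best_x = np.asarray(x0, dtype=float).copy()
    best_f = -np.inf
    history = []
    n_eval = 0
    for gen in range(cfg.generations):
        xs = es.ask()
        fs = _parallel_map(objective, xs, cfg.n_workers, objective_args)
        n_eval += len(fs)
        i = int(np.argmax(fs))
        if fs[i] > best_f:
            best_f = float(fs[i])
            best_x = xs[i].copy()
        history.append((float(fs[i]), float(np.mean(fs)), best_f))
        es.tell(xs, fs)
        if callback is not None:
            callback(gen, es, history[-1])
        if checkpoint_path is not None and (gen + 1) % checkpoint_every == 0:
            OptResult(best_x, best_f, history, n_eval,
                      seed_provenance).to_json(checkpoint_path)
    result = OptResult(best_x, best_f, history, n_eval, seed_provenance)
    if checkpoint_path is not None:
        result.to_json(checkpoint_path)
    return result


# ---------------------------------------------------------------------------
# warm starts
# ---------------------------------------------------------------------------

WARM_SIGMA0 = 0.05


def seed_from(prev: OptResult, n_expected: int = N_SEARCH) -> np.ndarray:
    """Warm-start mean from a previous optimization's best solution."""
    x0 = np.asarray(prev.best_params, dtype=float)
    if x0.shape != (n_expected,):
        raise ValueError(f"seed solution has dimension {x0.shape}, "
                         f"expected ({n_expected},)")
    return x0.copy()


def cold_start(seed: int, n: int = N_SEARCH) -> np.ndarray:
    """Uniform random start in the unit box under the run seed."""
    return np.random.default_rng(seed).uniform(0.0, 1.0, size=n)


def optimize_walking(cfg: OptConfig,
                     eval_cfg: EvalConfig | None = None,
                     x0: np.ndarray | None = None,
                     seed_provenance: str = "cold",
                     callback=None,
                     checkpoint_path=None,
                     restarts: int = 1) -> OptResult:
    """End-to-end: CMA-ES over the 49-dim (controller + initial state) box.

    ``restarts > 1`` runs independent searches from fresh cold starts (seeds
    derived from the master seed) and returns the best — a deterministic,
    single-process stand-in for parallel multi-start schemes.
    """
    eval_cfg = eval_cfg or EvalConfig(horizon=cfg.horizon, v_tgt=cfg.v_tgt)
    best = None
    for k in range(max(1, restarts)):
        sub = replace_seed(cfg, cfg.seed + 7919 * k) if k else cfg
        start = x0 if x0 is not None else cold_start(sub.seed)
        res = run_cmaes(evaluate_candidate, start, sub,
                        objective_args=(eval_cfg,), callback=callback,
                        seed_provenance=seed_provenance,
                        checkpoint_path=checkpoint_path)
        if best is None or res.best_reward > best.best_reward:
            best = res
    return best


def replace_seed(cfg: OptConfig, seed: int) -> OptConfig:
    from dataclasses import replace
    return replace(cfg, seed=int(seed) % (2 ** 31))
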