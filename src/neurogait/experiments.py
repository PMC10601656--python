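"""The three evaluation protocols as reproducible, config-driven runs.

1. *Self-selected speed*: optimize with the velocity cost removed over a
   20 s horizon and report the speed the model settles on (steady portion =
   final half of the episode).
2. *Speed sweep*: solve the anchor speed 1.45 m/s cold, then propagate
   outward to neighbor speeds with warm starts, covering 1.10-1.80 m/s.
3. *Plantarflexor weakness*: scale SOL or GAS maximum isometric force to
   80% or 60% bilaterally and re-optimize warm-started from the 1.45 m/s
   solution.

Every run is fully determined by (config, master seed).  Full-scale budgets
(population 16, 1000 generations) are the intended scientific conditions; the
smoke-scale defaults (population 8, 30 generations, 4 s horizon) exercise
the identical code path at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import GaitCycleSummary, ensemble_stats, segment_cycles
from .environment import EpisodeTrace
from .optimize import (EvalConfig, OptConfig, OptResult, WARM_SIGMA0,
                       optimize_walking, rollout_candidate, seed_from)

log = logging.getLogger(__name__)

ANCHOR_SPEED = 1.45  # m/s, the self-developed walking speed
#: sweep grid: 1.10, 1.27, 1.45, 1.80 m/s plus the
#: symmetric interpolant 1.62 completing five speeds
SWEEP_SPEEDS = (1.10, 1.27, 1.45, 1.62, 1.80)
WEAKNESS_MUSCLES = ("SOL", "GAS")
WEAKNESS_SCALES = (0.8, 0.6)


@dataclass
class ProtocolConfig:
    protocol: str = "self_selected"   # self_selected | speed_sweep | weakness
    horizon: float | None = None      # default: 20 s self-selected, else 10 s
    speeds: tuple = SWEEP_SPEEDS
    weakness_muscle: str = "SOL"
    mif_scale: float = 0.8
    seed_solution: str | None = None  # path to an OptResult JSON
    opt: OptConfig = field(default_factory=OptConfig)

    def __post_init__(self):
        if self.protocol not in ("self_selected", "speed_sweep", "weakness"):
            raise ValueError(f"unknown protocol: {self.protocol}")
        if self.horizon is None:
            self.horizon = 20.0 if self.protocol == "self_selected" else 10.0
        if self.protocol == "weakness":
            if self.weakness_muscle not in WEAKNESS_MUSCLES:
                raise ValueError("weakness protocol supports SOL or GAS")
            if self.mif_scale not in WEAKNESS_SCALES and self.mif_scale != 1.0:
                raise ValueError("mif_scale must be 0.8 or 0.6 (1.0 = baseline)")


def smoke_opt_config(seed: int = 0) -> OptConfig:
    """Desk-scale optimization budget for quick runs and CI."""
    return OptConfig(popsize=8, generations=30, horizon=4.0,
                     v_tgt=1.3, seed=seed)


@dataclass
class ProtocolResult:
    opt: OptResult
    trace: EpisodeTrace | None
    summary: GaitCycleSummary | None
    walking: bool
    settled_speed: float | None = None
    diagnostics: dict = field(default_factory=dict)


def _analyze_best(opt: OptResult, eval_cfg: EvalConfig) -> ProtocolResult:
    trace = rollout_candidate(opt.best_params, eval_cfg)
    cycles = segment_cycles(trace)
    walking = len(cycles) >= 2 and not trace.terminated_early
    summary = ensemble_stats(cycles) if cycles else None
    res = ProtocolResult(opt, trace, summary, walking)
    res.diagnostics = {
        "survival_s": float(trace.time[-1] - trace.time[0] + 0.01),
        "n_cycles": len(cycles),
        "terminated_early": trace.terminated_early,
    }
    if not walking:
        log.warning("best solution is not a stable gait (%d cycles, fell=%s)",
                    len(cycles), trace.terminated_early)
    return res


def run_self_selected(opt_cfg: OptConfig, horizon: float = 20.0,
                      callback=None) -> ProtocolResult:
    """Optimize without a velocity cost; report the settled speed over the
    steady portion (final half) of the best episode."""
    cfg = replace(opt_cfg, horizon=horizon, v_tgt=None)
    eval_cfg = EvalConfig(horizon=horizon, v_tgt=None)
    opt = optimize_walking(cfg, eval_cfg, callback=callback)
    res = _analyze_best(opt, eval_cfg)
    if res.trace is not None and res.trace.n_steps > 1:
        half = res.trace.n_steps // 2
        res.settled_speed = float(np.mean(res.trace.qdot[half:, 0]))
    return res


def run_speed_sweep(opt_cfg: OptConfig, speeds=SWEEP_SPEEDS,
                    anchor: float = ANCHOR_SPEED,
                    callback=None) -> dict[float, ProtocolResult]:
    """Anchor-first sweep with neighbor warm starts in both directions."""
    speeds = sorted(speeds)
    if anchor not in speeds:
        raise ValueError(f"speed list must include the anchor {anchor}")
    results: dict[float, ProtocolResult] = {}

    def solve(v_tgt, x0, provenance):
        cfg = replace(opt_cfg, v_tgt=v_tgt,
                      sigma0=opt_cfg.sigma0 if x0 is None else WARM_SIGMA0)
        eval_cfg = EvalConfig(horizon=cfg.horizon, v_tgt=v_tgt)
        opt = optimize_walking(cfg, eval_cfg, x0=x0,
                               seed_provenance=provenance, callback=callback)
        results[v_tgt] = _analyze_best(opt, eval_cfg)
        return opt

    anchor_opt = solve(anchor, None, "cold")
    ia = speeds.index(anchor)
    prev = anchor_opt
    for v in speeds[ia + 1:]:           # upward chain
        prev = solve(v, seed_from(prev), "warm")
    prev = anchor_opt
    for v in reversed(speeds[:ia]):     # downward chain
        prev = solve(v, seed_from(prev), "warm")
    return results


def run_weakness(muscle: str, mif_scale: float, seed_solution: OptResult,
                 opt_cfg: OptConfig, v_tgt: float = ANCHOR_SPEED,
                 callback=None) -> ProtocolResult:
    """Re-optimize with one muscle's MIF scaled bilaterally, warm-started
    from the normal-strength solution (no cold-start fallback)."""
    if seed_solution is None:
        raise ValueError("weakness protocol requires a seed solution")
    eval_cfg = EvalConfig(horizon=opt_cfg.horizon, v_tgt=v_tgt,
                          weakness_muscle=muscle if mif_scale != 1.0 else None,
                          mif_scale=mif_scale)
    cfg = replace(opt_cfg, v_tgt=v_tgt, sigma0=WARM_SIGMA0)
    opt = optimize_walking(cfg, eval_cfg, x0=seed_from(seed_solution),
                           seed_provenance=f"warm<-baseline@{v_tgt}",
                           callback=callback)
    res = _analyze_best(opt, eval_cfg)
    res.diagnostics["weakness_muscle"] = muscle
    res.diagnostics["mif_scale"] = mif_scale
    return res
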