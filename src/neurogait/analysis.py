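"""Gait-cycle analysis: segmentation, normalization, ensembles, correlation.

A gait cycle is the interval between successive initial contacts of the same
foot, detected from the vertical GRF (20 N threshold, 50 ms debounce, exact
in simulation).  Kinematics are resampled onto the conventional 101-point
0-100% gait-cycle grid; the vertical GRF is instead normalized to the stance
phase.  Ensembles report the pointwise mean +/- one sample standard
deviation across cycles.  Agreement with reference kinematics is quantified
by Pearson's correlation coefficient on the common grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import controller as ctl
from .environment import DT, EpisodeTrace, initial_contacts

log = logging.getLogger(__name__)

N_GRID = 101
PCT_GRID = np.linspace(0.0, 100.0, N_GRID)


@dataclass
class GaitCycle:
    start: int                      # control-step index of initial contact
    end: int                        # index of the next ipsilateral contact
    side: str
    toe_off_fraction: float | None  # % of cycle; None if never unloaded
    hip_deg: np.ndarray             # 101-point curves
    knee_deg: np.ndarray
    ankle_deg: np.ndarray
    stance_grf: np.ndarray          # 101 points over the stance phase
    mean_speed: float               # m/s over the cycle


@dataclass
class GaitCycleSummary:
    n_cycles: int
    mean: dict = field(default_factory=dict)   # signal -> 101-point curve
    sd: dict = field(default_factory=dict)
    mean_toe_off: float | None = None
    mean_speed: float | None = None


def normalize_cycle(signal: np.ndarray, start: int, end: int,
                    n_points: int = N_GRID) -> np.ndarray:
    """Linear-interpolation resampling of ``signal[start:end]`` onto
    0..100% of the cycle duration."""
    if end - start < 2:
        raise ValueError("cycle must span at least 2 samples")
    seg = np.asarray(signal[start:end + 1] if end < len(signal)
                     else signal[start:end], dtype=float)
    x = np.linspace(0.0, 1.0, len(seg))
    return np.interp(np.linspace(0.0, 1.0, n_points), x, seg)


def toe_off_fraction(grf_cycle: np.ndarray,
                     threshold: float = ctl.CONTACT_THRESHOLD) -> float | None:
    """% of the cycle at which the ipsilateral GRF falls below threshold
    without reloading for the remainder of the cycle; None if the foot never
    unloads (flagged by the caller)."""
    g = np.asarray(grf_cycle, dtype=float)
    below = g < threshold
    if not below.any():
        return None
    # last loaded->unloaded transition that is not followed by reloading
    idx = None
    loaded = g[0] >= threshold
    for i in range(1, len(g)):
        now_loaded = g[i] >= threshold
        if loaded and not now_loaded:
            idx = i
        loaded = now_loaded
    if idx is None:   # started unloaded and never loaded
        return None
    return 100.0 * idx / len(g)


def segment_cycles(trace: EpisodeTrace, side: str = "R",
                   dt: float = DT,
                   discard_first: bool = True) -> list[GaitCycle]:
    """Cycles bounded by successive ipsilateral initial contacts.

    The first cycle (startup transient) and any trailing partial cycle are
    discarded.  Fewer than two initial contacts yields an empty list.
    """
    col = 0 if side == "R" else 2
    grf = trace.grf[:, col]
    events = initial_contacts(grf, dt)
    if len(events) < 2:
        log.info("segment_cycles: fewer than 2 initial contacts on side %s", side)
        return []
    jnt = 0 if side == "R" else 3
    cycles = []
    for start, end in zip(events[:-1], events[1:]):
        if end - start < 10:
            continue
        to = toe_off_fraction(grf[start:end])
        hip = np.rad2deg(normalize_cycle(trace.q[:, 3 + jnt], start, end))
        knee = np.rad2deg(normalize_cycle(trace.q[:, 4 + jnt], start, end))
        ankle = np.rad2deg(normalize_cycle(trace.q[:, 5 + jnt], start, end))
        if to is not None:
            stance_end = start + max(2, int(round(to / 100.0 * (end - start))))
            stance = normalize_cycle(grf, start, stance_end)
        else:
            stance = normalize_cycle(grf, start, end)
        speed = float(np.mean(trace.qdot[start:end, 0]))
        cycles.append(GaitCycle(start, end, side, to, hip, knee, ankle,
                                stance, speed))
    if discard_first and cycles:
        cycles = cycles[1:]
    return cycles


def ensemble_stats(cycles: list[GaitCycle],
                   body_weight: float | None = None) -> GaitCycleSummary:
    """Pointwise mean and sample SD across cycles for each signal.

    With fewer than 2 cycles the SD is flagged unavailable (empty dict).
    ``body_weight`` (N) converts the stance GRF to body-weight units.
    """
    if not cycles:
        raise ValueError("ensemble_stats requires at least one cycle")
    summary = GaitCycleSummary(n_cycles=len(cycles))
    scale = 1.0 / body_weight if body_weight else 1.0
    signals = {
        "hip_deg": np.stack([c.hip_deg for c in cycles]),
        "knee_deg": np.stack([c.knee_deg for c in cycles]),
        "ankle_deg": np.stack([c.ankle_deg for c in cycles]),
        "stance_grf": np.stack([c.stance_grf for c in cycles]) * scale,
    }
    for name, arr in signals.items():
        summary.mean[name] = arr.mean(axis=0)
        if len(cycles) >= 2:
            summary.sd[name] = arr.std(axis=0, ddof=1)
    toffs = [c.toe_off_fraction for c in cycles if c.toe_off_fraction is not None]
    if toffs:
        summary.mean_toe_off = float(np.mean(toffs))
    summary.mean_speed = float(np.mean([c.mean_speed for c in cycles]))
    return summary


def correlate(sim_curve: np.ndarray, ref_curve: np.ndarray) -> float:
    """Pearson correlation coefficient between two curves on a common grid.

    Raises on zero-variance input rather than silently returning 0.
    """
    a = np.asarray(sim_curve, dtype=float)
    b = np.asarray(ref_curve, dtype=float)
    if a.shape != b.shape:
        raise ValueError("curves must share the sampling grid")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ValueError("correlation undefined for a zero-variance curve")
    return float(stats.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# reference kinematics interchange
# ---------------------------------------------------------------------------

REF_COLUMNS = ("percent_cycle", "hip_deg", "knee_deg", "ankle_deg")


def load_reference_kinematics(path) -> dict[str, np.ndarray]:
    """Read user-supplied reference joint kinematics.

    CSV columns: percent_cycle (0-100), hip_deg, knee_deg, ankle_deg;
    flexion/dorsiflexion positive.  Curves are resampled onto the 101-point
    grid.
    """
    df = pd.read_csv(path)
    missing = set(REF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV missing columns: {sorted(missing)}")
    pct = df["percent_cycle"].to_numpy(dtype=float)
    if pct.min() < 0 or pct.max() > 100:
        raise ValueError("percent_cycle must lie in [0, 100]")
    order = np.argsort(pct)
    out = {}
    for col in REF_COLUMNS[1:]:
        out[col] = np.interp(PCT_GRID, pct[order], df[col].to_numpy(dtype=float)[order])
    return out


def kinematic_correlations(summary: GaitCycleSummary,
                           reference: dict[str, np.ndarray]) -> dict[str, float]:
    """R values for hip, knee, ankle between ensemble means and reference."""
    return {joint: correlate(summary.mean[joint], reference[joint])
            for joint in ("hip_deg", "knee_deg", "ankle_deg")}


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def summary_to_files(summary: GaitCycleSummary, csv_path, json_path,
                     correlations: dict[str, float] | None = None) -> None:
    cols = {"percent_cycle": PCT_GRID}
    for name, curve in summary.mean.items():
        cols[f"{name}_mean"] = curve
    for name, curve in summary.sd.items():
        cols[f"{name}_sd"] = curve
    pd.DataFrame(cols).to_csv(csv_path, index=False)
    scalars = {
        "n_cycles": summary.n_cycles,
        "mean_toe_off_pct": summary.mean_toe_off,
        "mean_speed_m_s": summary.mean_speed,
    }
    if correlations:
        scalars["correlations"] = correlations
    with open(json_path, "w") as fh:
        json.dump(scalars, fh, indent=2)
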