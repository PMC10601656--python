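"""Configuration loading/validation, run manifests and result layout.

Configs are YAML (or JSON) with explicit SI units.  Unknown keys are
rejected; omitted keys take the shipped defaults, and the validated config
is echoed back fully populated.  Every run writes a manifest (config
snapshot + hash, master seed, package version) that suffices to reproduce it
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from . import __version__
from .environment import DT, FALL_HEIGHT, RewardWeights
from .muscle import MuscleSet, muscles_from_csv
from .optimize import OptConfig
from .skeleton import ContactConfig, SegmentParams, SkeletonConfig, SkeletonModel


class ConfigError(ValueError):
    pass


_MODEL_SECTIONS = {"segments", "joints", "contact", "gravity",
                   "muscle_table", "reward_weights"}


@dataclass
class ModelConfig:
    """Validated plant + reward description."""

    skeleton: SkeletonConfig = field(default_factory=SkeletonConfig)
    contact: ContactConfig = field(default_factory=ContactConfig)
    muscles: MuscleSet = field(default_factory=MuscleSet)
    reward_weights: RewardWeights = field(default_factory=RewardWeights)
    control_dt: float = DT
    fall_height: float = FALL_HEIGHT

    def build_skeleton(self) -> SkeletonModel:
        return SkeletonModel(self.skeleton, self.contact)


def _check_keys(section: dict, allowed: set, where: str):
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


def load_config(path) -> ModelConfig:
    """Load and validate a model configuration file (YAML or JSON)."""
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _MODEL_SECTIONS, "config")

    skeleton = SkeletonConfig()
    if "segments" in raw:
        segs = []
        for s in raw["segments"]:
            _check_keys(s, {"name", "mass", "length", "com_offset", "inertia"},
                        f"segment {s.get('name', '?')}")
            try:
                segs.append(SegmentParams(**{k: (v if k == "name" else float(v))
                                             for k, v in s.items()}))
            except (TypeError, ValueError) as err:
                raise ConfigError(f"segment (SI units expected): {err}") from err
        skeleton = dataclasses.replace(skeleton, segments=tuple(segs))
    if "joints" in raw:
        j = raw["joints"]
        _check_keys(j, {"limits_deg", "limit_stiffness", "limit_damping"}, "joints")
        kw = {}
        if "limits_deg" in j:
            import numpy as np
            kw["joint_limits"] = tuple(
                (float(np.deg2rad(lo)), float(np.deg2rad(hi)))
                for lo, hi in j["limits_deg"])
        if "limit_stiffness" in j:
            kw["joint_limit_stiffness"] = float(j["limit_stiffness"])
        if "limit_damping" in j:
            kw["joint_limit_damping"] = float(j["limit_damping"])
        skeleton = dataclasses.replace(skeleton, **kw)
    if "gravity" in raw:
        skeleton = dataclasses.replace(skeleton, gravity=float(raw["gravity"]))

    contact = ContactConfig()
    if "contact" in raw:
        c = raw["contact"]
        _check_keys(c, {"heel_offset", "toe_offset", "normal_stiffness",
                        "dissipation", "friction_mu", "friction_vel_smoothing"},
                    "contact")
        kw = {k: (tuple(float(x) for x in v) if k.endswith("offset") else float(v))
              for k, v in c.items()}
        try:
            contact = ContactConfig(**kw)
        except ValueError as err:
            raise ConfigError(f"contact: {err}") from err

    muscles = MuscleSet()
    if "muscle_table" in raw:
        table = raw["muscle_table"]
        if not os.path.isabs(table):
            table = os.path.join(os.path.dirname(os.path.abspath(path)), table)
        muscles = MuscleSet(muscles_from_csv(table))

    weights = RewardWeights()
    if "reward_weights" in raw:
        w = raw["reward_weights"]
        _check_keys(w, {"w_steps", "w_vel", "w_pel", "w_mul"}, "reward_weights")
        try:
            weights = RewardWeights(**{k: float(v) for k, v in w.items()})
        except ValueError as err:
            raise ConfigError(
                f"reward_weights (dimensionless, non-negative): {err}") from err

    return ModelConfig(skeleton, contact, muscles, weights)


def config_dict(cfg: ModelConfig) -> dict:
    """Echo a fully populated, JSON-serializable config snapshot."""
    return {
        "segments": [dataclasses.asdict(s) for s in cfg.skeleton.segments],
        "joints": {
            "limits_rad": [list(lim) for lim in cfg.skeleton.joint_limits],
            "limit_stiffness": cfg.skeleton.joint_limit_stiffness,
            "limit_damping": cfg.skeleton.joint_limit_damping,
        },
        "gravity": cfg.skeleton.gravity,
        "contact": {
            "heel_offset": list(cfg.contact.heel_offset),
            "toe_offset": list(cfg.contact.toe_offset),
            "normal_stiffness": cfg.contact.normal_stiffness,
            "dissipation": cfg.contact.dissipation,
            "friction_mu": cfg.contact.friction_mu,
            "friction_vel_smoothing": cfg.contact.friction_vel_smoothing,
        },
        "muscles": {name: {"MIF": float(cfg.muscles.mif[i]),
                           "l_opt": float(cfg.muscles.l_opt[i]),
                           "l_slack": float(cfg.muscles.l_slack[i]),
                           "l_ref": float(cfg.muscles.l_ref[i])}
                    for i, name in enumerate(cfg.muscles.names)},
        "reward_weights": dataclasses.asdict(cfg.reward_weights),
        "control_dt": cfg.control_dt,
        "fall_height": cfg.fall_height,
    }


def config_hash(cfg: ModelConfig) -> str:
    blob = json.dumps(config_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_snapshot: dict
    config_hash: str
    master_seed: int
    version: str = __version__
    outputs: dict = field(default_factory=dict)
    status: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def create(cls, cfg: ModelConfig, seed: int) -> "RunManifest":
        return cls(config_dict(cfg), config_hash(cfg), seed)


def write_results(out_dir, manifest: RunManifest, *,
                  opt_result=None, trace=None, summary=None,
                  params=None, extra_summary: dict | None = None) -> dict:
    """Deterministic file layout; atomic overwrite on re-run."""
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")
    paths = {}

    def _atomic(name, writer):
        final = os.path.join(out_dir, name)
        tmp = final + ".tmp"
        writer(tmp)
        os.replace(tmp, final)
        paths[name] = final

    if params is not None:
        from .controller import save_params_json
        _atomic("params.json", lambda p: save_params_json(params, p))
    if opt_result is not None:
        _atomic("optimization.json", opt_result.to_json)
    if trace is not None:
        from .environment import save_trace
        _atomic("trace.csv", lambda p: save_trace(trace, p))
        _atomic("trace_meta.json", lambda p: save_trace(trace, os.devnull, p))
    if summary is not None:
        from .analysis import summary_to_files
        tmp_json = os.path.join(out_dir, "summary.json.tmp")

        def _write_summary(p):
            summary_to_files(summary, p, tmp_json)
        _atomic("cycles.csv", _write_summary)
        with open(tmp_json) as fh:
            scalars = json.load(fh)
        os.remove(tmp_json)
        if extra_summary:
            scalars.update(extra_summary)
        _atomic("summary.json",
                lambda p: json.dump(scalars, open(p, "w"), indent=2))
    elif extra_summary is not None:
        _atomic("summary.json",
                lambda p: json.dump(extra_summary, open(p, "w"), indent=2))
    manifest.outputs = {k: os.path.basename(v) for k, v in paths.items()}
    _atomic("manifest.json", manifest.save)
    return paths
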