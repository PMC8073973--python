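"""Scenario configuration, end-to-end runs and in-silico sweeps over enzyme
loading, biomass loading and particle radius."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import __version__
from .fixtures import generate_synthetic_substrate
from .observables import compute_result
from .params import KineticTransportParams
from .solver import DEFAULT_RTOL, DEFAULT_T_END_MIN, default_output_times, simulate
from .substrate import SubstrateSpec, load_substrate_spec


@dataclass
class ScenarioConfig:
    """One runnable scenario, or a sweep when the axes hold several values.

    ``substrate`` may be a SubstrateSpec, a path to a YAML/JSON spec file,
    or an archetype name (native/mild/severe/ds2_beech) resolved through the
    synthetic generator with ``seed``.
    """

    substrate: Union[SubstrateSpec, str, Path]
    e_l: Sequence[float] = (1.0,)
    b_l: Sequence[float] = (0.02,)
    radius_cm: Optional[Sequence[float]] = None  # None: use the substrate's own radius
    times_min: Optional[Sequence[float]] = None
    t_end_min: float = DEFAULT_T_END_MIN
    n: int = 50
    rtol: float = DEFAULT_RTOL
    param_overrides: dict = field(default_factory=dict)
    output_dir: Optional[Union[str, Path]] = None
    seed: int = 0
    label: str = "scenario"

    def __post_init__(self) -> None:
        for axis in (self.e_l, self.b_l):
            if len(list(axis)) == 0:
                raise ValueError("sweep axes must be non-empty")
        if self.radius_cm is not None and len(list(self.radius_cm)) == 0:
            raise ValueError("radius axis must be non-empty when given")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ScenarioConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def resolve_substrate(self) -> SubstrateSpec:
        sub = self.substrate
        if isinstance(sub, SubstrateSpec):
            return sub
        sub = str(sub)
        if sub in ("native", "mild", "severe", "ds2_beech"):
            return generate_synthetic_substrate(seed=self.seed, archetype=sub)
        if not Path(sub).exists():
            raise FileNotFoundError(f"substrate spec file not found: {sub}")
        return load_substrate_spec(sub)

    def resolve_params(self) -> KineticTransportParams:
        return dataclasses.replace(KineticTransportParams(), **self.param_overrides)

    def manifest(self, extra: Optional[dict] = None) -> dict:
        spec = self.resolve_substrate()
        data = {
            "lignosim_version": __version__,
            "label": self.label,
            "substrate": spec.to_dict(),
            "params": self.resolve_params().to_dict(),
            "e_l": list(self.e_l),
            "b_l": list(self.b_l),
            "radius_cm": list(self.radius_cm) if self.radius_cm is not None else None,
            "t_end_min": self.t_end_min,
            "n": self.n,
            "rtol": self.rtol,
            "seed": self.seed,
        }
        if extra:
            data.update(extra)
        return data


def run_scenario(config: ScenarioConfig):
    """Run a single-point scenario end to end and (optionally) write the
    trajectory CSV, observables CSV and a JSON manifest.

    Returns (HydrolysisResult, RadialTrajectory, manifest dict).  Output
    files are deterministic for identical configs (no timestamps).
    """
    if len(list(config.e_l)) != 1 or len(list(config.b_l)) != 1 or (
        config.radius_cm is not None and len(list(config.radius_cm)) != 1
    ):
        raise ValueError("run_scenario needs single-point axes; use sweep() instead")
    spec = config.resolve_substrate()
    if config.radius_cm is not None:
        spec = dataclasses.replace(spec, radius_cm=float(list(config.radius_cm)[0]))
    params = config.resolve_params()
    times = (
        np.concatenate([[0.0], np.sort(np.asarray(config.times_min, dtype=float))])
        if config.times_min is not None
        else default_output_times(config.t_end_min)
    )
    traj = simulate(
        spec, params,
        e_l=float(list(config.e_l)[0]), b_l=float(list(config.b_l)[0]),
        n=config.n, output_times=times, rtol=config.rtol,
    )
    result = compute_result(traj)
    manifest = config.manifest(
        extra={
            "conditions": traj.conditions.to_dict(),
            "derived": traj.derived.to_dict(),
            "diagnostics": traj.diagnostics,
        }
    )
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        traj.to_frame().to_csv(outdir / f"{config.label}_trajectory.csv", index=False)
        result.to_frame().to_csv(outdir / f"{config.label}_results.csv", index=False)
        (outdir / f"{config.label}_manifest.json").write_text(
            json.dumps(manifest, indent=2, default=float)
        )
    return result, traj, manifest


def sweep(config: ScenarioConfig):
    """Cross the (e_l, b_l, radius) axes, run each cell, and return a
    long-format table with one row per (cell, output time).

    Per-cell failures are recorded in the ``status`` column and the sweep
    continues.
    """
    import pandas as pd

    spec0 = config.resolve_substrate()
    params = config.resolve_params()
    radii = list(config.radius_cm) if config.radius_cm is not None else [spec0.radius_cm]
    times = (
        np.concatenate([[0.0], np.sort(np.asarray(config.times_min, dtype=float))])
        if config.times_min is not None
        else default_output_times(config.t_end_min)
    )
    rows = []
    for r in radii:
        spec = dataclasses.replace(spec0, radius_cm=float(r))
        for e_l in config.e_l:
            for b_l in config.b_l:
                try:
                    traj = simulate(
                        spec, params, e_l=float(e_l), b_l=float(b_l),
                        n=config.n, output_times=times, rtol=config.rtol,
                    )
                    res = compute_result(traj)
                    for k, t in enumerate(res.times):
                        rows.append(
                            {
                                "e_l": float(e_l), "b_l": float(b_l), "radius_cm": float(r),
                                "time_min": float(t),
                                "yield_fraction": float(res.yield_fraction[k]),
                                "titer_g_per_L": float(res.titer_g_per_l[k]),
                                "mean_coverage": float(res.mean_coverage[k]),
                                "bulk_fraction": float(res.bulk_fraction[k]),
                                "status": "ok",
                            }
                        )
                except Exception as exc:
                    rows.append(
                        {
                            "e_l": float(e_l), "b_l": float(b_l), "radius_cm": float(r),
                            "time_min": np.nan, "yield_fraction": np.nan,
                            "titer_g_per_L": np.nan, "mean_coverage": np.nan,
                            "bulk_fraction": np.nan, "status": f"error: {exc}",
                        }
                    )
    df = pd.DataFrame(rows)
    if config.output_dir is not None:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        df.to_csv(outdir / f"{config.label}_sweep.csv", index=False)
        (outdir / f"{config.label}_sweep_manifest.json").write_text(
            json.dumps(config.manifest(), indent=2, default=float)
        )
    return df
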