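"""Configured end-to-end runs: phantom → traits → palisade → vaporsheds → RC.

A run is described by a single validated :class:`RunConfig` (YAML on
disk); all randomness flows from its one seed, so the same config run
twice produces byte-identical CSV outputs.  Each stage writes a
self-describing CSV (units in header comments) into the run directory,
together with a config snapshot and a log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import decomposition, palisade, tissue_traits, vaporshed
from .phantom import PhantomSpec, generate_leaf_phantom, generate_slab_phantom
from .stack_io import DEFAULT_LEGEND, LabelLegend, read_stack, write_stack

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("leafvox")


class PhantomConfig(BaseModel):
    kind: Literal["slab", "leaf"] = "leaf"
    voxel_size_um: float = 1.0
    leaf_thickness_um: float = 200.0
    epidermis_thickness_um: float = 15.0
    palisade_fraction: float = 0.5
    palisade_radius_top_um: float = 6.0
    palisade_radius_bottom_um: float = 9.0
    palisade_pitch_um: float = 20.0
    spongy_target_porosity: float = 0.30
    stoma_pitch_um: float = 60.0
    stoma_radius_um: float = 4.0
    lateral_extent_um: tuple[float, float] = (120.0, 120.0)

    def to_spec(self, seed: int, legend: LabelLegend) -> PhantomSpec:
        params = self.model_dump(exclude={"kind"})
        return PhantomSpec(**params, rng_seed=seed, legend=legend)


class DecompositionConfig(BaseModel):
    traits_csv: Optional[str] = None
    factor_columns: list[str] = ["Sm_Vcl", "one_minus_theta", "f_mes", "L_eff_leaf"]
    group_columns: list[str] = ["cultivar", "treatment"]
    reference_level: str = "shade"
    treatment_column: str = "treatment"


class RunConfig(BaseModel):
    """Schema-validated configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    legend: dict[str, int] = Field(default_factory=lambda: DEFAULT_LEGEND.as_dict())
    voxel_size_um: float = 1.0
    input_stack: Optional[str] = None
    phantom: Optional[PhantomConfig] = None
    marching_step: int = 2
    watershed_h: float = 2.0
    palisade_bounds: Optional[tuple[int, int]] = None
    g_ias: dict[str, float] = Field(
        default_factory=lambda: {
            "D_c_m2_s": 1.54e-5,
            "temperature_K": 298.15,
            "pressure_Pa": 101325.0,
        }
    )
    decomposition: Optional[DecompositionConfig] = None

    @field_validator("legend")
    @classmethod
    def _legend_complete(cls, v: dict[str, int]) -> dict[str, int]:
        LabelLegend.from_dict(v)  # raises on missing roles / bad labels
        return v

    @field_validator("marching_step")
    @classmethod
    def _step_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("marching_step must be >= 1")
        return v

    @field_validator("voxel_size_um")
    @classmethod
    def _voxel_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("voxel_size_um must be positive")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.model_validate(payload)


def _write_csv(df: pd.DataFrame, path: Path, units: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {units}\n")
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    (out / "config.yaml").write_text(
        yaml.safe_dump(json.loads(config.model_dump_json()), sort_keys=True)
    )
    legend = LabelLegend.from_dict(config.legend)

    stage = "input"
    try:
        truth = None
        if config.phantom is not None:
            stage = "phantom"
            spec = config.phantom.to_spec(config.seed, legend)
            gen = (
                generate_slab_phantom
                if config.phantom.kind == "slab"
                else generate_leaf_phantom
            )
            stack, truth = gen(spec)
            write_stack(stack, out / "phantom.tiff")
            logger.info("phantom generated: %s, %d stomata", spec, truth.stoma_count)
        elif config.input_stack is not None:
            stage = "read"
            stack = read_stack(
                config.input_stack, legend=legend, voxel_size_um=config.voxel_size_um
            )
            from .stack_io import canonicalize

            stack = canonicalize(stack)
        else:
            raise ValueError("config must provide either a phantom or an input_stack")

        stage = "tissue_traits"
        table = tissue_traits.compute_trait_table(stack, step=config.marching_step)
        traits_df = pd.DataFrame([table.as_dict()])
        _write_csv(
            traits_df,
            out / "traits.csv",
            "lengths um; areas um2; volumes um3; ratios dimensionless",
        )
        logger.info("traits: Sm_LA=%.4f theta=%.4f", table.Sm_LA, table.theta_ias)

        if truth is not None:
            stage = "truth_report"
            report = pd.DataFrame(
                [
                    {
                        "quantity": "theta_ias",
                        "measured": table.theta_ias,
                        "ground_truth": truth.theta_ias,
                    },
                    {
                        "quantity": "f_mes",
                        "measured": table.f_mes,
                        "ground_truth": truth.f_mes,
                    },
                    {
                        "quantity": "L_leaf_um",
                        "measured": table.L_leaf,
                        "ground_truth": truth.thickness_um["leaf"],
                    },
                    {
                        "quantity": "V_ias_um3",
                        "measured": table.V_ias,
                        "ground_truth": truth.volumes_um3["airspace"],
                    },
                ]
            )
            _write_csv(report, out / "truth_report.csv", "measured vs ground truth")

        stage = "palisade"
        bounds = config.palisade_bounds
        if bounds is None and truth is not None and truth.palisade_bounds is not None:
            bounds = truth.palisade_bounds
        cells_path = out / "cells.csv"
        if config.phantom is None or config.phantom.kind == "leaf":
            summary = palisade.palisade_summary(
                stack, bounds=bounds, h=config.watershed_h
            )
            rows = [
                {"slice": name, "diameter_um": d}
                for name, ds in summary.diameters_um.items()
                for d in ds
            ]
            _write_csv(pd.DataFrame(rows), cells_path, "equivalent diameters um")
            _write_csv(
                pd.DataFrame(
                    [
                        {
                            "r_top_um": summary.r_top_um,
                            "r_mid_um": summary.r_mid_um,
                            "r_bot_um": summary.r_bot_um,
                            "D_pal_per_mm2": summary.D_pal_per_mm2,
                            "V_pal_um3": summary.V_pal_um3,
                            "S_pal_um2": summary.S_pal_um2,
                            "S_over_V_per_um": summary.S_over_V_per_um,
                        }
                    ]
                ),
                out / "palisade_summary.csv",
                "radii um; density mm-2; volume um3; area um2",
            )

        stage = "vaporshed"
        field, sites, _ = vaporshed.assign_vaporsheds(stack)
        vtable = vaporshed.vaporshed_traits(stack, field, step=config.marching_step)
        vdf = pd.DataFrame([dataclasses.asdict(r) for r in vtable.rows])
        vdf["median_tau"] = vtable.median_tau
        vdf["median_lambda"] = vtable.median_lambda
        _write_csv(vdf, out / "vaporsheds.csv", "volumes um3; areas um2")
        field_stack = stack.copy_with(
            volume=np.where(field > 0, field, 0).astype(np.uint16),
            legend=legend,
        )
        # vaporshed id field bypasses legend validation on write
        import tifffile

        tifffile.imwrite(out / "vaporsheds.tiff", field_stack.volume)
        logger.info(
            "vaporsheds: %d stomata, median tau %.3f lambda %.3f",
            len(sites),
            vtable.median_tau,
            vtable.median_lambda,
        )

        stage = "decomposition"
        if config.decomposition is not None and config.decomposition.traits_csv:
            dc = config.decomposition
            df = pd.read_csv(dc.traits_csv, comment="#")
            cells = decomposition.group_mean_logs(
                df, dc.factor_columns, dc.group_columns
            )
            rc_rows = []
            tcol = dc.treatment_column
            t_idx = dc.group_columns.index(tcol)
            other_keys = sorted(
                {k[:t_idx] + k[t_idx + 1 :] for k in cells}
            )
            for other in other_keys:
                pair = {
                    k[t_idx]: fs
                    for k, fs in cells.items()
                    if k[:t_idx] + k[t_idx + 1 :] == other
                }
                if dc.reference_level not in pair or len(pair) != 2:
                    continue
                ref = pair.pop(dc.reference_level)
                (level, treat), = pair.items()
                result = decomposition.multiplicative_rc(ref, treat)
                for name, rc in result.rc.items():
                    rc_rows.append(
                        {
                            "group": "/".join(map(str, other)),
                            "contrast": f"{level} vs {dc.reference_level}",
                            "factor": name,
                            "RC": rc,
                            "relative_contribution_pct": 100.0 * rc,
                            "rc_sum": result.rc_sum,
                        }
                    )
            _write_csv(
                pd.DataFrame(rc_rows), out / "rc.csv", "response coefficients"
            )
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
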