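"""End-to-end study pipeline: tables in, audited report bundle out.

A :class:`StudyConfig` is a single validated document (JSON or YAML via the
CLI) naming the factors with their studied ranges, the responses, the model
stage (first-order screening or full quadratic response surface), the
elimination rule, the acceptance criteria, the evaluation grid and the
Monte-Carlo settings — with one top-level seed feeding every stochastic
stage.  :func:`run_pipeline` fits all responses, writes diagnostics in the
familiar per-response table layout, overlays the sweet spot, maps the MODR
and summarises the optimum for each elution-order branch.  The bundle is
deterministic: rerunning with the same config and tables reproduces it
byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .criteria import Criterion, CriterionSet, GridSpec, contour_slices, sweet_spot_map
from .design import DesignMatrix, FactorSpec
from .diagnostics import diagnostics_table
from .model import fit_responses
from .modr import EmptyModrError, McSettings, find_optimum, modr_map
from .terms import ModelSpec

__all__ = ["StudyConfig", "run_pipeline", "validate_tables"]


class FactorConfig(BaseModel):
    name: str
    low: float
    high: float
    units: str = ""

    def to_spec(self) -> FactorSpec:
        return FactorSpec(self.name, self.low, self.high, self.units)


class CriterionConfig(BaseModel):
    direction: Literal["nmt", "nlt", "branched"]
    threshold: float
    neg_threshold: float | None = None

    def to_criterion(self) -> Criterion:
        return Criterion(self.direction, self.threshold, self.neg_threshold)


class GridConfig(BaseModel):
    free: dict[str, tuple[float, float, int]]
    fixed: dict[str, float] = Field(default_factory=dict)

    def to_grid(self) -> GridSpec:
        return GridSpec(dict(self.free), dict(self.fixed))


class McConfig(BaseModel):
    n_draws: int = 10000
    threshold: float = 0.99
    coefficient_uncertainty: bool = True
    observation_noise: bool = True
    jitter: dict[str, float] | None = None
    jitter_dist: Literal["uniform", "normal"] = "uniform"
    mode: Literal["joint", "per_cma"] = "joint"


class StudyConfig(BaseModel):
    """Complete, self-contained description of one study analysis."""

    factors: list[FactorConfig]
    responses: list[str]
    model: Literal["linear", "quadratic"] = "linear"
    eliminate_alpha: float | None = None
    preserve_hierarchy: bool = True
    criteria: dict[str, CriterionConfig]
    grid: GridConfig | None = None
    mc: McConfig = Field(default_factory=McConfig)
    seed: int

    @model_validator(mode="after")
    def _cross_checks(self):
        names = [f.name for f in self.factors]
        if len(set(names)) != len(names):
            raise ValueError("duplicate factor names")
        unknown = set(self.criteria) - set(self.responses)
        if unknown:
            raise ValueError(f"criteria reference unknown response(s): {sorted(unknown)}")
        if self.grid is not None:
            covered = set(self.grid.free) | set(self.grid.fixed)
            if covered != set(names):
                raise ValueError(
                    f"grid covers {sorted(covered)}, factors are {sorted(names)}"
                )
        return self

    def factor_specs(self) -> list[FactorSpec]:
        return [f.to_spec() for f in self.factors]

    def criterion_set(self) -> CriterionSet:
        return CriterionSet({k: c.to_criterion() for k, c in self.criteria.items()})

    def model_spec(self) -> ModelSpec:
        names = [f.name for f in self.factors]
        if self.model == "linear":
            return ModelSpec.linear(names)
        return ModelSpec.full_quadratic(names)


def validate_tables(
    design_csv, response_csv, config: StudyConfig
) -> list[dict]:
    """Schema/consistency findings for a design + response table pair.

    Returns a list of finding records (empty = clean): missing columns,
    non-numeric cells, duplicate or misaligned run ids, out-of-range
    factor values.
    """
    findings: list[dict] = []

    def add(kind, **ctx):
        findings.append({"kind": kind, **ctx})

    design = pd.read_csv(design_csv)
    resp = pd.read_csv(response_csv)
    for df, which, cols in (
        (design, "design", ["run_id"] + [f.name for f in config.factors]),
        (resp, "response", ["run_id"] + list(config.responses)),
    ):
        for c in cols:
            if c not in df.columns:
                add("missing_column", table=which, column=c)
        if "run_id" in df.columns and df["run_id"].duplicated().any():
            dups = df["run_id"][df["run_id"].duplicated()].tolist()
            add("duplicate_run_id", table=which, run_ids=dups)
        for c in df.columns:
            if c == "run_id" or c not in cols:
                continue
            bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
            if bad.any():
                add("non_numeric", table=which, column=c,
                    rows=df.index[bad].tolist())
    if "run_id" in design.columns and "run_id" in resp.columns:
        d_ids, r_ids = set(design["run_id"]), set(resp["run_id"])
        for rid in sorted(d_ids - r_ids):
            add("missing_response_row", run_id=rid)
        for rid in sorted(r_ids - d_ids):
            add("missing_design_row", run_id=rid)
    for f in config.factors:
        if f.name in design.columns:
            vals = pd.to_numeric(design[f.name], errors="coerce")
            out = (vals < f.low) | (vals > f.high)
            if out.any():
                rows = design.loc[out, "run_id"].tolist() if "run_id" in design \
                    else design.index[out].tolist()
                add("out_of_range", column=f.name, run_ids=rows,
                    range=[f.low, f.high])
    return findings


def run_pipeline(
    config: StudyConfig, design_csv, response_csv, outdir
) -> dict:
    """Run fit → diagnostics → sweet spot → MODR → optima; write the bundle.

    Returns a manifest dict of the artefacts written.  Exits early (raising
    ``ValueError``) if the tables fail validation.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    findings = validate_tables(design_csv, response_csv, config)
    if findings:
        raise ValueError(f"table validation failed: {findings}")

    factors = config.factor_specs()
    design_df = pd.read_csv(design_csv).set_index("run_id")
    resp_df = pd.read_csv(response_csv).set_index("run_id")
    resp_df = resp_df.loc[design_df.index, config.responses]
    design = DesignMatrix.from_natural(
        design_df[[f.name for f in factors]], factors
    )

    fits = fit_responses(
        resp_df,
        design,
        config.model_spec(),
        eliminate_alpha=config.eliminate_alpha,
        preserve_hierarchy=config.preserve_hierarchy,
    )
    manifest: dict = {"version": __version__, "seed": config.seed, "artifacts": []}

    reports = {name: res.to_report() for name, res in fits.items()}
    _write_json(out / "fits.json", reports)
    manifest["artifacts"].append("fits.json")

    diagnostics_table(fits).to_csv(out / "diagnostics.csv")
    manifest["artifacts"].append("diagnostics.csv")

    if config.grid is not None:
        criteria = config.criterion_set()
        grid = config.grid.to_grid()
        ss = sweet_spot_map(fits, grid, criteria)
        ss.to_csv(out / "sweetspot.csv")
        manifest["artifacts"].append("sweetspot.csv")
        if len(grid.free) == 2:
            contour_slices(ss).to_csv(out / "sweetspot_classes.csv", index=False)
            manifest["artifacts"].append("sweetspot_classes.csv")

        settings = McSettings(seed=config.seed, **config.mc.model_dump())
        mm = modr_map(fits, grid, criteria, settings)
        mm.to_csv(out / "modr.csv")
        manifest["artifacts"].append("modr.csv")

        for branch in ("positive", "negative"):
            try:
                opt = find_optimum(mm, fits, branch=branch)
            except EmptyModrError as exc:
                _write_json(out / f"optimum_{branch}.json", {"empty": str(exc)})
            else:
                _write_json(out / f"optimum_{branch}.json", opt.to_json_obj())
            manifest["artifacts"].append(f"optimum_{branch}.json")

    _write_json(out / "config.json", config.model_dump(mode="json"))
    manifest["artifacts"].append("config.json")
    _write_json(out / "manifest.json", manifest)
    return manifest


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
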