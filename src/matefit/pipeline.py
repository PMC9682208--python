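"""End-to-end analysis pipeline.

Runs every stage on a validated dataset and writes plain-CSV result tables
plus a JSON manifest:

* ``selection_coefficients.csv`` — per (flour, treatment): s per sex with
  bootstrap CIs, the sex difference and its permutation p (focal-only assay);
* ``opportunity.csv``            — per (sex, flour, yeast): I with CI
  (whole-group assay);
* ``decomposition.csv``          — per male cell: variance/covariance terms
  (emitted both raw and doubled for covariances) with CIs;
* ``glm_contrasts.csv``          — Gaussian body-mass and quasi-Poisson
  offspring / mating-success contrast tables, BH-adjusted within each
  (response, flour, sex) family, plus sex-by-treatment interaction rows;
* ``mortality.csv``              — per flour: female died/survived counts by
  treatment and the (Yates-corrected) chi-squared test;
* ``run_manifest.json``          — seed, config hash, versions, warnings.

Deterministic given (config, seed): every analysis cell draws from its own
labelled substream of the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    CONTROL_YEAST,
    Dataset,
    read_fitness_table,
)
from .decomposition import TERM_NAMES, decompose
from .errors import (
    CapabilityError,
    DegenerateGroupError,
    DesignError,
    InsufficientDataError,
    MatefitError,
    StageError,
)
from .inference import bh_adjust, chisq_mortality, fit_interaction_glm, fit_treatment_glm
from .resampling import spawn_seed
from .selection import (
    estimate_opportunity,
    estimate_selection,
    relativize,
    sex_difference_in_s,
)
from .simulate import SimulationParams, simulate_both_assays

log = logging.getLogger("matefit")

_SKIPPABLE = (InsufficientDataError, DegenerateGroupError, DesignError)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (exactly one of input/simulate)."""

    input: str | Path | None = None
    simulate: bool = False
    sim_params: SimulationParams | None = None
    seed: int = 0
    n_boot: int = 10_000
    n_perm: int = 10_000
    ci_level: float = 0.95
    decomposition: bool = True
    paternity_share: str = "pooled"
    exclude_dead: bool = False
    strict: bool = True
    out_dir: str | Path = "results"

    def validate(self) -> None:
        if bool(self.input) == bool(self.simulate):
            raise ValueError("exactly one of input path or simulate must be set")
        if self.n_boot < 0 or self.n_perm < 0:
            raise ValueError("resample counts must be nonnegative")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload["input"] = str(payload["input"]) if payload["input"] else None
        payload.pop("out_dir", None)  # location must not change the hash
        if payload.get("sim_params") is not None:
            sp = payload["sim_params"]
            for key in ("mu", "p_mate", "mortality", "body_mass"):
                sp[key] = {"|".join(map(str, k)): v for k, v in sorted(sp[key].items())}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class RunResult:
    """Outputs of one pipeline run."""

    out_dir: Path
    tables: dict[str, pd.DataFrame]
    manifest: dict[str, Any]
    warnings: list[str] = field(default_factory=list)


def _flour_yeasts(dataset: Dataset) -> dict[str, list[str]]:
    """Observed yeast levels per flour, control first."""
    order = {"control_5pct": 0, "low_1pct": 1, "none": 2}
    out: dict[str, list[str]] = {}
    for r in dataset:
        out.setdefault(r.flour, [])
        if r.yeast not in out[r.flour]:
            out[r.flour].append(r.yeast)
    return {f: sorted(ys, key=lambda y: order.get(y, 9)) for f, ys in sorted(out.items())}


def _selection_stage(dataset: Dataset, cfg: RunConfig, warnings: list[str]) -> pd.DataFrame:
    rows = []
    assay = "focal_only"
    for flour, yeasts in _flour_yeasts(dataset).items():
        for yeast in yeasts:
            if yeast == CONTROL_YEAST:
                continue
            row: dict[str, Any] = {"assay": assay, "flour": flour, "treatment": yeast}
            try:
                for sex in ("male", "female"):
                    est = estimate_selection(
                        dataset,
                        assay,
                        sex,
                        flour,
                        yeast,
                        n_boot=cfg.n_boot,
                        level=cfg.ci_level,
                        seed=spawn_seed(cfg.seed, "s", assay, flour, yeast, sex),
                        exclude_dead=cfg.exclude_dead,
                    )
                    row.update(
                        {
                            f"s_{sex}": est.s_point,
                            f"s_{sex}_boot_mean": est.s_boot_mean,
                            f"s_{sex}_ci_low": est.ci_low,
                            f"s_{sex}_ci_high": est.ci_high,
                            f"n_control_{sex}": est.n_control,
                            f"n_stressed_{sex}": est.n_stressed,
                        }
                    )
                    if est.warning:
                        warnings.append(f"selection {flour}/{yeast}/{sex}: {est.warning}")
                diff = sex_difference_in_s(
                    dataset,
                    assay,
                    flour,
                    yeast,
                    n_boot=cfg.n_boot,
                    n_perm=cfg.n_perm,
                    level=cfg.ci_level,
                    seed=spawn_seed(cfg.seed, "sdiff", assay, flour, yeast),
                    exclude_dead=cfg.exclude_dead,
                )
                row.update(
                    {
                        "sex_difference": diff.delta,
                        "sex_difference_ci_low": diff.ci_low,
                        "sex_difference_ci_high": diff.ci_high,
                        "sex_difference_p_perm": diff.p_value,
                    }
                )
            except _SKIPPABLE as exc:
                warnings.append(f"selection {flour}/{yeast} skipped: {exc}")
                continue
            rows.append(row)
    return pd.DataFrame(rows)


def _opportunity_stage(dataset: Dataset, cfg: RunConfig, warnings: list[str]) -> pd.DataFrame:
    rows = []
    assay = "whole_group"
    for flour, yeasts in _flour_yeasts(dataset).items():
        for yeast in yeasts:
            for sex in ("male", "female"):
                try:
                    est = estimate_opportunity(
                        dataset,
                        assay,
                        sex,
                        flour,
                        yeast,
                        n_boot=cfg.n_boot,
                        level=cfg.ci_level,
                        seed=spawn_seed(cfg.seed, "I", assay, flour, yeast, sex),
                        exclude_dead=cfg.exclude_dead,
                    )
                except _SKIPPABLE as exc:
                    warnings.append(f"opportunity {flour}/{yeast}/{sex} skipped: {exc}")
                    continue
                rows.append(
                    {
                        "assay": assay,
                        "flour": flour,
                        "yeast": yeast,
                        "sex": sex,
                        "n": est.n,
                        "I": est.i_point,
                        "I_boot_mean": est.i_boot_mean,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                    }
                )
                if est.warning:
                    warnings.append(f"opportunity {flour}/{yeast}/{sex}: {est.warning}")
    return pd.DataFrame(rows)


def _decomposition_stage(dataset: Dataset, cfg: RunConfig, warnings: list[str]) -> pd.DataFrame:
    rows = []
    assay = "whole_group"
    for flour, yeasts in _flour_yeasts(dataset).items():
        for yeast in yeasts:
            males = dataset.select(assay=assay, sex="male", flour=flour, yeast=yeast)
            if not males:
                continue
            try:
                res = decompose(
                    males,
                    n_boot=cfg.n_boot,
                    level=cfg.ci_level,
                    seed=spawn_seed(cfg.seed, "decomp", assay, flour, yeast),
                    paternity_share=cfg.paternity_share,
                )
            except _SKIPPABLE as exc:
                warnings.append(f"decomposition {flour}/{yeast} skipped: {exc}")
                continue
            for term in TERM_NAMES:
                rows.append(
                    {
                        "assay": assay,
                        "flour": flour,
                        "yeast": yeast,
                        "term": term,
                        "point": res.terms[term],
                        "boot_mean": res.boot_mean[term] if res.boot_mean else None,
                        "ci_low": res.ci_low[term] if res.ci_low else None,
                        "ci_high": res.ci_high[term] if res.ci_high else None,
                        "n": res.n,
                    }
                )
                if term.startswith("cov_"):
                    # covariance contributions enter I_total doubled; emit both
                    rows.append(
                        {
                            "assay": assay,
                            "flour": flour,
                            "yeast": yeast,
                            "term": f"2x{term}",
                            "point": 2.0 * res.terms[term],
                            "boot_mean": 2.0 * res.boot_mean[term] if res.boot_mean else None,
                            "ci_low": 2.0 * res.ci_low[term] if res.ci_low else None,
                            "ci_high": 2.0 * res.ci_high[term] if res.ci_high else None,
                            "n": res.n,
                        }
                    )
            if res.warning:
                warnings.append(f"decomposition {flour}/{yeast}: {res.warning}")
    return pd.DataFrame(rows)


def _glm_stage(dataset: Dataset, cfg: RunConfig, warnings: list[str]) -> pd.DataFrame:
    frame = dataset.to_frame()
    if cfg.exclude_dead:
        frame = frame[frame["survived"]]
    rows: list[dict[str, Any]] = []

    def add_table(sub: pd.DataFrame, response: str, family: str, flour: str, sex: str, assay: str):
        try:
            fit = fit_treatment_glm(sub, response, family, factor="yeast")
        except _SKIPPABLE as exc:
            warnings.append(f"glm {response}/{flour}/{sex} skipped: {exc}")
            return
        for _, r in fit.table.iterrows():
            rows.append(
                {
                    "response": response,
                    "family": family,
                    "assay": assay,
                    "flour": flour,
                    "sex": sex,
                    "contrast": r["contrast"],
                    "estimate": r["estimate"],
                    "se": r["se"],
                    "t": r["t"],
                    "p_raw": r["p_raw"],
                    "p_adj": r["p_adj"],
                    "df_resid": fit.df_resid,
                    "f_value": fit.f_value,
                    "f_p": fit.f_p,
                    "n": fit.n,
                }
            )

    for flour in frame["flour"].unique():
        for sex in ("male", "female"):
            # body mass: focal treatment identical in both assays -> combined
            add_table(
                frame[(frame.flour == flour) & (frame.sex == sex)],
                "body_mass_mg",
                "gaussian",
                flour,
                sex,
                "combined",
            )
            add_table(
                frame[
                    (frame.flour == flour)
                    & (frame.sex == sex)
                    & (frame.assay == "focal_only")
                ],
                "offspring",
                "quasipoisson",
                flour,
                sex,
                "focal_only",
            )
        males = frame[
            (frame.flour == flour)
            & (frame.sex == "male")
            & (frame.assay == "focal_only")
            & frame["mating_success"].notna()
        ]
        if len(males):
            add_table(males, "mating_success", "quasipoisson", flour, "male", "focal_only")
        elif (frame.flour == flour).any():
            warnings.append(
                f"glm mating_success/{flour} skipped: per-partner detail unavailable"
            )

        # sex-by-treatment interaction on body mass relativized within sex
        sub = frame[(frame.flour == flour) & frame["body_mass_mg"].notna()].copy()
        if len(sub) >= 8 and sub["sex"].nunique() == 2 and sub["yeast"].nunique() >= 2:
            try:
                for sex in ("male", "female"):
                    mask = sub["sex"] == sex
                    sub.loc[mask, "rel_mass"] = relativize(
                        sub.loc[mask, "body_mass_mg"].to_numpy()
                    )
                itab = fit_interaction_glm(sub, "rel_mass", "sex", "yeast", "gaussian")
                for _, r in itab[itab["term"].str.contains(":")].iterrows():
                    rows.append(
                        {
                            "response": "rel_body_mass",
                            "family": "gaussian",
                            "assay": "combined",
                            "flour": flour,
                            "sex": "both",
                            "contrast": f"sex x {r['term']}",
                            "estimate": r["estimate"],
                            "se": r["se"],
                            "t": r["t"],
                            "p_raw": r["p"],
                            "p_adj": r["p"],
                            "df_resid": r["df_resid"],
                            "f_value": None,
                            "f_p": None,
                            "n": len(sub),
                        }
                    )
            except _SKIPPABLE as exc:
                warnings.append(f"glm interaction/{flour} skipped: {exc}")

    # week-1 vs week-2 laying contrast, where the sub-assay was recorded
    weekly = frame[frame["laying_week"].isin(["week1", "week2"])]
    for (flour, yeast), sub in weekly.groupby(["flour", "yeast"]):
        try:
            fit = fit_treatment_glm(sub, "offspring", "quasipoisson", factor="laying_week")
        except _SKIPPABLE as exc:
            warnings.append(f"glm laying_week {flour}/{yeast} skipped: {exc}")
            continue
        for _, r in fit.table.iterrows():
            rows.append(
                {
                    "response": "offspring_by_week",
                    "family": "quasipoisson",
                    "assay": "combined",
                    "flour": flour,
                    "sex": "female",
                    "contrast": f"{yeast}: {r['contrast']}",
                    "estimate": r["estimate"],
                    "se": r["se"],
                    "t": r["t"],
                    "p_raw": r["p_raw"],
                    "p_adj": r["p_adj"],
                    "df_resid": fit.df_resid,
                    "f_value": fit.f_value,
                    "f_p": fit.f_p,
                    "n": fit.n,
                }
            )
    return pd.DataFrame(rows)


def _mortality_stage(dataset: Dataset, cfg: RunConfig, warnings: list[str]) -> pd.DataFrame:
    frame = dataset.to_frame()
    rows = []
    for flour, sub in frame[frame.sex == "female"].groupby("flour"):
        counts = (
            sub.groupby("yeast")["survived"]
            .agg(died=lambda s: int((~s).sum()), survived_n="sum")
            .sort_index()
        )
        table = counts[["died", "survived_n"]].to_numpy().T  # 2 x k
        try:
            res = chisq_mortality(table, yates=True)
        except _SKIPPABLE as exc:
            warnings.append(f"mortality {flour} skipped: {exc}")
            continue
        for yeast, row in counts.iterrows():
            rows.append(
                {
                    "flour": flour,
                    "yeast": yeast,
                    "died": int(row["died"]),
                    "survived": int(row["survived_n"]),
                    "chi2": res.chi2,
                    "df": res.df,
                    "p": res.p,
                    "df_residual": res.df_residual,
                    "yates": res.yates,
                }
            )
    return pd.DataFrame(rows)


def load_input(cfg: RunConfig) -> Dataset:
    """Resolve the configured dataset (file or simulation)."""
    if cfg.simulate:
        params = cfg.sim_params or SimulationParams(seed=cfg.seed)
        return simulate_both_assays(params, seed=cfg.seed)
    return read_fitness_table(cfg.input, strict=cfg.strict)


def run_analysis(cfg: RunConfig) -> RunResult:
    """Run every stage and write the result bundle to ``cfg.out_dir``.

    Any stage error removes this run's partial outputs and re-raises as
    :class:`StageError` naming the failed stage.
    """
    cfg.validate()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    tables: dict[str, pd.DataFrame] = {}
    written: list[Path] = []

    stage = "load"
    try:
        dataset = load_input(cfg)
        log.info("loaded %d records (%s)", len(dataset), dataset.provenance)
        if dataset.validation_report:
            warnings.extend(f"validation: {v}" for v in dataset.validation_report)

        stage_fns = [
            ("selection_coefficients", _selection_stage),
            ("opportunity", _opportunity_stage),
        ]
        if cfg.decomposition and dataset.has_partner_detail:
            stage_fns.append(("decomposition", _decomposition_stage))
        elif cfg.decomposition:
            warnings.append(
                "decomposition disabled: male records lack per-partner detail"
            )
            log.warning("decomposition disabled: totals-only male dialect")
        stage_fns += [("glm_contrasts", _glm_stage), ("mortality", _mortality_stage)]

        for stage, fn in stage_fns:
            log.info("running stage %s", stage)
            tables[stage] = fn(dataset, cfg, warnings)
            path = out_dir / f"{stage}.csv"
            tables[stage].to_csv(path, index=False)
            written.append(path)

        stage = "manifest"
        manifest = {
            "package": "matefit",
            "version": __version__,
            "seed": cfg.seed,
            "n_boot": cfg.n_boot,
            "n_perm": cfg.n_perm,
            "ci_level": cfg.ci_level,
            "config_hash": cfg.config_hash(),
            "input": str(cfg.input) if cfg.input else "simulated",
            "n_records": len(dataset),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "outputs": [p.name for p in written],
            "warnings": warnings,
        }
        path = out_dir / "run_manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written.append(path)
    except MatefitError as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
    return RunResult(out_dir=out_dir, tables=tables, manifest=manifest, warnings=warnings)
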