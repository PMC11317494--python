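"""End-to-end orchestration: QA → diagnostics/indices/risk → multivariate → report.

The pipeline is a fixed DAG over the library stages.  A stage failure aborts
only its dependents; everything else still runs and the report records the
failure.  Outputs are written atomically (temp file + rename) as CSV and
JSON per stage plus a human-readable markdown summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .dwqi import DwqiStandards, dwqi_table
from .errors import ConfigError, HydrochemError
from .facies import facies_table
from .irrigation import irrigation_table
from .multivariate import hca_ward, pca_varimax, pearson_matrix
from .risk import McConfig, mc_campaign, mc_summary_frame, risk_table, RISK_ELEMENTS
from .samples import WaterSample, qa_report_frame, qa_screen, read_samples, samples_to_frame, to_meq
from .saturation import speciation_table
from .synthetic import CampaignConfig, generate_campaign

log = logging.getLogger(__name__)

ALL_STAGES = ("qa", "facies", "saturation", "dwqi", "irrigation", "risk", "mc", "multivariate")
#: stage → stages it needs (the DAG)
_DEPS: Mapping[str, tuple[str, ...]] = {s: (() if s == "qa" else ("qa",)) for s in ALL_STAGES}

#: variables entering the multivariate stage
_MV_VARS = ("Ca", "Mg", "Na", "K", "Cl", "SO4", "HCO3", "CO3", "NO3", "Fe", "Mn",
            "pH", "EC", "TDS", "TH")


@dataclass(frozen=True)
class RunConfig:
    input: str = "simulate"              # CSV path, or "simulate"
    out_dir: str = "hydrochem_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    qa_tolerance: float = 5.0
    qa_action: str = "flag"
    standards: DwqiStandards | None = None
    mc: McConfig | None = None
    campaign: CampaignConfig | None = None
    overwrite: bool = False

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stage(s): {', '.join(sorted(unknown))}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(bad))}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


@dataclass(frozen=True)
class RunReport:
    config: RunConfig
    outputs: Mapping[str, tuple[str, ...]]   # stage → files written
    skipped: tuple[str, ...]
    errors: Mapping[str, str]
    warnings: tuple[str, ...]
    version: str = __version__

    @property
    def ok(self) -> bool:
        return not self.errors


def _atomic_write_frame(frame: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, index=False, float_format="%.6g")
    tmp.replace(path)


def _atomic_write_json(frame: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(frame.to_json(orient="records", indent=2))
    tmp.replace(path)


def _load_samples(config: RunConfig) -> list[WaterSample]:
    if config.input == "simulate":
        campaign = config.campaign or CampaignConfig(seed=config.seed)
        if campaign.seed != config.seed:
            campaign = replace(campaign, seed=config.seed)
        return generate_campaign(campaign)
    return read_samples(config.input)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in DAG order and write all outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = _load_samples(config)
    if not samples:
        raise HydrochemError("no input samples")
    balances = [to_meq(s) for s in samples]

    outputs: dict[str, tuple[str, ...]] = {}
    errors: dict[str, str] = {}
    warnings: list[str] = []
    done: set[str] = set()

    def emit(stage: str, frame: pd.DataFrame) -> None:
        files = []
        for ext, writer in (("csv", _atomic_write_frame), ("json", _atomic_write_json)):
            path = out_dir / f"{stage}.{ext}"
            if path.exists() and not config.overwrite:
                raise HydrochemError(f"refusing to overwrite {path} (set overwrite)")
            writer(frame, path)
            files.append(str(path))
        outputs[stage] = tuple(files)
        done.add(stage)

    frames: dict[str, pd.DataFrame] = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        if any(dep not in done and dep in config.stages for dep in _DEPS[stage]):
            errors[stage] = "skipped: upstream stage failed"
            continue
        try:
            if stage == "qa":
                results = qa_screen(samples, tolerance=config.qa_tolerance,
                                    action=config.qa_action)
                n_fail = sum(not r.pass_flag for r in results)
                if n_fail:
                    warnings.append(f"{n_fail} sample(s) failed the CBE gate")
                if config.qa_action == "exclude":
                    samples = [r.sample for r in results]
                    balances = [to_meq(s) for s in samples]
                frames[stage] = qa_report_frame(results)
            elif stage == "facies":
                frames[stage] = facies_table(samples, balances)
            elif stage == "saturation":
                frames[stage] = speciation_table(samples)
            elif stage == "dwqi":
                frames[stage] = dwqi_table(samples, config.standards)
            elif stage == "irrigation":
                frames[stage] = irrigation_table(samples, balances)
            elif stage == "risk":
                frames[stage] = risk_table(samples)
            elif stage == "mc":
                conc = {el: [s.ion(el, default=0.0) for s in samples] for el in RISK_ELEMENTS}
                mc_cfg = config.mc or McConfig(seed=config.seed)
                frames[stage] = mc_summary_frame(mc_campaign(conc, config=mc_cfg))
            elif stage == "multivariate":
                table = samples_to_frame(samples)
                cols = [c for c in _MV_VARS if c in table.columns]
                data = table.rename(columns={"pH": "pH"})[
                    [c if c != "pH" else "pH" for c in cols]].astype(float).dropna(axis=1)
                corr = pearson_matrix(data)
                frames["multivariate"] = corr.r.reset_index(names="variable")
                pca = pca_varimax(data)
                _atomic_write_frame(pca.loadings.reset_index(names="variable"),
                                    out_dir / "pca_loadings.csv")
                tree = hca_ward(data)
                (out_dir / "hca_variables.nwk").write_text(tree.to_newick())
            emit(stage, frames[stage])
        except HydrochemError as exc:
            log.error("stage %s failed: %s", stage, exc)
            errors[stage] = str(exc)

    report = RunReport(config=config, outputs=outputs,
                       skipped=tuple(s for s in ALL_STAGES if s not in config.stages),
                       errors=errors, warnings=tuple(warnings))
    write_report(report, frames, out_dir)
    return report


def write_report(report: RunReport, frames: Mapping[str, pd.DataFrame], out_dir: Path) -> None:
    """Markdown summary + JSON manifest of a pipeline run."""
    if not frames and report.errors:
        raise HydrochemError("nothing to report: every stage failed")
    lines = [f"# hydrochem run report (v{report.version})", ""]
    lines.append(f"Input: `{report.config.input}`  seed: {report.config.seed}")
    lines.append("")
    if "qa" in frames:
        qa = frames["qa"]
        lines.append(f"## QA: {int(qa['pass'].sum())}/{len(qa)} samples within the CBE band")
    if "dwqi" in frames:
        d = frames["dwqi"]
        lines.append("## Drinking water quality")
        by_site = d.groupby("site_id")["dwqi"].mean()
        for site, score in by_site.items():
            label = "restricted for drinking" if score > 100 else "suitable for drinking"
            lines.append(f"- {site}: DWQI = {score:.1f} ({label})")
    if "irrigation" in frames:
        irr = frames["irrigation"]
        lines.append("## Irrigation suitability")
        lines.append(f"- PS excellent-to-good: {(irr['ps'] < 3).mean():.0%} of samples")
        lines.append(f"- RSC acceptable (< 1.25): {(irr['rsc'] < 1.25).mean():.0%} of samples")
    if "mc" in frames:
        mc = frames["mc"]
        worst = mc.loc[mc["mean"].idxmax()]
        lines.append("## Health risk (Monte Carlo)")
        lines.append(
            f"- max mean HQ = {worst['mean']:.3f} ({worst['element']}, {worst['cohort']}); "
            + ("below" if worst["mean"] < 1 else "above") + " the safety threshold of 1"
        )
    for stage, msg in report.errors.items():
        lines.append(f"**stage {stage} failed:** {msg}")
    (out_dir / "summary.md").write_text("\n".join(lines) + "\n")
    manifest = {
        "version": report.version,
        "input": report.config.input,
        "seed": report.config.seed,
        "outputs": {k: list(v) for k, v in report.outputs.items()},
        "skipped": list(report.skipped),
        "errors": dict(report.errors),
        "warnings": list(report.warnings),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
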