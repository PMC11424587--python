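"""Tab-separated file formats, run configuration and the end-to-end pipeline.

Formats (all UTF-8, tab-delimited, header row mandatory):

* study table — one row per study: ``study_id  year  ethnicity  snp
  case_mm  case_Mm  case_MM  ctrl_mm  ctrl_Mm  ctrl_MM`` (person counts for
  minor-homozygote / heterozygote / major-homozygote genotypes);
* MAF reference — ``snp  ancestry  minor_allele  maf`` with 0 < maf <= 0.5;
* outputs — ``verdicts.tsv``, ``summary.tsv``, ``tsa_curves.tsv`` (one row
  per interim look: fraction, z, boundaries, flags) and ``run.log``.

Outputs are bit-identical across runs with the same inputs and
configuration: all randomness is seeded and no timestamps enter data files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .classify import Verdict, stratified_run, summarize, verdict_table
from .meta import cumulative_series
from .records import GenotypeCounts, StudyRecord
from .simulate import ScenarioConfig, simulate_literature
from .tsa import (
    GridConfig,
    RISSpec,
    build_z_curve,
    compute_boundaries,
    required_information_size,
)

logger = logging.getLogger(__name__)

STUDY_COLUMNS = [
    "study_id", "year", "ethnicity", "snp",
    "case_mm", "case_Mm", "case_MM", "ctrl_mm", "ctrl_Mm", "ctrl_MM",
]
MAF_COLUMNS = ["snp", "ancestry", "minor_allele", "maf"]
COUNT_COLUMNS = STUDY_COLUMNS[4:]


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; defaults follow the published design (two-sided
    alpha 0.05, power 0.8, anticipated odds ratio 1.5, heterogeneity
    adjustment 80%)."""

    alpha: float = 0.05
    power: float = 0.8
    assumed_or: float = 1.5
    heterogeneity_adjustment: float = 0.80
    continuity: float = 0.5
    grid_nodes: int = 4001
    bisection_tol: float = 1e-6
    seed: int = 0

    @property
    def grid(self) -> GridConfig:
        return GridConfig(nodes=self.grid_nodes, prob_tol=self.bisection_tol)

    def ris_spec(self, control_maf: float) -> RISSpec:
        return RISSpec(
            control_maf=control_maf,
            alpha=self.alpha,
            power=self.power,
            assumed_or=self.assumed_or,
            heterogeneity_adjustment=self.heterogeneity_adjustment,
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def read_study_table(path: Union[str, Path]) -> list[StudyRecord]:
    """Parse and validate a study table; errors name the offending row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(STUDY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[StudyRecord] = []
    seen: set = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            counts = {}
            for col in COUNT_COLUMNS + ["year"]:
                raw = getattr(row, col)
                value = int(raw)
                if value < 0 and col != "year":
                    raise ValueError(f"{col} is negative")
                counts[col] = value
            key = (row.snp, row.ethnicity, row.study_id)
            if key in seen:
                raise ValueError(f"duplicate (snp, ethnicity, study_id) {key}")
            seen.add(key)
            records.append(
                StudyRecord(
                    study_id=str(row.study_id),
                    year=counts["year"],
                    ethnicity=str(row.ethnicity),
                    snp_label=str(row.snp),
                    cases=GenotypeCounts(counts["case_mm"], counts["case_Mm"], counts["case_MM"]),
                    controls=GenotypeCounts(counts["ctrl_mm"], counts["ctrl_Mm"], counts["ctrl_MM"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, line {i}: {exc}") from exc
    return records


def write_study_table(records: Sequence[StudyRecord], path: Union[str, Path]) -> None:
    rows = [
        {
            "study_id": r.study_id, "year": r.year, "ethnicity": r.ethnicity,
            "snp": r.snp_label,
            "case_mm": r.cases.n_mm, "case_Mm": r.cases.n_Mm, "case_MM": r.cases.n_MM,
            "ctrl_mm": r.controls.n_mm, "ctrl_Mm": r.controls.n_Mm, "ctrl_MM": r.controls.n_MM,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_maf_reference(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(subset=["snp", "ancestry"]).any():
        dupes = df[df.duplicated(subset=["snp", "ancestry"])][["snp", "ancestry"]]
        raise ValueError(f"{path}: duplicate (snp, ancestry) entries:\n{dupes}")
    bad = df[(df["maf"] <= 0) | (df["maf"] > 0.5)]
    if len(bad):
        raise ValueError(f"{path}: maf outside (0, 0.5] in rows {list(bad.index + 2)}")
    return df


def write_maf_reference(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, columns=MAF_COLUMNS)


# ---------------------------------------------------------------------------
# scenario files (synthetic panels)
# ---------------------------------------------------------------------------


def read_scenarios(path: Union[str, Path]) -> list[ScenarioConfig]:
    """Scenario YAML: a list (or single mapping) of ScenarioConfig fields."""
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if isinstance(data, dict):
        data = [data]
    return [ScenarioConfig(**item) for item in data]


def simulate_panel(
    scenarios: Sequence[ScenarioConfig],
) -> tuple[list[StudyRecord], pd.DataFrame]:
    """All studies of a scenario panel plus the matching MAF reference."""
    records: list[StudyRecord] = []
    maf_rows = []
    for cfg in scenarios:
        records.extend(simulate_literature(cfg))
        maf_rows.append(
            {"snp": cfg.snp_label, "ancestry": cfg.ethnicity,
             "minor_allele": "m", "maf": cfg.control_maf}
        )
    maf = pd.DataFrame(maf_rows, columns=MAF_COLUMNS).drop_duplicates(["snp", "ancestry"])
    return records, maf.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReportBundle:
    """Everything one pipeline run produces."""

    verdicts: pd.DataFrame
    summary: pd.DataFrame
    curves: pd.DataFrame
    skipped: list


def _curves_table(
    studies: Sequence[StudyRecord],
    maf: pd.DataFrame,
    config: RunConfig,
    skipped_pairs: set,
) -> pd.DataFrame:
    """Per-look table (one row per interim look per pair) for plotting."""
    lookup = {(str(r.snp), str(r.ancestry)): float(r.maf) for r in maf.itertuples()}
    groups: dict = {}
    for s in studies:
        groups.setdefault((s.snp_label, s.ethnicity), []).append(s)
    rows = []
    for (snp, eth) in sorted(groups):
        if (snp, eth) in skipped_pairs or (snp, eth) not in lookup:
            continue
        spec = config.ris_spec(lookup[(snp, eth)])
        series = cumulative_series(groups[(snp, eth)], config.continuity)
        ris = required_information_size(spec)
        curve = build_z_curve(series, ris)
        bounds = compute_boundaries(
            [p.info_fraction for p in curve.points],
            alpha=spec.alpha, beta=1 - spec.power, drift=spec.drift, grid=config.grid,
        )
        for p, mon, fut in zip(curve.points, bounds.monitoring, bounds.futility):
            rows.append(
                {
                    "snp": snp, "ethnicity": eth, "look": p.k,
                    "info_fraction": p.info_fraction, "z": p.z,
                    "cum_alleles": p.cum_alleles,
                    "monitoring": mon, "futility": fut,
                    "monitoring_crossed": abs(p.z) >= mon,
                    "in_futility_wedge": (not np.isnan(fut)) and abs(p.z) < fut,
                    "ris_reached": p.info_fraction >= 1.0,
                }
            )
    cols = [
        "snp", "ethnicity", "look", "info_fraction", "z", "cum_alleles",
        "monitoring", "futility", "monitoring_crossed", "in_futility_wedge",
        "ris_reached",
    ]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(
    study_path: Union[str, Path],
    maf_path: Union[str, Path],
    config: Optional[RunConfig] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> ReportBundle:
    """simulate-free end of the pipeline: analyze, classify, report.

    Reads a study table and a MAF reference, runs the cumulative
    random-effects meta-analysis and sequential monitoring per (snp,
    ethnicity) pair, classifies each pair, and (if ``out_dir`` is given)
    writes ``verdicts.tsv``, ``summary.tsv``, ``tsa_curves.tsv`` and
    ``run.log``.  Raises on any validation failure before writing outputs.
    """
    config = config or RunConfig()
    studies = read_study_table(study_path)
    if not studies:
        raise ValueError(f"{study_path}: study table is empty")
    maf = read_maf_reference(maf_path)

    log_lines: list[str] = []
    handler = _ListHandler(log_lines)
    root = logging.getLogger("tsameta")
    root.addHandler(handler)
    old_level = root.level
    root.setLevel(logging.INFO)
    try:
        log_lines.append(f"config: {asdict(config)}")
        verdicts, skipped = stratified_run(
            studies, maf,
            spec=config.ris_spec(control_maf=0.5),
            continuity=config.continuity,
            beta=1 - config.power,
            grid=config.grid,
        )
    finally:
        root.removeHandler(handler)
        root.setLevel(old_level)

    curves = _curves_table(studies, maf, config, set(skipped))
    vt = verdict_table(verdicts)
    summary = summarize(verdicts)
    for pair in skipped:
        log_lines.append(f"skipped (no MAF reference): {pair[0]} {pair[1]}")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        vt.to_csv(out / "verdicts.tsv", sep="\t", index=False)
        summary.to_csv(out / "summary.tsv", sep="\t")
        curves.to_csv(out / "tsa_curves.tsv", sep="\t", index=False)
        (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return ReportBundle(verdicts=vt, summary=summary, curves=curves, skipped=skipped)


class _ListHandler(logging.Handler):
    """Collects log records into a list (kept free of timestamps so that
    run.log is bit-identical across reruns)."""

    def __init__(self, sink: list):
        super().__init__()
        self.sink = sink

    def emit(self, record: logging.LogRecord) -> None:
        self.sink.append(f"{record.levelname} {record.name}: {record.getMessage()}")
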