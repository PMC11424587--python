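"""The decisive-gene verdict: conclusive risk / protective / null, or
inconclusive, per SNP per ethnicity stratum.

Sequential testing stops at the first boundary event in look order: a
monitoring crossing declares a conclusive association whose direction is the
sign of z at the crossing look (minor-allele OR > 1 is risk); entering the
futility wedge, or accumulating the adjusted required information size with
no crossing, declares a conclusive null; otherwise more cases are required
(inconclusive).  Conclusions taken at a look are never revoked by later
studies, so appending a study can only move a verdict from inconclusive to
conclusive.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

from .meta import CumulativeResult, cumulative_series
from .records import StudyRecord
from .tsa import (
    BoundarySet,
    CrossingReport,
    GridConfig,
    DEFAULT_GRID,
    RISSpec,
    ZCurve,
    assess_crossings,
    build_z_curve,
    compute_boundaries,
    required_information_size,
)

logger = logging.getLogger(__name__)

STATUSES = ("conclusive_risk", "conclusive_protective", "conclusive_null", "inconclusive")


@dataclass(frozen=True)
class Verdict:
    """The four-way classification for one SNP in one ethnicity stratum."""

    snp_label: str
    ethnicity: str
    status: str
    final_or: float
    ci_low: float
    ci_high: float
    i2: float
    cum_alleles: int
    adjusted_ris: float
    crossing_look: Optional[int] = None

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def classify(
    curve: ZCurve,
    bounds: BoundarySet,
    final: CumulativeResult,
    snp_label: str = "",
    ethnicity: str = "",
) -> Verdict:
    """Apply the stopping rule to a Z-curve and its boundaries.

    The first event in look order wins: monitoring crossing beats a later
    futility entry or required-size attainment, and vice versa.  The
    reported OR, confidence interval and I^2 always come from the last
    cumulative look (all evidence pooled).
    """
    if not curve.points:
        raise ValueError("empty Z-curve")
    report = assess_crossings(curve, bounds)
    events = []
    if report.first_monitoring_look is not None:
        events.append((report.first_monitoring_look, "monitoring"))
    if report.first_futility_look is not None:
        events.append((report.first_futility_look, "futility"))
    if report.first_ris_look is not None:
        events.append((report.first_ris_look, "ris"))
    crossing_look: Optional[int] = None
    if not events:
        status = "inconclusive"
    else:
        look, kind = min(events)
        if kind == "monitoring":
            status = "conclusive_risk" if report.monitoring_sign > 0 else "conclusive_protective"
            crossing_look = look
        else:
            status = "conclusive_null"
    return Verdict(
        snp_label=snp_label,
        ethnicity=ethnicity,
        status=status,
        final_or=final.pooled_or,
        ci_low=final.or_ci_low,
        ci_high=final.or_ci_high,
        i2=final.i2,
        cum_alleles=final.cum_alleles,
        adjusted_ris=curve.ris.adjusted_alleles,
        crossing_look=crossing_look,
    )


MafReference = Union[pd.DataFrame, Mapping[Tuple[str, str], float]]


def _maf_lookup(maf_reference: MafReference) -> dict:
    if isinstance(maf_reference, pd.DataFrame):
        required = {"snp", "ancestry", "maf"}
        missing = required - set(maf_reference.columns)
        if missing:
            raise ValueError(f"MAF reference is missing columns: {sorted(missing)}")
        return {
            (str(r.snp), str(r.ancestry)): float(r.maf)
            for r in maf_reference.itertuples()
        }
    return {k: float(v) for k, v in maf_reference.items()}


def stratified_run(
    studies: Sequence[StudyRecord],
    maf_reference: MafReference,
    spec: Optional[RISSpec] = None,
    continuity: float = 0.5,
    beta: Optional[float] = None,
    grid: GridConfig = DEFAULT_GRID,
) -> Tuple[list[Verdict], list[Tuple[str, str]]]:
    """One verdict per (snp, ethnicity) pair with at least one study.

    The control minor-allele frequency for each pair's information-size
    design is looked up in ``maf_reference`` by (snp, ancestry); pairs with
    no reference entry are skipped with a warning and returned in the second
    element.  ``spec`` supplies the design parameters other than
    ``control_maf`` (its own ``control_maf`` is ignored per pair).
    """
    base = spec if spec is not None else RISSpec(control_maf=0.5)
    if beta is None:
        beta = 1.0 - base.power
    maf = _maf_lookup(maf_reference)
    groups: dict[Tuple[str, str], list[StudyRecord]] = {}
    for s in studies:
        groups.setdefault((s.snp_label, s.ethnicity), []).append(s)
    verdicts: list[Verdict] = []
    skipped: list[Tuple[str, str]] = []
    for (snp, eth) in sorted(groups):
        if (snp, eth) not in maf:
            logger.warning("no MAF reference entry for (%s, %s); pair skipped", snp, eth)
            skipped.append((snp, eth))
            continue
        pair_spec = RISSpec(
            control_maf=maf[(snp, eth)],
            alpha=base.alpha,
            power=base.power,
            assumed_or=base.assumed_or,
            heterogeneity_adjustment=base.heterogeneity_adjustment,
        )
        series = cumulative_series(groups[(snp, eth)], continuity)
        ris = required_information_size(pair_spec)
        curve = build_z_curve(series, ris)
        bounds = compute_boundaries(
            [p.info_fraction for p in curve.points],
            alpha=pair_spec.alpha,
            beta=beta,
            drift=pair_spec.drift,
            grid=grid,
        )
        v = classify(curve, bounds, series[-1], snp_label=snp, ethnicity=eth)
        logger.info(
            "%s %s: %s (OR=%.3f CI %.3f-%.3f, I2=%.2f, alleles=%d/%.0f)",
            snp, eth, v.status, v.final_or, v.ci_low, v.ci_high, v.i2,
            v.cum_alleles, v.adjusted_ris,
        )
        verdicts.append(v)
    return verdicts, skipped


def summarize(verdicts: Sequence[Verdict]) -> pd.DataFrame:
    """Verdict counts per (ethnicity, status), all four statuses as columns."""
    rows = sorted({v.ethnicity for v in verdicts})
    table = pd.DataFrame(0, index=pd.Index(rows, name="ethnicity"), columns=list(STATUSES))
    for v in verdicts:
        table.loc[v.ethnicity, v.status] += 1
    return table


def verdict_table(verdicts: Sequence[Verdict]) -> pd.DataFrame:
    """Per-verdict rows sorted by (snp_label, ethnicity), stable column order."""
    cols = [
        "snp_label", "ethnicity", "status", "final_or", "ci_low", "ci_high",
        "i2", "cum_alleles", "adjusted_ris", "crossing_look",
    ]
    rows = [
        {c: getattr(v, c) for c in cols}
        for v in sorted(verdicts, key=lambda v: (v.snp_label, v.ethnicity))
    ]
    return pd.DataFrame(rows, columns=cols)
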