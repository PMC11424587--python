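"""Model/Results interface over the sequential meta-analysis pipeline.

``SequentialMetaAnalysis`` is built from the study records of one (snp,
ethnicity) pair plus the information-size design; ``fit()`` runs the
cumulative DerSimonian-Laird pooling, the boundary recursion and the
stopping rule, returning a ``SequentialMetaResults`` with the estimates,
their uncertainty, the per-look table and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import Verdict, classify
from .meta import CumulativeResult, cumulative_series
from .records import GenotypeCounts, StudyRecord
from .tsa import (
    BoundarySet,
    GridConfig,
    DEFAULT_GRID,
    RISResult,
    RISSpec,
    ZCurve,
    build_z_curve,
    compute_boundaries,
    required_information_size,
)


class SequentialMetaAnalysis:
    """Trial-sequential random-effects meta-analysis of one SNP in one stratum.

    Parameters
    ----------
    studies
        Case-control genotype records, all for the same SNP and ethnicity.
    design
        The required-information-size design (control MAF, alpha, power,
        anticipated odds ratio, heterogeneity adjustment).
    continuity
        Haldane-Anscombe correction added to all four allele-table cells
        when a cell is zero.
    grid
        Numerical settings for the boundary recursion.

    Examples
    --------
    >>> from tsameta import ScenarioConfig, simulate_literature
    >>> cfg = ScenarioConfig("rs0001", "Asian", control_maf=0.3, true_or=1.5,
    ...                      tau=0.0, n_studies=6, case_sizes=[200] * 6,
    ...                      control_sizes=[200] * 6, seed=7)
    >>> model = SequentialMetaAnalysis(simulate_literature(cfg),
    ...                                RISSpec(control_maf=0.3))
    >>> res = model.fit()
    >>> res.verdict.status in ("conclusive_risk", "inconclusive")
    True
    """

    def __init__(
        self,
        studies: Sequence[StudyRecord],
        design: RISSpec,
        continuity: float = 0.5,
        grid: GridConfig = DEFAULT_GRID,
    ) -> None:
        studies = list(studies)
        if not studies:
            raise ValueError("at least one study is required")
        self.studies = studies
        self.design = design
        self.continuity = continuity
        self.grid = grid
        self.snp_label = studies[0].snp_label
        self.ethnicity = studies[0].ethnicity

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        design: RISSpec,
        snp: Optional[str] = None,
        ethnicity: Optional[str] = None,
        **kwargs,
    ) -> "SequentialMetaAnalysis":
        """Build from a study-table DataFrame (columns as in the TSV format).

        ``snp``/``ethnicity`` select one pair when the frame holds several.
        """
        sub = df
        if snp is not None:
            sub = sub[sub["snp"] == snp]
        if ethnicity is not None:
            sub = sub[sub["ethnicity"] == ethnicity]
        records = [
            StudyRecord(
                study_id=str(r.study_id),
                year=int(r.year),
                ethnicity=str(r.ethnicity),
                snp_label=str(r.snp),
                cases=GenotypeCounts(int(r.case_mm), int(r.case_Mm), int(r.case_MM)),
                controls=GenotypeCounts(int(r.ctrl_mm), int(r.ctrl_Mm), int(r.ctrl_MM)),
            )
            for r in sub.itertuples()
        ]
        return cls(records, design, **kwargs)

    def fit(self) -> "SequentialMetaResults":
        series = cumulative_series(self.studies, self.continuity)
        ris = required_information_size(self.design)
        curve = build_z_curve(series, ris)
        bounds = compute_boundaries(
            [p.info_fraction for p in curve.points],
            alpha=self.design.alpha,
            beta=1 - self.design.power,
            drift=self.design.drift,
            grid=self.grid,
        )
        verdict = classify(curve, bounds, series[-1],
                           snp_label=self.snp_label, ethnicity=self.ethnicity)
        return SequentialMetaResults(self, series, ris, curve, bounds, verdict)


@dataclass
class SequentialMetaResults:
    """Fitted results: pooled effect, boundaries, looks and the verdict."""

    model: SequentialMetaAnalysis
    series: list
    ris: RISResult
    curve: ZCurve
    bounds: BoundarySet
    verdict: Verdict

    @property
    def final(self) -> CumulativeResult:
        return self.series[-1]

    @property
    def pooled_or(self) -> float:
        return self.final.pooled_or

    @property
    def conf_int(self) -> tuple:
        return (self.final.or_ci_low, self.final.or_ci_high)

    def look_table(self) -> pd.DataFrame:
        """One row per interim look: fraction, z, boundaries, pooled state."""
        rows = []
        for p, r, mon, fut in zip(
            self.curve.points, self.series, self.bounds.monitoring, self.bounds.futility
        ):
            rows.append(
                {
                    "look": p.k,
                    "info_fraction": p.info_fraction,
                    "cum_alleles": p.cum_alleles,
                    "z": p.z,
                    "monitoring": mon,
                    "futility": fut,
                    "pooled_or": r.pooled_or,
                    "or_ci_low": r.or_ci_low,
                    "or_ci_high": r.or_ci_high,
                    "tau2": r.tau2,
                    "i2": r.i2,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        f = self.final
        v = self.verdict
        lines = [
            "Trial-sequential meta-analysis",
            "=" * 64,
            f"SNP: {v.snp_label}    stratum: {v.ethnicity}    studies: {f.k}",
            f"design: alpha={self.model.design.alpha}, power={self.model.design.power}, "
            f"assumed OR={self.model.design.assumed_or}, "
            f"control MAF={self.model.design.control_maf}, "
            f"het. adjustment={self.model.design.heterogeneity_adjustment}",
            "-" * 64,
            f"pooled OR (random effects): {f.pooled_or:8.4f}   "
            f"95% CI [{f.or_ci_low:.4f}, {f.or_ci_high:.4f}]",
            f"z = {f.z:.4f}   Q = {f.q:.4f}   tau^2 = {f.tau2:.5f}   I^2 = {f.i2:.1%}",
            f"information: {f.cum_alleles} of {self.ris.adjusted_alleles:.0f} alleles "
            f"(fraction {f.cum_alleles / self.ris.adjusted_alleles:.3f}; "
            f"unadjusted RIS {self.ris.unadjusted_alleles:.0f})",
            "-" * 64,
            f"verdict: {v.status}"
            + (f" (first boundary crossing at look {v.crossing_look})"
               if v.crossing_look else ""),
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Z-curve with monitoring and futility boundaries vs information."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4.5))
        t = [p.info_fraction for p in self.curve.points]
        z = [p.z for p in self.curve.points]
        mon = np.asarray(self.bounds.monitoring)
        fut = np.asarray(self.bounds.futility)
        tc = np.minimum(t, 1.0)
        ax.plot(t, z, "o-", color="black", label="cumulative Z")
        ax.plot(tc, mon, "s--", color="firebrick", label="monitoring boundary")
        ax.plot(tc, -mon, "s--", color="firebrick")
        if np.any(~np.isnan(fut)):
            ax.plot(tc, fut, "^--", color="steelblue", label="futility wedge")
            ax.plot(tc, -fut, "^--", color="steelblue")
        ax.axvline(1.0, color="grey", lw=0.8, ls=":")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("information fraction (alleles / adjusted RIS)")
        ax.set_ylabel("z")
        ax.set_title(f"{self.verdict.snp_label} ({self.verdict.ethnicity}): "
                     f"{self.verdict.status}")
        ax.legend(loc="best", fontsize=8)
        return ax
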