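"""Allele-model effect sizes and DerSimonian-Laird random-effects pooling.

Genotype distributions are collapsed to allele-level 2x2 tables (two alleles
per person), per-study log odds ratios are computed with the usual Woolf
standard error, and studies are pooled with the DerSimonian-Laird
method-of-moments random-effects model.  :func:`cumulative_series` re-pools
after each study in publication order, which is the sequence of interim looks
the sequential-monitoring machinery in :mod:`tsameta.tsa` operates on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .records import GenotypeCounts, StudyRecord

logger = logging.getLogger(__name__)

#: Two-sided 5% normal quantile, pinned for bit-stable confidence limits.
Z_975 = 1.959964


class InformationFreeTableError(ValueError):
    """Raised for a 2x2 table with an empty margin (no usable information)."""


@dataclass(frozen=True)
class AlleleTable:
    """Minor/major allele counts in cases (a, b) and controls (c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("allele counts must be non-negative")
        if self.a + self.b == 0 or self.c + self.d == 0:
            raise ValueError("each arm must contribute at least one person")

    @property
    def alleles(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EffectEstimate:
    """A study's log odds ratio, its standard error and its allele count."""

    log_or: float
    se: float
    alleles: int
    study_id: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")
        if self.alleles <= 0 or self.alleles % 2:
            raise ValueError("alleles must be a positive even integer")


@dataclass(frozen=True)
class CumulativeResult:
    """Random-effects pooled summary after the first ``k`` studies."""

    k: int
    pooled_log_or: float
    pooled_se: float
    z: float
    q: float
    tau2: float
    i2: float
    cum_alleles: int
    or_ci_low: float
    or_ci_high: float

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)


def genotype_to_allele_table(cases: GenotypeCounts, controls: GenotypeCounts) -> AlleleTable:
    """Collapse genotype person counts to the allele-model 2x2 table.

    Each person contributes two alleles: ``a = 2*n_mm + n_Mm`` minor alleles
    in cases, ``b = 2*n_MM + n_Mm`` major alleles in cases, and ``c``/``d``
    analogously in controls.
    """
    if cases.total == 0 or controls.total == 0:
        raise ValueError("both arms must contain at least one person")
    return AlleleTable(
        a=cases.minor_alleles,
        b=cases.major_alleles,
        c=controls.minor_alleles,
        d=controls.major_alleles,
    )


def study_effect(
    table: AlleleTable,
    continuity: float = 0.5,
    study_id: str = "",
    year: int = 0,
) -> EffectEstimate:
    """Log odds ratio and Woolf standard error for one allele table.

    When any cell is zero, ``continuity`` is added to all four cells
    (Haldane-Anscombe) before taking logs.  A table with an entirely empty
    row or column carries no information about the odds ratio and is
    rejected with :class:`InformationFreeTableError`; callers building
    cumulative series skip such studies with a warning.
    """
    if continuity < 0:
        raise ValueError("continuity must be non-negative")
    a, b, c, d = table.a, table.b, table.c, table.d
    if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
        raise InformationFreeTableError(
            f"table ({a},{b},{c},{d}) has an empty margin; no odds ratio is estimable"
        )
    if min(a, b, c, d) == 0:
        if continuity == 0:
            raise InformationFreeTableError(
                f"table ({a},{b},{c},{d}) has a zero cell and no continuity correction"
            )
        a, b, c, d = (a + continuity, b + continuity, c + continuity, d + continuity)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        log_or=log_or, se=se, alleles=table.alleles, study_id=study_id, year=year
    )


def pool_dl(effects: Sequence[EffectEstimate]) -> CumulativeResult:
    """Pool study effects with the DerSimonian-Laird random-effects model.

    Fixed-effect (inverse-variance) weights give Cochran's Q; the
    method-of-moments between-study variance is
    ``tau2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))`` and the pooled
    estimate re-weights each study by ``1/(se_i^2 + tau2)``.  With one study
    the pooled values equal that study's values and ``tau2 = I^2 = 0``.
    """
    effects = list(effects)
    k = len(effects)
    if k == 0:
        raise ValueError("pool_dl requires at least one study")
    y = [e.log_or for e in effects]
    v = [e.se**2 for e in effects]
    w = [1.0 / vi for vi in v]
    sw = sum(w)
    y_fe = sum(wi * yi for wi, yi in zip(w, y)) / sw
    q = sum(wi * (yi - y_fe) ** 2 for wi, yi in zip(w, y))
    if k > 1:
        denom = sw - sum(wi**2 for wi in w) / sw
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        i2 = max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    else:
        tau2 = 0.0
        i2 = 0.0
    w_re = [1.0 / (vi + tau2) for vi in v]
    sw_re = sum(w_re)
    pooled = sum(wi * yi for wi, yi in zip(w_re, y)) / sw_re
    pooled_se = 1.0 / math.sqrt(sw_re)
    return CumulativeResult(
        k=k,
        pooled_log_or=pooled,
        pooled_se=pooled_se,
        z=pooled / pooled_se,
        q=q,
        tau2=tau2,
        i2=i2,
        cum_alleles=sum(e.alleles for e in effects),
        or_ci_low=math.exp(pooled - Z_975 * pooled_se),
        or_ci_high=math.exp(pooled + Z_975 * pooled_se),
    )


def _sorted_effects(
    studies: Iterable[StudyRecord], continuity: float
) -> list[EffectEstimate]:
    ordered = sorted(studies, key=lambda s: (s.year, s.study_id))
    effects: list[EffectEstimate] = []
    for s in ordered:
        table = genotype_to_allele_table(s.cases, s.controls)
        try:
            effects.append(
                study_effect(table, continuity, study_id=s.study_id, year=s.year)
            )
        except InformationFreeTableError as exc:
            logger.warning("excluding study %s (%s %s): %s", s.study_id, s.snp_label, s.ethnicity, exc)
    return effects


def cumulative_series(
    studies: Sequence[StudyRecord], continuity: float = 0.5
) -> list[CumulativeResult]:
    """Cumulative meta-analysis: one pooled result per interim look.

    Studies are ordered by ``(year, study_id)``; the k-th element pools the
    first k informative studies, so element k never depends on later
    studies.  All records must describe the same SNP and ethnicity stratum.
    """
    studies = list(studies)
    if not studies:
        raise ValueError("cumulative_series requires at least one study")
    snps = {s.snp_label for s in studies}
    strata = {s.ethnicity for s in studies}
    if len(snps) > 1 or len(strata) > 1:
        raise ValueError(
            f"mixed inputs: SNPs {sorted(snps)}, strata {sorted(strata)}; "
            "run one (snp, ethnicity) pair at a time"
        )
    effects = _sorted_effects(studies, continuity)
    if not effects:
        raise ValueError("no informative studies after exclusions")
    return [pool_dl(effects[: k + 1]) for k in range(len(effects))]
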