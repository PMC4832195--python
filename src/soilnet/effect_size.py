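"""Weighted log response ratios of organic-amended (COF) vs chemical-only
(CF) treatments.

For each variable the effect size is R = ln(X̄_COF / X̄_CF) with sampling
variance

    v = SD_COF² / (n_COF · X̄_COF²) + SD_CF² / (n_CF · X̄_CF²),

weight w = 1/v, and confidence interval R ± λ·sqrt(v) (λ = 1.96 for 95%).
An effect is significant iff the interval excludes zero.  Group means, SDs
and n pool all samples of a treatment across sites (n = 12 under the
default 4-site × 3-replicate design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import Metadata, SampleTable, ValidationError

DEFAULT_LAMBDA = 1.96


@dataclass(frozen=True)
class GroupStats:
    """Pooled summary of one treatment group for one variable."""

    treatment: str
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValidationError(f"group {self.treatment!r} needs n >= 2, got {self.n}")
        if self.sd < 0:
            raise ValidationError("SD must be non-negative")


@dataclass(frozen=True)
class EffectSizeRecord:
    """Per-variable log response ratio with variance, weight, CI and flag."""

    variable_id: str
    category: str
    r: float
    v: float
    w: float
    ci_low: float
    ci_high: float
    significant: bool
    excluded_reason: str | None = None


def group_stats(
    table: SampleTable, metadata: Metadata, variable_id: str, treatment: str
) -> GroupStats:
    """Pooled mean, sample SD (n − 1 denominator) and n of one treatment."""
    metadata.validate_against(table)
    sample_ids = [
        s for s in table.sample_ids
        if s in set(metadata.samples_where(fertilization=treatment))
    ]
    if len(sample_ids) < 2:
        raise ValidationError(
            f"treatment {treatment!r} has {len(sample_ids)} samples; need >= 2"
        )
    values = table.subset_samples(sample_ids).column(variable_id)
    mean = float(values.mean())
    if mean <= 0:
        raise ValidationError(
            f"non-positive {treatment} mean for {variable_id!r}: "
            "log response ratio undefined"
        )
    return GroupStats(
        treatment=treatment.upper(),
        mean=mean,
        sd=float(values.std(ddof=1)),
        n=len(values),
    )


def response_ratio(cof: GroupStats, cf: GroupStats) -> float:
    """R = ln(X̄_COF / X̄_CF)."""
    if cof.mean <= 0 or cf.mean <= 0:
        raise ValidationError("log response ratio requires positive group means")
    return math.log(cof.mean / cf.mean)


def rr_variance(cof: GroupStats, cf: GroupStats) -> float:
    """Delta-method sampling variance of the log response ratio."""
    if cof.mean <= 0 or cf.mean <= 0:
        raise ValidationError("sampling variance requires positive group means")
    return cof.sd ** 2 / (cof.n * cof.mean ** 2) + cf.sd ** 2 / (cf.n * cf.mean ** 2)


def confidence_interval(r: float, v: float, lam: float = DEFAULT_LAMBDA):
    """(ci_low, ci_high, significant); v = 0 collapses the interval to R."""
    if v < 0:
        raise ValidationError(f"sampling variance must be >= 0, got {v}")
    half = lam * math.sqrt(v)
    ci_low, ci_high = r - half, r + half
    significant = not (ci_low <= 0.0 <= ci_high)
    return ci_low, ci_high, significant


def _record(cof: GroupStats, cf: GroupStats, variable_id, category,
            lam) -> EffectSizeRecord:
    try:
        r = response_ratio(cof, cf)
    except ValidationError as exc:
        nan = float("nan")
        return EffectSizeRecord(variable_id, category, nan, nan, nan, nan, nan,
                                False, excluded_reason=str(exc))
    v = rr_variance(cof, cf)
    ci_low, ci_high, significant = confidence_interval(r, v, lam)
    w = 1.0 / v if v > 0 else math.inf
    return EffectSizeRecord(variable_id, category, r, v, w, ci_low, ci_high,
                            significant)


def rr_table(
    ion_table: SampleTable,
    enzyme_table: SampleTable,
    metadata: Metadata,
    lam: float = DEFAULT_LAMBDA,
) -> list:
    """One EffectSizeRecord per variable, ions first, in input order.

    Variables whose group means are non-positive are reported with an
    ``excluded_reason`` instead of numbers.
    """
    records = []
    for table in (ion_table, enzyme_table):
        metadata.validate_against(table)
        by_treatment = {}
        for treatment in ("COF", "CF"):
            keep = set(metadata.samples_where(fertilization=treatment))
            rows = [i for i, s in enumerate(table.sample_ids) if s in keep]
            if len(rows) < 2:
                raise ValidationError(
                    f"treatment {treatment!r} has {len(rows)} samples; need >= 2"
                )
            values = np.asarray(table.values)[rows, :]
            by_treatment[treatment] = (
                values.mean(axis=0), values.std(axis=0, ddof=1), len(rows)
            )
        for j, (variable_id, category) in enumerate(
            zip(table.variable_ids, table.categories)
        ):
            nan = float("nan")
            group = {}
            bad = None
            for treatment, (means, sds, n) in by_treatment.items():
                if means[j] <= 0:
                    bad = (f"non-positive {treatment} mean for {variable_id!r}: "
                           "log response ratio undefined")
                    break
                group[treatment] = GroupStats(treatment, float(means[j]),
                                              float(sds[j]), n)
            if bad is not None:
                records.append(EffectSizeRecord(
                    variable_id, category, nan, nan, nan, nan, nan, False,
                    excluded_reason=bad,
                ))
            else:
                records.append(_record(group["COF"], group["CF"],
                                       variable_id, category, lam))
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "variable_id": rec.variable_id,
            "category": rec.category,
            "R": rec.r,
            "v": rec.v,
            "w": rec.w,
            "ci_low": rec.ci_low,
            "ci_high": rec.ci_high,
            "significant": rec.significant,
            "excluded_reason": rec.excluded_reason or "",
        }
        for rec in records
    ])
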