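"""Callable-exome mutation rates and exact Poisson rate comparisons.

The mutation rate for a variant class is the class count divided by twice
the summed callable bp over families (the haploid rate: each trio exposes
two haplotypes). Per-group confidence intervals are exact Poisson (Garwood)
intervals from the chi-square relation. Case and control rates are compared
with the exact conditional rate-ratio test: given the total count, the case
count is binomial under the null with success probability proportional to
case exposure, and the one-tailed p-value is the binomial tail.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .records import CoverageRecord, DamageClass, DeNovoCall, Rarity


class Group(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


@dataclass(frozen=True)
class RateEstimate:
    variant_class: str
    group: Group
    count: int
    total_callable_bp: int
    rate: float          # per haploid bp
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RateRatioResult:
    variant_class: str
    rate_ratio: float
    ci_low: float
    ci_high: float
    p_one_tailed: float
    alternative: str = "greater"
    undefined: bool = False


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read a BED file into per-chromosome interval trees.

    BED intervals are 0-based half-open [start, end); conversion from
    1-based positions happens in :func:`callable_bp`.
    """
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            trees.setdefault(chrom, IntervalTree()).addi(int(start), int(end))
    return trees


def callable_bp(
    coverage: Optional[Sequence[CoverageRecord]] = None,
    site_summaries: Optional[pd.DataFrame] = None,
    capture_bed: Optional[dict[str, IntervalTree]] = None,
    min_depth: int = 20,
    min_bq: float = 20.0,
    min_mq: float = 30.0,
    families: Optional[Iterable[str]] = None,
) -> dict[str, int]:
    """Per-family callable bp, either validated from precomputed records or
    counted from per-site summaries.

    ``site_summaries`` needs columns family_id, chrom, pos (1-based), depth,
    base_quality, mapping_quality; a site is callable when all three
    thresholds are met and, if ``capture_bed`` is given, the site lies inside
    the capture intersection.
    """
    if (coverage is None) == (site_summaries is None):
        raise ValueError("supply exactly one of coverage / site_summaries")
    if coverage is not None:
        out = {c.family_id: c.callable_bp for c in coverage}
        if len(out) != len(coverage):
            raise ValueError("duplicate family_id in coverage records")
        if families is not None:
            missing = set(families) - set(out)
            if missing:
                raise ValueError(
                    "no coverage for families: " + ", ".join(sorted(missing))
                )
        return out

    df = site_summaries
    ok = (
        (df["depth"] >= min_depth)
        & (df["base_quality"] >= min_bq)
        & (df["mapping_quality"] >= min_mq)
    )
    if capture_bed is not None:
        in_bed = []
        for chrom, pos in zip(df["chrom"], df["pos"]):
            tree = capture_bed.get(chrom)
            # 1-based pos -> 0-based coordinate, half-open membership
            in_bed.append(bool(tree is not None and tree.overlaps(pos - 1)))
        ok &= np.asarray(in_bed)
    counts = df.loc[ok].groupby("family_id").size().to_dict()
    if families is not None:
        missing = set(families) - set(counts)
        if missing:
            raise ValueError(
                "no callable sites for families: " + ", ".join(sorted(missing))
            )
    return {str(k): int(v) for k, v in counts.items()}


def haploid_rate(
    x: int,
    total_bp: int,
    alpha: float = 0.05,
    variant_class: str = "",
    group: Group = Group.CASE,
) -> RateEstimate:
    """Haploid mutation rate x/(2T) with an exact Poisson CI.

    The CI comes from the chi-square representation of Poisson tails:
    lower = qchisq(alpha/2, 2x)/2 (0 when x=0), upper =
    qchisq(1-alpha/2, 2x+2)/2, each divided by the haploid exposure 2T.
    """
    if total_bp <= 0:
        raise ValueError("total callable bp must be positive")
    if x < 0:
        raise ValueError("count must be nonnegative")
    exposure = 2.0 * total_bp
    lower = 0.0 if x == 0 else stats.chi2.ppf(alpha / 2, 2 * x) / 2 / exposure
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * x + 2) / 2 / exposure
    return RateEstimate(
        variant_class=variant_class,
        group=group,
        count=x,
        total_callable_bp=total_bp,
        rate=x / exposure,
        ci_low=lower,
        ci_high=upper,
    )


def rate_ratio_test(
    x_case: int,
    t_case: int,
    x_control: int,
    t_control: int,
    alternative: str = "greater",
    alpha: float = 0.05,
    variant_class: str = "",
) -> RateRatioResult:
    """Exact conditional test of case vs control Poisson rates.

    Conditional on n = x_case + x_control, the case count is binomial with
    success probability p0 = T_case/(T_case + T_control) under equal rates;
    the one-tailed p-value (alternative "greater") is P(X >= x_case). The
    rate-ratio CI inverts the exact (Clopper-Pearson) interval for the
    conditional proportion. The haploid factor 2 cancels in the ratio.
    """
    if t_case <= 0 or t_control <= 0:
        raise ValueError("exposures must be positive")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    n = x_case + x_control
    if n == 0:
        return RateRatioResult(
            variant_class=variant_class,
            rate_ratio=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            p_one_tailed=1.0,
            alternative=alternative,
            undefined=True,
        )
    p0 = t_case / (t_case + t_control)
    if alternative == "greater":
        p = float(stats.binom.sf(x_case - 1, n, p0))
    else:
        p = float(stats.binom.cdf(x_case, n, p0))

    r_case = x_case / (2.0 * t_case)
    r_control = x_control / (2.0 * t_control)
    rr = float("inf") if x_control == 0 else r_case / r_control

    # Clopper-Pearson bounds on the conditional proportion, mapped to RR via
    # RR = (p/(1-p)) * (T_control/T_case)
    if x_case == 0:
        p_lo = 0.0
    else:
        p_lo = float(stats.beta.ppf(alpha / 2, x_case, n - x_case + 1))
    if x_case == n:
        p_hi = 1.0
    else:
        p_hi = float(stats.beta.ppf(1 - alpha / 2, x_case + 1, n - x_case))
    scale = t_control / t_case
    ci_low = 0.0 if p_lo == 0.0 else p_lo / (1 - p_lo) * scale
    ci_high = float("inf") if p_hi == 1.0 else p_hi / (1 - p_hi) * scale
    return RateRatioResult(
        variant_class=variant_class,
        rate_ratio=rr,
        ci_low=ci_low,
        ci_high=ci_high,
        p_one_tailed=p,
        alternative=alternative,
    )


#: class name -> damage classes counted
CLASS_DEFINITIONS: dict[str, frozenset[DamageClass]] = {
    "all": frozenset(DamageClass),
    "damaging": frozenset({DamageClass.PTV, DamageClass.MISD}),
    "ptv": frozenset({DamageClass.PTV}),
    "misd": frozenset({DamageClass.MISD}),
    "synonymous": frozenset({DamageClass.SYNONYMOUS}),
}

#: rarity selector -> tiers included ("rare" is a superset of "ultra_rare")
RARITY_DEFINITIONS: dict[str, frozenset[Rarity]] = {
    "rare": frozenset({Rarity.RARE, Rarity.ULTRA_RARE}),
    "ultra_rare": frozenset({Rarity.ULTRA_RARE}),
}


def count_calls(
    calls: Sequence[DeNovoCall],
    variant_class: str,
    rarity: str,
) -> int:
    classes = CLASS_DEFINITIONS[variant_class]
    tiers = RARITY_DEFINITIONS[rarity]
    return sum(
        1 for c in calls if c.damage_class in classes and c.rarity in tiers
    )


def burden_report(
    case_calls: Sequence[DeNovoCall],
    control_calls: Sequence[DeNovoCall],
    case_coverage: Sequence[CoverageRecord],
    control_coverage: Sequence[CoverageRecord],
    classes: Sequence[str] = ("all", "damaging", "ptv", "misd", "synonymous"),
    rarities: Sequence[str] = ("rare", "ultra_rare"),
    alpha: float = 0.05,
    alternative: str = "greater",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class x rarity haploid rates (both groups) and rate-ratio tests.

    Returns (rates, ratios) data frames; ``rates`` has one row per
    class x rarity x group with exact Poisson CIs, ``ratios`` one row per
    class x rarity with the one-tailed exact test.
    """
    if not case_coverage or not control_coverage:
        raise ValueError("both case and control coverage are required")
    t_case = sum(c.callable_bp for c in case_coverage)
    t_control = sum(c.callable_bp for c in control_coverage)

    rate_rows, ratio_rows = [], []
    for vclass in classes:
        for rarity in rarities:
            x_ca = count_calls(case_calls, vclass, rarity)
            x_co = count_calls(control_calls, vclass, rarity)
            for group, x, t in (
                (Group.CASE, x_ca, t_case),
                (Group.CONTROL, x_co, t_control),
            ):
                est = haploid_rate(
                    x, t, alpha=alpha, variant_class=vclass, group=group
                )
                rate_rows.append({
                    "variant_class": vclass,
                    "rarity": rarity,
                    "group": group.value,
                    "count": x,
                    "callable_bp": t,
                    "haploid_rate": est.rate,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                })
            rr = rate_ratio_test(
                x_ca, t_case, x_co, t_control,
                alternative=alternative, alpha=alpha, variant_class=vclass,
            )
            ratio_rows.append({
                "variant_class": vclass,
                "rarity": rarity,
                "case_count": x_ca,
                "control_count": x_co,
                "rate_ratio": rr.rate_ratio,
                "ci_low": rr.ci_low,
                "ci_high": rr.ci_high,
                "p_one_tailed": rr.p_one_tailed,
            })
    return pd.DataFrame(rate_rows), pd.DataFrame(ratio_rows)
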