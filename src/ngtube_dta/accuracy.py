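"""Paired diagnostic-accuracy statistics for the two-strip pH study.

Sensitivity is the proportion of gastric placements whose averaged pH
reading falls at or below the cut-off; lung specificity is the proportion
of lung aspirates reading above it.  The two index tests are applied to
the same aspirate, so the sensitivity difference is assessed on the 2x2
concordance table of per-patient calls (McNemar), and the mean reading
difference by a paired t test.  Confidence intervals are Wald (normal
approximation) throughout: back-solving shows this is the interval family
behind the published tables, with the lung series using the sample-
variance (n-1) flavour produced by a t-style mean interval on a binary
indicator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .records import PatientDataset, PatientRecord, TubeLocation

__all__ = [
    "ProportionEstimate",
    "PairedComparison",
    "TestResult",
    "SensitivityRow",
    "SensitivityTable",
    "SampleSizeResult",
    "average_readers",
    "classify_gastric",
    "proportion_ci",
    "sensitivity_table",
    "lung_specificity",
    "paired_comparison",
    "paired_t_test",
    "cohen_kappa",
    "inter_rater_kappa",
    "sample_size_two_proportions",
    "qc_batch_release",
    "mean_reading",
    "QC_EXPECTED_MODIFIED",
    "QC_EXPECTED_UNMODIFIED",
]


def _z(level: float) -> float:
    return float(stats.norm.ppf(0.5 + level / 2.0))


def average_readers(r1: Optional[float], r2: Optional[float]) -> float:
    """Final pH reading: the two readers' average, rounded to 1 d.p.

    Rounding is decimal half-up (5.55 -> 5.6), performed in decimal
    arithmetic so boundary cases do not depend on binary float
    representation.  If only one reader's value is present it stands as
    its own average.
    """
    if r1 is None and r2 is None:
        raise ValueError("both readers' values are missing")
    if r1 is None or r2 is None:
        mean = Decimal(repr(r1 if r1 is not None else r2))
    else:
        mean = (Decimal(repr(r1)) + Decimal(repr(r2))) / 2
    return float(mean.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def classify_gastric(ph: float, cutoff: float) -> bool:
    """Safe-to-feed call: True iff the reading is at or below the cut-off."""
    if not (0.0 < cutoff < 14.0):
        raise ValueError(f"cutoff {cutoff} outside (0, 14)")
    return ph <= cutoff


@dataclass(frozen=True)
class ProportionEstimate:
    """A count-based proportion with a Wald confidence interval."""

    numerator: int
    denominator: int
    point: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator):
            raise ValueError("need 0 <= numerator <= denominator")
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")

    def display(self, decimals: int = 1) -> str:
        f = 10.0**2  # report as percentages
        return (
            f"{self.point * f:.{decimals}f}% ({self.numerator}/{self.denominator}) "
            f"({self.ci_low * f:.{decimals}f}%, {self.ci_high * f:.{decimals}f}%)"
        )


def proportion_ci(
    k: int,
    n: int,
    level: float = 0.95,
    se_denominator: str = "n",
) -> ProportionEstimate:
    """Wald interval p +/- z*sqrt(p(1-p)/n), clipped to [0, 1].

    ``se_denominator="n-1"`` uses the sample-variance standard error
    sqrt(p(1-p)/(n-1)), the interval a mean +/- z*sd/sqrt(n) computation
    with sample sd yields on a binary vector.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    p = k / n
    denom = n - 1 if se_denominator == "n-1" else n
    if se_denominator not in ("n", "n-1"):
        raise ValueError("se_denominator must be 'n' or 'n-1'")
    if denom <= 0:
        raise ValueError("n-1 standard error needs n >= 2")
    half = _z(level) * math.sqrt(p * (1.0 - p) / denom)
    return ProportionEstimate(
        numerator=k,
        denominator=n,
        point=p,
        ci_low=max(0.0, p - half),
        ci_high=min(1.0, p + half),
        level=level,
    )


@dataclass(frozen=True)
class PairedComparison:
    """2x2 concordance table of per-patient calls under the two strips.

    ``both_pos``/``std_only``/``novel_only``/``both_neg`` are the a, b, c,
    d cells; the sensitivity difference (novel - standard) equals
    (c - b)/n exactly.  The difference CI is the paired Wald interval and
    the McNemar statistic is the continuity-corrected chi-square on the
    discordant cells.
    """

    n: int
    both_pos: int
    std_only: int
    novel_only: int
    both_neg: int
    difference: float
    diff_ci_low: float
    diff_ci_high: float
    mcnemar_statistic: float
    mcnemar_p: float
    level: float = 0.95


def _mcnemar(b: int, c: int, correction: bool = True) -> tuple[float, float]:
    if b + c == 0:
        return 0.0, 1.0
    if correction:
        statistic = (abs(b - c) - 1) ** 2 / (b + c)
    else:
        statistic = (b - c) ** 2 / (b + c)
    return statistic, float(stats.chi2.sf(statistic, df=1))


def _gastric_calls(
    dataset: PatientDataset, cutoff: float
) -> tuple[list[bool], list[bool]]:
    gastric = dataset.gastric
    if not gastric:
        raise ValueError("dataset contains no gastric records")
    std_calls, novel_calls = [], []
    for rec in gastric:
        std_calls.append(classify_gastric(average_readers(rec.std_r1, rec.std_r2), cutoff))
        novel_calls.append(
            classify_gastric(average_readers(rec.novel_r1, rec.novel_r2), cutoff)
        )
    return std_calls, novel_calls


def paired_comparison(
    dataset: PatientDataset,
    cutoff: float,
    level: float = 0.95,
    correction: bool = True,
) -> PairedComparison:
    """Compare per-patient safe-to-feed calls between the two strips."""
    std_calls, novel_calls = _gastric_calls(dataset, cutoff)
    n = len(std_calls)
    a = sum(s and v for s, v in zip(std_calls, novel_calls))
    b = sum(s and not v for s, v in zip(std_calls, novel_calls))
    c = sum(v and not s for s, v in zip(std_calls, novel_calls))
    d = n - a - b - c
    diff = (c - b) / n
    # paired Wald: diff +/- z*sqrt((b+c) - (b-c)^2/n)/n
    half = _z(level) * math.sqrt(max(0.0, (b + c) - (b - c) ** 2 / n)) / n
    statistic, p = _mcnemar(b, c, correction=correction)
    return PairedComparison(
        n=n,
        both_pos=a,
        std_only=b,
        novel_only=c,
        both_neg=d,
        difference=diff,
        diff_ci_low=max(-1.0, diff - half),
        diff_ci_high=min(1.0, diff + half),
        mcnemar_statistic=statistic,
        mcnemar_p=p,
        level=level,
    )


@dataclass(frozen=True)
class SensitivityRow:
    cutoff: float
    standard: ProportionEstimate
    novel: ProportionEstimate
    comparison: PairedComparison


@dataclass(frozen=True)
class SensitivityTable:
    rows: tuple[SensitivityRow, ...]
    level: float = 0.95

    def to_dataframe(self, display_rounding: bool = False) -> pd.DataFrame:
        """Flatten to one row per cutoff.

        With ``display_rounding`` the CIs are recomputed from the point
        estimate first rounded to 1 d.p. (as a percentage), matching how
        percentages were carried through the published analysis.
        """
        out = []
        for r in self.rows:
            if display_rounding:
                std = _display_ci(r.standard)
                nov = _display_ci(r.novel)
            else:
                std, nov = r.standard, r.novel
            out.append(
                {
                    "cutoff": r.cutoff,
                    "n": r.standard.denominator,
                    "standard_k": r.standard.numerator,
                    "standard_sens": std.point,
                    "standard_ci_low": std.ci_low,
                    "standard_ci_high": std.ci_high,
                    "novel_k": r.novel.numerator,
                    "novel_sens": nov.point,
                    "novel_ci_low": nov.ci_low,
                    "novel_ci_high": nov.ci_high,
                    "difference": r.comparison.difference,
                    "diff_ci_low": r.comparison.diff_ci_low,
                    "diff_ci_high": r.comparison.diff_ci_high,
                    "mcnemar_statistic": r.comparison.mcnemar_statistic,
                    "mcnemar_p": r.comparison.mcnemar_p,
                }
            )
        return pd.DataFrame(out)


def _display_ci(est: ProportionEstimate) -> ProportionEstimate:
    """Wald CI recomputed from the 1-d.p.-rounded percentage."""
    p = round(est.point * 100, 1) / 100
    half = _z(est.level) * math.sqrt(p * (1.0 - p) / est.denominator)
    return ProportionEstimate(
        numerator=est.numerator,
        denominator=est.denominator,
        point=p,
        ci_low=max(0.0, p - half),
        ci_high=min(1.0, p + half),
        level=est.level,
    )


def sensitivity_table(
    dataset: PatientDataset,
    cutoffs: Sequence[float] = (4.0, 5.0, 5.5, 6.0),
    level: float = 0.95,
    correction: bool = True,
) -> SensitivityTable:
    """Per-cutoff sensitivities of both strips with paired comparison."""
    rows = []
    for cutoff in cutoffs:
        std_calls, novel_calls = _gastric_calls(dataset, cutoff)
        n = len(std_calls)
        rows.append(
            SensitivityRow(
                cutoff=cutoff,
                standard=proportion_ci(sum(std_calls), n, level),
                novel=proportion_ci(sum(novel_calls), n, level),
                comparison=paired_comparison(dataset, cutoff, level, correction),
            )
        )
    return SensitivityTable(rows=tuple(rows), level=level)


def lung_specificity(
    dataset: PatientDataset,
    cutoff: float,
    strip: str = "novel",
    level: float = 0.95,
    se_denominator: str = "n-1",
) -> ProportionEstimate:
    """Proportion of lung aspirates reading above the cut-off.

    The lung series uses the sample-variance (n-1) Wald interval by
    default; see module docstring.
    """
    lung = dataset.lung
    if not lung:
        raise ValueError("dataset contains no lung records")
    calls = []
    for rec in lung:
        r1, r2 = rec.readings(strip)
        calls.append(not classify_gastric(average_readers(r1, r2), cutoff))
    k, n = sum(calls), len(calls)
    if k in (0, n):
        # degenerate interval collapses to the point
        p = k / n
        return ProportionEstimate(k, n, p, p, p, level)
    return proportion_ci(k, n, level, se_denominator=se_denominator)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def paired_t_test(dataset: PatientDataset) -> TestResult:
    """Paired t test of mean averaged readings, standard minus novel.

    A positive statistic means the novel strip reads lower (more acidic).
    Raises if the per-patient differences have zero variance, where the
    statistic is undefined.
    """
    gastric = dataset.gastric
    if len(gastric) < 2:
        raise ValueError("paired t test needs at least 2 gastric records")
    std = [average_readers(r.std_r1, r.std_r2) for r in gastric]
    novel = [average_readers(r.novel_r1, r.novel_r2) for r in gastric]
    diffs = [s - v for s, v in zip(std, novel)]
    if max(diffs) == min(diffs):
        raise ValueError("zero-variance differences: paired t statistic undefined")
    res = stats.ttest_rel(std, novel)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), df=float(res.df))


def cohen_kappa(reader1: Sequence[object], reader2: Sequence[object]) -> float:
    """Unweighted Cohen's kappa, (po - pe) / (1 - pe).

    Categories are whatever the ratings are (here, grid-snapped pH
    values).  Perfect agreement with a degenerate marginal (pe = 1)
    returns 1 by convention.
    """
    if len(reader1) != len(reader2):
        raise ValueError("rating vectors differ in length")
    n = len(reader1)
    if n == 0:
        raise ValueError("empty rating vectors")
    po = sum(a == b for a, b in zip(reader1, reader2)) / n
    cats = set(reader1) | set(reader2)
    from collections import Counter

    c1, c2 = Counter(reader1), Counter(reader2)
    pe = sum(c1[c] * c2[c] for c in cats) / (n * n)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def inter_rater_kappa(dataset: PatientDataset, strip: str) -> float:
    """Kappa between the two readers' raw (grid) readings of one strip."""
    r1, r2 = [], []
    for rec in dataset.gastric:
        a, b = rec.readings(strip)
        if a is not None and b is not None:
            r1.append(a)
            r2.append(b)
    if not r1:
        raise ValueError(f"no two-reader gastric records for strip {strip!r}")
    return cohen_kappa(r1, r2)


@dataclass(frozen=True)
class SampleSizeResult:
    n_per_group: int
    n_per_group_with_loss: int
    n_total: int


def sample_size_two_proportions(
    p1: float,
    p2: float,
    alpha: float = 0.05,
    power: float = 0.80,
    loss_fraction: float = 0.0,
) -> SampleSizeResult:
    """Two-sample proportion test sample size, normal approximation.

    n = (z_{a/2} sqrt(2 p̄q̄) + z_b sqrt(p1 q1 + p2 q2))^2 / (p1 - p2)^2
    per group, rounded up, then inflated for anticipated loss.
    """
    for name, p in (("p1", p1), ("p2", p2)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must be in (0, 1)")
    if p1 == p2:
        raise ValueError("p1 and p2 must differ")
    if not (0.0 <= loss_fraction < 1.0):
        raise ValueError("loss_fraction must be in [0, 1)")
    z_a = float(stats.norm.ppf(1.0 - alpha / 2.0))
    z_b = float(stats.norm.ppf(power))
    p_bar = (p1 + p2) / 2.0
    num = (
        z_a * math.sqrt(2.0 * p_bar * (1.0 - p_bar))
        + z_b * math.sqrt(p1 * (1.0 - p1) + p2 * (1.0 - p2))
    ) ** 2
    n = math.ceil(num / (p1 - p2) ** 2)
    n_loss = math.ceil(n / (1.0 - loss_fraction))
    return SampleSizeResult(n_per_group=n, n_per_group_with_loss=n_loss, n_total=2 * n_loss)


#: typical batch-release readings of tributyrin-modified strips against
#: water / porcine pancreatic lipase / Candida antarctica lipase
QC_EXPECTED_MODIFIED = {"water": 7.0, "ppl": 4.0, "cal": 3.5}
#: unmodified strips read near-neutral against all three solutions
QC_EXPECTED_UNMODIFIED = {"water": 7.0, "ppl": 7.0, "cal": 7.0}


def qc_batch_release(
    lipase_readings: Sequence[float],
    control_readings: Optional[Sequence[float]] = None,
) -> bool:
    """Batch release rule: all 5 lipase-exposed strips read pH <= 5.0.

    ``control_readings`` (water-exposed strips) are accepted for record
    keeping but do not gate release.
    """
    if len(lipase_readings) != 5:
        raise ValueError("batch QC requires exactly 5 lipase-exposed readings")
    if control_readings is not None and len(control_readings) != 5:
        raise ValueError("control readings, when given, must also number 5")
    return all(r <= 5.0 for r in lipase_readings)


def mean_reading(
    dataset: PatientDataset,
    strip: str,
    location: TubeLocation = TubeLocation.GASTRIC,
    level: float = 0.95,
) -> tuple[float, float, float]:
    """Mean averaged reading with a normal-approximation CI (mean, lo, hi)."""
    recs = dataset.subset(location)
    if not recs:
        raise ValueError(f"no {location.value} records")
    vals = []
    for rec in recs:
        r1, r2 = rec.readings(strip)
        if r1 is not None or r2 is not None:
            vals.append(average_readers(r1, r2))
    n = len(vals)
    if n < 2:
        raise ValueError("need at least 2 readings for a mean CI")
    m = sum(vals) / n
    sd = math.sqrt(sum((v - m) ** 2 for v in vals) / (n - 1))
    half = _z(level) * sd / math.sqrt(n)
    return m, m - half, m + half
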