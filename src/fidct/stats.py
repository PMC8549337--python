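"""Descriptive statistics of segmented marker volumes.

Groups are indexed by (injected volume, tube voltage).  For each group the
mean, sample SD, the norm interval mean ± 1.96·SD (the range expected to
contain 95% of observations under a normal model) and the ratio of mean
segmented to injected volume are computed.  The effect of tube voltage on
the same physical markers is a repeated-measures design, so the default
pairwise comparison is a paired two-sided t-test aligned by marker id;
Welch's unpaired test is available for independent groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "VolumeSample",
    "VolumeSummary",
    "PairwiseResult",
    "summarize",
    "pairwise_compare",
    "summary_table",
    "all_pairwise",
]


@dataclass
class VolumeSample:
    """Per-group segmented volumes, aligned with their marker ids."""

    injected_volume_ul: float
    kv: int
    values: np.ndarray
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if len(self.marker_ids) != self.values.size:
            raise ValueError("marker_ids must align with values")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("marker_ids must be unique")
        if np.any(self.values < 0):
            raise ValueError("segmented volumes must be >= 0")


@dataclass(frozen=True)
class VolumeSummary:
    """Group summary: mean, SD, norm interval, segmented/injected ratio."""

    injected_volume_ul: float
    kv: int
    n: int
    mean: float
    sd: float
    norm_interval: tuple[float, float]
    ratio: float


def summarize(sample: VolumeSample) -> VolumeSummary:
    """Summarize one (injected volume, kV) group.

    mean and SD (n-1 denominator) of the segmented volumes, the norm
    interval mean ± 1.96·SD, and ratio = mean / injected volume.  Values
    are kept unrounded; round only at reporting time (2 decimals for
    volumes and bounds, 1 for the ratio).
    """
    v = sample.values
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    if v.size == 1:
        raise ValueError("sample SD undefined for n = 1")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    return VolumeSummary(
        injected_volume_ul=sample.injected_volume_ul,
        kv=sample.kv,
        n=int(v.size),
        mean=mean,
        sd=sd,
        norm_interval=(mean - 1.96 * sd, mean + 1.96 * sd),
        ratio=mean / sample.injected_volume_ul,
    )


@dataclass(frozen=True)
class PairwiseResult:
    injected_volume_ul: float
    kv_a: int
    kv_b: int
    statistic: float
    pvalue: float
    method: str


def pairwise_compare(
    sample_a: VolumeSample, sample_b: VolumeSample, paired: bool = True
) -> PairwiseResult:
    """Two-sided comparison of the same injected volume at two kV settings.

    Paired mode (default) uses within-marker differences, as the same
    physical markers are scanned at every voltage; unpaired mode uses
    Welch's t-test.
    """
    if sample_a.injected_volume_ul != sample_b.injected_volume_ul:
        raise ValueError("pairwise comparison requires equal injected volumes")
    if paired:
        if sample_a.marker_ids != sample_b.marker_ids:
            raise ValueError("paired comparison requires aligned marker_ids")
        diff = sample_a.values - sample_b.values
        if np.allclose(diff, 0.0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_rel(sample_a.values, sample_b.values)
        method = "paired t-test"
    else:
        stat, p = sps.ttest_ind(sample_a.values, sample_b.values, equal_var=False)
        method = "Welch t-test"
    return PairwiseResult(
        sample_a.injected_volume_ul, sample_a.kv, sample_b.kv, float(stat), float(p), method
    )


def all_pairwise(
    samples: Iterable[VolumeSample], paired: bool = True, bonferroni: bool = False
) -> list[PairwiseResult]:
    """All kV-pair comparisons within each injected-volume stratum.

    No multiple-testing correction by default (raw pairwise p-values); a
    Bonferroni option is available.
    """
    by_volume: dict[float, list[VolumeSample]] = {}
    for s in samples:
        by_volume.setdefault(s.injected_volume_ul, []).append(s)
    results: list[PairwiseResult] = []
    for vol, group in sorted(by_volume.items()):
        group = sorted(group, key=lambda s: s.kv)
        for a, b in combinations(group, 2):
            results.append(pairwise_compare(a, b, paired=paired))
    if bonferroni and results:
        m = len(results)
        results = [
            PairwiseResult(
                r.injected_volume_ul,
                r.kv_a,
                r.kv_b,
                r.statistic,
                min(1.0, r.pvalue * m),
                r.method + " (Bonferroni)",
            )
            for r in results
        ]
    return results


def summary_table(summaries: Iterable[VolumeSummary]) -> pd.DataFrame:
    """Tabulate group summaries, one row per (injected volume, kV).

    Volumes and interval bounds are reported to 2 decimals, the
    segmented/injected ratio to 1 decimal.
    """
    rows = []
    for s in sorted(summaries, key=lambda s: (s.injected_volume_ul, s.kv)):
        rows.append(
            {
                "injected_ul": s.injected_volume_ul,
                "kv": s.kv,
                "n": s.n,
                "mean_segmented_ul": round(s.mean, 2),
                "sd_segmented_ul": round(s.sd, 2),
                "norm_lower_ul": round(s.norm_interval[0], 2),
                "norm_upper_ul": round(s.norm_interval[1], 2),
                "ratio_segmented_to_injected": round(s.ratio, 1),
            }
        )
    return pd.DataFrame(rows)
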