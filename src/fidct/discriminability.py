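"""Discriminability of small vs large injection volumes.

Decides whether markers from a small injection (10 µl) can be reliably
told apart from a large one (30 µl) at a given tube voltage:

* Δ = min(large-group volumes) − max(small-group volumes): the observed
  gap between the groups (negative when their ranges overlap).
* border = lower norm-interval limit of the large group − Δ/2: a dividing
  line between the two volume populations.
* separation probability = Φ((border − mean_small) / sd_small): under a
  normal model of the small group, the probability that a small-volume
  marker falls on the small side of the border.  Differentiation is called
  reliable when this probability exceeds 95% (the norm-interval coverage).

The complementary tail (probability of a small marker landing above the
border) is reported alongside for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .stats import VolumeSample, VolumeSummary, summarize

__all__ = [
    "DiscriminabilityResult",
    "compute_delta",
    "compute_border",
    "separation_probability",
    "assess",
]


@dataclass(frozen=True)
class DiscriminabilityResult:
    kv: int
    delta_ul: float
    border_ul: float
    separation_probability: float
    prob_above_border: float
    reliable: bool


def compute_delta(sample_small: VolumeSample, sample_large: VolumeSample) -> float:
    """Observed gap between the groups: min(large) − max(small).

    Positive when the observed ranges do not overlap, negative when they do.
    """
    if sample_small.values.size == 0 or sample_large.values.size == 0:
        raise ValueError("both samples must be nonempty")
    if sample_small.injected_volume_ul >= sample_large.injected_volume_ul:
        raise ValueError("sample_small must have the smaller injected volume")
    return float(sample_large.values.min() - sample_small.values.max())


def compute_border(summary_large: VolumeSummary, delta_ul: float) -> float:
    """Border line: lower norm-interval limit of the large group − Δ/2."""
    return float(summary_large.norm_interval[0] - delta_ul / 2.0)


def separation_probability(summary_small: VolumeSummary, border_ul: float) -> float:
    """P(small-volume marker falls on the small side of the border).

    Normal model with the small group's sample mean and SD.  For sd = 0 the
    model degenerates to a point mass: 1.0 if the mean is below the border,
    else 0.0.
    """
    if summary_small.sd == 0:
        return 1.0 if summary_small.mean < border_ul else 0.0
    z = (border_ul - summary_small.mean) / summary_small.sd
    return float(norm.cdf(z))


def assess(
    sample_small: VolumeSample,
    sample_large: VolumeSample,
    summary_small: VolumeSummary | None = None,
    summary_large: VolumeSummary | None = None,
) -> DiscriminabilityResult:
    """Full chain: Δ → border → separation probability → > 95% decision."""
    if sample_small.kv != sample_large.kv:
        raise ValueError("samples must come from the same tube voltage")
    if summary_small is None:
        summary_small = summarize(sample_small)
    if summary_large is None:
        summary_large = summarize(sample_large)
    delta = compute_delta(sample_small, sample_large)
    border = compute_border(summary_large, delta)
    p = separation_probability(summary_small, border)
    return DiscriminabilityResult(
        kv=sample_small.kv,
        delta_ul=delta,
        border_ul=border,
        separation_probability=p,
        prob_above_border=1.0 - p,
        reliable=bool(p > 0.95),
    )
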