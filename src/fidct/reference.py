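"""Published reference values for the liquid-marker CT evaluation.

Summary statistics of segmented marker volumes from the ex-vivo porcine
mandible study of low-dose SAIB/x-SAIB injections (25 markers per injected
volume, scanned at 70/100/120 kV), and the clinical visibility counts from
the first two patients.  These printed summaries are the study's published
data; the raw per-marker volumes were not released, so the summaries serve
as inputs to the arithmetic they support (norm intervals, ratios,
visibility percentages), not as targets the simulator re-estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReferenceGroup", "REFERENCE_GROUPS", "CLINICAL_COUNTS"]


@dataclass(frozen=True)
class ReferenceGroup:
    injected_ul: float
    kv: int
    n: int
    mean: float
    sd: float
    norm_lower: float
    norm_upper: float
    ratio: float
    #: printed ratio consistent with printed mean (one table entry is not)
    ratio_consistent: bool = True
    #: printed upper bound consistent with mean + 1.96*sd at ±0.02 µl
    upper_consistent: bool = True


#: One entry per (injected volume, kV) group.  The 10 µl @ 70 kV upper
#: bound and the 20 µl @ 100/120 kV ratios are internally inconsistent with
#: the printed mean/SD (rounding of unrounded source statistics), flagged.
REFERENCE_GROUPS: dict[tuple[float, int], ReferenceGroup] = {
    (10, 70): ReferenceGroup(10, 70, 25, 89.46, 10.14, 69.57, 109.38, 8.9, upper_consistent=False),
    (10, 100): ReferenceGroup(10, 100, 25, 73.40, 8.39, 56.94, 89.86, 7.3),
    (10, 120): ReferenceGroup(10, 120, 25, 67.48, 7.33, 53.11, 81.86, 6.7),
    (20, 70): ReferenceGroup(20, 70, 25, 148.10, 21.71, 105.54, 190.66, 7.4),
    (20, 100): ReferenceGroup(20, 100, 25, 125.10, 18.41, 89.00, 161.19, 6.2, ratio_consistent=False),
    (20, 120): ReferenceGroup(20, 120, 25, 117.14, 16.76, 84.29, 149.99, 5.8, ratio_consistent=False),
    (30, 70): ReferenceGroup(30, 70, 25, 214.80, 36.87, 142.52, 287.07, 7.2),
    (30, 100): ReferenceGroup(30, 100, 25, 188.83, 31.20, 127.67, 249.99, 6.3),
    (30, 120): ReferenceGroup(30, 120, 25, 176.48, 29.65, 118.36, 234.59, 5.9),
}

#: (injected, well identifiable) marker counts from the two patients:
#: single-energy follow-up CT and dual-energy CT respectively.
CLINICAL_COUNTS: dict[str, tuple[int, int]] = {
    "single_energy": (66, 57),
    "dual_energy": (52, 43),
}
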