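"""Descriptive comparison of two groups of per-position profiles.

At every position along a helix or striction curve each group of
structures contributes a sample of descriptor values.  The comparison is
deliberately non-parametric and descriptive (no hypothesis tests): per
group we summarize each position by the median, the quartiles and the
95% interpercentile range (IPR, 2.5th-97.5th percentile), then measure
how the two IPR intervals overlap:

* po_union — length of the intersection relative to the measure of the
  union of both intervals,
* po_a, po_b — intersection relative to each single interval,

all in percent.  The three percentages are merged into a three-class
super-score at a 90% threshold (class 1: all three below 90, strong
separation; class 2: exactly two below 90; class 3: at least two at or
above 90, no separation).  As a scatter measure, IPR lengths are summed
over maximal runs of constant class (Sigma-IPR).  Individual structures
with extreme profiles are flagged by the Hampel rule: a value is extreme
when it deviates from the position median by more than 3 scaled median
absolute deviations (scale 1.4826, the consistency factor for normal
data), and a structure is reported when it is extreme at more than two
positions of at least one descriptor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

HAMPEL_SCALE = 1.4826
HAMPEL_NSIGMA = 3.0
SUPER_SCORE_THRESHOLD = 90.0


@dataclass(frozen=True)
class PositionSummary:
    position: int
    median: float
    q25: float
    q75: float
    ipr_low: float
    ipr_high: float
    n: int

    @property
    def ipr_length(self) -> float:
        return self.ipr_high - self.ipr_low


@dataclass(frozen=True)
class OverlapResult:
    position: int
    po_union: float
    po_a: float
    po_b: float
    super_score_class: int
    ipr_len_a: float
    ipr_len_b: float


@dataclass
class OutlierReport:
    structure_id: str
    descriptor: str
    positions: list[int] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return len(self.positions) > 2


def position_summary(values, position: int = 0) -> PositionSummary:
    """Median, quartiles and 95%-IPR bounds of one position's sample.

    Percentiles use linear interpolation between closest ranks (the
    common 'type 7' rule).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q = np.percentile(v, [2.5, 25, 50, 75, 97.5])
    return PositionSummary(
        position=position,
        median=float(q[2]),
        q25=float(q[1]),
        q75=float(q[3]),
        ipr_low=float(q[0]),
        ipr_high=float(q[4]),
        n=int(v.size),
    )


def overlap_percentages(
    ipr_a: tuple[float, float], ipr_b: tuple[float, float]
) -> tuple[float, float, float]:
    """The three overlap percentages (po_union, po_a, po_b) of two IPR
    intervals, each in [0, 100].

    The union denominator is the measure of the set union
    |A| + |B| - |A ∩ B|.  Zero-length denominators: two identical point
    intervals overlap fully (100), otherwise the percentage is 0.
    """
    a_lo, a_hi = ipr_a
    b_lo, b_hi = ipr_b
    if a_hi < a_lo or b_hi < b_lo:
        raise ValueError("malformed interval (low > high)")
    inter = max(0.0, min(a_hi, b_hi) - max(a_lo, b_lo))
    len_a = a_hi - a_lo
    len_b = b_hi - b_lo
    union = len_a + len_b - inter

    def ratio(num: float, den: float) -> float:
        if den == 0.0:
            return 100.0 if (a_lo, a_hi) == (b_lo, b_hi) else 0.0
        # clamp fp overshoot so downstream classification stays in range
        return min(100.0, max(0.0, 100.0 * num / den))

    return ratio(inter, union), ratio(inter, len_a), ratio(inter, len_b)


def super_score(po_union: float, po_a: float, po_b: float) -> int:
    """Three-class separation label at a 90% threshold.

    Class 1: all three percentages < 90 (groups separate).  Class 2:
    exactly two < 90.  Class 3: two or all three >= 90 (groups overlap).
    The three classes partition all threshold patterns.
    """
    for p in (po_union, po_a, po_b):
        if not 0.0 <= p <= 100.0:
            raise ValueError("percentages must be in [0, 100]")
    n_below = sum(p < SUPER_SCORE_THRESHOLD for p in (po_union, po_a, po_b))
    if n_below == 3:
        return 1
    if n_below == 2:
        return 2
    return 3


def compare_position(
    values_a, values_b, position: int = 0
) -> tuple[PositionSummary, PositionSummary, OverlapResult]:
    """Summaries of both groups at one position plus their overlap."""
    sa = position_summary(values_a, position)
    sb = position_summary(values_b, position)
    po_u, po_a, po_b = overlap_percentages(
        (sa.ipr_low, sa.ipr_high), (sb.ipr_low, sb.ipr_high)
    )
    res = OverlapResult(
        position=position,
        po_union=po_u,
        po_a=po_a,
        po_b=po_b,
        super_score_class=super_score(po_u, po_a, po_b),
        ipr_len_a=sa.ipr_length,
        ipr_len_b=sb.ipr_length,
    )
    return sa, sb, res


@dataclass(frozen=True)
class IprRun:
    """Sigma-IPR over one maximal run of constant super-score class."""

    super_score_class: int
    start: int
    end: int
    sigma_ipr_a: float
    sigma_ipr_b: float


def ipr_sums(
    summaries_a: list[PositionSummary],
    summaries_b: list[PositionSummary],
    classes: list[int],
) -> list[IprRun]:
    """Partition positions into maximal runs of equal class and sum the
    IPR lengths of each group within each run (Sigma-IPR).  The grand
    totals over all runs equal the column sums."""
    if not (len(summaries_a) == len(summaries_b) == len(classes)):
        raise ValueError("summaries and classes must have equal length")
    runs: list[IprRun] = []
    i = 0
    n = len(classes)
    while i < n:
        j = i
        while j + 1 < n and classes[j + 1] == classes[i]:
            j += 1
        runs.append(
            IprRun(
                super_score_class=classes[i],
                start=summaries_a[i].position,
                end=summaries_a[j].position,
                sigma_ipr_a=float(sum(s.ipr_length for s in summaries_a[i : j + 1])),
                sigma_ipr_b=float(sum(s.ipr_length for s in summaries_b[i : j + 1])),
            )
        )
        i = j + 1
    return runs


def hampel_flags(
    profiles: dict[str, np.ndarray], descriptor: str = ""
) -> list[OutlierReport]:
    """Hampel outlier screen over a set of structures.

    ``profiles`` maps structure id -> per-position values (all the same
    length).  At each position a value is extreme when
    |x - median| > 3 * 1.4826 * MAD across the structures; positions with
    MAD = 0 are skipped with a warning.  Every structure gets a report;
    ``flagged`` is true when it is extreme at more than two positions.
    NaN values never count as extreme.
    """
    ids = list(profiles)
    if len(ids) < 5:
        raise ValueError("need at least 5 structures for the Hampel screen")
    mat = np.vstack([np.asarray(profiles[s], dtype=float) for s in ids])
    n_pos = mat.shape[1]
    reports = {s: OutlierReport(structure_id=s, descriptor=descriptor) for s in ids}
    for p in range(n_pos):
        col = mat[:, p]
        med = np.nanmedian(col)
        mad = np.nanmedian(np.abs(col - med))
        if mad == 0.0 or np.isnan(mad):
            warnings.warn(f"position {p + 1}: MAD = 0, skipped", stacklevel=2)
            continue
        cutoff = HAMPEL_NSIGMA * HAMPEL_SCALE * mad
        for i, s in enumerate(ids):
            if not np.isnan(col[i]) and abs(col[i] - med) > cutoff:
                reports[s].positions.append(p + 1)
    return [reports[s] for s in ids]


def comparison_tsv(
    summaries_a: list[PositionSummary],
    summaries_b: list[PositionSummary],
    overlaps: list[OverlapResult],
) -> str:
    """Full per-position group-comparison table as TSV."""
    lines = [
        "position\tmedian_a\tmedian_b\tipr_low_a\tipr_high_a\tipr_low_b\t"
        "ipr_high_b\tpo_union\tpo_a\tpo_b\tclass\tipr_len_a\tipr_len_b"
    ]
    for sa, sb, ov in zip(summaries_a, summaries_b, overlaps):
        lines.append(
            f"{ov.position}\t{sa.median!r}\t{sb.median!r}\t{sa.ipr_low!r}\t"
            f"{sa.ipr_high!r}\t{sb.ipr_low!r}\t{sb.ipr_high!r}\t"
            f"{ov.po_union:.1f}\t{ov.po_a:.1f}\t{ov.po_b:.1f}\t"
            f"{ov.super_score_class}\t{ov.ipr_len_a!r}\t{ov.ipr_len_b!r}"
        )
    return "\n".join(lines) + "\n"
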