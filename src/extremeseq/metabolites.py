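"""Carrier-group metabolite contrasts.

Samples are partitioned by locus-variant carrier status crossed with
case/control group; plasma metabolite levels (anandamide, 2-AG) are compared
between groups with a pooled-variance two-sample t-test computed from group
summaries, plus the percent difference of group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

GROUP_LABELS = ("carrier-case", "carrier-control", "noncarrier-case", "noncarrier-control")


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: Optional[float]  # pmol/ml; None when n == 0
    sd: Optional[float]

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.n == 0 and (self.mean is not None or self.sd is not None):
            raise ValueError("mean/sd must be absent for an empty group")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")


@dataclass
class TTestResult:
    t: float
    df: int
    p_two_sided: float
    percent_difference: float


def partition_by_carrier(
    carrier: np.ndarray,
    status: np.ndarray,
    values: np.ndarray,
) -> tuple[dict[str, GroupSummary], int]:
    """Summarize a metabolite by carrier status x case/control group.

    ``values`` may contain NaN for unmeasured samples; those are dropped per
    metabolite, and the dropped count is returned alongside the summaries.
    """
    carrier = np.asarray(carrier, dtype=bool)
    status = np.asarray(status, dtype=bool)
    values = np.asarray(values, dtype=float)
    measured = ~np.isnan(values)
    n_dropped = int((~measured).sum())
    groups = {
        "carrier-case": carrier & status,
        "carrier-control": carrier & ~status,
        "noncarrier-case": ~carrier & status,
        "noncarrier-control": ~carrier & ~status,
    }
    out = {}
    for label, mask in groups.items():
        v = values[mask & measured]
        if v.size == 0:
            out[label] = GroupSummary(label, 0, None, None)
        else:
            sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
            out[label] = GroupSummary(label, int(v.size), float(v.mean()), sd)
    return out, n_dropped


def pooled_t_from_summaries(g1: GroupSummary, g2: GroupSummary) -> TTestResult:
    """Two-sided pooled-variance t-test from (n, mean, sd) summaries.

    sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2);
    t = (m1-m2) / (sp * sqrt(1/n1 + 1/n2)), df = n1+n2-2.
    """
    if g1.n < 2 or g2.n < 2:
        raise ValueError("pooled t-test needs n >= 2 in both groups")
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    se = np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    t = (g1.mean - g2.mean) / se if se > 0 else 0.0
    p = float(2 * stats.t.sf(abs(t), df)) if se > 0 else 1.0
    pct = percent_difference(g1.mean, g2.mean) if g2.mean and g2.mean > 0 else float("nan")
    return TTestResult(t=float(t), df=df, p_two_sided=p, percent_difference=pct)


def percent_difference(m1: float, m2: float) -> float:
    """100 * (m1 - m2) / m2; report alongside its nearest-integer rounding."""
    if m2 <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (m1 - m2) / m2
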