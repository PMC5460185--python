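"""Shared statistics helpers: masked Pearson correlation and Welch's t-test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from hic3d.errors import ValidationError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError("p-value outside [0, 1]")


def welch_t(sample_a, sample_b) -> TestResult:
    """Two-sided Welch's unequal-variances t-test with Satterthwaite df."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, 1.0, float(len(a) + len(b) - 2),
                              float(a.mean()), float(b.mean()), len(a), len(b))
        raise ValidationError("both samples are degenerate (zero variance)")
    sa, sb = va / len(a), vb / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(min(p, 1.0)), float(df),
                      float(a.mean()), float(b.mean()), len(a), len(b))


def masked_pearson(x, y, mask=None) -> float:
    """Pearson r over jointly unmasked entries (``mask`` True = excluded)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("inputs have different shapes")
    if mask is None:
        mask = np.zeros(x.shape, dtype=bool)
    keep = ~np.asarray(mask, dtype=bool) & np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValidationError("need at least 3 jointly unmasked entries")
    xs, ys = x[keep], y[keep]
    if xs.std() == 0 or ys.std() == 0:
        raise ValidationError("constant input under the mask")
    return float(np.corrcoef(xs, ys)[0, 1])
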