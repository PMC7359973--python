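"""Agreement statistics for paired dose measurements and paired ratings.

The comparison battery treats the Ho-only measurement as the reference:
Bland–Altman limits of agreement (mean difference +- the coefficient of
reproducibility, CRP = 1.96 x SD of the paired differences), Pearson's r,
a two-sided paired t test, and Cohen's kappa for categorical rater
agreement. Sample (n-1) standard deviations are used throughout, and
quantile summaries use linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "BlandAltmanResult",
    "KappaResult",
    "bland_altman",
    "pearson_r",
    "paired_t_test",
    "cohens_kappa",
    "summarize_median_qd",
]


@dataclass
class PairedSample:
    """Paired measurements; x is the reference (Ho-only), y the comparison (DI)."""

    x: np.ndarray
    y: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1D arrays")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("paired samples must be finite")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def differences(self) -> np.ndarray:
        return self.y - self.x


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    crp: float
    loa_lower: float
    loa_upper: float


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    observed_agreement: float
    expected_agreement: float


def bland_altman(s: PairedSample) -> BlandAltmanResult:
    """Limits of agreement: mean difference +- CRP, CRP = 1.96 x sample SD."""
    if s.n < 2:
        raise ValueError("Bland-Altman requires at least 2 pairs")
    d = s.differences
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    crp = 1.96 * sd
    return BlandAltmanResult(mean, sd, crp, mean - crp, mean + crp)


def pearson_r(s: PairedSample) -> float:
    if s.x.std() == 0 or s.y.std() == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(sps.pearsonr(s.x, s.y).statistic)


def paired_t_test(s: PairedSample) -> tuple[float, float]:
    """t = mean(d) / (sd(d)/sqrt(n)), df = n - 1, two-sided p."""
    d = s.differences
    n = s.n
    if n < 2:
        raise ValueError("paired t test requires at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate differences: zero standard deviation")
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 1))
    return t, p


def cohens_kappa(ratings_a, ratings_b) -> KappaResult:
    """Chance-corrected agreement between two raters over a shared category
    set: kappa = (p_o - p_e) / (1 - p_e)."""
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be equal-length non-empty 1D sequences")
    cats = np.unique(np.concatenate([a, b]))
    p_o = float((a == b).mean())
    pa = np.array([(a == c).mean() for c in cats])
    pb = np.array([(b == c).mean() for c in cats])
    p_e = float((pa * pb).sum())
    if p_e == 1.0:
        raise ValueError("expected agreement is 1 (both raters constant); kappa undefined")
    return KappaResult(float((p_o - p_e) / (1.0 - p_e)), p_o, p_e)


def summarize_median_qd(values) -> tuple[float, float]:
    """Median and quartile deviation (IQR/2), linear-interpolation quantiles."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method="linear")
    return float(med), float((q3 - q1) / 2.0)
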