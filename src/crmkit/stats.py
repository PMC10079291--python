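"""Inferential toolkit: Welch t, Cohen's d, one-sided Fisher exact,
qPCR percent-input with propagated replicate error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats as sps


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test (two-sided, unequal variances).

    Returns the t statistic, the Welch–Satterthwaite fractional degrees of
    freedom, and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("zero variance in both samples")
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def cohens_d(x: Sequence[float], y: Sequence[float]) -> float:
    """Cohen's d with the pooled (n−1 weighted) standard deviation.

    Sign follows mean(x) − mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    pooled_var = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / math.sqrt(pooled_var))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b / c, d): rows = in-category vs not, columns = in-group vs not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


def fisher_greater(table: ContingencyTable2x2) -> float:
    """One-sided (greater) Fisher exact p-value.

    The upper-tail hypergeometric probability of observing at least ``a``
    successes given the table margins.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total = a + b + c + d
    # population n_total, (a+b) successes, draw (a+c); tail P(X >= a)
    return float(sps.hypergeom.sf(a - 1, n_total, a + b, a + c))


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def propagate_ratio_error(
    a: float, sigma_a: float, b: float, sigma_b: float
) -> tuple[float, float]:
    """Quotient a/b with the quadrature-propagated standard error.

    sigma_r = |r| * sqrt((sigma_a/a)^2 + (sigma_b/b)^2).
    """
    if b == 0:
        raise ValueError("denominator is zero")
    if sigma_a < 0 or sigma_b < 0:
        raise ValueError("sigmas must be >= 0")
    if a == 0:
        if sigma_a > 0:
            raise ValueError("relative error undefined for a = 0 with sigma_a > 0")
        return 0.0, 0.0
    r = a / b
    sigma_r = abs(r) * math.sqrt((sigma_a / a) ** 2 + (sigma_b / b) ** 2)
    return r, sigma_r


@dataclass(frozen=True)
class QpcrMeasurement:
    """ChIP-qPCR Ct values for one target locus.

    ``input_dilution`` is the fold-dilution of the input aliquot relative to
    one embryo equivalency; the input Ct is adjusted by log2 of it before
    comparison with the IP Ct.
    """

    target_id: str
    ip_ct: tuple[float, ...]
    input_ct: tuple[float, ...]
    input_dilution: float = 1.0

    def __post_init__(self) -> None:
        if not self.ip_ct or not self.input_ct:
            raise ValueError("need at least one replicate for IP and input")
        if self.input_dilution <= 0:
            raise ValueError("dilution factor must be positive")
        if any(not math.isfinite(c) for c in self.ip_ct + self.input_ct):
            raise ValueError("Ct values must be finite")


def percent_input(m: QpcrMeasurement) -> tuple[float, float | None]:
    """DNA recovery of the IP as a percentage of the (dilution-adjusted) input.

    percent = 100 × 2^(adjusted input Ct − mean IP Ct), with
    adjusted input Ct = mean input Ct − log2(dilution). The standard error
    combines the replicate Ct spreads (sample sd, delta method on the
    exponential scale) through the ratio error-propagation rule; it is None
    when either side has a single replicate.
    """
    mean_ip = float(np.mean(m.ip_ct))
    adjusted_input = float(np.mean(m.input_ct)) - math.log2(m.input_dilution)
    percent = 100.0 * 2 ** (adjusted_input - mean_ip)
    if len(m.ip_ct) < 2 or len(m.input_ct) < 2:
        return percent, None
    ln2 = math.log(2.0)
    # linear-scale quantities with delta-method sigmas from Ct spreads
    ip_lin = 2.0**-mean_ip
    input_lin = 2.0**-adjusted_input
    sigma_ip = ip_lin * ln2 * float(np.std(m.ip_ct, ddof=1))
    sigma_input = input_lin * ln2 * float(np.std(m.input_ct, ddof=1))
    _, sigma_ratio = propagate_ratio_error(ip_lin, sigma_ip, input_lin, sigma_input)
    return percent, 100.0 * sigma_ratio
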