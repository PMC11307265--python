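"""Disproportionality statistics on 2x2 (and r x c) contingency tables.

Conventions:

* ROR = (a*d)/(b*c) with a Woolf (log-normal) 95% CI.
* PRR = [a/(a+b)] / [c/(c+d)] with its log-normal CI.
* Pearson chi-square, no continuity correction by default (Yates optional).
* A table with any zero cell is "not countable" under the default
  no-correction policy; the Haldane-Anscombe +0.5 correction is opt-in.
* Signal-of-disproportionate-reporting rules:
  ci_rule:   PRR 95% CI lower bound >= 1 and case count >= 3
  chi2_rule: PRR > 2 and chi-square > 4
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

Z95 = 1.959964  # two-sided 95% normal quantile


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the printed-table convention), not banker's."""
    if x is None or (isinstance(x, float) and not math.isfinite(x)):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a = exposed with event, b = exposed without,
    c = comparator with event, d = comparator without."""

    a: int
    b: int
    c: int
    d: int
    exposure_label: str = "exposed"
    event_label: str = "event"
    unit: str = "pt"

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def swapped(self) -> "ContingencyTable":
        """Exposure and comparator interchanged."""
        return ContingencyTable(self.c, self.d, self.a, self.b,
                                exposure_label=f"not {self.exposure_label}",
                                event_label=self.event_label, unit=self.unit)

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class SDRFlags:
    ci_rule: bool
    chi2_rule: bool
    reason: Optional[str] = None

    @property
    def any(self) -> bool:
        return self.ci_rule or self.chi2_rule


@dataclass
class DisproResult:
    table: ContingencyTable
    ror: float
    ror_ci: Tuple[float, float]
    prr: float
    prr_ci: Tuple[float, float]
    chi2: float
    dof: int
    p: float
    n_cases: int
    countable: bool
    sdr: SDRFlags = field(default=SDRFlags(False, False))

    def p_display(self, floor: float = 1e-4) -> str:
        if not math.isfinite(self.p):
            return "N/C"
        return "<0.0001" if self.p < floor else f"{self.p:.4f}"


def _woolf_interval(estimate: float, se: float) -> Tuple[float, float]:
    return (estimate * math.exp(-Z95 * se), estimate * math.exp(Z95 * se))


def ror(table: ContingencyTable, correction: bool = False):
    """Reporting odds ratio with Woolf 95% CI.

    Returns ``(estimate, (lower, upper))``; ``(nan, (nan, nan))`` when a
    zero cell makes the table non-countable and no correction is requested.
    Pass ``correction=True`` for the Haldane-Anscombe +0.5 adjustment.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.has_zero_cell():
        if not correction:
            return math.nan, (math.nan, math.nan)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, _woolf_interval(est, se)


def prr(table: ContingencyTable, correction: bool = False):
    """Proportional reporting ratio with its log-normal 95% CI."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if table.has_zero_cell():
        if not correction:
            return math.nan, (math.nan, math.nan)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    return est, _woolf_interval(est, se)


def chi_square_rxc(observed, correction: bool = False):
    """Pearson chi-square on an r x c table of counts.

    Returns ``(chi2, dof, p)``; a zero row/column margin yields
    ``(nan, dof, nan)`` (non-countable). ``correction`` applies Yates'
    continuity adjustment (2x2 only).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if row.min() == 0 or col.min() == 0:
        return math.nan, dof, math.nan
    expected = np.outer(row, col) / obs.sum()
    diff = np.abs(obs - expected)
    if correction and obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff ** 2 / expected).sum())
    return chi2, dof, float(sps.chi2.sf(chi2, dof))


def chi_square(table: ContingencyTable, correction: bool = False):
    """Pearson chi-square of a 2x2 table, dof = 1."""
    return chi_square_rxc([[table.a, table.b], [table.c, table.d]],
                          correction=correction)


def compute(table: ContingencyTable, correction: bool = False,
            yates: bool = False) -> DisproResult:
    """Full disproportionality result for one table (ROR, PRR, chi-square,
    SDR flags)."""
    ror_est, ror_ci = ror(table, correction=correction)
    prr_est, prr_ci = prr(table, correction=correction)
    chi2, dof, p = chi_square(table, correction=yates)
    countable = correction or not table.has_zero_cell()
    result = DisproResult(
        table=table, ror=ror_est, ror_ci=ror_ci, prr=prr_est, prr_ci=prr_ci,
        chi2=chi2, dof=dof, p=p, n_cases=table.a, countable=countable,
    )
    result.sdr = sdr_evaluate(result)
    return result


def sdr_evaluate(result: DisproResult) -> SDRFlags:
    """EMA signal-of-disproportionate-reporting rules.

    ci_rule uses weak inequalities (>= 1, >= 3); chi2_rule uses strict
    ones (> 2, > 4), exactly as stated.
    """
    if not result.countable or not math.isfinite(result.prr):
        return SDRFlags(False, False, reason="not_countable")
    ci_rule = result.prr_ci[0] >= 1.0 and result.n_cases >= 3
    chi2_rule = (result.prr > 2.0 and math.isfinite(result.chi2)
                 and result.chi2 > 4.0)
    return SDRFlags(ci_rule, chi2_rule)


def bh_adjust(p_values: Sequence[float]) -> list:
    """Benjamini-Hochberg step-up adjusted p-values (opt-in extra; the
    default reporting applies no multiplicity correction)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out.tolist()
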