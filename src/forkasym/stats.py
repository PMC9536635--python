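"""Odds ratios and the Breslow-Day homogeneity test with Tarone correction.

Used to ask whether the association between replication domain (ERD vs
LRD) and phase of better repair (early vs late S) is homogeneous across
chromatin states: one 2x2 table per state, a common Mantel-Haenszel odds
ratio, and the Breslow-Day statistic comparing each stratum's observed
a-cell with its expectation under the common OR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class OddsRatioResult:
    odds_ratio: float
    log_or: float
    se_log_or: float
    ci_low: float
    ci_high: float
    corrected: bool


@dataclass
class BreslowDayResult:
    statistic: float
    df: int
    pvalue: float
    or_mh: float
    uncorrected_statistic: float
    n_strata_used: int
    n_strata_excluded: int


def odds_ratio(table: tuple[int, int, int, int], alpha: float = 0.05) -> OddsRatioResult:
    """OR = ad/bc with a Wald CI on the log scale; the Haldane-Anscombe
    0.5 continuity correction is applied when any cell is zero."""
    a, b, c, d = (float(x) for x in table)
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    log_or = np.log(orr)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.ppf(1 - alpha / 2)
    return OddsRatioResult(
        odds_ratio=orr,
        log_or=log_or,
        se_log_or=se,
        ci_low=float(np.exp(log_or - z * se)),
        ci_high=float(np.exp(log_or + z * se)),
        corrected=corrected,
    )


def _expected_a(psi: float, r1: float, c1: float, n: float) -> float:
    """Expected a-cell under common OR psi given margins (row1 r1, col1
    c1, total n): the root of psi (r1-E)(c1-E) = E (n-r1-c1+E) that
    respects all margins."""
    lo = max(0.0, r1 + c1 - n)
    hi = min(r1, c1)
    if abs(psi - 1.0) < 1e-12:
        return r1 * c1 / n
    A = psi - 1.0
    B = -(psi * (r1 + c1) + (n - r1 - c1))
    C = psi * r1 * c1
    disc = B * B - 4 * A * C
    disc = max(disc, 0.0)
    roots = [(-B - np.sqrt(disc)) / (2 * A), (-B + np.sqrt(disc)) / (2 * A)]
    for e in roots:
        if lo - 1e-9 <= e <= hi + 1e-9:
            return float(min(max(e, lo), hi))
    raise ArithmeticError("no admissible root for expected cell")


def mantel_haenszel_or(tables: list[tuple[int, int, int, int]]) -> float:
    num = sum(a * d / (a + b + c + d) for a, b, c, d in tables)
    den = sum(b * c / (a + b + c + d) for a, b, c, d in tables)
    if den == 0:
        raise ValueError("Mantel-Haenszel OR undefined (zero denominator)")
    return num / den


def breslow_day_tarone(tables: list[tuple[int, int, int, int]]) -> BreslowDayResult:
    """Breslow-Day homogeneity test of odds ratios with Tarone's
    correction.

    Strata with a zero margin (an empty row or column) carry no OR
    information and are excluded with a warning, reducing the degrees of
    freedom. With a single informative stratum the statistic is 0 with
    df 0 and an undefined (NaN) p-value.
    """
    used = []
    excluded = 0
    for t in tables:
        a, b, c, d = t
        if min(a + b, c + d, a + c, b + d) <= 0:
            excluded += 1
            continue
        used.append(tuple(float(x) for x in t))
    if excluded:
        warnings.warn(f"{excluded} strata with degenerate margins excluded", stacklevel=2)
    if not used:
        raise ValueError("no informative strata")
    psi = mantel_haenszel_or(used)
    if len(used) == 1:
        return BreslowDayResult(0.0, 0, float("nan"), psi, 0.0, 1, excluded)
    resid_sum = 0.0
    var_sum = 0.0
    bd = 0.0
    for a, b, c, d in used:
        n = a + b + c + d
        e = _expected_a(psi, a + b, a + c, n)
        # fitted cells under the common OR
        fb = (a + b) - e
        fc = (a + c) - e
        fd = n - (a + b) - (a + c) + e
        v = 1.0 / (1.0 / max(e, 1e-12) + 1.0 / max(fb, 1e-12) + 1.0 / max(fc, 1e-12) + 1.0 / max(fd, 1e-12))
        bd += (a - e) ** 2 / v
        resid_sum += a - e
        var_sum += v
    tarone = bd - resid_sum**2 / var_sum
    tarone = max(tarone, 0.0)
    df = len(used) - 1
    pvalue = float(sps.chi2.sf(tarone, df))
    return BreslowDayResult(
        statistic=float(tarone),
        df=df,
        pvalue=pvalue,
        or_mh=float(psi),
        uncorrected_statistic=float(bd),
        n_strata_used=len(used),
        n_strata_excluded=excluded,
    )
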