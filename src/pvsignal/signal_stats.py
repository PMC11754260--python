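"""Disproportionality statistics: ROR, PRR with chi-square, and BCPNN.

All three estimators work on the 2x2 table (a, b, c, d):

* ROR = (a*d)/(b*c), with a lognormal Wald 95% CI from
  se = sqrt(1/a + 1/b + 1/c + 1/d).
* PRR = (a/(a+b)) / (c/(c+d)), se = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)),
  plus a Pearson chi-square (Yates-corrected by default).
* BCPNN information component IC = log2(a*N / ((a+b)*(a+c))), with the
  closed-form posterior approximations E(IC), V(IC) under conjugate Beta
  priors and the signal bound IC025 = E(IC) - 2*sqrt(V(IC)).

Signal thresholds: ROR requires a >= 3 and CI lower bound > 1; PRR requires
a >= 3, CI lower bound > 1 and chi-square > 4; BCPNN requires IC025 > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .contingency import ContingencyTable

Z95 = 1.96  # two-sided 95% normal multiplier, as conventionally printed
LN2 = math.log(2.0)

#: default exclusion list for IC ranking: the merged device-handling term and
#: common indication / therapeutic-failure terms
DEFAULT_RANK_EXCLUSIONS: tuple[str, ...] = (
    "Device use issue",
    "Wrong technique in product usage process",
    "Product use issue",
    "Chronic obstructive pulmonary disease",
    "Asthma",
    "Condition aggravated",
    "Disease progression",
    "Drug ineffective",
    "Product dose omission",
    "Off label use",
)


@dataclass(frozen=True)
class BcpnnPriors:
    """Conjugate prior constants for the BCPNN posterior.

    Defaults are the standard symmetric choice: gamma11 = alpha1 = beta1 = 1,
    alpha = beta = 2.  ``gamma`` is recomputed per table so the prior expected
    joint probability matches the product of the marginal prior expectations.
    """

    alpha: float = 2.0
    beta: float = 2.0
    alpha1: float = 1.0
    beta1: float = 1.0
    gamma11: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "beta", "alpha1", "beta1", "gamma11"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior constant {name} must be positive")

    def gamma(self, a, b, c, d):
        n = a + b + c + d
        return (
            self.gamma11 * (n + self.alpha) * (n + self.beta)
            / ((a + b + self.alpha1) * (a + c + self.beta1))
        )


DEFAULT_PRIORS = BcpnnPriors()


class RorResult(NamedTuple):
    ror: float
    ci_low: float
    ci_high: float
    se: float


class PrrResult(NamedTuple):
    prr: float
    ci_low: float
    ci_high: float
    se: float
    chisq: float


class BcpnnResult(NamedTuple):
    ic: float
    eic: float
    vic: float
    ic025: float


def _cells(t: ContingencyTable, continuity: bool) -> tuple[float, float, float, float]:
    a, b, c, d = t.as_tuple()
    if continuity and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float(a), float(b), float(c), float(d)


def ror(t: ContingencyTable, continuity: bool = False) -> RorResult:
    """Reporting odds ratio with its lognormal Wald 95% CI.

    A zero cell makes the estimate non-evaluable (NaNs) unless ``continuity``
    enables the Haldane +0.5 correction.
    """
    a, b, c, d = _cells(t, continuity)
    if min(a, b, c, d) == 0:
        return RorResult(math.nan, math.nan, math.nan, math.nan)
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), se)


def prr(t: ContingencyTable, yates: bool = True, continuity: bool = False) -> PrrResult:
    """Proportional reporting ratio, its 95% CI, and the Pearson chi-square.

    ``yates`` selects the continuity-corrected chi-square (default); the
    uncorrected statistic is available for cross-checks.
    """
    a, b, c, d = _cells(t, continuity)
    chisq = _chisq(a, b, c, d, yates=yates)
    if a == 0 or c == 0 or (a + b) == 0 or (c + d) == 0:
        return PrrResult(math.nan, math.nan, math.nan, math.nan, chisq)
    est = (a / (a + b)) / (c / (c + d))
    se_sq = 1 / a - 1 / (a + b) + 1 / c - 1 / (c + d)
    se = math.sqrt(max(se_sq, 0.0))
    return PrrResult(est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se), se, chisq)


def _chisq(a, b, c, d, yates: bool):
    n = a + b + c + d
    r1, r0, c1, c0 = a + b, c + d, a + c, b + d
    denom = r1 * r0 * c1 * c0
    if denom == 0:
        return math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / denom


def bcpnn(t: ContingencyTable, priors: BcpnnPriors = DEFAULT_PRIORS) -> BcpnnResult:
    """Information component with closed-form posterior mean and variance.

    ``ic`` is the raw log2 observed-to-expected ratio (``-inf`` when a = 0);
    ``eic``/``vic`` are the standard closed-form approximations to the
    posterior mean and variance of the IC under the Beta priors, and
    ``ic025 = eic - 2*sqrt(vic)``.
    """
    a, b, c, d = (float(x) for x in t.as_tuple())
    n = a + b + c + d
    g = priors.gamma(a, b, c, d)
    p = priors

    if a == 0 or (a + b) == 0 or (a + c) == 0:
        ic = -math.inf
    else:
        ic = math.log2(a * n / ((a + b) * (a + c)))

    eic = math.log2(
        (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
        / ((n + g) * (a + b + p.alpha1) * (a + c + p.beta1))
    )
    vic = (
        (n - a + g - p.gamma11) / ((a + p.gamma11) * (1 + n + g))
        + (n - (a + b) + p.alpha - p.alpha1) / ((a + b + p.alpha1) * (1 + n + p.alpha))
        + (n - (a + c) + p.beta - p.beta1) / ((a + c + p.beta1) * (1 + n + p.beta))
    ) / (LN2 * LN2)
    return BcpnnResult(ic, eic, vic, eic - 2.0 * math.sqrt(vic))


def bcpnn_posterior_moments(
    t: ContingencyTable, priors: BcpnnPriors = DEFAULT_PRIORS
) -> tuple[float, float]:
    """Exact posterior mean and variance of the IC under the same model.

    The closed forms used by :func:`bcpnn` are first-order (delta-method)
    approximations; this evaluates the exact moments of
    ``log2(p_xy / (p_x p_y))`` under the independent Beta posteriors via
    digamma/trigamma functions.  Useful as an analytic cross-check of
    Monte-Carlo oracles.
    """
    a, b, c, d = (float(x) for x in t.as_tuple())
    n = a + b + c + d
    p = priors
    g = p.gamma(a, b, c, d)
    u = (a + p.gamma11, a + b + p.alpha1, a + c + p.beta1)
    s = (n + g, n + p.alpha, n + p.beta)
    mean = (
        special.digamma(u[0]) - special.digamma(s[0])
        - special.digamma(u[1]) + special.digamma(s[1])
        - special.digamma(u[2]) + special.digamma(s[2])
    ) / LN2
    var = sum(
        special.polygamma(1, ui) - special.polygamma(1, si) for ui, si in zip(u, s)
    ) / (LN2 * LN2)
    return float(mean), float(var)


# ---------------------------------------------------------------------------
# vectorized evaluation and threshold logic


def compute_signals(
    tables: Mapping[str, ContingencyTable] | pd.DataFrame,
    level: str = "PT",
    stratum: str = "overall",
    priors: BcpnnPriors = DEFAULT_PRIORS,
    yates: bool = True,
    continuity: bool = False,
) -> pd.DataFrame:
    """Evaluate all three statistics over a set of contingency tables.

    Accepts either a mapping event -> :class:`ContingencyTable` or a frame
    with ``event, a, b, c, d`` columns.  Returns one row per event with the
    estimates, intervals, chi-square, IC quantities and threshold flags.
    """
    if isinstance(tables, pd.DataFrame):
        frame = tables.copy()
        events = frame["event"].to_numpy()
        a = frame["a"].to_numpy(dtype=float)
        b = frame["b"].to_numpy(dtype=float)
        c = frame["c"].to_numpy(dtype=float)
        d = frame["d"].to_numpy(dtype=float)
    else:
        events = np.array(list(tables.keys()), dtype=object)
        cells = np.array([tables[e].as_tuple() for e in events], dtype=float).reshape(-1, 4)
        a, b, c, d = cells.T

    if len(events) == 0:
        return pd.DataFrame(columns=_SIGNAL_COLUMNS)

    a0, b0, c0, d0 = a, b, c, d
    if continuity:
        zero = np.minimum.reduce([a, b, c, d]) == 0
        a = np.where(zero, a + 0.5, a)
        b = np.where(zero, b + 0.5, b)
        c = np.where(zero, c + 0.5, c)
        d = np.where(zero, d + 0.5, d)
    n = a + b + c + d

    with np.errstate(divide="ignore", invalid="ignore"):
        ok_ror = np.minimum.reduce([a, b, c, d]) > 0
        ror_est = np.where(ok_ror, (a * d) / np.where(ok_ror, b * c, 1.0), np.nan)
        se_ror = np.where(ok_ror, np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), np.nan)
        ror_lo = ror_est * np.exp(-Z95 * se_ror)
        ror_hi = ror_est * np.exp(Z95 * se_ror)

        ok_prr = (a > 0) & (c > 0)
        prr_est = np.where(ok_prr, (a / (a + b)) / np.where(ok_prr, c / (c + d), 1.0), np.nan)
        se_prr = np.where(
            ok_prr, np.sqrt(np.maximum(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d), 0.0)), np.nan
        )
        prr_lo = prr_est * np.exp(-Z95 * se_prr)
        prr_hi = prr_est * np.exp(Z95 * se_prr)

        diff = np.abs(a * d - b * c)
        if yates:
            diff = np.maximum(diff - n / 2.0, 0.0)
        denom = (a + b) * (c + d) * (a + c) * (b + d)
        chisq = np.where(denom > 0, n * diff * diff / np.where(denom > 0, denom, 1.0), np.nan)

        p = priors
        g = p.gamma(a, b, c, d)
        ic = np.where(a0 > 0, np.log2(a * n / ((a + b) * (a + c))), -np.inf)
        eic = np.log2(
            (a + p.gamma11) * (n + p.alpha) * (n + p.beta)
            / ((n + g) * (a + b + p.alpha1) * (a + c + p.beta1))
        )
        vic = (
            (n - a + g - p.gamma11) / ((a + p.gamma11) * (1 + n + g))
            + (n - (a + b) + p.alpha - p.alpha1) / ((a + b + p.alpha1) * (1 + n + p.alpha))
            + (n - (a + c) + p.beta - p.beta1) / ((a + c + p.beta1) * (1 + n + p.beta))
        ) / (LN2 * LN2)
        ic025 = eic - 2.0 * np.sqrt(vic)

    out = pd.DataFrame(
        {
            "event": events,
            "level": level,
            "stratum": stratum,
            "a": a0.astype(int) if np.allclose(a0, np.round(a0)) else a0,
            "b": b0.astype(int) if np.allclose(b0, np.round(b0)) else b0,
            "c": c0.astype(int) if np.allclose(c0, np.round(c0)) else c0,
            "d": d0.astype(int) if np.allclose(d0, np.round(d0)) else d0,
            "ror": ror_est,
            "ror_ci_low": ror_lo,
            "ror_ci_high": ror_hi,
            "se_ln_ror": se_ror,
            "prr": prr_est,
            "prr_ci_low": prr_lo,
            "prr_ci_high": prr_hi,
            "se_ln_prr": se_prr,
            "chisq": chisq,
            "ic": ic,
            "eic": eic,
            "vic": vic,
            "ic025": ic025,
        }
    )
    return apply_thresholds(out)


_SIGNAL_COLUMNS = [
    "event", "level", "stratum", "a", "b", "c", "d",
    "ror", "ror_ci_low", "ror_ci_high", "se_ln_ror",
    "prr", "prr_ci_low", "prr_ci_high", "se_ln_prr",
    "chisq", "ic", "eic", "vic", "ic025",
    "ror_signal", "prr_signal", "bcpnn_signal", "all_three",
]


def apply_thresholds(results: pd.DataFrame) -> pd.DataFrame:
    """Attach the boolean signal flags.

    ror_signal: a >= 3 and ROR CI lower bound > 1.
    prr_signal: a >= 3, PRR CI lower bound > 1 and chi-square > 4.
    bcpnn_signal: IC025 > 0 (strict).
    all_three: conjunction.  Non-evaluable statistics flag False.
    """
    out = results.copy()
    a = out["a"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        ror_ok = np.nan_to_num(out["ror_ci_low"].to_numpy(dtype=float), nan=-np.inf) > 1.0
        prr_ok = (
            (np.nan_to_num(out["prr_ci_low"].to_numpy(dtype=float), nan=-np.inf) > 1.0)
            & (np.nan_to_num(out["chisq"].to_numpy(dtype=float), nan=-np.inf) > 4.0)
        )
        ic_ok = np.nan_to_num(out["ic025"].to_numpy(dtype=float), nan=-np.inf) > 0.0
    out["ror_signal"] = (a >= 3) & ror_ok
    out["prr_signal"] = (a >= 3) & prr_ok
    out["bcpnn_signal"] = ic_ok
    out["all_three"] = out["ror_signal"] & out["prr_signal"] & out["bcpnn_signal"]
    return out


def rank_by_ic(
    results: pd.DataFrame,
    k: int,
    exclude: Sequence[str] = DEFAULT_RANK_EXCLUSIONS,
) -> pd.DataFrame:
    """Top-k events by IC, after removing excluded terms.

    Sorted by IC descending, ties broken by ``a`` descending then event name
    ascending.  Exclusion matching is case-insensitive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    excluded = {e.casefold() for e in exclude}
    df = results[~results["event"].str.casefold().isin(excluded)].copy()
    df = df.sort_values(
        ["ic", "a", "event"], ascending=[False, False, True], kind="mergesort"
    )
    return df.head(k).reset_index(drop=True)
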