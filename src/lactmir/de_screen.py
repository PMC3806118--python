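"""Differential-expression screening of miRNA count libraries.

The screen compares two un-replicated small-RNA libraries per miRNA with an
exact count-ratio test: given ``x`` reads in library 1 (total clean reads
``N1``), the probability of observing ``y`` reads in library 2 (total ``N2``)
under equal underlying abundance is

    p(y | x) = (N2/N1)^y (x+y)! / ( x! y! (1 + N2/N1)^(x+y+1) )

which is the negative-binomial predictive NB(x+1, N1/(N1+N2)) — the Poisson
rate posterior under a flat prior, integrated out.  The lower tail
``C = P(Y <= y | x)`` and upper tail ``D = P(Y >= y | x)`` both include the
observed point, so C + D >= 1; the default two-sided p-value is
``min(1, 2 * min(C, D))``.

A miRNA is retained when all three rules hold:

* normalized expression above ``min_expression`` reads per million in at
  least one stage,
* |log2 fold change| strictly above ``fc_cut`` (infinite fold changes from a
  single zero count pass; 0/0 never does),
* exact-test p-value strictly below ``p_cut``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io_tables import ReadCountTable

__all__ = [
    "ScreenConfig",
    "DifferentialResult",
    "normalize",
    "expression_profile",
    "log2_fold_change",
    "ac_point_prob",
    "ac_tails",
    "ac_pvalue",
    "differential_table",
    "screen_mirnas",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the three screening rules.

    min_expression : reads-per-million floor (kept if above it in >=1 stage)
    fc_cut         : absolute log2 fold-change threshold (strict)
    p_cut          : p-value threshold (strict)
    count_basis    : "raw" tests the raw counts against library totals;
                     "rounded-normalized" tests round(rpm) against 10^6,
                     mirroring a literal reading of running the exact test on
                     normalized expressions.
    sided          : "two" -> min(1, 2*min(C, D)); "one" -> min(C, D)
    """

    min_expression: float = 50.0
    fc_cut: float = 1.0
    p_cut: float = 0.01
    count_basis: Literal["raw", "rounded-normalized"] = "raw"
    sided: Literal["two", "one"] = "two"

    def __post_init__(self) -> None:
        if self.min_expression <= 0 or self.fc_cut <= 0 or self.p_cut <= 0:
            raise ValueError("all thresholds must be > 0")
        if self.count_basis not in ("raw", "rounded-normalized"):
            raise ValueError(f"unknown count_basis {self.count_basis!r}")
        if self.sided not in ("two", "one"):
            raise ValueError(f"unknown sidedness {self.sided!r}")


@dataclass
class DifferentialResult:
    """Per-miRNA outcome of the two-library comparison."""

    x: int
    y: int
    n1: int
    n2: int
    h_expr: float
    s_expr: float
    log2_fc: float
    tail_c: float
    tail_d: float
    p_value: float
    significant: bool


def normalize(count: float, total_clean_reads: float) -> float:
    """Reads-per-million: count / total clean reads x 10^6."""
    if total_clean_reads <= 0:
        raise ValueError("total_clean_reads must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / total_clean_reads * 1_000_000


def expression_profile(counts: ReadCountTable) -> pd.DataFrame:
    """Normalized (reads-per-million) expression, miRNA x stage."""
    totals = pd.Series(counts.total_clean_reads, dtype="float64")
    return counts.counts / totals[counts.libraries] * 1_000_000


def log2_fold_change(h: float, s: float) -> float:
    """log2(H/S) with sentinel values for zero expression.

    Returns ``+inf`` when only S is zero, ``-inf`` when only H is zero and
    ``nan`` (never significant) when both are.
    """
    if h < 0 or s < 0:
        raise ValueError("expressions must be >= 0")
    if h == 0 and s == 0:
        return math.nan
    if s == 0:
        return math.inf
    if h == 0:
        return -math.inf
    return math.log2(h / s)


def _check_counts(x, y, n1, n2) -> None:
    x, y = np.asarray(x), np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be >= 0")
    if np.any(np.asarray(n1) <= 0) or np.any(np.asarray(n2) <= 0):
        raise ValueError("library totals must be > 0")


def ac_point_prob(x, y, n1, n2):
    """Exact probability p(y | x) of the count-ratio test.

    Evaluated in log-gamma space, so it does not overflow for counts up to
    at least 10^6.  Accepts scalars or numpy arrays (broadcast).
    """
    _check_counts(x, y, n1, n2)
    x = np.asarray(x, dtype="float64")
    y = np.asarray(y, dtype="float64")
    n1 = np.asarray(n1, dtype="float64")
    n2 = np.asarray(n2, dtype="float64")
    # ratios computed before taking logs: keeps symmetric cases exact
    log_p = (
        gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        + y * np.log(n2 / (n1 + n2))
        + (x + 1) * np.log(n1 / (n1 + n2))
    )
    out = np.exp(log_p)
    return float(out) if out.ndim == 0 else out


def ac_tails(x, y, n1, n2):
    """Lower and upper cumulative tails (C, D) of the count-ratio test.

    Both tails include the observed count, so ``C + D = 1 + p(y|x)``.  The
    infinite upper sum is evaluated through the negative-binomial survival
    function (regularized incomplete beta), not by truncation.
    """
    _check_counts(x, y, n1, n2)
    x = np.asarray(x)
    y = np.asarray(y)
    n1 = np.asarray(n1, dtype="float64")
    n2 = np.asarray(n2, dtype="float64")
    p_success = n1 / (n1 + n2)
    tail_c = stats.nbinom.cdf(y, x + 1, p_success)
    tail_d = stats.nbinom.sf(y - 1, x + 1, p_success)
    if np.ndim(tail_c) == 0:
        return float(tail_c), float(tail_d)
    return tail_c, tail_d


def ac_pvalue(x, y, n1, n2, sided: Literal["two", "one"] = "two"):
    """Exact-test p-value; two-sided doubles the smaller tail, capped at 1."""
    tail_c, tail_d = ac_tails(x, y, n1, n2)
    smaller = np.minimum(tail_c, tail_d)
    if sided == "two":
        p = np.minimum(1.0, 2.0 * smaller)
    elif sided == "one":
        p = smaller
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    return float(p) if np.ndim(p) == 0 else p


def differential_table(
    counts: ReadCountTable,
    stage_pair: tuple[str, str] = ("peak", "early"),
    cfg: ScreenConfig | None = None,
) -> dict[str, DifferentialResult]:
    """Exact-test results for every miRNA between the named stage pair.

    ``stage_pair = (h_stage, s_stage)`` names the numerator and denominator
    of the fold change; x/N1 come from the h library, y/N2 from the s
    library.  Which stage plays numerator is a caller decision.
    """
    cfg = cfg or ScreenConfig()
    h_stage, s_stage = stage_pair
    for stage in (h_stage, s_stage):
        if stage not in counts.libraries:
            raise ValueError(f"unknown stage label {stage!r}; have {counts.libraries}")
    profile = expression_profile(counts)
    n1 = counts.total_clean_reads[h_stage]
    n2 = counts.total_clean_reads[s_stage]

    x_raw = counts.counts[h_stage].to_numpy()
    y_raw = counts.counts[s_stage].to_numpy()
    if cfg.count_basis == "raw":
        x_arr, y_arr, n1_eff, n2_eff = x_raw, y_raw, n1, n2
    else:
        x_arr = np.rint(profile[h_stage].to_numpy()).astype("int64")
        y_arr = np.rint(profile[s_stage].to_numpy()).astype("int64")
        n1_eff = n2_eff = 1_000_000

    tail_c, tail_d = ac_tails(x_arr, y_arr, n1_eff, n2_eff)
    tail_c = np.atleast_1d(tail_c)
    tail_d = np.atleast_1d(tail_d)
    smaller = np.minimum(tail_c, tail_d)
    p_values = np.minimum(1.0, 2.0 * smaller) if cfg.sided == "two" else smaller

    results: dict[str, DifferentialResult] = {}
    max_expr = profile.max(axis=1)
    for i, mirna in enumerate(counts.mirnas):
        h = float(profile.at[mirna, h_stage])
        s = float(profile.at[mirna, s_stage])
        fc = log2_fold_change(h, s)
        p = float(p_values[i])
        passes_fc = not math.isnan(fc) and abs(fc) > cfg.fc_cut
        passes = (
            passes_fc
            and p < cfg.p_cut
            and float(max_expr.at[mirna]) > cfg.min_expression
        )
        results[mirna] = DifferentialResult(
            x=int(x_arr[i]),
            y=int(y_arr[i]),
            n1=int(n1_eff),
            n2=int(n2_eff),
            h_expr=h,
            s_expr=s,
            log2_fc=fc,
            tail_c=float(tail_c[i]),
            tail_d=float(tail_d[i]),
            p_value=p,
            significant=passes,
        )
    return results


def screen_mirnas(
    counts: ReadCountTable,
    cfg: ScreenConfig | None = None,
    stage_pair: tuple[str, str] = ("peak", "early"),
) -> list[tuple[str, DifferentialResult]]:
    """miRNAs passing all three screening rules, sorted by miRNA id."""
    results = differential_table(counts, stage_pair=stage_pair, cfg=cfg)
    return [(m, results[m]) for m in sorted(results) if results[m].significant]
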