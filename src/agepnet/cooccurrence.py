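"""Marginal prevalences, pair/triad counts, and observed/expected ratios.

For a retained cohort of N reports, the marginal prevalence of drug *d* is
``n_d / N`` (distinct reports containing *d*).  A combination (pair or
triad) has observed prevalence ``n_obs / N`` and, under independence of its
members, expected prevalence equal to the product of the member marginal
prevalences.  The O/E ratio is observed over expected prevalence; for a
pair this reduces to ``n_obs * N / (n1 * n2)`` and for a triad to
``n_obs * N^2 / (n1 * n2 * n3)``.  Ratios above 1 mean the combination is
reported more often than its members' frequencies alone would predict.

O/E is reported as a point estimate without shrinkage or multiple-testing
correction; an optional permutation null is provided for exploration.
All sorting and comparisons are done on unrounded values; 2-decimal
half-up rounding is display-only.
"""

from __future__ import annotations

import decimal
from collections import Counter
from itertools import combinations
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .types import ReportSet


class UndefinedOERatioError(ValueError):
    """O/E requested for a combination with a zero/missing marginal count."""


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (display convention for prevalence tables)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(value))).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


def marginal_counts(report_set: ReportSet) -> Counter:
    """Number of distinct reports containing each drug."""
    counts: Counter = Counter()
    for report in report_set.reports:
        counts.update(report.drugs)
    return counts


def marginal_prevalence(report_set: ReportSet) -> pd.DataFrame:
    """Per-drug report counts and prevalences, ranked by count.

    Raises on an empty report set (prevalence undefined).  Drugs appearing
    in no report are simply absent.
    """
    n_reports = report_set.n_reports
    if n_reports == 0:
        raise ValueError("empty report set: prevalence undefined")
    counts = marginal_counts(report_set)
    rows = [
        {
            "drug": drug,
            "n": n,
            "prevalence": n / n_reports,
            "atc1": report_set.atc1_of(drug),
        }
        for drug, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["drug", "n", "prevalence", "atc1"])
    return df.sort_values(
        ["n", "drug"], ascending=[False, True], ignore_index=True
    )


def count_ksets(report_set: ReportSet, k: int) -> Counter:
    """Counts of all observed unordered k-subsets of report drug sets.

    Each report contributes each k-subset of its (set-valued) drugs exactly
    once, so a pair is counted at most once per report regardless of how
    many times its members were listed.
    """
    if k not in (2, 3):
        raise ValueError(f"k must be 2 or 3, got {k}")
    counts: Counter = Counter()
    for report in report_set.reports:
        if len(report.drugs) < k:
            continue
        for combo in combinations(sorted(report.drugs), k):
            counts[frozenset(combo)] += 1
    return counts


def oe_ratio(
    combo_counts: Mapping[frozenset, int],
    marginals: Mapping[str, int],
    n_reports: int,
) -> pd.DataFrame:
    """Observed and expected prevalence plus O/E ratio per combination.

    ``marginals`` are distinct-report counts; ``n_reports`` is the cohort
    size N shared by all prevalences (the >=2-drug retained cohort).
    """
    if n_reports < 1:
        raise ValueError("n_reports must be >= 1")
    rows = []
    for combo, n_obs in combo_counts.items():
        drugs = tuple(sorted(combo))
        member_counts = []
        for d in drugs:
            m = marginals.get(d, 0)
            if m <= 0:
                raise UndefinedOERatioError(
                    f"marginal count of {d!r} is zero; O/E undefined for "
                    f"{drugs}"
                )
            member_counts.append(m)
        obs_prev = n_obs / n_reports
        exp_prev = float(np.prod([m / n_reports for m in member_counts]))
        rows.append(
            {
                "drugs": drugs,
                "k": len(drugs),
                "n_obs": n_obs,
                "obs_prev": obs_prev,
                "exp_prev": exp_prev,
                "oe": obs_prev / exp_prev,
            }
        )
    df = pd.DataFrame(
        rows, columns=["drugs", "k", "n_obs", "obs_prev", "exp_prev", "oe"]
    )
    return df.sort_values(
        ["n_obs", "drugs"], ascending=[False, True], ignore_index=True
    )


def top_table(
    stats: pd.DataFrame, rank_by: str = "n_obs", top_n: int = 20
) -> pd.DataFrame:
    """Top rows by ``rank_by`` (``n_obs``/``n`` or ``oe``), ties alphabetical.

    Returns all rows when fewer than ``top_n`` are available.  Raw values
    are preserved; use :func:`format_table` for 2-decimal display.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    allowed = {"n_obs", "n", "oe", "prevalence"}
    if rank_by not in allowed or rank_by not in stats.columns:
        raise ValueError(f"rank_by must be one of {sorted(allowed)} and present")
    key = "drugs" if "drugs" in stats.columns else "drug"
    out = stats.copy()
    out["__tie"] = out[key].map(
        lambda v: " + ".join(v) if isinstance(v, tuple) else str(v)
    )
    out = out.sort_values(
        [rank_by, "__tie"], ascending=[False, True], ignore_index=True
    ).drop(columns="__tie")
    return out.head(top_n)


def format_table(stats: pd.DataFrame) -> pd.DataFrame:
    """Display copy: percentages and O/E at 2 decimals, half-up."""
    out = stats.copy()
    for col in ("prevalence", "obs_prev", "exp_prev"):
        if col in out.columns:
            out[col] = out[col].map(
                lambda v: f"{round_half_up(100 * v, 2):.2f}%")
    if "oe" in out.columns:
        out["oe"] = out["oe"].map(lambda v: f"{round_half_up(v, 2):.2f}")
    if "drugs" in out.columns:
        out["drugs"] = out["drugs"].map(lambda v: " + ".join(v))
    return out


def combination_table(
    report_set: ReportSet, k: int, top_n: Optional[int] = None
) -> pd.DataFrame:
    """Convenience: counts -> O/E -> (optionally) top table for one k."""
    counts = count_ksets(report_set, k)
    if not counts:
        return pd.DataFrame(
            columns=["drugs", "k", "n_obs", "obs_prev", "exp_prev", "oe"]
        )
    stats = oe_ratio(counts, marginal_counts(report_set), report_set.n_reports)
    if top_n is not None:
        stats = top_table(stats, "n_obs", top_n)
    return stats


def permutation_null(
    report_set: ReportSet,
    combos: Iterable[frozenset],
    n_permutations: int = 200,
    seed: int = 0,
    k: int = 2,
) -> pd.DataFrame:
    """Monte-Carlo null for O/E: shuffle drugs across reports, keep set sizes.

    Off the main path (the published analysis reports point estimates only);
    provided for exploratory calibration of large O/E values.
    """
    rng = np.random.default_rng(seed)
    combos = list(combos)
    sizes = [r.n_drugs for r in report_set.reports]
    pool = [d for r in report_set.reports for d in r.drugs]
    observed = count_ksets(report_set, k)
    exceed = np.zeros(len(combos))
    for _ in range(n_permutations):
        rng.shuffle(pool)
        null_counts: Counter = Counter()
        pos = 0
        for size in sizes:
            drugs = set(pool[pos:pos + size])
            pos += size
            if len(drugs) >= k:
                for combo in combinations(sorted(drugs), k):
                    fs = frozenset(combo)
                    null_counts[fs] += 1
        for i, c in enumerate(combos):
            if null_counts.get(c, 0) >= observed.get(c, 0):
                exceed[i] += 1
    return pd.DataFrame(
        {
            "drugs": [tuple(sorted(c)) for c in combos],
            "n_obs": [observed.get(c, 0) for c in combos],
            "p_null": (exceed + 1) / (n_permutations + 1),
        }
    )
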