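"""Balanced three-way fixed-effects ANOVA and Fisher's LSD mean separation.

The treatment-testing stage of the pipeline: a fully crossed, balanced
Year x Fertility x Management design with r >= 2 replicates per cell.  For a
balanced design the classical sum-of-squares decomposition is orthogonal, so
each effect's SS is computed directly from marginal means by
inclusion-exclusion; F ratios use the pooled error mean square and p-values
come from the F upper tail.  Unbalanced data are rejected outright (no
Type-II/III fallback).

A zero-variance response is reported as F = 0, p = 1 for every effect rather
than erroring, so the pipeline runs on trivial fixtures.

Fisher's least significant difference for a factor's level means is
t(1 - alpha/2, df_error) * sqrt(2 * MS_error / n_per_mean); compact letters
are assigned by the standard descending-mean sweep in which each maximal run
of means spanning less than the LSD shares a letter.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .exceptions import InvalidInputError

__all__ = ["AnovaResult", "anova3", "lsd_test"]


@dataclass
class AnovaResult:
    """ANOVA table plus the pieces LSD needs (error MS/df, cell structure)."""

    table: pd.DataFrame  # index: effect names + "error"; columns df, ss, ms, F, p, sig
    ms_error: float
    df_error: int
    factors: list[str]
    response: str
    data: pd.DataFrame


def _check_balanced(data: pd.DataFrame, factors: list[str], response: str) -> int:
    counts = data.groupby(factors, sort=False).size()
    levels = [data[f].nunique() for f in factors]
    n_cells = int(np.prod(levels))
    if len(counts) != n_cells:
        raise InvalidInputError("design is not fully crossed: some cells are empty")
    if counts.nunique() != 1:
        raise InvalidInputError("design is unbalanced: unequal replicates per cell")
    r = int(counts.iloc[0])
    if r < 2:
        raise InvalidInputError("need >= 2 replicates per cell")
    if not np.isfinite(data[response]).all():
        raise InvalidInputError("response contains non-finite values")
    return r


def anova3(
    data: pd.DataFrame,
    response: str,
    factors: tuple[str, str, str] = ("year", "fertility", "management"),
) -> AnovaResult:
    """Classical balanced three-way fixed-effects ANOVA.

    Returns the full table (3 main effects, 3 two-way and 1 three-way
    interaction, error) with df, SS, MS, F, p and a significance flag
    ('**' p<0.01, '*' p<0.05, 'ns').
    """
    factors = list(factors)
    if len(factors) != 3:
        raise InvalidInputError("exactly three factors are required")
    for col in (*factors, response):
        if col not in data.columns:
            raise InvalidInputError(f"column {col!r} not in data")
    r = _check_balanced(data, factors, response)

    y = data[response].to_numpy(dtype=float)
    n = len(y)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    levels = {f: data[f].nunique() for f in factors}
    degenerate = sst <= 1e-12 * n * max(1.0, grand * grand)

    # means of every factor-subset margin, as aligned per-observation vectors
    margin = {(): np.full(n, grand)}
    for k in (1, 2, 3):
        for subset in itertools.combinations(factors, k):
            margin[subset] = data.groupby(list(subset), sort=False)[response].transform(
                "mean"
            ).to_numpy(dtype=float)

    rows = {}
    for k in (1, 2, 3):
        for subset in itertools.combinations(factors, k):
            # inclusion-exclusion over sub-margins gives the orthogonal effect
            effect = np.zeros(n)
            for j in range(k + 1):
                for sub in itertools.combinations(subset, j):
                    effect += (-1.0) ** (k - j) * margin[sub]
            ss = float((effect**2).sum())
            df = int(np.prod([levels[f] - 1 for f in subset]))
            rows[" x ".join(subset)] = {"df": df, "ss": ss}

    ss_model = sum(v["ss"] for v in rows.values())
    ss_error = float(((y - margin[tuple(factors)]) ** 2).sum())
    df_error = n - int(np.prod(list(levels.values())))
    table_rows = []
    for name, v in rows.items():
        ms = v["ss"] / v["df"]
        if degenerate:
            fval, p = 0.0, 1.0
        else:
            ms_err = ss_error / df_error
            fval = ms / ms_err if ms_err > 0 else np.inf
            p = float(f_dist.sf(fval, v["df"], df_error))
        sig = "**" if p < 0.01 else "*" if p < 0.05 else "ns"
        table_rows.append(
            {"effect": name, "df": v["df"], "ss": v["ss"], "ms": ms, "F": fval,
             "p": p, "sig": sig}
        )
    table_rows.append(
        {
            "effect": "error",
            "df": df_error,
            "ss": ss_error,
            "ms": ss_error / df_error,
            "F": np.nan,
            "p": np.nan,
            "sig": "",
        }
    )
    table = pd.DataFrame(table_rows).set_index("effect")
    # decomposition sanity: effects + error must recover the total SS
    assert abs((ss_model + ss_error) - sst) <= 1e-8 * max(sst, 1.0)
    return AnovaResult(
        table=table,
        ms_error=ss_error / df_error,
        df_error=df_error,
        factors=factors,
        response=response,
        data=data,
    )


def lsd_test(result: AnovaResult, factor: str, alpha: float = 0.05) -> pd.DataFrame:
    """Fisher's LSD comparison of one factor's level means, with letters.

    Returns levels sorted by descending mean with columns ``mean``, ``n`` and
    ``letters``; the LSD threshold is attached as ``DataFrame.attrs['lsd']``.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must lie in (0, 1), got {alpha!r}")
    if factor not in result.factors:
        raise InvalidInputError(f"{factor!r} is not one of the design factors")
    means = (
        result.data.groupby(factor, sort=False)[result.response]
        .agg(["mean", "size"])
        .sort_values("mean", ascending=False, kind="stable")
    )
    n_per_mean = int(means["size"].iloc[0])
    t_crit = float(t_dist.ppf(1.0 - alpha / 2.0, result.df_error))
    lsd = t_crit * np.sqrt(2.0 * result.ms_error / n_per_mean)

    mu = means["mean"].to_numpy()
    k = len(mu)
    # maximal windows of mutually non-different (|diff| < lsd) sorted means
    windows = []
    for i in range(k):
        j = i
        while j + 1 < k and mu[i] - mu[j + 1] < lsd:
            j += 1
        windows.append((i, j))
    windows = [
        w for w in windows if not any(o != w and o[0] <= w[0] and w[1] <= o[1] for o in windows)
    ]
    letters = ["" for _ in range(k)]
    for letter, (i, j) in zip(string.ascii_lowercase, windows):
        for idx in range(i, j + 1):
            letters[idx] += letter
    out = pd.DataFrame(
        {"mean": mu, "n": means["size"].to_numpy(), "letters": letters},
        index=means.index,
    )
    out.attrs["lsd"] = float(lsd)
    out.attrs["alpha"] = alpha
    return out
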