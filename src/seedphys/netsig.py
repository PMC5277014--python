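"""Information-theoretic node significance of metabolic variables for seed weight.

Each continuous variable is discretized into equal-frequency bins (3 by
default) and scored against the discretized target (100-seed weight) with the
plug-in mutual information of the empirical joint distribution.  Reported per
node:

* ``nmi_pct`` — normalized mutual information, 100 * MI / H(target), i.e. the
  percentage of the target's entropy explained by the node;
* ``relative_significance`` — NMI divided by the maximum NMI over all nodes,
  so the top node scores exactly 1;
* the likelihood-ratio independence test G = 2 sum O ln(O/E) with expected
  counts from the marginals, df = (rows-1)(cols-1) and a chi-square upper-tail
  p-value.  For plug-in estimates G equals 2N times the mutual information in
  nats, an identity the test suite asserts to 1e-9.

Only pairwise node-target significance is computed; no network structure is
inferred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .exceptions import InvalidInputError

__all__ = [
    "DiscretizationSpec",
    "NodeSignificanceResult",
    "discretize",
    "contingency",
    "mutual_information",
    "g_test",
    "rank_nodes",
    "relative_significance",
]

#: Node columns expected in a biochemistry sample table (others are accepted).
EXPECTED_NODES = (
    "susy",
    "c_inv",
    "v_inv",
    "sps",
    "h_atpase",
    "h_ppase",
    "pepc",
    "sucrose",
    "d_glucose",
    "d_fructose",
    "starch",
)


@dataclass(frozen=True)
class DiscretizationSpec:
    """Equal-frequency discretization with a fixed number of bins (default 3)."""

    bins: int = 3

    def __post_init__(self):
        if self.bins < 2:
            raise InvalidInputError(f"bins must be >= 2, got {self.bins}")


@dataclass(frozen=True)
class NodeSignificanceResult:
    node: str
    mi_bits: float
    nmi_pct: float
    relative_significance: float
    g_stat: float
    df: int
    p_value: float


def discretize(values, spec: DiscretizationSpec = DiscretizationSpec()) -> np.ndarray:
    """Equal-frequency bin labels (0..bins-1) with stable-rank tie breaking.

    Observations are ranked with a stable sort, and consecutive rank blocks of
    near-equal size are assigned to consecutive bins, so every bin is
    non-empty and a permutation of the input yields the same label multiset.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < spec.bins:
        raise InvalidInputError("need a 1-d vector with at least `bins` values")
    if not np.isfinite(v).all():
        raise InvalidInputError("values must be finite (clean missing data first)")
    if len(np.unique(v)) < spec.bins:
        raise InvalidInputError(
            f"need >= {spec.bins} distinct values, got {len(np.unique(v))}"
        )
    n = len(v)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    # rank r falls in bin floor(r * bins / n): block sizes differ by at most 1
    return (ranks * spec.bins) // n


def contingency(x, y) -> np.ndarray:
    """Contingency table of two equal-length label vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise InvalidInputError("x and y must be 1-d label vectors of equal length")
    if len(x) == 0:
        raise InvalidInputError("label vectors must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    table = np.zeros((xi.max() + 1, yi.max() + 1), dtype=np.int64)
    np.add.at(table, (xi, yi), 1)
    return table


def _entropy_nats(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(x, y) -> dict[str, float]:
    """Plug-in mutual information of two label vectors.

    Returns ``mi_bits``, ``mi_nats`` and the marginal entropies ``H_x``/``H_y``
    in bits.  Symmetric in its arguments; non-negative up to floating error
    (clamped at zero).
    """
    table = contingency(x, y)
    n = table.sum()
    hx = _entropy_nats(table.sum(axis=1))
    hy = _entropy_nats(table.sum(axis=0))
    hxy = _entropy_nats(table.ravel())
    mi_nats = max(hx + hy - hxy, 0.0)
    ln2 = np.log(2.0)
    return {
        "mi_bits": mi_nats / ln2,
        "mi_nats": mi_nats,
        "H_x": hx / ln2,
        "H_y": hy / ln2,
        "n": int(n),
    }


def g_test(x, y) -> dict[str, float]:
    """Likelihood-ratio (G) test of independence of two label vectors.

    G = 2 sum O ln(O/E) over non-empty cells, E from the row/column marginals;
    df = (rows-1)(cols-1); p from the chi-square upper tail.  A zero marginal
    is an error — collapse bins upstream.
    """
    table = contingency(x, y).astype(float)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise InvalidInputError("zero marginal in contingency table; collapse bins")
    n = table.sum()
    expected = np.outer(rows, cols) / n
    obs = table[table > 0]
    g = 2.0 * float((obs * np.log(obs / expected[table > 0])).sum())
    g = max(g, 0.0)
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(chi2.sf(g, df)) if df > 0 else 1.0
    return {"g_stat": g, "df": int(df), "p_value": p}


def relative_significance(nmi) -> np.ndarray:
    """NMI values scaled by their maximum, so the top node scores exactly 1."""
    arr = np.asarray(nmi, dtype=float)
    if len(arr) == 0 or not (arr.max() > 0):
        raise InvalidInputError("relative significance needs a positive maximum NMI")
    return arr / arr.max()


def rank_nodes(
    table: pd.DataFrame,
    target: str = "seed_weight_100",
    spec: DiscretizationSpec = DiscretizationSpec(),
    nodes: list[str] | None = None,
) -> pd.DataFrame:
    """Score every predictor column against the target and rank by NMI.

    Returns one row per node with columns ``node``, ``mi_bits``, ``nmi_pct``,
    ``relative_significance``, ``g_stat``, ``df`` and ``p_value``, sorted by
    NMI descending with alphabetical tie-break.
    """
    if target not in table.columns:
        raise InvalidInputError(f"target column {target!r} not in table")
    if nodes is None:
        nodes = [
            c
            for c in table.columns
            if c != target and pd.api.types.is_numeric_dtype(table[c])
        ]
    if target in nodes:
        raise InvalidInputError("target must not appear among the predictor nodes")
    if not nodes:
        raise InvalidInputError("no predictor nodes found")
    if table[[target, *nodes]].isna().any().any():
        raise InvalidInputError("table contains missing values; clean first")
    n = len(table)
    if n < 3 * spec.bins**2:
        raise InvalidInputError(
            f"need n >= 3 * bins^2 = {3 * spec.bins ** 2} samples, got {n}"
        )
    t_labels = discretize(table[target].to_numpy(), spec)
    h_target_bits = mutual_information(t_labels, t_labels)["H_x"]
    rows = []
    for node in nodes:
        labels = discretize(table[node].to_numpy(), spec)
        mi = mutual_information(labels, t_labels)
        gt = g_test(labels, t_labels)
        rows.append(
            {
                "node": node,
                "mi_bits": mi["mi_bits"],
                "nmi_pct": 100.0 * mi["mi_bits"] / h_target_bits,
                "g_stat": gt["g_stat"],
                "df": gt["df"],
                "p_value": gt["p_value"],
            }
        )
    out = pd.DataFrame(rows)
    out["relative_significance"] = relative_significance(out["nmi_pct"].to_numpy())
    out = out.sort_values(
        ["nmi_pct", "node"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out[
        [
            "node",
            "mi_bits",
            "nmi_pct",
            "relative_significance",
            "g_stat",
            "df",
            "p_value",
        ]
    ]
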