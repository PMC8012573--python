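"""Morphology-trait association with the extremes of the lifespan screen.

Compares quantitative cell-morphology trait scores between the longest- and
shortest-lived strains of the screen (top and bottom 10% by lifespan score by
default) with a two-sided Mann-Whitney U test per trait, followed by
Benjamini-Hochberg correction across traits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["select_extremes", "trait_association"]


def select_extremes(
    scores: Mapping[str, float], fraction: float = 0.10
) -> Tuple[list[str], list[str]]:
    """Top and bottom ``fraction`` of strains by lifespan score.

    Each set holds ``ceil(fraction * n)`` strains; ties at the cut are broken
    lexicographically by strain_id so repeated runs are identical. Strains
    with non-finite scores are ignored. Raises if the two sets would overlap.
    """
    if not (0 < fraction < 0.5):
        raise ValueError("fraction must lie in (0, 0.5)")
    valid = [(s, v) for s, v in scores.items() if v is not None and np.isfinite(v)]
    n = len(valid)
    if n < 10:
        raise ValueError("need at least 10 scored strains")
    k = math.ceil(fraction * n)
    if 2 * k > n:
        raise ValueError("extreme sets would overlap")
    top = sorted(valid, key=lambda kv: (-kv[1], kv[0]))[:k]
    bottom = sorted(valid, key=lambda kv: (kv[1], kv[0]))[:k]
    return [s for s, _ in top], [s for s, _ in bottom]


@dataclass(frozen=True)
class TraitAssociation:
    trait_id: str
    mean_long: float
    mean_short: float
    U: float
    p: float
    q: float
    direction: str  # "positive" iff mean_long > mean_short
    n_long: int
    n_short: int


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    # exact enumeration for small groups without ties, normal approximation
    # with tie correction otherwise
    small = len(x) <= 20 and len(y) <= 20
    no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def trait_association(
    traits: pd.DataFrame,
    long_set: Sequence[str],
    short_set: Sequence[str],
    min_n: int = 3,
) -> Tuple[pd.DataFrame, list[str]]:
    """Per-trait Mann-Whitney comparison of long- vs short-lived strains.

    Parameters
    ----------
    traits
        Strains x traits matrix (index strain_id); missing values allowed and
        dropped pairwise per trait, never imputed.
    long_set, short_set
        Strain ids from :func:`select_extremes`; ids absent from the matrix
        simply contribute no values.
    min_n
        Minimum non-missing values required in each group for a trait to be
        analysed.

    Returns
    -------
    (results, skipped)
        ``results`` is a DataFrame indexed by trait_id with columns
        mean_long, mean_short, U, p, q, direction, n_long, n_short, sorted by
        q then p; ``q`` is the Benjamini-Hochberg adjustment over all
        analysed traits. ``skipped`` lists traits failing the minimum-n rule.
    """
    if set(long_set) & set(short_set):
        raise ValueError("long and short sets overlap")
    long_rows = traits.loc[traits.index.intersection(long_set)]
    short_rows = traits.loc[traits.index.intersection(short_set)]
    rows = []
    skipped: list[str] = []
    for trait in traits.columns:
        x = long_rows[trait].dropna().to_numpy(dtype=float)
        y = short_rows[trait].dropna().to_numpy(dtype=float)
        if len(x) < min_n or len(y) < min_n:
            skipped.append(trait)
            continue
        u, p = _mannwhitney(x, y)
        rows.append({
            "trait_id": trait,
            "mean_long": float(x.mean()),
            "mean_short": float(y.mean()),
            "U": u,
            "p": p,
            "direction": "positive" if x.mean() > y.mean() else "negative",
            "n_long": len(x),
            "n_short": len(y),
        })
    if not rows:
        out = pd.DataFrame(columns=["mean_long", "mean_short", "U", "p", "q",
                                    "direction", "n_long", "n_short"])
        out.index.name = "trait_id"
        return out, skipped
    out = pd.DataFrame(rows).set_index("trait_id")
    out["q"] = stats.false_discovery_control(out["p"].to_numpy(), method="bh")
    out = out.sort_values(["q", "p", "trait_id"])
    return out[["mean_long", "mean_short", "U", "p", "q", "direction",
                "n_long", "n_short"]], skipped
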