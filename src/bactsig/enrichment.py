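"""Gene-set over-representation analysis with Enrichr-style combined scores.

For a query gene list against each set of a GMT collection within an explicit
background universe, the 2x2 table (a = query∩set, b = query∖set,
c = set∖query, d = remainder) is tested with the one-sided hypergeometric
(Fisher) over-representation p-value; p-values are Benjamini-Hochberg
adjusted across all sets; the odds ratio is (a·d)/(b·c) (Haldane 0.5
correction only when b·c = 0); and sets are ranked by the combined score

    score = odds_ratio x (−ln p).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Collection, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, FormatError


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT collection: set name, description, tab-separated genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_gene_list(path: str | Path) -> list[str]:
    return [g.strip() for g in Path(path).read_text().splitlines() if g.strip()]


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ConfigurationError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def combined_score(p_value: float, odds_ratio: float) -> float:
    """Enrichr-style combined score: odds_ratio x (−ln p)."""
    if p_value <= 0 or p_value > 1:
        raise ConfigurationError(f"p-value {p_value} outside (0, 1]")
    if odds_ratio < 0:
        raise ConfigurationError(f"odds ratio {odds_ratio} is negative")
    return float(odds_ratio * -math.log(p_value))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return (a * d) / (b * c)


def fisher_enrich(
    query_genes: Sequence[str],
    gene_sets: Mapping[str, Collection[str]],
    background: int | Collection[str],
) -> pd.DataFrame:
    """Over-representation of a query list in each gene set.

    ``background`` is either the universe size or the explicit universe
    (in which case query membership is validated). Returns one row per set
    with contingency counts, one-sided hypergeometric p, BH-adjusted p,
    odds ratio and combined score, sorted by descending combined score.
    """
    query = set(query_genes)
    if not gene_sets:
        raise ConfigurationError("empty gene-set collection")
    if any(len(s) == 0 for s in gene_sets.values()):
        raise ConfigurationError("gene sets must be non-empty")
    if isinstance(background, int):
        n_background = background
    else:
        universe = set(background)
        offenders = sorted(query - universe)
        if offenders:
            raise ConfigurationError(
                "query genes absent from background: " + ", ".join(offenders[:10])
            )
        n_background = len(universe)
    if n_background < len(query):
        raise ConfigurationError("background smaller than the query list")

    rows = []
    for name, members in gene_sets.items():
        members = set(members)
        if len(members) > n_background:
            raise ConfigurationError(f"set {name!r} larger than the background")
        a = len(query & members)
        b = len(query) - a
        c = len(members) - a
        d = n_background - a - b - c
        if d < 0:
            raise ConfigurationError(
                f"set {name!r}: contingency table exceeds the background size"
            )
        # P(X >= a) with X ~ Hypergeom(N=background, K=set size, n=query size)
        p = float(stats.hypergeom.sf(a - 1, n_background, a + c, a + b))
        p = min(1.0, max(p, np.nextafter(0, 1)))
        odds = _odds_ratio(a, b, c, d) if a > 0 else 0.0
        rows.append((name, a, b, c, d, p, odds))
    df = pd.DataFrame(
        rows, columns=["set_name", "a", "b", "c", "d", "p_value", "odds_ratio"]
    )
    df["adj_p"] = bh_adjust(df["p_value"])
    df["combined_score"] = [
        combined_score(p, o) for p, o in zip(df["p_value"], df["odds_ratio"])
    ]
    return (
        df.sort_values(
            ["combined_score", "p_value", "set_name"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    )
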