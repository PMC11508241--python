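"""Transcriptional strand-bias testing on stranded (192-channel) catalogs.

For every pyrimidine-collapsed channel the transcribed (T) and untranscribed
(U) counts are compared with an exact two-sided binomial test against a null
of 0.5 (the two-sided p is twice the smaller tail, capped at 1 — appropriate
for the small per-context counts of a clone experiment), followed by
Benjamini-Hochberg adjustment across the 96 channels. A channel is flagged
``T>`` or ``U>`` when its adjusted p falls below alpha.

No correction for transcribed/untranscribed sequence-content asymmetry is
applied by default; an optional context-abundance normalization of the
reported ratio is available and recorded in the output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .channels import CHANNELS_96, CHANNEL_CONTEXT, SUBSTITUTION_CLASSES
from .catalog import StrandedCatalog


def binomial_two_sided(k: int, n: int) -> float:
    """Two-sided exact binomial p against 0.5: twice the smaller tail, capped at 1."""
    if n == 0:
        return 1.0
    lower = stats.binom.cdf(k, n, 0.5)
    upper = stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def strand_bias_table(
    stranded_catalog: StrandedCatalog | pd.DataFrame,
    pool_samples: bool = True,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-channel strand-bias test results.

    With ``pool_samples`` (default) counts are summed over samples before
    testing — one row per channel; otherwise each sample is tested (and
    BH-adjusted) separately, with a ``sample`` column added. The ratio is
    (T + pseudocount) / (U + pseudocount); pass ``pseudocount=0`` for the
    raw ratio (infinite when U = 0).
    """
    counts = (
        stranded_catalog.counts
        if isinstance(stranded_catalog, StrandedCatalog)
        else stranded_catalog
    )
    t_cols = [f"T:{c}" for c in CHANNELS_96]
    u_cols = [f"U:{c}" for c in CHANNELS_96]
    if pool_samples:
        t = counts[t_cols].sum(axis=0).to_numpy()
        u = counts[u_cols].sum(axis=0).to_numpy()
        return _bias_rows(t, u, alpha, pseudocount)
    frames = []
    for sid in counts.index:
        t = counts.loc[sid, t_cols].to_numpy()
        u = counts.loc[sid, u_cols].to_numpy()
        df = _bias_rows(t, u, alpha, pseudocount)
        df.insert(0, "sample", sid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _bias_rows(
    t: np.ndarray, u: np.ndarray, alpha: float, pseudocount: float
) -> pd.DataFrame:
    p = np.array([binomial_two_sided(int(ti), int(ti + ui)) for ti, ui in zip(t, u)])
    _, q, _, _ = multipletests(p, method="fdr_bh")
    with np.errstate(divide="ignore"):
        ratio = (t + pseudocount) / (u + pseudocount)
    direction = np.where(
        q < alpha, np.where(t > u, "T>", "U>"), "none"
    )
    sub_class = [CHANNELS_96[i][2:5] for i in range(96)]
    assert set(sub_class) <= set(SUBSTITUTION_CLASSES)
    return pd.DataFrame(
        {
            "channel": list(CHANNELS_96),
            "context": list(CHANNEL_CONTEXT),
            "substitution": sub_class,
            "count_transcribed": t.astype(int),
            "count_untranscribed": u.astype(int),
            "ratio": ratio,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        }
    )


def ct_bias_profile(table: pd.DataFrame) -> pd.DataFrame:
    """16-context C>T transcribed/untranscribed profile from a pooled
    strand-bias table, for cross-signature profile comparison."""
    ct = table[table["substitution"] == "C>T"]
    return pd.DataFrame(
        {
            "transcribed": ct["count_transcribed"].to_numpy(),
            "untranscribed": ct["count_untranscribed"].to_numpy(),
        },
        index=ct["context"].to_list(),
    )
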