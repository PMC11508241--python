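"""Cosine-similarity comparison of signatures against a COSMIC-format catalog."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS_96
from .errors import ChannelAlignmentError, FormatError

_HEADER_DIALECTS = ("Type", "MutationType")


def read_cosmic(path: str | Path) -> pd.DataFrame:
    """Read a COSMIC-style signature TSV into canonical channel order.

    The file must have a ``Type`` (or ``MutationType``) column with the 96
    ``X[R>A]Y`` labels and one column per signature. Rows may appear in any
    order; columns are renormalized to sum to 1 (with a warning when off by
    more than 1e-3). Missing or duplicated channels raise a format error.
    """
    df = pd.read_csv(path, sep="\t")
    label_col = next((c for c in _HEADER_DIALECTS if c in df.columns), None)
    if label_col is None:
        raise FormatError(
            f"{path}: no channel-label column (expected one of {_HEADER_DIALECTS})"
        )
    df = df.set_index(label_col)
    dupes = sorted(df.index[df.index.duplicated()].unique())
    if dupes:
        raise FormatError(f"{path}: duplicated channels: {', '.join(dupes)}")
    missing = sorted(set(CHANNELS_96) - set(df.index))
    if missing:
        raise FormatError(f"{path}: missing channels: {', '.join(missing)}")
    extra = sorted(set(df.index) - set(CHANNELS_96))
    if extra:
        raise FormatError(f"{path}: unknown channels: {', '.join(extra)}")
    df = df.loc[list(CHANNELS_96)].astype(float)
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative signature values")
    sums = df.sum(axis=0)
    if (sums == 0).any():
        raise FormatError(f"{path}: all-zero signature column")
    off = (sums - 1.0).abs()
    if (off > 1e-3).any():
        bad = ", ".join(sums.index[off > 1e-3])
        warnings.warn(
            f"{path}: columns not normalized (renormalizing): {bad}", stacklevel=2
        )
    return df / sums


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (‖u‖·‖v‖); in [0, 1] for non-negative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def rank_matches(
    signature: pd.Series | np.ndarray,
    catalog: pd.DataFrame,
    top_n: int | None = None,
) -> pd.DataFrame:
    """Catalog signatures ranked by descending cosine similarity to the
    query; ties broken by name."""
    sig = np.asarray(signature, dtype=float)
    if sig.shape != (catalog.shape[0],):
        raise ChannelAlignmentError(
            f"query length {sig.shape} does not match catalog channels "
            f"{catalog.shape[0]}"
        )
    sims = [(name, cosine_similarity(sig, catalog[name])) for name in catalog.columns]
    out = pd.DataFrame(sims, columns=["name", "similarity"])
    out = out.sort_values(
        ["similarity", "name"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    if top_n is not None:
        out = out.head(top_n)
    return out


def strand_bias_profile_compare(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    tol: float = 0.0,
) -> tuple[pd.DataFrame, int, int]:
    """Per-context agreement of two transcribed/untranscribed C>T profiles.

    Each profile indexes the 16 C>T contexts with ``transcribed`` and
    ``untranscribed`` columns (counts or proportions). A context's direction
    is ``T>`` when transcribed exceeds untranscribed by more than ``tol``,
    ``U>`` in the opposite case, ``none`` otherwise. Returns the per-context
    report, the number of concordant contexts (same non-``none`` direction)
    and the number of comparable contexts (direction non-``none`` in both).
    """
    contexts = list(profile_a.index)
    if list(profile_b.index) != contexts:
        profile_b = profile_b.reindex(contexts)

    def direction(row) -> str:
        d = row["transcribed"] - row["untranscribed"]
        if d > tol:
            return "T>"
        if d < -tol:
            return "U>"
        return "none"

    dir_a = profile_a.apply(direction, axis=1)
    dir_b = profile_b.apply(direction, axis=1)
    comparable = (dir_a != "none") & (dir_b != "none")
    concordant = comparable & (dir_a == dir_b)
    report = pd.DataFrame(
        {
            "direction_a": dir_a,
            "direction_b": dir_b,
            "concordant": concordant,
        },
        index=contexts,
    )
    return report, int(concordant.sum()), int(comparable.sum())
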