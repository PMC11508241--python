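"""Bootstrap NMF mutational-signature extraction.

The catalog (samples x 96 channels) is factorized as V ≈ W·H with V the
channels x samples count matrix, W the channels x k signature matrix and H
the k x samples exposure matrix. The factorization minimizes the generalized
Kullback-Leibler divergence (the count-appropriate objective) by
multiplicative updates. Robustness of a candidate signature number k is
assessed by resampling each sample's counts multinomially (its own total
preserved), running the factorization for every bootstrap x restart, pooling
all resulting signature vectors and partitioning them into k clusters by
cosine distance; the per-cluster mean silhouette is the reported stability
and the cluster centroids are the consensus signatures.

Exposures are refit against the original catalog by non-negative least
squares, reported both as mutation counts and relative contributions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .channels import CHANNELS_96, CHANNEL_TO_CONTEXT, CONTEXTS_32
from .errors import ChannelAlignmentError, ConfigurationError, NormalizationError

_EPS = 1e-9


@dataclass
class SignatureSet:
    """Extracted signatures with per-signature stability.

    ``signatures``: channels x k DataFrame, each column non-negative and
    summing to 1. ``stability``: mean cosine silhouette of each signature's
    bootstrap cluster (mean cosine similarity to the centroid when k = 1).
    ``reconstruction_error``: Frobenius norm of catalog − model on the
    original (non-resampled) catalog.
    """

    signatures: pd.DataFrame
    stability: pd.Series
    reconstruction_error: float
    k: int


@dataclass
class ExposureMatrix:
    """Samples x k attribution of mutations to signatures."""

    counts: pd.DataFrame

    @property
    def relative(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        rel = self.counts.div(totals.where(totals > 0, 1.0), axis=0)
        rel[totals == 0] = 0.0
        return rel


@dataclass
class SelectKResult:
    table: pd.DataFrame  # columns: k, stability, reconstruction_error
    recommended_k: int
    signature_sets: dict[int, SignatureSet]


# ---------------------------------------------------------------------------
# core factorization


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = float(WH.sum() - V.sum())
    div += float((V[mask] * np.log(V[mask] / WH[mask])).sum())
    return div


def nmf_kl(
    V: np.ndarray,
    k: int,
    *,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    seed: int | np.random.SeedSequence | None = None,
    track_objective: bool = False,
    check_every: int = 10,
) -> tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, list[float]]:
    """Multiplicative-update NMF under generalized KL divergence.

    Stops when the relative objective change over ``check_every`` iterations
    falls below ``tol`` or after ``max_iter`` iterations. Zero rows/columns
    are tolerated through a 1e-9 pseudocount inside the updates only.
    """
    V = np.asarray(V, dtype=float)
    if (V < 0).any():
        raise ConfigurationError("NMF input must be non-negative")
    m, n = V.shape
    if not 1 <= k <= min(m, n):
        raise ConfigurationError(f"k={k} not in [1, min{V.shape}]")
    rng = np.random.default_rng(seed)
    scale = max(V.mean(), _EPS)
    W = rng.uniform(0.5, 1.5, size=(m, k)) * np.sqrt(scale / k)
    H = rng.uniform(0.5, 1.5, size=(k, n)) * np.sqrt(scale / k)

    history: list[float] = []
    prev = np.inf
    for it in range(max_iter):
        WH = W @ H + _EPS
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + _EPS)
        WH = W @ H + _EPS
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + _EPS)
        if track_objective or (it + 1) % check_every == 0 or it == max_iter - 1:
            obj = _kl_divergence(V, W @ H + _EPS)
            if track_objective:
                history.append(obj)
            if (it + 1) % check_every == 0 or it == max_iter - 1:
                if np.isfinite(prev) and abs(prev - obj) <= tol * max(abs(prev), _EPS):
                    break
                prev = obj
    if track_objective:
        return W, H, history
    return W, H


def _normalize_columns(W: np.ndarray) -> np.ndarray:
    sums = W.sum(axis=0)
    sums[sums == 0] = 1.0
    return W / sums


def _as_signature_df(signatures) -> pd.DataFrame:
    if isinstance(signatures, SignatureSet):
        return signatures.signatures
    return signatures


def _check_channels(index) -> None:
    if list(index) != list(CHANNELS_96):
        raise ChannelAlignmentError(
            "signature/catalog channel order does not match canonical order"
        )


# ---------------------------------------------------------------------------
# bootstrap extraction


def _sample_seed(root: int, tag: int, *parts: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([root & 0x7FFFFFFF, tag, *parts])


def _bootstrap_matrix(
    counts: np.ndarray, sample_ids: list[str], root_seed: int, b: int
) -> np.ndarray:
    """Per-sample multinomial resample, each with the sample's own total.

    Per-sample seeds derive from the sample id (not its position), so the
    result is invariant to row permutation of the input catalog.
    """
    out = np.zeros_like(counts)
    for j, sid in enumerate(sample_ids):
        total = int(counts[:, j].sum())
        if total == 0:
            continue
        rng = np.random.default_rng(
            _sample_seed(root_seed, 0xB007, b, zlib.crc32(sid.encode()))
        )
        out[:, j] = rng.multinomial(total, counts[:, j] / total)
    return out


def extract_signatures(
    catalog: pd.DataFrame,
    k: int,
    *,
    n_bootstraps: int = 100,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    cluster_restarts: int = 20,
) -> SignatureSet:
    """Consensus signatures of a catalog by bootstrap-resampled NMF.

    Samples are processed in sorted-id order internally, so the result does
    not depend on the row order of ``catalog``.
    """
    if n_bootstraps < 2:
        raise ConfigurationError("n_bootstraps must be >= 2")
    _check_channels(catalog.columns)
    order = sorted(catalog.index)
    V0 = catalog.loc[order].to_numpy(dtype=float).T  # channels x samples

    pooled: list[np.ndarray] = []
    for b in range(n_bootstraps):
        Vb = _bootstrap_matrix(V0, order, seed, b)
        for r in range(n_restarts):
            W, _ = nmf_kl(
                Vb,
                k,
                max_iter=max_iter,
                tol=tol,
                seed=_sample_seed(seed, 0x17E5, b, r),
            )
            pooled.append(_normalize_columns(W))
    X = np.hstack(pooled).T  # (n_boot*n_restart*k) x channels, L1-normalized rows

    centroids, stabilities = _cluster_signatures(X, k, seed, cluster_restarts)
    # deterministic ordering: by descending stability, then by profile
    order_idx = sorted(
        range(k), key=lambda i: (-stabilities[i], tuple(np.round(centroids[i], 12)))
    )
    S = np.column_stack([centroids[i] for i in order_idx])
    stab = np.array([stabilities[i] for i in order_idx])

    names = [f"S{i + 1}" for i in range(k)]
    sig_df = pd.DataFrame(S, index=list(CHANNELS_96), columns=names)
    E = _nnls_exposures(V0, S)
    recon = float(np.linalg.norm(V0 - S @ E, "fro"))
    return SignatureSet(
        signatures=sig_df,
        stability=pd.Series(stab, index=names, name="stability"),
        reconstruction_error=recon,
        k=k,
    )


def _cluster_signatures(
    X: np.ndarray, k: int, seed: int, cluster_restarts: int
) -> tuple[list[np.ndarray], list[float]]:
    """Partition pooled signature vectors into k clusters by cosine distance.

    Cosine k-partition is realized as Euclidean k-means on L2-normalized
    vectors; silhouettes use the cosine metric directly.
    """
    norms = np.linalg.norm(X, axis=1)
    norms[norms == 0] = 1.0
    Xn = X / norms[:, None]
    if k == 1:
        centroid = X.mean(axis=0)
        centroid /= max(centroid.sum(), _EPS)
        cn = centroid / max(np.linalg.norm(centroid), _EPS)
        stability = float((Xn @ cn).mean())
        return [centroid], [stability]
    km_state = int(_sample_seed(seed, 0xC7, k).generate_state(1)[0] & 0x7FFFFFFF)
    km = KMeans(n_clusters=k, n_init=cluster_restarts, random_state=km_state)
    labels = km.fit_predict(Xn)
    sil = silhouette_samples(Xn, labels, metric="cosine")
    centroids, stabilities = [], []
    for c in range(k):
        members = labels == c
        centroid = X[members].mean(axis=0)
        centroid /= max(centroid.sum(), _EPS)
        centroids.append(centroid)
        stabilities.append(float(sil[members].mean()))
    return centroids, stabilities


def select_k(
    catalog: pd.DataFrame,
    k_min: int = 1,
    k_max: int = 5,
    stability_threshold: float = 0.8,
    **extract_kwargs,
) -> SelectKResult:
    """Stability/error table over a k range with a recommended k.

    Recommended k is the largest k whose mean stability stays at or above the
    threshold for every k' ≤ k (i.e. before the first stability drop); ties
    break toward lower k. Falls back to ``k_min`` when even ``k_min`` is
    below threshold.
    """
    n_samples = catalog.shape[0]
    if k_max >= min(n_samples, 96):
        raise ConfigurationError("k_max must be < min(n_samples, n_channels)")
    rows = []
    sets: dict[int, SignatureSet] = {}
    for k in range(k_min, k_max + 1):
        ss = extract_signatures(catalog, k, **extract_kwargs)
        sets[k] = ss
        rows.append((k, float(ss.stability.mean()), ss.reconstruction_error))
    table = pd.DataFrame(rows, columns=["k", "stability", "reconstruction_error"])
    recommended = k_min
    for k, stab, _ in rows:
        if stab >= stability_threshold:
            recommended = k
        else:
            break
    return SelectKResult(table=table, recommended_k=recommended, signature_sets=sets)


# ---------------------------------------------------------------------------
# exposures and renormalization


def _nnls_exposures(V: np.ndarray, S: np.ndarray) -> np.ndarray:
    E = np.zeros((S.shape[1], V.shape[1]))
    for j in range(V.shape[1]):
        E[:, j], _ = nnls(S, V[:, j])
    return E


def fit_exposures(
    catalog: pd.DataFrame, signatures: SignatureSet | pd.DataFrame
) -> ExposureMatrix:
    """Per-sample non-negative least-squares attribution of counts to
    signatures."""
    S_df = _as_signature_df(signatures)
    _check_channels(catalog.columns)
    _check_channels(S_df.index)
    V = catalog.to_numpy(dtype=float).T
    E = _nnls_exposures(V, S_df.to_numpy(dtype=float))
    return ExposureMatrix(
        counts=pd.DataFrame(E.T, index=catalog.index, columns=list(S_df.columns))
    )


def renormalize_signature(
    signature: pd.Series,
    source_freqs: pd.Series,
    target_freqs: pd.Series,
) -> pd.Series:
    """Re-weight a signature from one genome's trinucleotide frequencies to
    another's.

    Each channel is multiplied by target_freq / source_freq of its context,
    then the vector is renormalized to sum to 1. With target = source this is
    the identity.
    """
    _check_channels(signature.index)
    src = source_freqs.reindex(list(CONTEXTS_32)).to_numpy(dtype=float)
    tgt = target_freqs.reindex(list(CONTEXTS_32)).to_numpy(dtype=float)
    if np.isnan(src).any() or np.isnan(tgt).any():
        raise NormalizationError("frequency vectors must cover all 32 contexts")
    sig = signature.to_numpy(dtype=float)
    ctx = CHANNEL_TO_CONTEXT
    bad = (src[ctx] == 0) & (sig > 0)
    if bad.any():
        raise NormalizationError(
            "zero source frequency for context(s) with signature mass: "
            + ", ".join(sorted({CONTEXTS_32[c] for c in np.unique(ctx[bad])}))
        )
    factors = np.divide(tgt[ctx], src[ctx], out=np.zeros(96), where=src[ctx] > 0)
    out = sig * factors
    total = out.sum()
    if total == 0:
        raise NormalizationError("renormalized signature has zero mass")
    return pd.Series(out / total, index=signature.index, name=signature.name)


# ---------------------------------------------------------------------------
# signature TSV IO


def write_signatures_tsv(signatures: SignatureSet | pd.DataFrame, path) -> None:
    df = _as_signature_df(signatures).copy()
    df.index.name = "Type"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_exposures_tsv(exposures: ExposureMatrix, path) -> None:
    df = exposures.counts.copy()
    df.index.name = "Sample"
    df.to_csv(path, sep="\t", float_format="%.10g")
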