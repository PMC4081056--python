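"""Alignment-free composition and complexity descriptors.

Artificially generated sequences are by construction unique, so they
cannot be validated against real DNA by alignment. Instead each
sequence is summarized by a vector of descriptors:

* composition — G+C content ``gc``, G/C skew ``gcs`` and CpG ratio
  ``cpg`` (the dimer count over the product of the G and C counts, as
  classically printed, without length normalization; a length-normalized
  variant is available separately and never substituted silently);
* complexity — Wootton-Federhen complexity ``cwf``, symbol entropy
  ``ce`` (both base-4), word entropies ``cm_m`` and linguistic
  complexities ``cl_m`` at word lengths m = 6, 8 and 12, and zlib
  compressibility ``cz`` (compressed bytes over raw bytes at a pinned
  compression level).

Descriptor matrices are z-scored and compared across sequence classes
by PCA and by PAM (k-medoids) clustering with the mean silhouette as
the diagnostic.

Ambiguous ('N') bases are excluded from every count; any word
containing one is skipped.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, fields
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .model import encode_bases

ZLIB_LEVEL = 6  # pinned: cz values are only comparable at a fixed level
WORD_LENGTHS = (6, 8, 12)


def _base_counts(codes: np.ndarray) -> np.ndarray:
    return np.bincount(codes[codes >= 0], minlength=4)


def gc_content(seq: str) -> float:
    """(n_G + n_C) / (n_A + n_T + n_C + n_G), N excluded."""
    n = _base_counts(encode_bases(seq))
    total = n.sum()
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return float((n[1] + n[2]) / total)


def gc_skew(seq: str) -> float:
    """(n_G - n_C) / (n_G + n_C); 0 (flagged elsewhere) when no G or C."""
    n = _base_counts(encode_bases(seq))
    denom = n[1] + n[2]
    if denom == 0:
        return 0.0
    return float((n[2] - n[1]) / denom)


def _cg_dimer_count(codes: np.ndarray) -> int:
    if len(codes) < 2:
        return 0
    return int(((codes[:-1] == 1) & (codes[1:] == 2)).sum())


def cpg_ratio(seq: str, length_normalized: bool = False) -> float:
    """n_CG / (n_G * n_C); optionally multiplied by N for the normalized variant."""
    codes = encode_bases(seq)
    n = _base_counts(codes)
    denom = float(n[1]) * float(n[2])
    if denom == 0:
        return 0.0
    value = _cg_dimer_count(codes) / denom
    if length_normalized:
        value *= n.sum()
    return float(value)


def wootton_federhen(seq: str) -> float:
    """(1/N) log4( N! / prod n_i! ), via log-gamma for numerical safety."""
    n = _base_counts(encode_bases(seq))
    N = n.sum()
    if N == 0:
        raise ValueError("sequence has no unambiguous bases")
    log4 = np.log(4.0)
    return float((gammaln(N + 1) - gammaln(n + 1).sum()) / (N * log4))


def entropy(seq: str) -> float:
    """Base-4 Shannon entropy of the mononucleotide composition."""
    n = _base_counts(encode_bases(seq))
    N = n.sum()
    if N == 0:
        raise ValueError("sequence has no unambiguous bases")
    p = n[n > 0] / N
    return float(-(p * np.log(p)).sum() / np.log(4.0))


def _word_codes(codes: np.ndarray, m: int) -> np.ndarray:
    """Integer codes of all N-m+1 sliding m-words, N-containing words dropped."""
    if len(codes) < m:
        return np.empty(0, dtype=np.int64)
    view = np.lib.stride_tricks.sliding_window_view(codes, m).astype(np.int64)
    valid = (view >= 0).all(axis=1)
    pow4 = 4 ** np.arange(m - 1, -1, -1, dtype=np.int64)
    return view[valid] @ pow4


def markov_entropy(seq: str, m: int) -> float:
    """Word entropy at length m with the N-m-1 denominator, log base 4^m."""
    codes = encode_bases(seq)
    N = len(codes)
    if N <= m + 1:
        warnings.warn(f"sequence too short for word length {m}")
        return float("nan")
    words = _word_codes(codes, m)
    if len(words) == 0:
        return float("nan")
    _, counts = np.unique(words, return_counts=True)
    denom = N - m - 1
    p = counts / denom
    return float(-(p * np.log(p)).sum() / (m * np.log(4.0)))


def linguistic_complexity(seq: str, m: int) -> float:
    """Observed distinct words up to length m over the maximum possible.

    V_max(i) = min(4^i, N-i+1), the vocabulary ceiling of a length-N
    sequence at word length i.
    """
    codes = encode_bases(seq)
    N = len(codes)
    num = den = 0.0
    for i in range(1, m + 1):
        words = _word_codes(codes, i)
        num += len(np.unique(words))
        den += min(4**i, max(N - i + 1, 0))
    if den == 0:
        return float("nan")
    return float(num / den)


def compressibility(seq: str, level: int = ZLIB_LEVEL) -> float:
    """Compressed size over raw size (one byte per base), DEFLATE at a pinned level."""
    raw = seq.encode("ascii")
    if not raw:
        raise ValueError("empty sequence")
    return len(zlib.compress(raw, level)) / len(raw)


@dataclass
class MetricsVector:
    """All descriptors of one sequence, in matrix column order."""

    gc: float
    gcs: float
    cpg: float
    cwf: float
    ce: float
    cm_6: float
    cm_8: float
    cm_12: float
    cl_6: float
    cl_8: float
    cl_12: float
    cz: float

    @classmethod
    def column_names(cls) -> List[str]:
        return [f.name for f in fields(cls)]

    def as_array(self) -> np.ndarray:
        return np.asarray([getattr(self, n) for n in self.column_names()])


def metrics_vector(seq: str) -> MetricsVector:
    """Compute all descriptors of one sequence."""
    codes = encode_bases(seq)
    n_frac = float((codes < 0).mean()) if len(codes) else 0.0
    if n_frac > 0.10:
        warnings.warn(f"sequence is {n_frac:.0%} ambiguous; metrics unreliable")
    return MetricsVector(
        gc=gc_content(seq),
        gcs=gc_skew(seq),
        cpg=cpg_ratio(seq),
        cwf=wootton_federhen(seq),
        ce=entropy(seq),
        cm_6=markov_entropy(seq, 6),
        cm_8=markov_entropy(seq, 8),
        cm_12=markov_entropy(seq, 12),
        cl_6=linguistic_complexity(seq, 6),
        cl_8=linguistic_complexity(seq, 8),
        cl_12=linguistic_complexity(seq, 12),
        cz=compressibility(seq),
    )


def metric_matrix(
    sequences: Sequence[str], labels: Sequence[str], standardize: bool = True
) -> pd.DataFrame:
    """One descriptor row per sequence; columns z-scored by default."""
    if len(sequences) != len(labels):
        raise ValueError("sequences and labels differ in length")
    rows = np.stack([metrics_vector(s).as_array() for s in sequences])
    df = pd.DataFrame(rows, index=list(labels), columns=MetricsVector.column_names())
    if standardize:
        std = df.std(axis=0, ddof=0)
        df = (df - df.mean(axis=0)).div(std.replace(0.0, 1.0), axis=1)
    return df


def pca_project(
    matrix: pd.DataFrame | np.ndarray, n_components: int = 2
) -> Tuple[np.ndarray, np.ndarray]:
    """Principal-component projection; returns (coordinates, explained variance ratio)."""
    X = np.asarray(matrix, dtype=float)
    n_components = min(n_components, *X.shape)
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_


def _pam_build(D: np.ndarray, k: int) -> List[int]:
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _pam_cost(D: np.ndarray, medoids: List[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam_cluster(X: np.ndarray, n_clusters: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning Around Medoids with deterministic BUILD + SWAP phases."""
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    n = D.shape[0]
    if n_clusters >= n:
        return np.arange(n)
    medoids = _pam_build(D, n_clusters)
    cost = _pam_cost(D, medoids)
    for _ in range(max_iter):
        best = (0.0, None)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids[:mi] + [h] + medoids[mi + 1 :]
                delta = _pam_cost(D, trial) - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        cost += best[0]
    return np.asarray(D[:, medoids].argmin(axis=1))


def pam_silhouette(
    matrix: pd.DataFrame | np.ndarray, n_clusters: int = 3
) -> Tuple[np.ndarray, float]:
    """PAM labels and mean silhouette (standard [-1, 1] definition)."""
    X = np.asarray(matrix, dtype=float)
    if np.allclose(X, X[0]):
        warnings.warn("all rows identical; clustering is degenerate")
        return np.zeros(len(X), dtype=int), float("nan")
    labels = pam_cluster(X, n_clusters)
    k = len(np.unique(labels))
    if k < 2 or k > len(X) - 1:  # silhouette undefined
        return labels, float("nan")
    return labels, float(silhouette_score(X, labels, metric="euclidean"))
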