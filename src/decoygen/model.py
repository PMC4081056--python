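"""Training of the background-genome model.

The model of unconstrained intergenic DNA has two coupled parts:

* a per-GC-bin table of empirical k-mer continuation probabilities
  P(next base | previous k bases, GC bin), tabulated in fixed
  non-overlapping windows (default 1 kb) whose GC bin is taken from the
  surrounding section average (default 10 kb);
* a first-order Markov chain over GC bins, estimated from transitions
  between adjacent windows.

Five GC bins with boundaries at 37%, 39%, 42% and 45% G+C are the
default stratification; they divide the human genome into strata of
roughly equal span and are user-overridable for other species.
"""

from __future__ import annotations

import json
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np

from .intervals import IntervalSet, mask_regions

MODEL_FORMAT_VERSION = 1

DEFAULT_K = 4
DEFAULT_WINDOW = 1000
DEFAULT_SECTION = 10000
DEFAULT_BIN_BOUNDARIES = (0.37, 0.39, 0.42, 0.45)
DEFAULT_MAX_N_FRACTION = 0.5

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def encode_bases(seq: str) -> np.ndarray:
    """Encode a DNA string as int8: A/C/G/T -> 0..3, anything else -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def gc_bin_of(gc: float, boundaries: Sequence[float]) -> int:
    """Bin index of a GC fraction; boundaries are left-closed/right-open."""
    return bisect_right(list(boundaries), gc)


@dataclass
class GCProfile:
    """Per-window GC values and bin labels for one sequence.

    ``bin_index[i] == -1`` marks a window unusable for training (too much
    masked/ambiguous sequence). Bin labels come from the section-averaged
    GC, not the window's own GC.
    """

    window_size: int
    section_size: int
    bin_boundaries: Tuple[float, ...]
    window_gc: np.ndarray  # float per window, NaN when unusable
    bin_index: np.ndarray  # int per window, -1 when unusable

    @property
    def n_bins(self) -> int:
        return len(self.bin_boundaries) + 1

    @property
    def n_windows(self) -> int:
        return len(self.bin_index)


def gc_profile(
    seq: str,
    window_size: int = DEFAULT_WINDOW,
    section_size: int = DEFAULT_SECTION,
    bin_boundaries: Sequence[float] = DEFAULT_BIN_BOUNDARIES,
    max_n_fraction: float = DEFAULT_MAX_N_FRACTION,
) -> GCProfile:
    """Compute local GC in non-overlapping windows, binned by section average.

    Sentinel ('N') bases are ignored in the GC numerator and denominator;
    a window whose sentinel fraction exceeds *max_n_fraction* is flagged
    unusable. Each window's bin label is assigned from the mean GC of the
    usable windows in its enclosing section.
    """
    if section_size % window_size:
        raise ValueError("window_size must divide section_size")
    boundaries = tuple(bin_boundaries)
    if any(b2 <= b1 for b1, b2 in zip(boundaries, boundaries[1:])):
        raise ValueError("bin boundaries must be strictly increasing")
    n_windows = len(seq) // window_size
    if n_windows == 0:
        warnings.warn("sequence shorter than one window; empty GC profile")
        return GCProfile(
            window_size,
            section_size,
            boundaries,
            np.empty(0),
            np.empty(0, dtype=int),
        )
    codes = encode_bases(seq[: n_windows * window_size]).reshape(
        n_windows, window_size
    )
    n_valid = (codes >= 0).sum(axis=1)
    n_gc = ((codes == _BASE_INDEX["C"]) | (codes == _BASE_INDEX["G"])).sum(axis=1)
    usable = n_valid >= (1.0 - max_n_fraction) * window_size
    usable &= n_valid > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        window_gc = np.where(n_valid > 0, n_gc / np.maximum(n_valid, 1), np.nan)
    window_gc[~usable] = np.nan

    per_section = section_size // window_size
    bin_index = np.full(n_windows, -1, dtype=int)
    for s0 in range(0, n_windows, per_section):
        sl = slice(s0, min(s0 + per_section, n_windows))
        vals = window_gc[sl]
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        section_gc = float(vals[ok].mean())
        b = gc_bin_of(section_gc, boundaries)
        idx = np.arange(sl.start, sl.stop)[ok]
        bin_index[idx] = b
    return GCProfile(window_size, section_size, boundaries, window_gc, bin_index)


@dataclass
class KmerTable:
    """Empirical k-mer continuation probabilities, stratified by GC bin.

    ``tables[bin][context]`` is the probability vector over A/C/G/T of the
    base following *context* in windows of that bin. ``context_marginal``
    gives the occurrence distribution of contexts per bin (used to seed
    generation); ``mono`` the per-bin single-base distribution and
    ``pooled_mono`` the genome-wide one (both used as generation-time
    back-off when a context was never observed).
    """

    k: int
    n_bins: int
    tables: List[Dict[str, np.ndarray]]
    context_marginal: List[Dict[str, float]]
    mono: List[np.ndarray]
    pooled_mono: np.ndarray


def _count_kmers(
    genome: Mapping[str, str],
    profiles: Mapping[str, GCProfile],
    k: int,
    n_bins: int,
) -> np.ndarray:
    """Sparse counts of (bin, context-code, next-base) over usable windows.

    A (k+1)-mer is attributed to the window containing its first base and
    may extend past that window's end; any sentinel base invalidates it.
    Returns an array of (combined_code, count) pairs.
    """
    pow4 = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    all_codes: list[np.ndarray] = []
    all_counts: list[np.ndarray] = []
    for name, seq in genome.items():
        prof = profiles[name]
        codes = encode_bases(seq)
        n_pos = len(codes) - k
        if n_pos <= 0 or prof.n_windows == 0:
            continue
        view = np.lib.stride_tricks.sliding_window_view(codes, k + 1)[:n_pos]
        valid = (view >= 0).all(axis=1)
        win = np.arange(n_pos) // prof.window_size
        in_profile = win < prof.n_windows
        bins = np.where(in_profile, prof.bin_index[np.minimum(win, prof.n_windows - 1)], -1)
        keep = valid & (bins >= 0)
        if not keep.any():
            continue
        view = view[keep].astype(np.int64)
        ctx = view[:, :k] @ pow4
        nxt = view[:, k]
        combined = (bins[keep] * (4**k) + ctx) * 4 + nxt
        uniq, cnt = np.unique(combined, return_counts=True)
        all_codes.append(uniq)
        all_counts.append(cnt)
    if not all_codes:
        return np.empty((0, 2), dtype=np.int64)
    combined = np.concatenate(all_codes)
    counts = np.concatenate(all_counts)
    uniq, inv = np.unique(combined, return_inverse=True)
    summed = np.bincount(inv, weights=counts).astype(np.int64)
    return np.stack([uniq, summed], axis=1)


def _decode_context(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def train_kmer_table(
    genome: Mapping[str, str],
    profiles: Mapping[str, GCProfile],
    k: int = DEFAULT_K,
) -> KmerTable:
    """Tabulate P(next base | k-mer context, GC bin) from usable windows.

    Only sentinel-free (k+1)-mers starting in usable windows contribute.
    No pseudocounts are added: contexts never observed are simply absent
    (generation backs off instead of smoothing).
    """
    n_bins = next(iter(profiles.values())).n_bins
    pairs = _count_kmers(genome, profiles, k, n_bins)
    tables: List[Dict[str, np.ndarray]] = [dict() for _ in range(n_bins)]
    counts: List[Dict[str, np.ndarray]] = [dict() for _ in range(n_bins)]
    for code, cnt in pairs:
        nxt = int(code % 4)
        ctx_code = int(code // 4) % (4**k)
        b = int(code // 4) // (4**k)
        ctx = _decode_context(ctx_code, k)
        vec = counts[b].setdefault(ctx, np.zeros(4))
        vec[nxt] += cnt
    mono = []
    context_marginal: List[Dict[str, float]] = []
    pooled = np.zeros(4)
    for b in range(n_bins):
        bin_mono = np.zeros(4)
        total_ctx = 0.0
        marg: Dict[str, float] = {}
        for ctx, vec in counts[b].items():
            tables[b][ctx] = vec / vec.sum()
            marg[ctx] = float(vec.sum())
            total_ctx += vec.sum()
            bin_mono += vec
        if not counts[b]:
            warnings.warn(f"GC bin {b} has no usable windows; empty k-mer table")
        pooled += bin_mono
        mono.append(bin_mono / bin_mono.sum() if bin_mono.sum() else np.full(4, 0.25))
        context_marginal.append(
            {c: v / total_ctx for c, v in marg.items()} if total_ctx else {}
        )
    pooled = pooled / pooled.sum() if pooled.sum() else np.full(4, 0.25)
    return KmerTable(k, n_bins, tables, context_marginal, mono, pooled)


@dataclass
class GCTransitionMatrix:
    """Row-stochastic matrix of GC-bin transitions between adjacent windows."""

    matrix: np.ndarray
    initial: np.ndarray  # empirical bin occupancy, used to seed sampling

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def stationary(self) -> np.ndarray:
        """Stationary distribution (left eigenvector for eigenvalue 1)."""
        vals, vecs = np.linalg.eig(self.matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.real(vecs[:, i])
        v = np.abs(v)
        return v / v.sum()


def train_gc_transitions(profiles: Mapping[str, GCProfile] | GCProfile) -> GCTransitionMatrix:
    """Estimate bin-to-bin transition probabilities from adjacent usable windows.

    Pairs straddling an unusable window (or a sequence break) are not
    counted. A bin never seen as a source gets a uniform row.
    """
    if isinstance(profiles, GCProfile):
        profiles = {"_": profiles}
    n_bins = next(iter(profiles.values())).n_bins
    counts = np.zeros((n_bins, n_bins))
    occupancy = np.zeros(n_bins)
    for prof in profiles.values():
        b = prof.bin_index
        for bi in b[b >= 0]:
            occupancy[bi] += 1
        src, dst = b[:-1], b[1:]
        ok = (src >= 0) & (dst >= 0)
        np.add.at(counts, (src[ok], dst[ok]), 1)
    if counts.sum() == 0:
        raise ValueError("no adjacent usable window pairs; cannot train transitions")
    matrix = np.empty_like(counts)
    for i in range(n_bins):
        row = counts[i]
        if row.sum() == 0:
            warnings.warn(f"GC bin {i} never observed as source; uniform row")
            matrix[i] = 1.0 / n_bins
        else:
            matrix[i] = row / row.sum()
    initial = (
        occupancy / occupancy.sum() if occupancy.sum() else np.full(n_bins, 1 / n_bins)
    )
    return GCTransitionMatrix(matrix, initial)


@dataclass
class GenomeModel:
    """Trained background model: k-mer tables + GC-bin chain + metadata."""

    kmer_table: KmerTable
    gc_transitions: GCTransitionMatrix
    window_size: int = DEFAULT_WINDOW
    section_size: int = DEFAULT_SECTION
    bin_boundaries: Tuple[float, ...] = DEFAULT_BIN_BOUNDARIES
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.kmer_table.k

    @property
    def n_bins(self) -> int:
        return self.kmer_table.n_bins


def train_model(
    genome: Mapping[str, str],
    tracks: Sequence[IntervalSet] = (),
    k: int = DEFAULT_K,
    window_size: int = DEFAULT_WINDOW,
    section_size: int = DEFAULT_SECTION,
    bin_boundaries: Sequence[float] = DEFAULT_BIN_BOUNDARIES,
    source: str = "unknown",
) -> GenomeModel:
    """Mask functional regions, profile GC, and train the full model."""
    masked, retained = mask_regions(genome, tracks)
    profiles = {
        name: gc_profile(seq, window_size, section_size, bin_boundaries)
        for name, seq in masked.items()
    }
    profiles = {n: p for n, p in profiles.items() if p.n_windows > 0}
    if not profiles:
        raise ValueError("no sequence long enough for one window")
    kmer_table = train_kmer_table(masked, profiles, k)
    transitions = train_gc_transitions(profiles)
    meta = {
        "source": source,
        "retained_fraction": retained,
        "base_count": int(sum(len(s) for s in genome.values())),
    }
    return GenomeModel(
        kmer_table,
        transitions,
        window_size,
        section_size,
        tuple(bin_boundaries),
        meta,
    )


# ---------------------------------------------------------------------------
# Serialization: versioned JSON. Saves are deterministic (sorted keys, exact
# float round-trip via repr), so identical models give byte-identical files.
# ---------------------------------------------------------------------------


def save_model(model: GenomeModel, path) -> None:
    doc = {
        "format": "decoygen-model",
        "version": MODEL_FORMAT_VERSION,
        "k": model.k,
        "n_bins": model.n_bins,
        "window_size": model.window_size,
        "section_size": model.section_size,
        "bin_boundaries": list(model.bin_boundaries),
        "metadata": model.metadata,
        "kmer_tables": [
            {ctx: [float(x) for x in vec] for ctx, vec in sorted(tab.items())}
            for tab in model.kmer_table.tables
        ],
        "context_marginal": [
            {c: float(v) for c, v in sorted(m.items())}
            for m in model.kmer_table.context_marginal
        ],
        "mono": [[float(x) for x in v] for v in model.kmer_table.mono],
        "pooled_mono": [float(x) for x in model.kmer_table.pooled_mono],
        "transition_matrix": model.gc_transitions.matrix.tolist(),
        "initial_distribution": model.gc_transitions.initial.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")


def load_model(path) -> GenomeModel:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"corrupt or truncated model file {path}: {exc}")
    if doc.get("format") != "decoygen-model":
        raise ValueError(f"{path} is not a decoygen model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"model format version {doc.get('version')} unsupported "
            f"(expected {MODEL_FORMAT_VERSION})"
        )
    kt = KmerTable(
        k=doc["k"],
        n_bins=doc["n_bins"],
        tables=[
            {c: np.asarray(v, dtype=float) for c, v in tab.items()}
            for tab in doc["kmer_tables"]
        ],
        context_marginal=[dict(m) for m in doc["context_marginal"]],
        mono=[np.asarray(v, dtype=float) for v in doc["mono"]],
        pooled_mono=np.asarray(doc["pooled_mono"], dtype=float),
    )
    tm = GCTransitionMatrix(
        np.asarray(doc["transition_matrix"], dtype=float),
        np.asarray(doc["initial_distribution"], dtype=float),
    )
    return GenomeModel(
        kt,
        tm,
        doc["window_size"],
        doc["section_size"],
        tuple(doc["bin_boundaries"]),
        doc["metadata"],
    )
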