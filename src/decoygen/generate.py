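"""Base-sequence generation.

A GC-bin series is first sampled from the trained bin-transition chain
(one bin per window), then the sequence is extended base by base from
the per-bin k-mer continuation tables. The Markov context carries across
window boundaries — only the lookup table switches with the bin — so no
seam artifacts are introduced.

Unseen contexts are resolved by back-off: drop the leftmost context base
until a context observed in the current bin is found; failing that, use
the bin's mononucleotide distribution; failing that, the pooled-genome
distribution. The trained table itself is never smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model import BASES, GenomeModel


@dataclass
class GeneratorConfig:
    """Parameters of one generation run."""

    length: int
    gc_range: Optional[Tuple[float, float]] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.gc_range is not None:
            lo, hi = self.gc_range
            if not (0.0 <= lo < hi <= 1.0):
                raise ValueError("gc_range must be a subinterval of [0, 1]")


def _bin_span(i: int, boundaries: Tuple[float, ...]) -> Tuple[float, float]:
    lo = boundaries[i - 1] if i > 0 else 0.0
    hi = boundaries[i] if i < len(boundaries) else 1.0
    return lo, hi


def allowed_bins(
    model: GenomeModel, gc_range: Optional[Tuple[float, float]]
) -> np.ndarray:
    """Indices of GC bins overlapping *gc_range* (all bins if None)."""
    if gc_range is None:
        return np.arange(model.n_bins)
    lo, hi = gc_range
    out = [
        i
        for i in range(model.n_bins)
        if _bin_span(i, model.bin_boundaries)[0] < hi
        and _bin_span(i, model.bin_boundaries)[1] > lo
    ]
    if not out:
        raise ValueError(f"gc_range {gc_range} overlaps no GC bin")
    return np.asarray(out)


def _restrict(dist: np.ndarray, allowed: np.ndarray) -> np.ndarray:
    sub = np.zeros_like(dist)
    sub[allowed] = dist[allowed]
    if sub.sum() == 0:
        sub[allowed] = 1.0
    return sub / sub.sum()


def sample_bin_series(
    model: GenomeModel,
    n_windows: int,
    rng: np.random.Generator,
    gc_range: Optional[Tuple[float, float]] = None,
) -> np.ndarray:
    """Sample a window-bin series from the GC-transition chain.

    The first bin is drawn from the trained occupancy distribution; each
    subsequent bin from the corresponding matrix row. With *gc_range*,
    distributions are renormalized over the bins overlapping the range.
    """
    allowed = allowed_bins(model, gc_range)
    tm = model.gc_transitions
    series = np.empty(n_windows, dtype=int)
    current = int(rng.choice(model.n_bins, p=_restrict(tm.initial, allowed)))
    series[0] = current
    rows = [_restrict(tm.matrix[i], allowed) for i in range(model.n_bins)]
    for i in range(1, n_windows):
        current = int(rng.choice(model.n_bins, p=rows[current]))
        series[i] = current
    return series


class _BinSampler:
    """Cumulative-probability lookups for one GC bin, with back-off cache."""

    def __init__(self, model: GenomeModel, b: int):
        kt = model.kmer_table
        self.k = kt.k
        self.full = {ctx: np.cumsum(p) for ctx, p in kt.tables[b].items()}
        self._raw = kt.tables[b]
        self._marginal = kt.context_marginal[b]
        self._backoff: Dict[str, np.ndarray] = {}
        mono = kt.mono[b] if kt.tables[b] else kt.pooled_mono
        self.mono_cum = np.cumsum(mono)
        marg = sorted(self._marginal.items())
        self.seed_contexts = [c for c, _ in marg]
        self.seed_cum = np.cumsum([p for _, p in marg]) if marg else None

    def cum_for(self, ctx: str) -> np.ndarray:
        """P(next | ctx) as a cumulative vector, backing off on misses."""
        hit = self.full.get(ctx)
        if hit is not None:
            return hit
        for j in range(1, self.k):
            suffix = ctx[j:]
            cached = self._backoff.get(suffix)
            if cached is not None:
                return cached
            agg = np.zeros(4)
            for c, w in self._marginal.items():
                if c.endswith(suffix):
                    agg += w * self._raw[c]
            if agg.sum() > 0:
                cum = np.cumsum(agg / agg.sum())
                self._backoff[suffix] = cum
                return cum
        return self.mono_cum


def extend_sequence(
    model: GenomeModel,
    bin_series: np.ndarray,
    rng: np.random.Generator,
    length: Optional[int] = None,
) -> str:
    """Generate DNA following the bin series, one window per bin label.

    Output length is ``len(bin_series) * window_size``, truncated to
    *length* when given (the final window is cut short rather than the
    target padded). The initial k-mer context is drawn from the first
    bin's context-occurrence distribution.
    """
    w = model.window_size
    total = len(bin_series) * w
    if length is not None:
        if length > total:
            raise ValueError("length exceeds bin series capacity")
        total = length
    k = model.k
    samplers = [_BinSampler(model, b) for b in range(model.n_bins)]

    out: List[str] = []
    s0 = samplers[bin_series[0]]
    if s0.seed_cum is not None:
        i = int(np.searchsorted(s0.seed_cum, rng.random() * s0.seed_cum[-1]))
        ctx = s0.seed_contexts[min(i, len(s0.seed_contexts) - 1)]
    else:
        ctx = "".join(
            BASES[int(np.searchsorted(s0.mono_cum, rng.random() * s0.mono_cum[-1]))]
            for _ in range(k)
        )
    out.extend(ctx)
    randoms = rng.random(max(total - len(out), 0))
    pos = len(out)
    for i in range(total - pos):
        sampler = samplers[bin_series[(pos + i) // w]]
        cum = sampler.cum_for(ctx)
        b = int(np.searchsorted(cum, randoms[i] * cum[-1]))
        b = min(b, 3)
        base = BASES[b]
        out.append(base)
        ctx = ctx[1:] + base
    return "".join(out[:total])


def generate_base(
    model: GenomeModel, config: GeneratorConfig, rng: np.random.Generator
) -> Tuple[str, np.ndarray]:
    """Sample a bin series long enough for ``config.length`` and extend it."""
    n_windows = -(-config.length // model.window_size)
    series = sample_bin_series(model, n_windows, rng, config.gc_range)
    seq = extend_sequence(model, series, rng, length=config.length)
    return seq, series
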