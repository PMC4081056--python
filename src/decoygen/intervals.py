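"""Genomic interval sets and functional-region masking.

Coordinates are 0-based half-open throughout. BED input is used as-is;
any interval source with 1-based inclusive coordinates must be converted
by its reader before reaching :class:`IntervalSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Tuple

import pandas as pd

MASK_SENTINEL = "N"


@dataclass
class IntervalSet:
    """Per-sequence sorted, merged lists of (start, end) half-open ranges."""

    ranges: Dict[str, List[Tuple[int, int]]] = field(default_factory=dict)
    name: str = "intervals"

    def __post_init__(self) -> None:
        for seq, ivs in self.ranges.items():
            for s, e in ivs:
                if s >= e:
                    raise ValueError(
                        f"{self.name}: invalid interval ({s},{e}) on {seq!r}"
                    )
            self.ranges[seq] = merge_intervals(ivs)

    def clipped(self, seq: str, length: int) -> List[Tuple[int, int]]:
        """Intervals for *seq* clipped to [0, length)."""
        out = []
        for s, e in self.ranges.get(seq, []):
            s, e = max(0, s), min(length, e)
            if s < e:
                out.append((s, e))
        return out

    def total_span(self) -> int:
        return sum(e - s for ivs in self.ranges.values() for s, e in ivs)


def merge_intervals(ivs: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Union of half-open intervals: sorted and non-overlapping."""
    ivs = sorted(ivs)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def read_bed(path, name: str | None = None) -> IntervalSet:
    """Read a BED3+ file into an IntervalSet (columns beyond 3 ignored)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": int, "end": int},
    )
    ranges: Dict[str, List[Tuple[int, int]]] = {}
    for chrom, s, e in df.itertuples(index=False):
        ranges.setdefault(chrom, []).append((int(s), int(e)))
    return IntervalSet(ranges, name=name or str(path))


def mask_regions(
    genome: Mapping[str, str], tracks: Iterable[IntervalSet]
) -> Tuple[Dict[str, str], float]:
    """Replace every base covered by any track with the sentinel 'N'.

    Masking takes union semantics over tracks, so it is idempotent and
    order-independent. Returns the masked genome and the retained
    (unmasked) fraction of the input bases.

    Raises
    ------
    KeyError
        If a track names a sequence absent from the genome.
    """
    tracks = list(tracks)
    for track in tracks:
        for seq in track.ranges:
            if seq not in genome:
                raise KeyError(
                    f"track {track.name!r} refers to unknown sequence {seq!r}"
                )
    masked: Dict[str, str] = {}
    total = retained = 0
    for name, seq in genome.items():
        ivs = merge_intervals(
            iv for track in tracks for iv in track.clipped(name, len(seq))
        )
        chars = list(seq)
        covered = 0
        for s, e in ivs:
            covered += e - s
            chars[s:e] = MASK_SENTINEL * (e - s)
        masked[name] = "".join(chars)
        total += len(seq)
        retained += len(seq) - covered
    fraction = retained / total if total else 1.0
    return masked, fraction
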