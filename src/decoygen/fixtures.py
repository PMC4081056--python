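"""Synthetic toy genome + annotations for self-contained training runs.

The fixture emulates, at desk scale, the inputs a real training run
needs: a genome with GC-content structure (blocks of distinct G+C),
masked "gene" regions, planted interspersed repeats evolved from a toy
consensus library (including a fragmented element with a younger
element nested in the gap), and planted tandem repeats with TRF-style
records. Planted copies are written into the RepeatMasker-dialect
annotation with divergence measured by global alignment against the
consensus — not copied from the requested parameters — so the
annotations are honest with respect to the sequence.

What it does not emulate: real isochore length distributions, CpG
islands, satellite/telomeric arrays, and the long-range correlation
structure of real genomes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evolution import EvolutionParams, evolve, expand_monomer, trim_consensus
from .intervals import IntervalSet
from .repeats import (
    RepeatAnnotation,
    SimpleRepeatAnnotation,
    write_repeatmasker_out,
)

CHROM = "chrT"


@dataclass
class FixtureSpec:
    """Shape of the toy genome."""

    genome_length: int = 200_000
    gc_blocks: Tuple[float, ...] = (0.35, 0.55)
    block_length: int = 25_000  # GC blocks cycle so both transition directions occur
    divergence_levels: Tuple[float, ...] = (5.0, 10.0, 20.0)
    copies_per_level: int = 4
    n_gene_blocks: int = 4
    gene_block_length: int = 3_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 20_000:
            raise ValueError("toy genome must be at least 20 kb")


# toy consensus library: (class/family string, length or monomer)
TOY_FAMILIES = {
    "TSINE1": ("SINE/toy", 300),
    "TLINE1": ("LINE/toy", 1_500),
}
TOY_MONOMERS = ("AT", "CAG")


@dataclass
class ToyFixture:
    """In-memory toy genome with its complete planted truth."""

    genome: Dict[str, str]
    gene_mask: IntervalSet
    repeat_mask: IntervalSet
    rm_annotations: List[RepeatAnnotation]
    trf_annotations: List[SimpleRepeatAnnotation]
    consensus: Dict[str, str]
    truth: List[dict] = field(default_factory=list)


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> str:
    p = np.asarray([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.asarray(list("ACGT"))[rng.choice(4, size=n, p=p)])


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -0.5


def alignment_identity(a: str, b: str) -> float:
    """Percent identity of the best global alignment of a and b."""
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    total = counts.identities + counts.mismatches + counts.gaps
    return 100.0 * counts.identities / total


def measured_divergence(evolved: str, consensus_slice: str) -> float:
    """Divergence (100 - % identity) measured by alignment, not assumed."""
    return 100.0 - alignment_identity(evolved, consensus_slice)


def _reserve(
    occupied: List[Tuple[int, int]],
    length: int,
    genome_length: int,
    rng: np.random.Generator,
    pad: int = 50,
) -> Optional[int]:
    """Find a start so [start, start+length) clears all occupied intervals."""
    for _ in range(200):
        start = int(rng.integers(0, genome_length - length))
        if all(start + length + pad <= s or start >= e + pad for s, e in occupied):
            occupied.append((start, start + length))
            return start
    return None


def make_toy_genome(spec: FixtureSpec) -> ToyFixture:
    """Build the toy genome, its masks, annotations and consensus library."""
    rng = np.random.default_rng(spec.seed)
    pieces = []
    pos = 0
    i = 0
    while pos < spec.genome_length:
        n = min(spec.block_length, spec.genome_length - pos)
        pieces.append(_random_dna(n, spec.gc_blocks[i % len(spec.gc_blocks)], rng))
        pos += n
        i += 1
    background = "".join(pieces)
    genome_length = len(background)
    chars = list(background)
    occupied: List[Tuple[int, int]] = []
    truth: List[dict] = []

    consensus = {
        fam: _random_dna(length, 0.45, rng) for fam, (_, length) in TOY_FAMILIES.items()
    }

    # gene blocks (mask targets; content left as background)
    gene_ranges = []
    for _ in range(spec.n_gene_blocks):
        s = _reserve(occupied, spec.gene_block_length, genome_length, rng)
        if s is not None:
            gene_ranges.append((s, s + spec.gene_block_length))

    rm: List[RepeatAnnotation] = []
    link = 0

    def plant(fam: str, div: float, length: int, link_id: str) -> Optional[dict]:
        class_family, _ = TOY_FAMILIES[fam]
        sl, _start = trim_consensus(
            consensus[fam], length, rng, class_family.split("/")[0]
        )
        params = EvolutionParams(
            length=len(sl), divergence=div, ins_pct=1.0, del_pct=1.0
        )
        seq, _log = evolve(sl, params, rng)
        s = _reserve(occupied, len(seq), genome_length, rng)
        if s is None:
            return None
        chars[s : s + len(seq)] = seq
        realized = measured_divergence(seq, sl)
        rm.append(
            RepeatAnnotation(
                seqname=CHROM,
                start=s,
                end=s + len(seq),
                strand="+",
                family=fam,
                class_family=class_family,
                divergence=round(realized, 1),
                deletion=params.del_pct,
                insertion=params.ins_pct,
                link_id=link_id,
            )
        )
        return {
            "family": fam,
            "start": s,
            "end": s + len(seq),
            "requested_divergence": div,
            "measured_divergence": realized,
        }

    for fam in TOY_FAMILIES:
        for div in spec.divergence_levels:
            for _ in range(spec.copies_per_level):
                link += 1
                t = plant(fam, div, TOY_FAMILIES[fam][1], str(link))
                if t:
                    truth.append(t)

    # one fragmented LINE with a younger SINE nested in the gap
    link += 1
    host_id = str(link)
    host_div = max(spec.divergence_levels)
    guest_div = min(spec.divergence_levels)
    line_cons = consensus["TLINE1"]
    half = len(line_cons) // 2
    sine_len = TOY_FAMILIES["TSINE1"][1]
    total = len(line_cons) + sine_len
    s = _reserve(occupied, total, genome_length, rng)
    if s is not None:
        frag1, _ = evolve(
            line_cons[:half], EvolutionParams(half, host_div), rng
        )
        frag2, _ = evolve(
            line_cons[half:], EvolutionParams(len(line_cons) - half, host_div), rng
        )
        guest, _ = evolve(
            consensus["TSINE1"], EvolutionParams(sine_len, guest_div), rng
        )
        piece = frag1 + guest + frag2
        chars[s : s + len(piece)] = piece
        a = s
        b = a + len(frag1)
        c = b + len(guest)
        d = c + len(frag2)
        rm.append(
            RepeatAnnotation(
                CHROM, a, b, "+", "TLINE1", "LINE/toy",
                round(measured_divergence(frag1, line_cons[:half]), 1),
                0.0, 0.0, link_id=host_id,
            )
        )
        link += 1
        rm.append(
            RepeatAnnotation(
                CHROM, b, c, "+", "TSINE1", "SINE/toy",
                round(measured_divergence(guest, consensus["TSINE1"]), 1),
                0.0, 0.0, link_id=str(link),
            )
        )
        rm.append(
            RepeatAnnotation(
                CHROM, c, d, "+", "TLINE1", "LINE/toy",
                round(measured_divergence(frag2, line_cons[half:]), 1),
                0.0, 0.0, link_id=host_id,
            )
        )

    # tandem repeats with TRF-style records
    trf: List[SimpleRepeatAnnotation] = []
    for monomer in TOY_MONOMERS:
        for div in spec.divergence_levels[:2]:
            length = int(rng.integers(60, 200))
            array = expand_monomer(monomer, length)
            seq, _ = evolve(array, EvolutionParams(length, div), rng)
            s = _reserve(occupied, len(seq), genome_length, rng)
            if s is None:
                continue
            chars[s : s + len(seq)] = seq
            identity = alignment_identity(seq, array)
            trf.append(
                SimpleRepeatAnnotation(
                    seqname=CHROM,
                    start=s,
                    end=s + len(seq),
                    monomer=monomer,
                    copy_number=round(len(seq) / len(monomer), 1),
                    pct_matches=round(identity, 1),
                    pct_indels=0.0,
                )
            )

    genome = {CHROM: "".join(chars)}
    gene_mask = IntervalSet({CHROM: gene_ranges}, name="genes") if gene_ranges else IntervalSet({}, name="genes")
    repeat_ranges = [(a.start, a.end) for a in rm] + [(a.start, a.end) for a in trf]
    repeat_mask = IntervalSet({CHROM: repeat_ranges}, name="repeats")
    rm.sort(key=lambda a: a.start)
    trf.sort(key=lambda a: a.start)
    return ToyFixture(genome, gene_mask, repeat_mask, rm, trf, consensus, truth)


def write_trf_dat(annotations: List[SimpleRepeatAnnotation], fh) -> None:
    """Write TRF `.dat`-style records (1-based inclusive coordinates)."""
    by_seq: Dict[str, List[SimpleRepeatAnnotation]] = {}
    for a in annotations:
        by_seq.setdefault(a.seqname, []).append(a)
    for seqname in sorted(by_seq):
        fh.write(f"Sequence: {seqname}\n\n")
        for a in by_seq[seqname]:
            fh.write(
                f"{a.start + 1} {a.end} {len(a.monomer)} {a.copy_number} "
                f"{len(a.monomer)} {a.pct_matches} {a.pct_indels} 50 "
                f"25 25 25 25 1.9 {a.monomer} "
                f"{expand_monomer(a.monomer, a.end - a.start)}\n"
            )


def write_fixture_files(fix: ToyFixture, outdir: str) -> Dict[str, str]:
    """Write the fixture as the standard input files a training run reads."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "genes": os.path.join(outdir, "genes.bed"),
        "repeats_bed": os.path.join(outdir, "repeats.bed"),
        "repeats_out": os.path.join(outdir, "repeats.out"),
        "trf": os.path.join(outdir, "simple.dat"),
        "consensus": os.path.join(outdir, "consensus.fa"),
    }
    with open(paths["genome"], "w") as fh:
        SeqIO.write(
            [SeqRecord(Seq(s), id=n, description="") for n, s in fix.genome.items()],
            fh,
            "fasta",
        )
    with open(paths["genes"], "w") as fh:
        for seq, ivs in fix.gene_mask.ranges.items():
            for s, e in ivs:
                fh.write(f"{seq}\t{s}\t{e}\tgene\n")
    with open(paths["repeats_bed"], "w") as fh:
        for seq, ivs in fix.repeat_mask.ranges.items():
            for s, e in ivs:
                fh.write(f"{seq}\t{s}\t{e}\trepeat\n")
    with open(paths["repeats_out"], "w") as fh:
        write_repeatmasker_out(fix.rm_annotations, fh)
    with open(paths["trf"], "w") as fh:
        write_trf_dat(fix.trf_annotations, fh)
    with open(paths["consensus"], "w") as fh:
        for fam, seq in fix.consensus.items():
            class_family = TOY_FAMILIES[fam][0]
            fh.write(f">{fam}#{class_family}\n")  # RepBase-style name#class/family
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    return paths
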