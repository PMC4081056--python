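"""Assembly of artificial sequences: repeat insertion and ground truth.

Evolved repeats are spliced into the base sequence (the sequence grows;
nothing is overwritten, so the base-sequence statistics between repeats
are preserved) oldest-first: the plan is sorted by divergence
descending, using divergence from consensus as a proxy for age. Each
insert lands at a random position in a window whose local GC bin — read
from the current, partially assembled sequence — matches the bin the
instance was annotated in, on a random strand.

Because younger elements may land inside older ones, an insertion that
falls strictly inside an existing record splits that record into linked
fragments, exactly as RepeatMasker annotates interrupted elements. This
keeps the ground truth byte-exact: slicing any record's interval out of
the final FASTA returns the corresponding piece of the evolved repeat
(or of its reverse complement on the minus strand).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .evolution import EvolutionParams, EvolvedRepeat, evolve_instance, revcomp
from .generate import GeneratorConfig, _BinSampler, generate_base
from .model import GenomeModel, encode_bases, gc_bin_of
from .repeats import (
    NestingTable,
    RepeatAnnotation,
    RepeatFamilyModel,
    write_repeatmasker_out,
)


@dataclass
class InsertRecord:
    """One fragment of one planted repeat element on the final sequence."""

    element_id: int
    family: str
    repeat_class: str
    start: int
    end: int
    strand: str
    divergence: float
    ins_pct: float
    del_pct: float
    fragment_index: int = 0
    parent_id: Optional[int] = None
    nested_in_host: bool = False  # guest planted during host evolution
    kind: str = "interspersed"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ArtificialSequence:
    """Generated DNA plus the complete ground truth of its construction."""

    name: str
    seq: str
    records: List[InsertRecord] = field(default_factory=list)
    elements: Dict[int, EvolvedRepeat] = field(default_factory=dict)
    provenance: Dict[str, object] = field(default_factory=dict)

    def repeat_fraction(self) -> float:
        """Fraction of bases covered by any annotated repeat (interval union)."""
        if not self.records or not self.seq:
            return 0.0
        cov = np.zeros(len(self.seq), dtype=bool)
        for r in self.records:
            cov[r.start : r.end] = True
        return float(cov.mean())


def plan_insertions(
    models: Mapping[str, RepeatFamilyModel],
    fraction: float,
    base_length: int,
    bin_series: np.ndarray,
    rng: np.random.Generator,
    families: Optional[Sequence[str]] = None,
    titv: float = 2.0,
) -> List[Tuple[str, EvolutionParams]]:
    """Sample instances until the target repetitive fraction is covered.

    The final sequence length is ``base_length / (1 - fraction)``;
    instances are drawn — families proportional to their per-GC-bin
    abundance mixed by the bin occupancy of the planned series — until
    the planned repeat bases reach ``fraction`` of it. The plan is
    returned sorted by divergence descending (oldest first).
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("repeat fraction must be in [0, 1)")
    if fraction == 0.0:
        return []
    pool = {
        name: m
        for name, m in models.items()
        if families is None or name in families or m.family in families
    }
    if not pool:
        raise ValueError("no repeat family available for planning")
    final_length = base_length / (1.0 - fraction)
    target_bases = fraction * final_length

    names = sorted(pool)
    n_bins = len(next(iter(pool.values())).bases_per_bin)
    occupancy = np.bincount(bin_series, minlength=n_bins) / max(len(bin_series), 1)
    per_bin = np.stack([pool[n].bases_per_bin for n in names])  # family x bin
    col = per_bin.sum(axis=0)
    norm = np.divide(per_bin, col, out=np.zeros_like(per_bin), where=col > 0)
    weights = norm @ occupancy
    if weights.sum() == 0:
        weights = per_bin.sum(axis=1)
    weights = weights / weights.sum()

    plan: List[Tuple[str, EvolutionParams]] = []
    planned = 0.0
    while planned < target_bases:
        fam = names[int(rng.choice(len(names), p=weights))]
        rec = pool[fam].sample_instance(rng)
        params = EvolutionParams.from_instance(rec, titv=titv)
        plan.append((fam, params))
        planned += params.length
    plan.sort(key=lambda fp: -fp[1].divergence)
    return plan


def _window_gc_bins(
    seq: str, window_size: int, boundaries: Tuple[float, ...]
) -> np.ndarray:
    """GC bin of each (possibly trailing-partial) window of *seq*."""
    codes = encode_bases(seq)
    n_windows = -(-len(seq) // window_size)
    bins = np.empty(n_windows, dtype=int)
    for w in range(n_windows):
        chunk = codes[w * window_size : (w + 1) * window_size]
        gc = float(((chunk == 1) | (chunk == 2)).mean()) if len(chunk) else 0.0
        bins[w] = gc_bin_of(gc, boundaries)
    return bins


def _choose_position(
    seq: str,
    want_bin: int,
    window_size: int,
    boundaries: Tuple[float, ...],
    rng: np.random.Generator,
) -> int:
    bins = _window_gc_bins(seq, window_size, boundaries)
    candidates = np.flatnonzero(bins == want_bin)
    if len(candidates) == 0:  # nearest bin, then uniform
        dist = np.abs(bins - want_bin)
        candidates = np.flatnonzero(dist == dist.min())
    if len(candidates) == 0:
        return int(rng.integers(0, len(seq) + 1))
    w = int(candidates[int(rng.integers(len(candidates)))])
    lo = w * window_size
    hi = min((w + 1) * window_size, len(seq))
    return int(rng.integers(lo, hi + 1))


def _flatten_element(
    rep: EvolvedRepeat, start: int, strand: str, element_id: int,
    next_id: List[int], parent_id: Optional[int],
    elements: Dict[int, EvolvedRepeat], records: List[InsertRecord],
    nested: bool = False,
) -> None:
    """Emit records for an evolved element and its evolution-time guests."""
    elements[element_id] = rep
    records.append(
        InsertRecord(
            element_id=element_id,
            family=rep.family,
            repeat_class=rep.repeat_class,
            start=start,
            end=start + len(rep.seq),
            strand=strand,
            divergence=rep.params.divergence,
            ins_pct=rep.params.ins_pct,
            del_pct=rep.params.del_pct,
            parent_id=parent_id,
            nested_in_host=nested,
            kind=rep.kind,
        )
    )
    for off, child in rep.children:
        if strand == "-":
            child_start = start + len(rep.seq) - off - len(child.seq)
            child_strand = "-"
        else:
            child_start = start + off
            child_strand = "+"
        next_id[0] += 1
        _flatten_element(
            child, child_start, child_strand, next_id[0], next_id,
            element_id, elements, records, nested=True,
        )


def insert_repeats(
    base_seq: str,
    plan: Sequence[Tuple[str, EvolutionParams]],
    models: Mapping[str, RepeatFamilyModel],
    nesting_table: Optional[NestingTable],
    model: GenomeModel,
    rng: np.random.Generator,
    name: str = "artificial",
) -> ArtificialSequence:
    """Evolve and splice each planned repeat into the growing sequence.

    The plan must already be sorted oldest-first. Insertions shift all
    downstream coordinates; a position strictly inside an existing
    record splits it into two linked fragments of the same element.
    """
    art = ArtificialSequence(name=name, seq=base_seq)
    samplers: Dict[int, _BinSampler] = {}
    next_id = [0]
    for fam_name, params in plan:
        fam = models[fam_name]
        b = min(params.gc_bin, model.n_bins - 1)
        sampler = samplers.setdefault(b, _BinSampler(model, b))

        def base_sampler(context: str, _s=sampler, _k=model.k) -> str:
            cum = _s.cum_for(context[-_k:]) if len(context) >= _k else _s.mono_cum
            from .model import BASES

            return BASES[min(int(np.searchsorted(cum, rng.random() * cum[-1])), 3)]

        rep = evolve_instance(
            fam,
            params,
            rng,
            nesting_table=nesting_table,
            models=dict(models),
            base_sampler=base_sampler,
        )
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = rep.seq if strand == "+" else revcomp(rep.seq)
        pos = _choose_position(
            art.seq, b, model.window_size, model.bin_boundaries, rng
        )
        L = len(inserted)

        updated: List[InsertRecord] = []
        parent_for_new: Optional[int] = None
        innermost_start = -1
        for r in art.records:
            if r.end <= pos:
                updated.append(r)
            elif r.start >= pos:
                r.start += L
                r.end += L
                updated.append(r)
            else:  # strictly inside: split into two fragments
                left = InsertRecord(**{**r.__dict__, "end": pos})
                right = InsertRecord(
                    **{**r.__dict__, "start": pos + L, "end": r.end + L}
                )
                updated.extend([left, right])
                if r.start > innermost_start:  # innermost containing element
                    innermost_start = r.start
                    parent_for_new = r.element_id
        art.records = updated
        art.seq = art.seq[:pos] + inserted + art.seq[pos:]
        next_id[0] += 1
        _flatten_element(
            rep, pos, strand, next_id[0], next_id, parent_for_new,
            art.elements, art.records,
        )

    # renumber fragment indices per element in genomic order
    by_element: Dict[int, List[InsertRecord]] = {}
    for r in art.records:
        by_element.setdefault(r.element_id, []).append(r)
    for recs in by_element.values():
        recs.sort(key=lambda r: r.start)
        for i, r in enumerate(recs):
            r.fragment_index = i
    art.records.sort(key=lambda r: (r.start, r.end))
    return art


def generate_artificial(
    model: GenomeModel,
    repeat_models: Mapping[str, RepeatFamilyModel],
    nesting_table: Optional[NestingTable],
    length: int,
    repeat_fraction: float = 0.0,
    gc_range: Optional[Tuple[float, float]] = None,
    seed: Optional[int] = None,
    families: Optional[Sequence[str]] = None,
    titv: float = 2.0,
    name: str = "artificial",
) -> ArtificialSequence:
    """Full generation pipeline: base sequence + repeat bombardment.

    *length* is the target length of the final sequence; the base
    sequence is generated correspondingly shorter so that splice-in
    insertion realizes the requested repetitive fraction.
    """
    rng = np.random.default_rng(seed)
    base_length = max(model.window_size, round(length * (1.0 - repeat_fraction)))
    config = GeneratorConfig(length=base_length, gc_range=gc_range, seed=seed)
    base_seq, bin_series = generate_base(model, config, rng)
    plan = plan_insertions(
        repeat_models, repeat_fraction, base_length, bin_series, rng,
        families=families, titv=titv,
    ) if repeat_fraction > 0 else []
    art = insert_repeats(
        base_seq, plan, repeat_models, nesting_table, model, rng, name=name
    )
    cfg = {
        "length": length,
        "repeat_fraction": repeat_fraction,
        "gc_range": list(gc_range) if gc_range else None,
        "families": list(families) if families else None,
        "titv": titv,
        "k": model.k,
        "window_size": model.window_size,
    }
    art.provenance = {
        "generator": "decoygen",
        "model_source": model.metadata.get("source", "unknown"),
        "seed": seed,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
    }
    return art


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------


def records_to_annotations(art: ArtificialSequence) -> List[RepeatAnnotation]:
    out = []
    for r in art.records:
        out.append(
            RepeatAnnotation(
                seqname=art.name,
                start=r.start,
                end=r.end,
                strand=r.strand,
                family=r.family,
                class_family=r.repeat_class,
                divergence=min(r.divergence, 100.0),
                deletion=min(r.del_pct, 100.0),
                insertion=min(r.ins_pct, 100.0),
                link_id=str(r.element_id),
            )
        )
    return out


def write_outputs(art: ArtificialSequence, prefix: str) -> Dict[str, str]:
    """Write FASTA + BED + RepeatMasker-dialect + mutation log + provenance."""
    paths = {
        "fasta": f"{prefix}.fa",
        "bed": f"{prefix}.bed",
        "out": f"{prefix}.out",
        "mutations": f"{prefix}.mutations.tsv",
        "provenance": f"{prefix}.provenance.json",
    }
    record = SeqRecord(Seq(art.seq), id=art.name, description="")
    with open(paths["fasta"], "w") as fh:
        SeqIO.write([record], fh, "fasta")
    with open(paths["bed"], "w") as fh:
        for r in art.records:
            fh.write(
                f"{art.name}\t{r.start}\t{r.end}\t"
                f"{r.family}|{r.element_id}|{r.fragment_index}\t0\t{r.strand}\n"
            )
    with open(paths["out"], "w") as fh:
        write_repeatmasker_out(records_to_annotations(art), fh)
    with open(paths["mutations"], "w") as fh:
        fh.write("element_id\tfamily\tevent_index\top\tpos\tbefore\tafter\n")
        for eid in sorted(art.elements):
            rep = art.elements[eid]
            for i, ev in enumerate(rep.log.events):
                fh.write(
                    f"{eid}\t{rep.family}\t{i}\t{ev.op}\t{ev.pos}\t"
                    f"{ev.before}\t{ev.after}\n"
                )
    with open(paths["provenance"], "w") as fh:
        json.dump(art.provenance, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return paths


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (baseline decoy method)
# ---------------------------------------------------------------------------


def _ae_shuffle_window(s: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle of one window.

    Uniformly samples a sequence with the same dinucleotide multiset and
    the same first and last base, via a random Eulerian path in the
    dinucleotide multigraph (random last-edge arborescence toward the
    final vertex, then random order of the remaining edges).
    """
    if len(s) < 3:
        return s
    edges: Dict[str, List[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    sink = s[-1]
    vertices = [v for v in edges if v != sink]
    while True:
        last_edge = {
            v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices
        }
        ok = True
        for v in vertices:
            seen = set()
            u = v
            while u != sink:
                if u in seen or (u not in last_edge and u != sink):
                    ok = False
                    break
                seen.add(u)
                u = last_edge[u]
            if not ok:
                break
        if ok:
            break
    walk_lists: Dict[str, List[str]] = {}
    for v, lst in edges.items():
        rest = list(lst)
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        walk_lists[v] = rest
    result = [s[0]]
    cursor = {v: 0 for v in walk_lists}
    u = s[0]
    while u in cursor and cursor[u] < len(walk_lists[u]):
        nxt = walk_lists[u][cursor[u]]
        cursor[u] += 1
        result.append(nxt)
        u = nxt
    return "".join(result)


def shuffle_dinucleotide(
    seq: str, rng: np.random.Generator, window: Optional[int] = None
) -> str:
    """Shuffle preserving the exact dinucleotide multiset per window.

    With *window*, each non-overlapping window is permuted independently
    (local shuffling); windows shorter than 2 are returned unchanged.
    """
    if window is None:
        return _ae_shuffle_window(seq, rng)
    out = []
    for i in range(0, len(seq), window):
        out.append(_ae_shuffle_window(seq[i : i + window], rng))
    return "".join(out)
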