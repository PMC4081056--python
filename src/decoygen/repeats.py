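"""Empirical repeat-family models from RepeatMasker and TRF annotations.

For every annotated interspersed repeat we keep the joint tuple
(length, divergence, insertion %, deletion %, fragment count, GC bin)
of each genomic instance, tied to the family consensus. Sampling an
instance is a bootstrap draw from these tuples, which preserves the
covariance between age (divergence), truncation length and GC placement
that independent marginals would destroy. Simple (tandem) repeats from
TRF are modeled the same way, keyed by their consensus monomer.

Nesting — the interruption of an older element by a younger one — is
tabulated from fragmented elements: when one annotation's span lies in
the gap between two fragments of another element, the pair counts as
(host, guest).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, TextIO, Tuple

import numpy as np

from .model import GCProfile

RM_CLASSES = ("SINE", "LINE", "LTR", "DNA")


def repeat_class_of(class_family: str) -> str:
    """Collapse a RepeatMasker class/family string to its major class."""
    head = class_family.split("/")[0]
    return head if head in RM_CLASSES else "Other"


@dataclass
class RepeatAnnotation:
    """One RepeatMasker `.out` row, coordinates converted to 0-based half-open."""

    seqname: str
    start: int
    end: int
    strand: str  # '+' or '-'
    family: str
    class_family: str
    divergence: float
    deletion: float
    insertion: float
    link_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (self.start < self.end):
            raise ValueError(f"empty repeat interval {self.start}..{self.end}")
        for v in (self.divergence, self.deletion, self.insertion):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"percentage {v} outside [0, 100]")

    @property
    def repeat_class(self) -> str:
        return repeat_class_of(self.class_family)


@dataclass
class SimpleRepeatAnnotation:
    """One Tandem Repeat Finder record (0-based half-open)."""

    seqname: str
    start: int
    end: int
    monomer: str
    copy_number: float
    pct_matches: float
    pct_indels: float

    def __post_init__(self) -> None:
        if not self.monomer or set(self.monomer) - set("ACGT"):
            raise ValueError(f"invalid monomer {self.monomer!r}")
        if not (self.start < self.end):
            raise ValueError("empty simple-repeat interval")


def parse_repeatmasker_out(
    stream: Iterable[str], strict: bool = False
) -> List[RepeatAnnotation]:
    """Parse RepeatMasker `.out` text (3 header lines, whitespace columns).

    File coordinates are 1-based inclusive and strand 'C' means minus;
    both are converted. Malformed lines are skipped with a warning unless
    *strict*.
    """
    out: List[RepeatAnnotation] = []
    skipped = 0
    for line in stream:
        fields = line.split()
        if not fields or not fields[0].replace(".", "").isdigit():
            continue  # header / blank
        try:
            strand = fields[8]
            out.append(
                RepeatAnnotation(
                    seqname=fields[4],
                    start=int(fields[5]) - 1,
                    end=int(fields[6]),
                    strand="-" if strand == "C" else "+",
                    family=fields[9],
                    class_family=fields[10],
                    divergence=float(fields[1]),
                    deletion=float(fields[2]),
                    insertion=float(fields[3]),
                    link_id=fields[14] if len(fields) > 14 else None,
                )
            )
        except (IndexError, ValueError) as exc:
            if strict:
                raise ValueError(f"malformed RepeatMasker line: {line!r}") from exc
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} malformed RepeatMasker line(s)")
    return out


RM_HEADER = (
    "   SW   perc perc perc  query      position in query           matching"
    "       repeat              position in repeat\n"
    "score   div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def write_repeatmasker_out(annotations: Iterable[RepeatAnnotation], fh: TextIO) -> None:
    """Write annotations in the RepeatMasker `.out` dialect (round-trips)."""
    fh.write(RM_HEADER)
    for i, a in enumerate(annotations):
        strand = "C" if a.strand == "-" else "+"
        span = a.end - a.start
        fh.write(
            f"{1000:>5} {a.divergence:>6.1f} {a.deletion:>4.1f} {a.insertion:>4.1f}  "
            f"{a.seqname:<10} {a.start + 1:>8} {a.end:>8} (0)  {strand}  "
            f"{a.family:<14} {a.class_family:<20} {1:>5} {span:>5} (0) "
            f"{a.link_id if a.link_id is not None else i + 1}\n"
        )


def parse_trf_dat(stream: Iterable[str]) -> List[SimpleRepeatAnnotation]:
    """Parse Tandem Repeat Finder `.dat` output (1-based inclusive coords)."""
    out: List[SimpleRepeatAnnotation] = []
    seqname = ""
    for line in stream:
        line = line.strip()
        if line.startswith("Sequence:"):
            seqname = line.split(None, 1)[1].split()[0]
            continue
        fields = line.split()
        if len(fields) < 14 or not fields[0].isdigit():
            continue
        out.append(
            SimpleRepeatAnnotation(
                seqname=seqname,
                start=int(fields[0]) - 1,
                end=int(fields[1]),
                monomer=fields[13],
                copy_number=float(fields[3]),
                pct_matches=float(fields[5]),
                pct_indels=float(fields[6]),
            )
        )
    return out


def read_consensus_fasta(path) -> Dict[str, str]:
    """Read a repeat consensus library; RepBase-style `name#class/family`
    headers are accepted, keyed by the bare name."""
    from Bio import SeqIO

    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id.split("#")[0]
        out[name] = str(rec.seq).upper()
    return out


@dataclass
class InstanceRecord:
    """Joint empirical tuple describing one genomic repeat instance."""

    length: int
    divergence: float
    ins_pct: float
    del_pct: float
    fragments: int
    gc_bin: int


@dataclass
class RepeatFamilyModel:
    """Consensus plus the empirical instance tuples of one repeat family."""

    family: str
    repeat_class: str
    consensus: str
    instances: List[InstanceRecord]
    bases_per_bin: np.ndarray  # abundance weight per GC bin
    kind: str = "interspersed"  # or "simple"

    def sample_instance(self, rng: np.random.Generator) -> InstanceRecord:
        """Bootstrap draw (with replacement) from the observed tuples."""
        return self.instances[int(rng.integers(len(self.instances)))]


@dataclass
class NestingTable:
    """Host-family -> guest-family insertion distribution + fragmentation rates."""

    guest_dist: Dict[str, Dict[str, float]] = field(default_factory=dict)
    fragmentation_prob: Dict[str, float] = field(default_factory=dict)

    def sample_guest(self, host: str, rng: np.random.Generator) -> Optional[str]:
        dist = self.guest_dist.get(host)
        if not dist:
            return None
        fams = sorted(dist)
        probs = np.asarray([dist[f] for f in fams])
        return fams[int(rng.choice(len(fams), p=probs / probs.sum()))]


def _gc_bin_at(profiles: Mapping[str, GCProfile], seqname: str, pos: int) -> int:
    prof = profiles.get(seqname)
    if prof is None or prof.n_windows == 0:
        return 0
    w = min(pos // prof.window_size, prof.n_windows - 1)
    b = int(prof.bin_index[w])
    if b >= 0:
        return b
    usable = prof.bin_index[prof.bin_index >= 0]
    return int(np.bincount(usable).argmax()) if len(usable) else 0


def build_repeat_models(
    annotations: List[RepeatAnnotation],
    consensus_library: Mapping[str, str],
    profiles: Mapping[str, GCProfile],
    simple_annotations: Optional[List[SimpleRepeatAnnotation]] = None,
) -> Tuple[Dict[str, RepeatFamilyModel], NestingTable]:
    """Tabulate per-family instance tuples, abundances and nesting rates.

    Fragments sharing a RepeatMasker linkage id form one element; an
    element is "fragmented" when its id spans >= 2 rows. Families with
    no consensus in the library are dropped with a warning.
    """
    if not annotations and not simple_annotations:
        raise ValueError("no repeat annotations given")
    n_bins = (
        next(iter(profiles.values())).n_bins if profiles else 1
    )

    # group fragments into elements by (seqname, link id)
    elements: Dict[Tuple[str, str], List[RepeatAnnotation]] = {}
    for i, a in enumerate(annotations):
        key = (a.seqname, a.link_id if a.link_id is not None else f"_row{i}")
        elements.setdefault(key, []).append(a)

    models: Dict[str, RepeatFamilyModel] = {}
    dropped = set()
    frag_counts: Dict[str, List[int]] = {}
    for frags in elements.values():
        frags.sort(key=lambda a: a.start)
        fam = frags[0].family
        if fam not in consensus_library:
            dropped.add(fam)
            continue
        length = sum(a.end - a.start for a in frags)
        weights = np.asarray([a.end - a.start for a in frags], dtype=float)
        weights /= weights.sum()
        div = float(sum(w * a.divergence for w, a in zip(weights, frags)))
        ins = float(sum(w * a.insertion for w, a in zip(weights, frags)))
        dele = float(sum(w * a.deletion for w, a in zip(weights, frags)))
        gc_bin = _gc_bin_at(profiles, frags[0].seqname, frags[0].start)
        rec = InstanceRecord(length, div, ins, dele, len(frags), gc_bin)
        m = models.get(fam)
        if m is None:
            m = RepeatFamilyModel(
                fam,
                frags[0].repeat_class,
                consensus_library[fam],
                [],
                np.zeros(n_bins),
            )
            models[fam] = m
            frag_counts[fam] = []
        m.instances.append(rec)
        m.bases_per_bin[gc_bin] += length
        frag_counts[fam].append(len(frags))
    for fam in sorted(dropped):
        warnings.warn(f"family {fam!r} has no consensus in the library; dropped")

    # nesting: annotations falling in the gap between fragments of an element
    nest_counts: Dict[str, Dict[str, float]] = {}
    by_seq: Dict[str, List[RepeatAnnotation]] = {}
    for a in annotations:
        by_seq.setdefault(a.seqname, []).append(a)
    for (seqname, _), frags in elements.items():
        if len(frags) < 2 or frags[0].family not in models:
            continue
        host = frags[0].family
        for left, right in zip(frags, frags[1:]):
            for a in by_seq.get(seqname, []):
                if a is left or a is right or a.link_id == left.link_id:
                    continue
                if left.end <= a.start and a.end <= right.start:
                    nest_counts.setdefault(host, {})[a.family] = (
                        nest_counts.setdefault(host, {}).get(a.family, 0.0) + 1.0
                    )
    table = NestingTable()
    for host, dist in nest_counts.items():
        total = sum(dist.values())
        table.guest_dist[host] = {f: c / total for f, c in dist.items()}
    for fam, counts in frag_counts.items():
        table.fragmentation_prob[fam] = sum(1 for c in counts if c >= 2) / len(counts)

    if simple_annotations:
        for a in simple_annotations:
            fam = f"({a.monomer})n"
            gc_bin = _gc_bin_at(profiles, a.seqname, a.start)
            div = max(0.0, 100.0 - a.pct_matches)
            rec = InstanceRecord(
                a.end - a.start, div, a.pct_indels / 2.0, a.pct_indels / 2.0, 1, gc_bin
            )
            m = models.get(fam)
            if m is None:
                m = RepeatFamilyModel(
                    fam, "Simple_repeat", a.monomer, [], np.zeros(n_bins), kind="simple"
                )
                models[fam] = m
            m.instances.append(rec)
            m.bases_per_bin[gc_bin] += a.end - a.start
            table.fragmentation_prob.setdefault(fam, 0.0)

    if not models:
        raise ValueError("no repeat family could be modeled")
    return models, table
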