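"""Artificial evolution of repeat instances from their family consensus.

An instance is produced by (1) trimming the consensus to the annotated
length — 5'-truncation for LINEs, mimicking incomplete target-primed
reverse transcription; a random contiguous window otherwise — and then
(2) three mutation stages in fixed order: deletions, substitutions
(transitions vs transversions at a configurable ti:tv ratio, default
2.0, the standard mammalian genome-wide estimate), and insertions.
Event counts derive deterministically from the annotated percentages
(rounding half-up); randomness enters only through positions and event
identities, so realized divergence tracks the sampled annotation tuple
tightly.

Every event is appended to a mutation log; replaying the log on the
consensus reproduces the evolved sequence exactly. Fragmentation/nesting
inserts an artificially evolved *younger* (lower-divergence) guest at a
uniform break point, recursively, with a depth cap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .repeats import InstanceRecord, NestingTable, RepeatFamilyModel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class EvolutionParams:
    """Target shape of one evolved instance (percentages per 100 bases)."""

    length: int
    divergence: float
    ins_pct: float = 0.0
    del_pct: float = 0.0
    fragments: int = 1
    titv: float = 2.0
    gc_bin: int = 0

    def __post_init__(self) -> None:
        for v in (self.divergence, self.ins_pct, self.del_pct):
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"percentage {v} outside [0, 100]")
        if self.length < 1 or self.fragments < 1:
            raise ValueError("length and fragment count must be >= 1")

    @classmethod
    def from_instance(cls, rec: InstanceRecord, titv: float = 2.0) -> "EvolutionParams":
        return cls(
            length=max(1, rec.length),
            divergence=rec.divergence,
            ins_pct=rec.ins_pct,
            del_pct=rec.del_pct,
            fragments=max(1, rec.fragments),
            titv=titv,
            gc_bin=rec.gc_bin,
        )


@dataclass
class MutationEvent:
    """One logged edit; positions refer to the sequence at application time."""

    op: str  # trim | expand | del | sub_ti | sub_tv | ins | fragment_break | nest
    pos: int
    before: str = ""
    after: str = ""


@dataclass
class MutationLog:
    events: List[MutationEvent] = field(default_factory=list)

    def add(self, op: str, pos: int, before: str = "", after: str = "") -> None:
        self.events.append(MutationEvent(op, pos, before, after))

    def replay(self, consensus: str) -> str:
        """Apply the logged events to *consensus*; must reproduce the output."""
        seq = consensus
        for ev in self.events:
            if ev.op == "trim":
                seq = seq[ev.pos : int(ev.after)]
            elif ev.op == "expand":
                target = int(ev.after)
                reps = -(-target // len(seq))
                seq = (seq * reps)[:target]
            elif ev.op == "del":
                assert seq[ev.pos] == ev.before, "log/sequence mismatch"
                seq = seq[: ev.pos] + seq[ev.pos + 1 :]
            elif ev.op in ("sub_ti", "sub_tv"):
                assert seq[ev.pos] == ev.before, "log/sequence mismatch"
                seq = seq[: ev.pos] + ev.after + seq[ev.pos + 1 :]
            elif ev.op in ("ins", "nest"):
                seq = seq[: ev.pos] + ev.after + seq[ev.pos :]
            elif ev.op == "fragment_break":
                pass
            else:
                raise ValueError(f"unknown mutation op {ev.op!r}")
        return seq


def trim_consensus(
    consensus: str,
    target_length: int,
    rng: np.random.Generator,
    repeat_class: str = "Other",
) -> Tuple[str, int]:
    """Trim the consensus to the annotated instance length.

    LINEs are 5'-truncated (the 3'-most bases are kept); other classes
    get a uniformly random contiguous window. Returns (slice, start).
    """
    n = len(consensus)
    if target_length >= n:
        if target_length > n:
            warnings.warn(
                f"target length {target_length} exceeds consensus ({n}); using full"
            )
        return consensus, 0
    if repeat_class == "LINE":
        start = n - target_length
    else:
        start = int(rng.integers(0, n - target_length + 1))
    return consensus[start : start + target_length], start


def _apply_deletions(seq: str, n: int, rng: np.random.Generator, log: MutationLog) -> str:
    n = min(n, len(seq))
    positions = sorted(rng.choice(len(seq), size=n, replace=False), reverse=True)
    for p in positions:
        p = int(p)
        log.add("del", p, before=seq[p])
        seq = seq[:p] + seq[p + 1 :]
    return seq


def _apply_substitutions(
    seq: str, n: int, titv: float, rng: np.random.Generator, log: MutationLog
) -> str:
    n = min(n, len(seq))
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    rng.shuffle(positions)
    if math.isinf(titv):
        n_ti = n
    else:
        n_ti = round_half_up(n * titv / (titv + 1.0))
    chars = list(seq)
    for i, p in enumerate(positions):
        p = int(p)
        before = chars[p]
        if i < n_ti:
            after = TRANSITION[before]
            op = "sub_ti"
        else:
            after = TRANSVERSIONS[before][int(rng.integers(2))]
            op = "sub_tv"
        log.add(op, p, before=before, after=after)
        chars[p] = after
    return "".join(chars)


def _apply_insertions(
    seq: str,
    n: int,
    rng: np.random.Generator,
    log: MutationLog,
    base_sampler: Optional[Callable[[str], str]] = None,
) -> str:
    n = min(n, len(seq) + 1)
    positions = sorted(
        rng.choice(len(seq) + 1, size=n, replace=False), reverse=True
    )
    for p in positions:
        p = int(p)
        if base_sampler is not None:
            base = base_sampler(seq[:p])
        else:
            base = "ACGT"[int(rng.integers(4))]
        log.add("ins", p, after=base)
        seq = seq[:p] + base + seq[p:]
    return seq


def evolve(
    slice_seq: str,
    params: EvolutionParams,
    rng: np.random.Generator,
    base_sampler: Optional[Callable[[str], str]] = None,
    log: Optional[MutationLog] = None,
) -> Tuple[str, MutationLog]:
    """Run the delete -> substitute -> insert stages on a consensus slice.

    Event counts are round(pct * L / 100) on the slice length L. The
    optional *base_sampler* draws inserted bases from a background k-mer
    model given the left context (uniform when absent).
    """
    if log is None:
        log = MutationLog()
    L = len(slice_seq)
    seq = _apply_deletions(seq=slice_seq, n=round_half_up(params.del_pct * L / 100.0), rng=rng, log=log)
    seq = _apply_substitutions(seq, round_half_up(params.divergence * L / 100.0), params.titv, rng, log)
    seq = _apply_insertions(seq, round_half_up(params.ins_pct * L / 100.0), rng, log, base_sampler)
    return seq, log


@dataclass
class EvolvedRepeat:
    """One artificially evolved instance plus its construction record."""

    family: str
    repeat_class: str
    seq: str
    log: MutationLog
    params: EvolutionParams
    consensus: str
    kind: str = "interspersed"
    # nested guests: (offset into seq, EvolvedRepeat)
    children: List[Tuple[int, "EvolvedRepeat"]] = field(default_factory=list)


def maybe_nest(
    host: EvolvedRepeat,
    nesting_table: NestingTable,
    models: Dict[str, RepeatFamilyModel],
    rng: np.random.Generator,
    base_sampler: Optional[Callable[[str], str]] = None,
    depth: int = 3,
) -> EvolvedRepeat:
    """Possibly fragment *host* and insert a younger guest at the break.

    With the host family's empirical fragmentation probability, a break
    point is drawn uniformly inside the host and a guest family is drawn
    from the nesting distribution. The guest instance is resampled until
    its divergence is strictly below the host's (younger element); if no
    such instance exists the host is left broken without a guest.
    """
    if depth <= 0 or len(host.seq) < 2:
        return host
    p_frag = nesting_table.fragmentation_prob.get(host.family, 0.0)
    if rng.random() >= p_frag:
        return host
    break_pos = int(rng.integers(1, len(host.seq)))
    host.log.add("fragment_break", break_pos)
    guest_family = nesting_table.sample_guest(host.family, rng)
    if guest_family is None or guest_family not in models:
        warnings.warn(f"no eligible guest family for host {host.family!r}")
        return host
    fam = models[guest_family]
    eligible = [r for r in fam.instances if r.divergence < host.params.divergence]
    if not eligible:
        warnings.warn(
            f"no instance of {guest_family!r} younger than host; break without guest"
        )
        return host
    rec = eligible[int(rng.integers(len(eligible)))]
    guest = evolve_instance(
        fam,
        EvolutionParams.from_instance(rec, titv=host.params.titv),
        rng,
        nesting_table=nesting_table,
        models=models,
        base_sampler=base_sampler,
        depth=depth - 1,
    )
    host.log.add("nest", break_pos, after=guest.seq)
    host.seq = host.seq[:break_pos] + guest.seq + host.seq[break_pos:]
    shifted = []
    for off, child in host.children:
        shifted.append((off + len(guest.seq), child) if off >= break_pos else (off, child))
    host.children = shifted + [(break_pos, guest)]
    return host


def evolve_instance(
    family: RepeatFamilyModel,
    params: EvolutionParams,
    rng: np.random.Generator,
    nesting_table: Optional[NestingTable] = None,
    models: Optional[Dict[str, RepeatFamilyModel]] = None,
    base_sampler: Optional[Callable[[str], str]] = None,
    depth: int = 3,
) -> EvolvedRepeat:
    """Evolve one instance of *family* according to *params*.

    Simple (tandem) families expand their monomer to the target length
    first; interspersed families trim their consensus. Both then run the
    same three mutation stages. Nesting applies to interspersed hosts
    when a nesting table is supplied.
    """
    log = MutationLog()
    if family.kind == "simple":
        sl = expand_monomer(family.consensus, params.length, log)
    else:
        sl, start = trim_consensus(
            family.consensus, params.length, rng, family.repeat_class
        )
        log.add("trim", start, after=str(start + len(sl)))
    seq, log = evolve(sl, params, rng, base_sampler=base_sampler, log=log)
    rep = EvolvedRepeat(
        family.family, family.repeat_class, seq, log, params, family.consensus,
        kind=family.kind,
    )
    if (
        family.kind == "interspersed"
        and nesting_table is not None
        and models is not None
    ):
        rep = maybe_nest(rep, nesting_table, models, rng, base_sampler, depth)
    return rep


def expand_monomer(monomer: str, target_length: int, log: Optional[MutationLog] = None) -> str:
    """Tandemly repeat the monomer to *target_length* (last copy truncated)."""
    if not monomer:
        raise ValueError("empty monomer")
    reps = -(-target_length // len(monomer))
    seq = (monomer * reps)[:target_length]
    if log is not None:
        # logged as a trim on the virtual tandem array so replay stays exact
        log.add("expand", 0, after=str(target_length))
    return seq


def evolve_simple_repeat(
    monomer: str,
    target_length: int,
    params: EvolutionParams,
    rng: np.random.Generator,
    base_sampler: Optional[Callable[[str], str]] = None,
) -> Tuple[str, MutationLog]:
    """Expand a tandem-repeat monomer and run the mutation stages on it."""
    log = MutationLog()
    seq = expand_monomer(monomer, target_length, log)
    return evolve(seq, params, rng, base_sampler=base_sampler, log=log)
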