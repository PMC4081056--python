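from collections import Counter
from itertools import permutations

import numpy as np
import pytest
from Bio import SeqIO
from scipy import stats

from decoygen import (
    EvolutionParams,
    generate_artificial,
    insert_repeats,
    parse_repeatmasker_out,
    plan_insertions,
    revcomp,
    sample_bin_series,
    shuffle_dinucleotide,
    write_outputs,
)


def dimer_counts(s):
    return Counter(zip(s, s[1:]))


@pytest.fixture(scope="module")
def generated(toy_model, toy_repeats):
    models, nesting = toy_repeats
    return generate_artificial(
        toy_model, models, nesting, 50_000, repeat_fraction=0.4, seed=21
    )


class TestPlanning:
    def test_zero_fraction_gives_empty_plan(self, toy_model, toy_repeats):
        models, _ = toy_repeats
        plan = plan_insertions(models, 0.0, 10_000, np.zeros(10, int), np.random.default_rng(0))
        assert plan == []

    def test_plan_is_sorted_oldest_first(self, toy_model, toy_repeats):
        models, _ = toy_repeats
        series = sample_bin_series(toy_model, 50, np.random.default_rng(1))
        plan = plan_insertions(models, 0.5, 50_000, series, np.random.default_rng(1))
        divs = [p.divergence for _, p in plan]
        assert divs == sorted(divs, reverse=True)

    def test_planned_bases_cover_target(self, toy_repeats):
        models, _ = toy_repeats
        plan = plan_insertions(
            models, 0.5, 50_000, np.zeros(50, int), np.random.default_rng(2)
        )
        assert sum(p.length for _, p in plan) >= 50_000  # fraction/(1-fraction) x base

    def test_fraction_one_rejected(self, toy_repeats):
        models, _ = toy_repeats
        with pytest.raises(ValueError):
            plan_insertions(models, 1.0, 1000, np.zeros(1, int), np.random.default_rng(0))


class TestInsertion:
    def test_empty_plan_returns_base_unchanged(self, toy_model, toy_repeats):
        models, nesting = toy_repeats
        art = insert_repeats("ACGT" * 1000, [], models, nesting, toy_model,
                             np.random.default_rng(0))
        assert art.seq == "ACGT" * 1000 and art.records == []

    def test_single_insert_is_splice_inverse(self, toy_model, toy_repeats):
        models, nesting = toy_repeats
        base = "ACGT" * 500
        plan = [("TSINE1", EvolutionParams(300, 0.0, gc_bin=4))]
        art = insert_repeats(base, plan, models, nesting, toy_model,
                             np.random.default_rng(3))
        (r,) = art.records
        assert len(art.seq) == len(base) + 300
        assert art.seq[: r.start] + art.seq[r.end :] == base

    def test_minus_strand_contains_reverse_complement(self, generated):
        minus = [r for r in generated.records if r.strand == "-" and r.parent_id is None
                 and r.fragment_index == 0]
        assert minus, "expected at least one minus-strand insert"
        for r in minus[:5]:
            rep = generated.elements[r.element_id]
            frags = sorted(
                (q for q in generated.records if q.element_id == r.element_id),
                key=lambda q: q.start,
            )
            joined = "".join(generated.seq[q.start : q.end] for q in frags)
            assert joined == revcomp(rep.seq)

    def test_realized_fraction_near_target(self, generated):
        assert generated.repeat_fraction() == pytest.approx(0.4, abs=0.02)

    def test_nested_records_are_younger_and_inside(self, generated):
        by_el = {}
        for r in generated.records:
            by_el.setdefault(r.element_id, []).append(r)
        for r in generated.records:
            if r.parent_id is None:
                continue
            parent_frags = by_el[r.parent_id]
            lo = min(p.start for p in parent_frags)
            hi = max(p.end for p in parent_frags)
            assert lo < r.start and r.end < hi
            assert generated.elements[r.parent_id].params.divergence > \
                generated.elements[r.element_id].params.divergence


class TestOutputs:
    def test_round_trip_reproduces_every_evolved_repeat(self, generated, tmp_path):
        paths = write_outputs(generated, str(tmp_path / "run"))
        rec = next(SeqIO.parse(paths["fasta"], "fasta"))
        seq = str(rec.seq)
        assert seq == generated.seq
        with open(paths["out"]) as fh:
            anns = parse_repeatmasker_out(fh)
        by_link = {}
        for a in anns:
            by_link.setdefault(a.link_id, []).append(a)
        assert len(anns) == len(generated.records)
        for link, frags in by_link.items():
            frags.sort(key=lambda a: a.start)
            joined = "".join(seq[a.start : a.end] for a in frags)
            rep = generated.elements[int(link)]
            expect = rep.seq if frags[0].strand == "+" else revcomp(rep.seq)
            assert joined == expect

    def test_mutation_log_replay_matches_every_element(self, generated):
        for rep in generated.elements.values():
            assert rep.log.replay(rep.consensus) == rep.seq

    def test_provenance_records_seed_and_config_hash(self, generated, tmp_path):
        import json

        paths = write_outputs(generated, str(tmp_path / "run"))
        prov = json.loads(open(paths["provenance"]).read())
        assert prov["seed"] == 21
        assert len(prov["config_sha256"]) == 64

    def test_no_records_gives_header_only_annotation(self, toy_model, toy_repeats, tmp_path):
        models, nesting = toy_repeats
        art = generate_artificial(toy_model, models, nesting, 5_000,
                                  repeat_fraction=0.0, seed=1)
        paths = write_outputs(art, str(tmp_path / "empty"))
        with open(paths["out"]) as fh:
            assert parse_repeatmasker_out(fh) == []

    def test_pipeline_outputs_byte_reproducible(self, toy_model, toy_repeats, tmp_path):
        models, nesting = toy_repeats
        blobs = []
        for d in ("a", "b"):
            art = generate_artificial(toy_model, models, nesting, 20_000,
                                      repeat_fraction=0.3, seed=77)
            paths = write_outputs(art, str(tmp_path / d))
            blobs.append({k: open(p, "rb").read() for k, p in paths.items()})
        assert blobs[0] == blobs[1]


class TestShuffle:
    def test_homopolymer_unchanged(self):
        assert shuffle_dinucleotide("AAAA", np.random.default_rng(0)) == "AAAA"

    def test_window_shorter_than_two_returned_unchanged(self):
        assert shuffle_dinucleotide("A", np.random.default_rng(0)) == "A"

    def test_dinucleotide_counts_preserved_per_window(self):
        rng = np.random.default_rng(4)
        seq = "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, 5000)])
        out = shuffle_dinucleotide(seq, rng, window=1000)
        assert len(out) == len(seq)
        for i in range(0, 5000, 1000):
            a, b = seq[i : i + 1000], out[i : i + 1000]
            assert dimer_counts(a) == dimer_counts(b)
            assert a[0] == b[0] and a[-1] == b[-1]

    def test_uniform_over_enumerated_arrangements(self):
        """Empirical draw frequencies match brute-force enumeration."""
        s = "ACGTCAGT"
        valid = {
            s[0] + "".join(p) + s[-1]
            for p in set(permutations(s[1:-1]))
            if dimer_counts(s[0] + "".join(p) + s[-1]) == dimer_counts(s)
        }
        assert len(valid) == 3
        rng = np.random.default_rng(5)
        draws = Counter(shuffle_dinucleotide(s, rng) for _ in range(3000))
        assert set(draws) == valid
        assert stats.chisquare(list(draws.values())).pvalue > 0.01
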