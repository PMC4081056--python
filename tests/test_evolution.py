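import numpy as np
import pytest
from Bio import Align

from decoygen import (
    EvolutionParams,
    RepeatFamilyModel,
    evolve,
    evolve_instance,
    evolve_simple_repeat,
    expand_monomer,
    maybe_nest,
    trim_consensus,
)
from decoygen.repeats import InstanceRecord, NestingTable

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -0.5


def nw_identity(a, b):
    """Needleman-Wunsch oracle: % identical columns of the best alignment."""
    aln = _aligner.align(a, b)[0]
    c = aln.counts()
    return 100.0 * c.identities / (c.identities + c.mismatches + c.gaps)


def random_dna(n, rng):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, n)])


class TestTrim:
    def test_full_length_returns_consensus(self):
        cons = "ACGT" * 25
        sl, start = trim_consensus(cons, 100, np.random.default_rng(0))
        assert sl == cons and start == 0

    def test_line_class_keeps_three_prime_end(self):
        cons = random_dna(100, np.random.default_rng(1))
        sl, start = trim_consensus(cons, 40, np.random.default_rng(2), "LINE")
        assert start == 60 and sl == cons[60:]

    def test_single_base_target(self):
        sl, _ = trim_consensus("ACGT", 1, np.random.default_rng(0))
        assert len(sl) == 1

    def test_oversized_target_warns_and_uses_full(self):
        with pytest.warns(UserWarning, match="exceeds"):
            sl, _ = trim_consensus("ACGT", 10, np.random.default_rng(0))
        assert sl == "ACGT"


class TestEvolve:
    def test_zero_params_is_identity_with_empty_log(self):
        cons = random_dna(200, np.random.default_rng(3))
        seq, log = evolve(cons, EvolutionParams(200, 0.0), np.random.default_rng(4))
        assert seq == cons and log.events == []

    def test_divergence_recovered_by_alignment_oracle(self):
        rng = np.random.default_rng(5)
        cons = random_dna(1000, rng)
        seq, _ = evolve(cons, EvolutionParams(1000, 10.0), rng)
        assert nw_identity(seq, cons) == pytest.approx(90.0, abs=2.0)

    def test_infinite_titv_gives_only_transitions(self):
        rng = np.random.default_rng(6)
        cons = random_dna(500, rng)
        _, log = evolve(
            cons, EvolutionParams(500, 20.0, titv=float("inf")), rng
        )
        subs = [e for e in log.events if e.op.startswith("sub")]
        assert subs and all(e.op == "sub_ti" for e in subs)
        for e in subs:
            assert {e.before, e.after} in ({"A", "G"}, {"C", "T"})

    def test_mean_identity_strictly_decreases_with_divergence(self):
        rng = np.random.default_rng(7)
        cons = random_dna(500, rng)
        means = []
        for d in (0, 5, 10, 20, 30):
            ids = [
                nw_identity(evolve(cons, EvolutionParams(500, d), rng)[0], cons)
                for _ in range(20)
            ]
            means.append(np.mean(ids))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_log_replay_reproduces_sequence_exactly(self):
        """Replay contract over 1,000 random parameterizations."""
        rng = np.random.default_rng(8)
        for _ in range(1000):
            n = int(rng.integers(20, 300))
            cons = random_dna(n, rng)
            params = EvolutionParams(
                length=n,
                divergence=float(rng.uniform(0, 30)),
                ins_pct=float(rng.uniform(0, 10)),
                del_pct=float(rng.uniform(0, 10)),
            )
            seq, log = evolve(cons, params, rng)
            assert log.replay(cons) == seq

    def test_length_accounting(self):
        rng = np.random.default_rng(9)
        cons = random_dna(400, rng)
        seq, log = evolve(cons, EvolutionParams(400, 10.0, ins_pct=5.0, del_pct=3.0), rng)
        n_del = sum(1 for e in log.events if e.op == "del")
        n_ins = sum(1 for e in log.events if e.op == "ins")
        assert len(seq) == len(cons) - n_del + n_ins
        assert n_del == 12 and n_ins == 20  # round(pct * L / 100)


def _nest_setup(frag_prob):
    rng = np.random.default_rng(10)
    host_model = RepeatFamilyModel(
        "HOST", "LINE", random_dna(400, rng), [InstanceRecord(400, 20.0, 0, 0, 1, 0)],
        np.ones(5),
    )
    guest_model = RepeatFamilyModel(
        "GUEST", "SINE", random_dna(150, rng),
        [InstanceRecord(150, 5.0, 0, 0, 1, 0)], np.ones(5),
    )
    table = NestingTable(
        guest_dist={"HOST": {"GUEST": 1.0}},
        fragmentation_prob={"HOST": frag_prob, "GUEST": 0.0},
    )
    models = {"HOST": host_model, "GUEST": guest_model}
    return host_model, models, table


class TestNesting:
    def test_zero_fragmentation_never_nests(self):
        host_model, models, table = _nest_setup(0.0)
        rng = np.random.default_rng(11)
        for _ in range(50):
            rep = evolve_instance(
                host_model, EvolutionParams(400, 20.0), rng,
                nesting_table=table, models=models,
            )
            assert rep.children == []

    def test_certain_fragmentation_nests_exactly_one_guest_inside(self):
        host_model, models, table = _nest_setup(1.0)
        rng = np.random.default_rng(12)
        rep = evolve_instance(
            host_model, EvolutionParams(400, 20.0), rng,
            nesting_table=table, models=models, depth=1,
        )
        assert len(rep.children) == 1
        off, guest = rep.children[0]
        assert 0 < off < len(rep.seq) - len(guest.seq)
        assert rep.seq[off : off + len(guest.seq)] == guest.seq
        assert rep.log.replay(rep.consensus) == rep.seq

    def test_guest_always_younger_than_host(self):
        host_model, models, table = _nest_setup(1.0)
        rng = np.random.default_rng(13)
        for _ in range(500):
            rep = evolve_instance(
                host_model, EvolutionParams(400, 20.0), rng,
                nesting_table=table, models=models, depth=1,
            )
            for _, guest in rep.children:
                assert guest.params.divergence < rep.params.divergence


class TestSimpleRepeats:
    @pytest.mark.parametrize(
        "monomer,length,expected",
        [("AT", 6, "ATATAT"), ("A", 5, "AAAAA"), ("CAG", 7, "CAGCAGC")],
    )
    def test_monomer_expansion(self, monomer, length, expected):
        seq, log = evolve_simple_repeat(
            monomer, length, EvolutionParams(length, 0.0), np.random.default_rng(0)
        )
        assert seq == expected
        assert log.replay(monomer) == seq

    def test_mutated_tandem_identity(self):
        rng = np.random.default_rng(14)
        ids = []
        for _ in range(20):
            seq, _ = evolve_simple_repeat(
                "CAG", 300, EvolutionParams(300, 10.0), rng
            )
            ids.append(nw_identity(seq, expand_monomer("CAG", 300)))
        assert np.mean(ids) == pytest.approx(90.0, abs=5.0)
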