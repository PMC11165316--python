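"""Low-cost clade search: costs, planted recovery, brute-force oracle."""

import numpy as np
import pytest

from orthocanon.cladefind import clade_cost, find_low_cost_clades
from orthocanon.gapdist import gap_distance_matrix
from orthocanon.njtree import nj_tree
from orthocanon.simulate import SimulationConfig, generate_orthogroup

from oracles import brute_force_low_cost_clades


def analyze(sim, **kwargs):
    matrix = gap_distance_matrix(sim.msa)
    tree = nj_tree(matrix)
    records = {r.accession: r for r in sim.bundle.members}
    cands = find_low_cost_clades(
        tree, matrix, records, sim.bundle.orthogroup_id, **kwargs
    )
    return matrix, tree, records, cands


class TestCladeCost:
    def test_gapless_clade_costs_zero(self):
        from orthocanon.msa import MultipleAlignment

        msa = MultipleAlignment(
            "X", [("A", "MKVW"), ("B", "MRVW"), ("C", "MKVY")]
        )
        m = gap_distance_matrix(msa)
        assert clade_cost(["A", "B", "C"], m) == 0.0

    def test_boundary_cost_is_accepted(self):
        # one pair carries a 5-column gap over a 250-column span: 0.02
        from orthocanon.msa import MultipleAlignment

        a = "A" * 250
        b = "A" * 100 + "-" * 5 + "A" * 145
        msa = MultipleAlignment("X", [("A", a), ("B", b), ("C", a)])
        m = gap_distance_matrix(msa)
        assert clade_cost(["A", "B", "C"], m) == pytest.approx(5 / 250)
        tree = nj_tree(m)
        records = {
            acc: _rec(acc, prot)
            for acc, prot in [("A", "HUMAN"), ("B", "MOUSE"), ("C", "RAT")]
        }
        cands = find_low_cost_clades(tree, m, records, cost_threshold=0.02)
        assert len(cands) == 1 and cands[0].cost == pytest.approx(0.02)

    def test_long_one_sided_gap_rejected(self):
        # a 104-column insertion over a ~400-column span: cost ~0.26 >> 0.02
        from orthocanon.msa import MultipleAlignment

        a = "A" * 400
        b = "A" * 150 + "-" * 104 + "A" * 146
        msa = MultipleAlignment("X", [("A", a), ("B", b), ("C", a)])
        m = gap_distance_matrix(msa)
        assert clade_cost(["A", "B", "C"], m) == pytest.approx(104 / 400)
        records = {
            acc: _rec(acc, prot)
            for acc, prot in [("A", "HUMAN"), ("B", "MOUSE"), ("C", "RAT")]
        }
        cands = find_low_cost_clades(nj_tree(m), m, records)
        assert cands == []

    def test_singleton_costs_zero_by_convention(self):
        from orthocanon.msa import MultipleAlignment

        m = gap_distance_matrix(
            MultipleAlignment("X", [("A", "MK"), ("B", "MK")])
        )
        assert clade_cost(["A"], m) == 0.0


def _rec(acc, prot, canonical=True):
    from conftest import make_record

    return make_record(acc, prot, "MKV", canonical=canonical)


class TestPlantedRecovery:
    def test_planted_clade_found_exactly_once(self, planted_sim):
        _, _, _, cands = analyze(planted_sim)
        assert len(cands) == 1
        (cand,) = cands
        assert cand.n_proteomes == 6
        assert cand.cost == 0.0
        truth = planted_sim.truth.expected_canonical
        assert {m.accession for m in cand.members.values()} == set(truth.values())

    def test_no_candidate_when_all_pairs_gapped(self):
        from orthocanon.msa import MultipleAlignment

        rows = [
            ("A", "AAAA----"),
            ("B", "----CCCC"),
            ("C", "AA----CC"),
        ]
        m = gap_distance_matrix(MultipleAlignment("X", rows))
        records = {
            acc: _rec(acc, prot)
            for acc, prot in [("A", "HUMAN"), ("B", "MOUSE"), ("C", "RAT")]
        }
        assert find_low_cost_clades(nj_tree(m), m, records) == []

    def test_two_proteome_clade_not_emitted(self):
        from orthocanon.msa import MultipleAlignment

        rows = [("A", "MKVW"), ("B", "MKVW"), ("C", "MKVW----------------")]
        rows = [("A", "MKVW" + "-" * 16), ("B", "MKVW" + "-" * 16),
                ("C", "MKVWMKVWMKVWMKVWMKVW")]
        m = gap_distance_matrix(MultipleAlignment("X", rows))
        records = {
            acc: _rec(acc, prot)
            for acc, prot in [("A", "HUMAN"), ("B", "MOUSE"), ("C", "RAT")]
        }
        assert find_low_cost_clades(nj_tree(m), m, records, min_proteomes=3) == []


class TestInvariants:
    def configs(self):
        return [
            SimulationConfig(rng_seed=s, n_proteomes=4, decoy_fraction=0.25)
            for s in range(5)
        ]

    def test_no_duplicate_proteomes_in_candidates(self):
        for i, cfg in enumerate(self.configs()):
            sim = generate_orthogroup(cfg, np.random.default_rng(cfg.rng_seed), i)
            _, _, _, cands = analyze(sim)
            for c in cands:
                proteomes = [m.proteome_id for m in c.members.values()]
                assert len(proteomes) == len(set(proteomes))

    def test_threshold_monotonicity(self):
        # a candidate at a low threshold is covered, at a higher one, by a
        # candidate at the same or an ancestral node with >= coverage
        for i, cfg in enumerate(self.configs()):
            sim = generate_orthogroup(cfg, np.random.default_rng(cfg.rng_seed), i)
            matrix, tree, records, lo = analyze(sim, cost_threshold=0.01)
            _, _, _, hi = analyze(sim, cost_threshold=0.05)
            for cand in lo:
                assert any(
                    cand.source_leaves <= other.source_leaves
                    and other.n_proteomes >= cand.n_proteomes
                    for other in hi
                )

    def test_min_proteomes_monotonicity(self):
        for i, cfg in enumerate(self.configs()):
            sim = generate_orthogroup(cfg, np.random.default_rng(cfg.rng_seed), i)
            _, _, _, at3 = analyze(sim, min_proteomes=3)
            _, _, _, at2 = analyze(sim, min_proteomes=2)
            sets3 = {c.accessions for c in at3}
            sets2 = {c.accessions for c in at2}
            assert sets3 <= sets2


class TestOracleEquivalence:
    def test_matches_brute_force_on_small_orthogroups(self):
        for seed in range(20):
            cfg = SimulationConfig(
                rng_seed=seed, n_proteomes=3, decoy_fraction=0.34
            )
            sim = generate_orthogroup(cfg, np.random.default_rng(seed), seed)
            assert len(sim.bundle.members) <= 8
            matrix, tree, records, cands = analyze(sim)
            expected = brute_force_low_cost_clades(
                tree, sim.msa.rows, records, 0.02, 3
            )
            got = {c.accessions: c.cost for c in cands}
            assert set(got) == set(expected)
            for key in got:
                assert got[key] == pytest.approx(expected[key], abs=1e-12)
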