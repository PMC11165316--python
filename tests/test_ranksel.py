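"""Clade ranking, non-overlapping selection, suggestion classification."""

import numpy as np
import pytest

from orthocanon.cladefind import CladeCandidate
from orthocanon.pipeline import analyze_orthogroup
from orthocanon.ranksel import (
    ACTION_CONFIRM,
    ACTION_FLAG_REVIEWED,
    ACTION_PROPOSE,
    canonical_by_group,
    emit_suggestions,
    length_penalty,
    rank_clades,
    select_clades,
)
from orthocanon.simulate import SimulationConfig, generate_orthogroup

from conftest import make_record


def candidate(og="OG1", cost=0.0, members=None, penalty=0.0):
    members = members or {}
    c = CladeCandidate(orthogroup_id=og, members=members, cost=cost)
    c.length_penalty = penalty
    return c


def members_of(*specs):
    out = {}
    for acc, prot, length, canonical, reviewed in specs:
        out[prot] = make_record(
            acc, prot, "M" * length, canonical=canonical, reviewed=reviewed,
            group=f"G_{prot}",
        )
    return out


class TestLengthPenalty:
    def test_matching_medians_penalty_zero(self):
        c = candidate(members=members_of(("A", "HUMAN", 196, True, True),
                                         ("B", "MOUSE", 196, True, True)))
        assert length_penalty(c, [196, 196, 196]) == 0.0

    def test_sixty_residue_offset(self):
        c = candidate(members=members_of(("A", "HUMAN", 256, True, False)))
        assert length_penalty(c, [196]) == pytest.approx(60 / 196)

    def test_single_member_median_well_defined(self):
        c = candidate(members=members_of(("A", "HUMAN", 100, True, False)))
        assert length_penalty(c, [150]) == pytest.approx(50 / 150)

    def test_empty_canonical_set_warns_and_zero(self):
        c = candidate(members=members_of(("A", "HUMAN", 100, True, False)))
        assert length_penalty(c, []) == 0.0


class TestRankClades:
    def test_cost_dominates_size(self):
        a = candidate(cost=0.0, members=members_of(
            *[(f"A{i}", p, 100, True, False)
              for i, p in enumerate(["HUMAN", "MOUSE", "RAT", "BOVIN", "PIG"])]))
        b = candidate(cost=0.01, members=members_of(
            *[(f"B{i}", p, 100, True, False)
              for i, p in enumerate(
                  ["HUMAN", "MOUSE", "RAT", "BOVIN", "PIG", "HORSE", "CANLF"])]))
        assert rank_clades([b, a]) == [a, b]

    def test_canonical_count_breaks_cost_and_size_ties(self):
        a = candidate(cost=0.0, members=members_of(
            ("A1", "HUMAN", 100, True, False), ("A2", "MOUSE", 100, True, False),
            ("A3", "RAT", 100, True, False)))
        b = candidate(cost=0.0, members=members_of(
            ("B1", "HUMAN", 100, True, False), ("B2", "MOUSE", 100, False, False),
            ("B3", "RAT", 100, False, False)))
        assert rank_clades([b, a]) == [a, b]

    def test_reviewed_human_mouse_breaks_further_ties(self):
        a = candidate(cost=0.0, members=members_of(
            ("A1", "HUMAN", 100, True, True), ("A2", "MOUSE", 100, True, True),
            ("A3", "RAT", 100, False, False)))
        b = candidate(cost=0.0, members=members_of(
            ("B1", "HUMAN", 100, True, False), ("B2", "MOUSE", 100, True, False),
            ("B3", "RAT", 100, False, True)))  # reviewed RAT does not count
        assert rank_clades([b, a]) == [a, b]

    def test_fully_tied_falls_back_to_accession(self):
        a = candidate(cost=0.0, members=members_of(
            ("A1", "HUMAN", 100, True, False)))
        b = candidate(cost=0.0, members=members_of(
            ("B1", "HUMAN", 100, True, False)))
        assert rank_clades([b, a]) == [a, b]
        assert rank_clades([a, b]) == [a, b]  # stable across input order

    def test_length_penalty_recomputed_when_lengths_given(self):
        a = candidate(cost=0.0, members=members_of(
            ("A1", "HUMAN", 256, True, False)))
        ranked = rank_clades([a], canonical_lengths=[196])
        assert ranked[0].length_penalty == pytest.approx(60 / 196)


class TestSelectClades:
    def test_disjoint_gene_sets_all_selected(self):
        clades = [
            candidate(members=members_of((f"A{i}", p, 100, True, False)))
            for i, p in enumerate(["HUMAN", "MOUSE", "RAT"])
        ]
        assert select_clades(rank_clades(clades)) == rank_clades(clades)

    def test_overlapping_gene_set_keeps_better_ranked(self):
        shared = members_of(("A1", "HUMAN", 100, True, False))
        a = candidate(cost=0.0, members=shared)
        b = candidate(cost=0.01, members=dict(shared))
        selected = select_clades(rank_clades([a, b]))
        assert selected == [a]

    def test_single_candidate_selected(self):
        a = candidate(members=members_of(("A1", "HUMAN", 100, True, False)))
        assert select_clades([a]) == [a]


class TestEmitSuggestions:
    def run_sim(self, reviewed_decoys=False):
        cfg = SimulationConfig(
            rng_seed=5, n_proteomes=6, decoy_fraction=0.3,
            reviewed_decoys=reviewed_decoys,
        )
        sim = generate_orthogroup(
            cfg, np.random.default_rng(5), 0, decoy_proteomes=["BOVIN", "MONDO"]
        )
        return sim, analyze_orthogroup(sim.bundle, sim.msa)

    def test_decoy_canonicals_proposed(self):
        sim, res = self.run_sim()
        actions = {s.proteome_id: s for s in res.suggestions}
        for p in ["BOVIN", "MONDO"]:
            assert actions[p].action == ACTION_PROPOSE
            expected = sim.truth.expected_canonical[p]
            assert actions[p].new_canonical == expected.rsplit("-", 1)[0]
        for p in ["HUMAN", "MOUSE", "RAT", "GORGO"]:
            assert actions[p].action == ACTION_CONFIRM
            assert actions[p].old_canonical == actions[p].new_canonical

    def test_all_canonical_clade_all_confirms(self):
        cfg = SimulationConfig(rng_seed=6, n_proteomes=5, decoy_fraction=0.0)
        sim = generate_orthogroup(cfg, np.random.default_rng(6), 0,
                                  decoy_proteomes=[])
        res = analyze_orthogroup(sim.bundle, sim.msa)
        assert res.suggestions
        assert all(s.action == ACTION_CONFIRM for s in res.suggestions)

    def test_reviewed_old_canonical_flagged_not_changed(self):
        sim, res = self.run_sim(reviewed_decoys=True)
        actions = {s.proteome_id: s for s in res.suggestions}
        for p in ["BOVIN", "MONDO"]:
            assert actions[p].action == ACTION_FLAG_REVIEWED
        assert not any(
            s.action == ACTION_PROPOSE
            and s.proteome_id in ("BOVIN", "MONDO")
            for s in res.suggestions
        )

    def test_member_without_gene_group_skipped(self):
        rec = make_record("A1", "HUMAN", "MKVW", canonical=True)
        rec.gene_group_id = ""
        clade = candidate(members={"HUMAN": rec})
        assert emit_suggestions([clade], {}) == []

    def test_one_suggestion_per_gene_group(self):
        sim, res = self.run_sim()
        keys = [(s.orthogroup_id, s.gene_group_id) for s in res.suggestions]
        assert len(keys) == len(set(keys))

    def test_canonical_by_group_maps_each_group_once(self):
        sim, _ = self.run_sim()
        by_group = canonical_by_group(sim.bundle.members)
        assert set(by_group) == {
            m.gene_group_id for m in sim.bundle.members if m.is_canonical
        }
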