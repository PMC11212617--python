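"""Novelty and importance scores: golden values, identities and invariants."""

import random

import pytest

from tinx.corpus import EntityKind, MentionRow, build_publications
from tinx.ontology import propagate_support
from tinx.scoring import disease_novelty, importance, novelty, score_all
from tinx.simulate import GOLDEN_X, GOLDEN_Y, GOLDEN_Z, SimulationConfig, simulate_corpus


def _mk_index(pubs):
    rows = []
    for pid, (targets, diseases) in pubs.items():
        rows += [MentionRow(pid, EntityKind.TARGET, t) for t in targets]
        rows += [MentionRow(pid, EntityKind.DISEASE, d) for d in diseases]
    return build_publications(rows)


class TestNovelty:
    def test_single_publication_single_target_is_one(self):
        index = _mk_index({"P1": (["A"], [])})
        assert novelty("A", index) == 1.0

    @pytest.mark.parametrize(
        "target, expected", [("A", 2 / 3), ("B", 1.0), ("C", 2 / 3)]
    )
    def test_golden_values(self, golden_index, target, expected):
        assert novelty(target, golden_index) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("m, t", [(1, 1), (3, 2), (7, 5)])
    def test_closed_form_uniform_corpus(self, m, t):
        """m publications each tagging exactly t targets including i gives N_i = t/m."""
        others = [f"O{j}" for j in range(t - 1)]
        index = _mk_index({f"P{k}": (["i"] + others, []) for k in range(m)})
        assert novelty("i", index) == pytest.approx(t / m, abs=1e-12)

    def test_zero_publication_target_raises(self, golden_index):
        with pytest.raises(KeyError):
            novelty("nope", golden_index)

    def test_upper_bound_is_max_target_count(self, golden_index):
        max_t = max(p.n_targets for p in golden_index.by_pub.values())
        for t in golden_index.by_target:
            assert 0 < novelty(t, golden_index) <= max_t


class TestDiseaseNovelty:
    def test_single_publication_single_disease_is_one(self):
        index = _mk_index({"P1": ([], ["X"])})
        assert disease_novelty("X", index) == 1.0

    @pytest.mark.parametrize("disease, expected", [(GOLDEN_X, 2 / 3), (GOLDEN_Y, 2 / 3)])
    def test_golden_values(self, golden_index, disease, expected):
        assert disease_novelty(disease, golden_index) == pytest.approx(expected, abs=1e-12)

    def test_propagated_parent_uses_descendant_publications(self, golden_index, golden_graph):
        # Z is never directly mentioned: its pool is P1, P2, P3 with D_k 1, 2, 1
        assert disease_novelty(GOLDEN_Z, golden_index, golden_graph) == pytest.approx(
            1 / (1 + 0.5 + 1), abs=1e-12
        )

    def test_zero_publication_disease_raises(self, golden_index):
        with pytest.raises(KeyError):
            disease_novelty("DOID:404", golden_index)


class TestImportance:
    def test_single_exclusive_comention_is_one(self):
        index = _mk_index({"P1": (["A"], ["X"])})
        sup = propagate_support(index, None)
        assert importance("A", "X", sup, index) == 1.0

    @pytest.mark.parametrize(
        "target, disease, expected",
        [
            ("A", GOLDEN_X, 1.25),
            ("A", GOLDEN_Y, 0.25),
            ("B", GOLDEN_X, 0.25),
            ("B", GOLDEN_Y, 0.75),
            ("C", GOLDEN_Y, 0.5),
        ],
    )
    def test_golden_direct_values(self, golden_index, golden_support_direct, target, disease, expected):
        got = importance(target, disease, golden_support_direct, golden_index)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_golden_propagated_parent_value(self, golden_index, golden_support):
        assert importance("A", GOLDEN_Z, golden_support, golden_index) == pytest.approx(
            1.25, abs=1e-12
        )

    def test_empty_support_raises(self, golden_index, golden_support):
        with pytest.raises(KeyError):
            importance("A", "DOID:404", golden_support, golden_index)

    def test_each_publication_contributes_at_most_one(self, golden_index, golden_support):
        for (t, d), pubs in golden_support.items():
            assert importance(t, d, golden_support, golden_index) <= len(pubs) + 1e-12


class TestScoreAll:
    def test_direct_pairs_give_five_records(self, golden_index, golden_support_direct, golden_catalog):
        df = score_all(golden_index, golden_support_direct, golden_catalog)
        assert len(df) == 5
        assert set(zip(df.target_id, df.disease_id)) == {
            ("A", GOLDEN_X), ("A", GOLDEN_Y), ("B", GOLDEN_X),
            ("B", GOLDEN_Y), ("C", GOLDEN_Y),
        }

    def test_propagation_adds_parent_records(self, golden_table):
        assert len(golden_table) == 8
        parents = golden_table[golden_table.disease_id == GOLDEN_Z]
        assert set(parents.target_id) == {"A", "B", "C"}

    def test_annotations_from_catalog(self, golden_table):
        row = golden_table[(golden_table.target_id == "C")].iloc[0]
        assert row.tdl == "Tdark" and row.idg_family == "IonChannel"
        assert row.symbol == "GENE3"

    def test_uncataloged_target_gets_unknown(self, golden_index, golden_support_direct):
        df = score_all(golden_index, golden_support_direct, catalog={})
        assert set(df.tdl) == {"unknown"}

    def test_empty_index_gives_empty_table(self):
        df = score_all(build_publications([]), {})
        assert df.empty

    def test_n_pubs_matches_support(self, golden_table, golden_support):
        for row in golden_table.itertuples(index=False):
            assert row.n_pubs == len(golden_support[(row.target_id, row.disease_id)])
            assert row.pub_ids == tuple(sorted(golden_support[(row.target_id, row.disease_id)]))


class TestConservation:
    """For targets whose every publication mentions a disease,
    the direct importances split 1/N_i exactly."""

    def test_holds_for_fully_disease_covered_targets(self, golden_index, golden_support_direct):
        for t in ("A", "B"):
            total = sum(
                importance(t, d, golden_support_direct, golden_index)
                for (tt, d) in golden_support_direct
                if tt == t
            )
            assert total == pytest.approx(1 / novelty(t, golden_index), abs=1e-9)

    def test_fails_when_a_publication_lacks_diseases(self, golden_index, golden_support_direct):
        # P4 mentions C and no disease, so C's importances cannot sum to 1/N_C
        total = sum(
            importance("C", d, golden_support_direct, golden_index)
            for (tt, d) in golden_support_direct
            if tt == "C"
        )
        assert abs(total - 1 / novelty("C", golden_index)) > 0.1

    def test_deleting_the_diseaseless_publication_restores_the_law(self):
        pubs = {
            "P1": (["A"], [GOLDEN_X]),
            "P2": (["A", "B"], [GOLDEN_X, GOLDEN_Y]),
            "P3": (["B", "C"], [GOLDEN_Y]),
        }
        index = _mk_index(pubs)
        sup = propagate_support(index, None)
        assert novelty("C", index) == pytest.approx(2.0, abs=1e-12)
        total = sum(importance("C", d, sup, index) for (t, d) in sup if t == "C")
        assert total == pytest.approx(0.5, abs=1e-9)


class TestMonotonicity:
    def test_new_publication_strictly_decreases_novelty(self, golden_index):
        before = novelty("A", golden_index)
        rows = [
            MentionRow(p, EntityKind.TARGET, t)
            for p, pub in golden_index.by_pub.items()
            for t in pub.targets
        ] + [
            MentionRow(p, EntityKind.DISEASE, d)
            for p, pub in golden_index.by_pub.items()
            for d in pub.diseases
        ]
        rows.append(MentionRow("P9", EntityKind.TARGET, "A"))
        after = novelty("A", build_publications(rows))
        assert after < before

    def test_new_comention_strictly_increases_importance(self, golden_index, golden_support_direct):
        before = importance("A", GOLDEN_X, golden_support_direct, golden_index)
        pubs = {
            p: (list(pub.targets), list(pub.diseases))
            for p, pub in golden_index.by_pub.items()
        }
        pubs["P9"] = (["A", "B", "Q"], [GOLDEN_X, GOLDEN_Y])
        index = _mk_index(pubs)
        sup = propagate_support(index, None)
        assert importance("A", GOLDEN_X, sup, index) > before


def _score_dict(paths):
    from tinx.corpus import read_mentions

    index = build_publications(read_mentions(paths["mentions"]))
    from tinx.ontology import parse_obo

    graph = parse_obo(paths["obo"])
    sup = propagate_support(index, graph)
    df = score_all(index, sup, graph=graph)
    return index, df


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [11, 22, 33])
    def test_pipeline_matches_naive_double_loop(self, tmp_path, seed):
        cfg = SimulationConfig(seed=seed, n_targets=15, n_diseases=10, n_pubs=120)
        paths, gt = simulate_corpus(cfg, tmp_path / f"c{seed}")
        index, df = _score_dict(paths)
        got = {
            (r.target_id, r.disease_id): r.importance for r in df.itertuples(index=False)
        }
        assert set(got) == set(gt.importance_propagated)
        for pair, v in gt.importance_propagated.items():
            assert got[pair] == pytest.approx(v, abs=1e-12)
        for t, n in gt.novelty.items():
            if t in index.by_target:
                assert novelty(t, index) == pytest.approx(n, abs=1e-12)

    def test_scores_invariant_under_row_shuffle(self, golden_paths):
        from tinx.corpus import read_mentions

        rows = read_mentions(golden_paths["mentions"])
        shuffled = rows[:]
        random.Random(5).shuffle(shuffled)
        a = score_all(build_publications(rows), propagate_support(build_publications(rows), None))
        b = score_all(
            build_publications(shuffled), propagate_support(build_publications(shuffled), None)
        )
        assert a.equals(b)
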