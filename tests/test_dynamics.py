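from __future__ import annotations

import pytest

from bcrnet.dynamics import (
    avg_clonal_frequency,
    clonal_frequency,
    component_dynamics,
    rank_candidates,
)
from bcrnet.network import Component
from bcrnet.repertoire import RepertoireCollection


def comp_of(vids, cid=1):
    return Component(component_id=cid, vertex_ids=frozenset(vids), edge_count=0)


@pytest.fixture()
def coll() -> RepertoireCollection:
    return RepertoireCollection.from_counts(
        {
            "AAAAAAAA": {"wk0": 5, "wk5": 40},
            "AAAAAAAT": {"wk0": 0, "wk5": 30},
            "AAAAAATT": {"wk0": 0, "wk5": 20},
            "CCCCCCCC": {"wk0": 40, "wk5": 9},
            "CCCCCCCT": {"wk0": 5, "wk5": 1},
        },
        timepoints=("wk0", "wk5"),
    )


class TestClonalFrequency:
    def test_count_over_total(self, coll):
        v = next(x for x in coll if x.sequence == "AAAAAAAA")
        assert clonal_frequency(v, "wk0", coll) == pytest.approx(5 / 50)

    def test_zero_count_gives_zero(self, coll):
        v = next(x for x in coll if x.sequence == "AAAAAAAT")
        assert clonal_frequency(v, "wk0", coll) == 0.0

    def test_sole_vertex_gives_one(self):
        c = RepertoireCollection.from_counts(
            {"ACGTACGT": {"wk0": 12}}, timepoints=("wk0",)
        )
        assert clonal_frequency(c.vertices[0], "wk0", c) == 1.0

    def test_frequencies_sum_to_one(self, coll):
        for tp in coll.timepoints:
            total = sum(clonal_frequency(v, tp, coll) for v in coll)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_empty_timepoint_is_an_error(self):
        c = RepertoireCollection.from_counts(
            {"ACGTACGT": {"wk0": 3, "wk5": 0}}, timepoints=("wk0", "wk5")
        )
        with pytest.raises(ValueError):
            clonal_frequency(c.vertices[0], "wk5", c)


class TestAvgClonalFrequency:
    def test_mean_over_all_members(self):
        c = RepertoireCollection.from_counts(
            {"AAAA": {"wk0": 10}, "CCCC": {"wk0": 20}, "GGGG": {"wk0": 30},
             "TTTT": {"wk0": 40}},
            timepoints=("wk0",),
        )
        ids = {v.sequence: v.vertex_id for v in c}
        comp = comp_of([ids["AAAA"], ids["CCCC"], ids["GGGG"]])
        assert avg_clonal_frequency(comp, "wk0", c) == pytest.approx((0.1 + 0.2 + 0.3) / 3)

    def test_zero_count_members_dilute_all_mode_but_not_active_mode(self, coll):
        ids = {v.sequence: v.vertex_id for v in coll}
        comp = comp_of([ids["AAAAAAAA"], ids["AAAAAAAT"], ids["AAAAAATT"]])
        all_mode = avg_clonal_frequency(comp, "wk0", coll, mode="all")
        active_mode = avg_clonal_frequency(comp, "wk0", coll, mode="active")
        assert all_mode == pytest.approx((5 / 50) / 3)
        assert active_mode == pytest.approx(5 / 50)

    def test_singleton_component_is_its_vertex_frequency(self, coll):
        ids = {v.sequence: v.vertex_id for v in coll}
        comp = comp_of([ids["CCCCCCCC"]])
        assert avg_clonal_frequency(comp, "wk0", coll) == pytest.approx(40 / 50)

    def test_active_mode_with_no_active_members_is_zero(self, coll):
        ids = {v.sequence: v.vertex_id for v in coll}
        comp = comp_of([ids["AAAAAAAT"], ids["AAAAAATT"]])
        assert avg_clonal_frequency(comp, "wk0", coll, mode="active") == 0.0


class TestComponentDynamics:
    def test_expansion_deltas(self, coll):
        ids = {v.sequence: v.vertex_id for v in coll}
        comp = comp_of([ids["AAAAAAAA"], ids["AAAAAAAT"], ids["AAAAAATT"]])
        d = component_dynamics(comp, coll)
        assert d.n_vertices_active == {"wk0": 1, "wk5": 3}
        assert d.delta_vertices == 2
        assert d.delta_avg_freq == pytest.approx(0.9 / 3 - 0.1 / 3)
        assert d.fold_freq > 2

    def test_static_component_has_zero_deltas(self):
        c = RepertoireCollection.from_counts(
            {"AAAA": {"wk0": 10, "wk5": 10}, "CCCC": {"wk0": 10, "wk5": 10}},
            timepoints=("wk0", "wk5"),
        )
        comp = comp_of([v.vertex_id for v in c])
        d = component_dynamics(comp, c)
        assert d.delta_vertices == 0
        assert d.delta_avg_freq == pytest.approx(0.0)
        assert d.fold_freq == pytest.approx(1.0)

    def test_contraction_gives_negative_deltas(self, coll):
        ids = {v.sequence: v.vertex_id for v in coll}
        comp = comp_of([ids["CCCCCCCC"], ids["CCCCCCCT"]])
        d = component_dynamics(comp, coll)
        assert d.delta_vertices == 0
        assert d.delta_avg_freq < 0
        assert d.fold_freq < 1


class TestRankCandidates:
    def make_dyn(self, cid, dv, ff):
        from bcrnet.dynamics import ComponentDynamics

        return ComponentDynamics(
            component_id=cid, n_vertices=10, delta_vertices=dv, fold_freq=ff
        )

    def test_no_component_passes(self):
        dyns = [self.make_dyn(1, 2, 1.5), self.make_dyn(2, 10, 1.2)]
        assert rank_candidates(dyns) == []

    def test_single_passer(self):
        dyns = [self.make_dyn(1, 8, 3.0), self.make_dyn(2, 1, 9.0)]
        out = rank_candidates(dyns)
        assert [d.component_id for d in out] == [1]

    def test_rank_sum_ordering(self):
        dyns = [
            self.make_dyn(1, 20, 2.5),  # ranks 1 + 3 = 4
            self.make_dyn(2, 10, 5.0),  # ranks 2 + 2 = 4 (tie -> id order)
            self.make_dyn(3, 6, 8.0),  # ranks 3 + 1 = 4
        ]
        out = rank_candidates(dyns)
        assert [d.component_id for d in out] == [1, 2, 3]
        assert all(d.candidate_score == 4 for d in out)

    def test_raising_thresholds_never_adds_candidates(self):
        dyns = [self.make_dyn(i, dv, ff) for i, (dv, ff) in enumerate(
            [(3, 1.0), (6, 2.5), (9, 4.0), (12, 1.9), (5, 2.0)]
        )]
        base = {d.component_id for d in rank_candidates(dyns, 5, 2.0)}
        for dv_min in (5, 6, 8, 10):
            for ff_min in (2.0, 3.0, 5.0):
                tighter = {
                    d.component_id for d in rank_candidates(dyns, dv_min, ff_min)
                }
                assert tighter <= base
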