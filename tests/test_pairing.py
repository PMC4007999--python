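"""Repulsion detection, the difference ratio, and pairing summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from polylink import (
    GeneticMap,
    LinkageGroup,
    MarkerMatrix,
    SimulationConfig,
    detect_repulsion,
    difference_ratio,
    generate_population,
    hg_difference_ratios,
    invert_matrix,
    pairing_summary,
    two_point,
    two_stage_build,
)
from polylink.pairing import DifferenceRatioRecord, RepulsionLink


def random_matrix(seed, n_markers=6, n_progeny=80, missing=0.1):
    rng = np.random.default_rng(seed)
    calls = rng.integers(0, 2, size=(n_markers, n_progeny)).astype(float)
    calls[rng.random(calls.shape) < missing] = np.nan
    return MarkerMatrix(
        calls=pd.DataFrame(calls, index=[f"m{i}" for i in range(n_markers)])
    )


class TestInvertMatrix:
    def test_calls_swapped_missing_preserved(self):
        m = random_matrix(1)
        inv = invert_matrix(m)
        orig = m.calls.to_numpy()
        out = inv.calls.to_numpy()
        mask = ~np.isnan(orig)
        assert np.array_equal(out[mask], 1.0 - orig[mask])
        assert np.isnan(out[~mask]).all()
        assert all(i.endswith("_r") for i in inv.calls.index)

    @given(st.integers(0, 2**32 - 1))
    def test_double_inversion_is_identity(self, seed):
        m = random_matrix(seed)
        back = invert_matrix(invert_matrix(m, suffix=""), suffix="")
        pd.testing.assert_frame_equal(back.calls, m.calls)


class TestRepulsionDetection:
    def test_repulsion_lod_equals_complemented_coupling_lod(self):
        # identity: repulsion LOD(a, b) == coupling LOD(a, 1-b)
        for seed in range(10):
            m = random_matrix(seed, n_markers=4, n_progeny=120)
            calls = m.calls.to_numpy()
            lg_a = LinkageGroup("A", ["m0", "m1"], np.array([0.0, 1.0]))
            lg_b = LinkageGroup("B", ["m2", "m3"], np.array([0.0, 1.0]))
            gmap = GeneticMap(groups=[lg_a, lg_b])
            links = detect_repulsion(m, gmap, lod_min=0.0, min_informative=1)
            for link in links:
                for a, b in link.support:
                    lod_rep = two_point(
                        m.calls.loc[a], 1.0 - m.calls.loc[b]
                    ).lod
                    assert lod_rep >= 0.0
            # cross-check the best LOD of the link against direct evaluation
            if links:
                link = links[0]
                best = max(
                    two_point(m.calls.loc[a], 1.0 - m.calls.loc[b]).lod
                    for a in lg_a.markers
                    for b in lg_b.markers
                )
                assert link.best_lod == pytest.approx(best)

    def test_exact_complement_reaches_full_lod(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 2, size=100).astype(float)
        c = 1.0 - a
        b2 = rng.integers(0, 2, size=100).astype(float)
        d2 = rng.integers(0, 2, size=100).astype(float)
        calls = pd.DataFrame([a, b2, c, d2], index=["a", "b", "c", "d"])
        m = MarkerMatrix(calls=calls)
        gmap = GeneticMap(
            groups=[
                LinkageGroup("A", ["a", "b"], np.array([0.0, 1.0])),
                LinkageGroup("B", ["c", "d"], np.array([0.0, 1.0])),
            ]
        )
        links = detect_repulsion(m, gmap, lod_min=5.0)
        assert links
        assert links[0].best_lod == pytest.approx(30.10, abs=0.01)

    def test_strict_disomic_partners_accepted(self, disomic_cross):
        matrix = disomic_cross.matrix
        gmap = two_stage_build(matrix)
        mapped = matrix.subset([m for m in matrix.marker_ids if m in gmap.lg_of()])
        links = [l for l in detect_repulsion(mapped, gmap) if l.accepted]
        assert len(links) == 4  # one per partner pair
        truth = disomic_cross.truth
        for link in links:
            by_name = {g.name: g for g in gmap.groups}
            hom_a = int(truth.loc[by_name[link.lg_a].markers[0], "homologues"])
            hom_b = int(truth.loc[by_name[link.lg_b].markers[0], "homologues"])
            assert {hom_a, hom_b} in ({0, 1}, {2, 3}, {4, 5}, {6, 7})
            assert link.best_lod >= 5.0

    def test_fully_polysomic_control_yields_no_links(self, polysomic_cross):
        matrix = polysomic_cross.matrix
        gmap = two_stage_build(matrix)
        mapped = matrix.subset([m for m in matrix.marker_ids if m in gmap.lg_of()])
        links = detect_repulsion(mapped, gmap)
        assert not any(l.accepted for l in links)

    def test_power_monotone_in_pairing_preference(self):
        # accepted-link rate rises from polysomy to strict disomy; the
        # control must be octoploid, where random chromosomal pairing
        # leaves only weak repulsion signal (15/70 vs 1/4) at this n
        rates = []
        for pref in (0.0, 0.5, 1.0):
            accepted = 0
            for rep in range(5):
                cfg = SimulationConfig(
                    seed=100 + rep, n_homology_groups=1, homologues_per_hg=8,
                    markers_per_homologue=8, dosage_mix=(1, 0, 0),
                    anchor_families_per_hg=0, missing_rate=0.0,
                    subset_scored_fraction=0.0, distorted_homologue_fraction=0.0,
                    pairing_preference=pref, n_progeny=227,
                )
                cross = generate_population(cfg)
                gmap = two_stage_build(cross.matrix)
                mapped = cross.matrix.subset(
                    [m for m in cross.matrix.marker_ids if m in gmap.lg_of()]
                )
                links = detect_repulsion(mapped, gmap)
                accepted += sum(l.accepted for l in links)
            rates.append(accepted)
        assert rates[0] <= rates[1] <= rates[2]
        assert rates[2] > rates[0]


def _lg_from_positions(name, families, positions):
    markers = [f"{name.lower()}_{f}" for f in families]
    order = np.argsort(positions)
    return (
        LinkageGroup(
            name,
            [markers[i] for i in order],
            np.asarray(positions, dtype=float)[order],
        ),
        {markers[i]: families[i] for i in range(len(families))},
    )


class TestDifferenceRatio:
    def test_single_shared_interval_worked_example(self):
        # one shared interval of 12.1 vs 4.8 cM: ratio 7.3/16.9 = 0.43
        ref, fam1 = _lg_from_positions("R", ["F1", "F2"], [0.0, 12.1])
        cmp_, fam2 = _lg_from_positions("C", ["F1", "F2"], [0.0, 4.8])
        rec = difference_ratio(ref, cmp_, {**fam1, **fam2})
        assert rec.sum_abs_diff == pytest.approx(7.3)
        assert rec.sum_total == pytest.approx(16.9)
        assert round(rec.ratio, 1) == 0.4

    def test_second_worked_example(self):
        ref, fam1 = _lg_from_positions("R", ["F1", "F2"], [0.0, 17.1])
        cmp_, fam2 = _lg_from_positions("C", ["F1", "F2"], [0.0, 24.6])
        rec = difference_ratio(ref, cmp_, {**fam1, **fam2})
        assert rec.sum_abs_diff == pytest.approx(7.5)
        assert rec.sum_total == pytest.approx(41.7)
        assert round(rec.ratio, 1) == 0.2

    def test_identical_interval_structure_gives_zero(self):
        ref, fam1 = _lg_from_positions("R", ["F1", "F2", "F3"], [0.0, 10.0, 25.0])
        cmp_, fam2 = _lg_from_positions("C", ["F1", "F2", "F3"], [5.0, 15.0, 30.0])
        rec = difference_ratio(ref, cmp_, {**fam1, **fam2})
        assert rec.ratio == 0.0

    def test_reversed_compared_lg_is_reoriented(self):
        ref, fam1 = _lg_from_positions("R", ["F1", "F2", "F3"], [0.0, 10.0, 25.0])
        cmp_, fam2 = _lg_from_positions("C", ["F1", "F2", "F3"], [30.0, 20.0, 5.0])
        rec = difference_ratio(ref, cmp_, {**fam1, **fam2})
        assert rec.ratio == 0.0
        assert rec.skipped_intervals == 0

    def test_order_conflict_skipped_and_counted(self):
        ref, fam1 = _lg_from_positions("R", ["F1", "F2", "F3", "F4"], [0.0, 5.0, 10.0, 15.0])
        cmp_, fam2 = _lg_from_positions("C", ["F1", "F3", "F2", "F4"], [0.0, 5.0, 10.0, 15.0])
        rec = difference_ratio(ref, cmp_, {**fam1, **fam2})
        assert rec.skipped_intervals >= 1

    def test_insufficient_shared_markers_returns_none(self):
        ref, fam1 = _lg_from_positions("R", ["F1", "F9"], [0.0, 10.0])
        cmp_, fam2 = _lg_from_positions("C", ["F1", "F8"], [0.0, 10.0])
        assert difference_ratio(ref, cmp_, {**fam1, **fam2}) is None

    def test_divergent_partner_sets_score_higher_between_than_within(self):
        # two structurally diverged homologue subsets: ratios against the
        # reference are larger across the subset boundary than inside it
        cfg = SimulationConfig(
            seed=77, n_homology_groups=1, homologues_per_hg=8,
            markers_per_homologue=10, dosage_mix=(1, 0, 0),
            anchor_families_per_hg=10, anchor_allele_range=(6, 8),
            cross_hg_anchor_rate=0.0, pairing_preference=1.0,
            partner_sets=[[[0, 1, 2, 3], [4, 5, 6, 7]]],
            partner_set_divergence=8.0,
            distorted_homologue_fraction=0.0, missing_rate=0.0,
            subset_scored_fraction=0.0, n_progeny=227,
        )
        cross = generate_population(cfg)
        gmap = two_stage_build(cross.matrix)
        truth = cross.truth
        fams = cross.matrix.metadata["locus_family"].to_dict()
        recs = hg_difference_ratios({"1": [g.name for g in gmap.groups]}, gmap, fams)
        by_name = {g.name: g for g in gmap.groups}

        def hom_of(lg_name):
            return int(truth.loc[by_name[lg_name].markers[0], "homologues"])

        within, between = [], []
        for r in recs:
            same = (hom_of(r.reference_lg) < 4) == (hom_of(r.compared_lg) < 4)
            (within if same else between).append(r.ratio)
        assert within and between
        assert np.mean(between) > np.mean(within)


class TestPairingSummary:
    def _link(self, a, b, accepted=True):
        return RepulsionLink(a, b, 10.0, [("x", "y")] * 3, 0.5, 0.5, accepted)

    def _ratio(self, hg, ratio):
        return DifferenceRatioRecord(hg, "R", "C", 1, [1.0], [1.0], 0.0, 2.0, ratio)

    def test_no_accepted_links_gives_zero_percent(self):
        table, _ = pairing_summary(
            [self._link("A", "B", accepted=False)],
            [self._ratio("1", 0.3)],
            {"A": "1", "B": "1"},
            {"1": ["A", "B", "C"]},
        )
        assert table.loc["1", "pct_repulsion"] == 0.0

    def test_percentage_uses_hg_lg_count(self):
        table, _ = pairing_summary(
            [self._link("A", "B")],
            [],
            {"A": "1", "B": "1", "C": "1"},
            {"1": ["A", "B", "C"]},
        )
        assert table.loc["1", "n_lg_repulsion"] == 2
        assert table.loc["1", "pct_repulsion"] == pytest.approx(66.7)

    def test_perfectly_collinear_summaries_give_r2_one(self):
        links, ratios, hg_of, members = [], [], {}, {}
        # 4 HGs with pct = 100 * ratio by construction
        for hg, (n_lg, n_rep, ratio) in enumerate(
            [(10, 0, 0.0), (10, 2, 0.2), (10, 4, 0.4), (10, 8, 0.8)], start=1
        ):
            lgs = [f"H{hg}L{i}" for i in range(n_lg)]
            members[str(hg)] = lgs
            for lg_name in lgs:
                hg_of[lg_name] = str(hg)
            for i in range(0, n_rep, 2):
                links.append(self._link(lgs[i], lgs[i + 1]))
            ratios.append(self._ratio(str(hg), ratio))
        table, r2 = pairing_summary(links, ratios, hg_of, members)
        assert r2 == pytest.approx(1.0)

    def test_r2_matches_least_squares_oracle(self):
        rng = np.random.default_rng(4)
        ratios, links, hg_of, members = [], [], {}, {}
        xs, ys = [], []
        for hg in range(1, 7):
            x = float(rng.uniform(0.1, 0.9))
            n_lg = 10
            n_rep = int(rng.integers(0, 6)) * 2
            lgs = [f"H{hg}L{i}" for i in range(n_lg)]
            members[str(hg)] = lgs
            for lg_name in lgs:
                hg_of[lg_name] = str(hg)
            for i in range(0, n_rep, 2):
                links.append(self._link(lgs[i], lgs[i + 1]))
            ratios.append(self._ratio(str(hg), x))
            xs.append(round(x, 2))
            ys.append(round(100.0 * n_rep / n_lg, 1))
        table, r2 = pairing_summary(links, ratios, hg_of, members)
        oracle = stats.linregress(xs, ys)
        assert r2 == pytest.approx(oracle.rvalue**2, abs=1e-9)

    def test_r2_omitted_below_three_hgs(self):
        table, r2 = pairing_summary(
            [], [self._ratio("1", 0.5), self._ratio("2", 0.3)],
            {}, {"1": ["A", "B"], "2": ["C", "D"]},
        )
        assert r2 is None
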