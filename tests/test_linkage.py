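"""Two-point estimation, grouping, SARF ordering and two-stage maps."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polylink import (
    SimulationConfig,
    generate_population,
    group_markers,
    haldane_cm,
    order_group,
    two_point,
    two_point_tables,
    two_stage_build,
)
from polylink.linkage import _sarf


class TestTwoPoint:
    def test_identical_vectors_full_lod(self):
        v = [1.0, 0.0] * 50
        est = two_point(v, v)
        assert est.rf == 0.0
        assert est.lod == pytest.approx(30.10, abs=0.01)  # 100 log10(2)

    def test_ten_recombinants_in_hundred(self):
        a = [1.0] * 100
        b = [1.0] * 90 + [0.0] * 10
        est = two_point(a, b)
        assert est.rf == pytest.approx(0.10)
        assert est.lod == pytest.approx(15.98, abs=0.01)

    def test_independent_markers_zero_lod(self):
        a = [1.0] * 50 + [0.0] * 50
        b = ([1.0] * 25 + [0.0] * 25) * 2
        est = two_point(a, b)
        assert est.rf == 0.5
        assert est.lod == 0.0

    def test_low_overlap_flagged_uninformative(self):
        a = [1.0] * 10 + [np.nan] * 90
        b = [1.0] * 10 + [np.nan] * 90
        est = two_point(a, b)
        assert est.n_informative == 10
        assert not est.informative

    def test_tables_agree_with_scalar(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 2, size=(6, 120)).astype(float)
        calls[rng.random(calls.shape) < 0.1] = np.nan
        df = pd.DataFrame(calls, index=[f"m{i}" for i in range(6)])
        rf, lod, n = two_point_tables(df)
        for i in range(6):
            for j in range(i + 1, 6):
                est = two_point(calls[i], calls[j])
                assert rf[i, j] == pytest.approx(est.rf)
                assert lod[i, j] == pytest.approx(est.lod)
                assert n[i, j] == est.n_informative


class TestHaldane:
    @pytest.mark.parametrize("rf,cm", [(0.0, 0.0), (0.10, 11.16), (0.25, 34.66)])
    def test_known_values(self, rf, cm):
        assert haldane_cm(rf) == pytest.approx(cm, abs=0.01)

    def test_undefined_at_half(self):
        with pytest.raises(ValueError):
            haldane_cm(0.5)

    @given(st.floats(0.0, 0.45), st.floats(0.0, 0.45))
    def test_monotone(self, r1, r2):
        if r1 < r2:
            assert haldane_cm(r1) < haldane_cm(r2)


class TestGrouping:
    def _tables(self, calls):
        df = pd.DataFrame(calls, index=[f"m{i}" for i in range(len(calls))])
        return two_point_tables(df), df.index.tolist()

    def test_lod_threshold_is_inclusive(self):
        # engineered pair with LOD exactly at the threshold counts as linked
        rf = np.array([[0.0, 0.2], [0.2, 0.0]])
        lod = np.array([[0.0, 10.0], [10.0, 0.0]])
        n = np.full((2, 2), 100)
        groups, unlinked = group_markers(rf, lod, n, ["a", "b"])
        assert groups == [["a", "b"]] and unlinked == []
        lod_lo = lod - 1e-9
        groups, unlinked = group_markers(rf, lod_lo, n, ["a", "b"])
        assert groups == [] and unlinked == ["a", "b"]

    def test_independent_markers_all_unlinked(self):
        rng = np.random.default_rng(11)
        calls = rng.integers(0, 2, size=(8, 200)).astype(float)
        (rf, lod, n), ids = self._tables(calls)
        groups, unlinked = group_markers(rf, lod, n, ids)
        assert groups == []
        assert len(unlinked) == 8

    def test_recovers_three_simulated_chromosomes(self):
        cfg = SimulationConfig(
            seed=21, n_homology_groups=3, homologues_per_hg=2,
            markers_per_homologue=10, dosage_mix=(1, 0, 0),
            anchor_families_per_hg=0, missing_rate=0.0,
            subset_scored_fraction=0.0, distorted_homologue_fraction=0.0,
            pairing_preference=1.0, n_progeny=227,
        )
        cross = generate_population(cfg)
        gmap = two_stage_build(cross.matrix)
        # disomic pair per HG: each HG yields 2 homologue LGs
        assert len(gmap.groups) == 6
        assert gmap.unplaced == []
        lg_of = gmap.lg_of()
        truth = cross.truth
        for g in gmap.groups:
            hgs = truth.loc[g.markers, "hg"].unique()
            homs = truth.loc[g.markers, "homologues"].unique()
            assert len(hgs) == 1 and len(homs) == 1


class TestOrdering:
    def _rf_df(self, ids, vals):
        return pd.DataFrame(np.array(vals), index=ids, columns=ids)

    def test_three_marker_chain(self):
        rf = self._rf_df(
            ["m1", "m2", "m3"],
            [[0.0, 0.1, 0.18], [0.1, 0.0, 0.1], [0.18, 0.1, 0.0]],
        )
        lg = order_group(rf)
        assert lg.markers == ["m1", "m2", "m3"]
        assert lg.length == pytest.approx(22.31, abs=0.01)

    def test_two_markers(self):
        rf = self._rf_df(["a", "b"], [[0.0, 0.05], [0.05, 0.0]])
        lg = order_group(rf)
        assert lg.length == pytest.approx(5.27, abs=0.01)

    def test_orientation_canonical_under_input_reversal(self):
        rng = np.random.default_rng(5)
        pos = np.sort(rng.uniform(0, 80, size=7))
        ids = [f"m{i}" for i in rng.permutation(7)]
        d = np.abs(pos[:, None] - pos[None, :])
        rf = 0.5 * (1 - np.exp(-2 * d / 100))
        df = pd.DataFrame(rf, index=ids, columns=ids)
        lg1 = order_group(df)
        rev = df.iloc[::-1, ::-1]
        lg2 = order_group(rev)
        assert lg1.markers == lg2.markers
        np.testing.assert_allclose(lg1.positions, lg2.positions)

    def test_matches_exhaustive_sarf_oracle(self):
        # oracle: brute-force permutation search on small groups
        rng = np.random.default_rng(17)
        for _ in range(20):
            k = int(rng.integers(4, 8))
            pos = np.sort(rng.uniform(0, 60, size=k))
            d = np.abs(pos[:, None] - pos[None, :])
            rf = 0.5 * (1 - np.exp(-2 * d / 100))
            rf += rng.normal(0, 0.01, size=rf.shape)
            rf = np.clip((rf + rf.T) / 2, 0, 0.49)
            np.fill_diagonal(rf, 0)
            ids = [f"m{i}" for i in range(k)]
            lg = order_group(pd.DataFrame(rf, index=ids, columns=ids))
            got = _sarf([ids.index(m) for m in lg.markers], rf)
            best = min(
                _sarf(list(p), rf) for p in itertools.permutations(range(k))
            )
            assert got == pytest.approx(best, abs=1e-9)

    def test_degenerate_single_marker_rejected(self):
        with pytest.raises(ValueError):
            order_group(pd.DataFrame([[0.0]], index=["a"], columns=["a"]))


class TestTwoStageBuild:
    def _cross(self, **kw):
        base = dict(
            seed=31, n_homology_groups=2, homologues_per_hg=2,
            markers_per_homologue=10, dosage_mix=(1, 0, 0),
            anchor_families_per_hg=0, missing_rate=0.0,
            distorted_homologue_fraction=0.0, pairing_preference=1.0,
            n_progeny=227,
        )
        base.update(kw)
        return generate_population(SimulationConfig(**base))

    def test_no_partial_markers_identical_to_framework(self):
        cross = self._cross(subset_scored_fraction=0.0)
        gmap = two_stage_build(cross.matrix)
        gmap2 = two_stage_build(cross.matrix, framework_min_scored=1)
        assert [g.markers for g in gmap.groups] == [g.markers for g in gmap2.groups]

    def test_partial_marker_inserted_near_true_neighbour(self):
        cross = self._cross(subset_scored_fraction=0.3)
        matrix = cross.matrix
        gmap = two_stage_build(matrix)
        truth = cross.truth
        lg_of = gmap.lg_of()
        restricted = matrix.metadata.index[matrix.metadata["panel_restricted"]]
        placed = [m for m in restricted if m in lg_of]
        assert len(placed) >= 0.9 * len(restricted)
        by_name = {g.name: g for g in gmap.groups}
        for m in placed:
            g = by_name[lg_of[m]]
            # correct homologue
            homs = truth.loc[g.markers, "homologues"]
            assert truth.loc[m, "homologues"] == homs.mode().iat[0]
            # placed within 10 cM of its true nearest framework marker
            others = [x for x in g.markers if x != m]
            true_gap = (
                truth.loc[others, "position_cm"] - truth.loc[m, "position_cm"]
            ).abs().min()
            est_gap = min(
                abs(g.position_of(m) - g.position_of(x)) for x in others
            )
            assert est_gap - true_gap < 10.0

    def test_partial_marker_from_foreign_chromosome_unplaced(self):
        cross = self._cross(subset_scored_fraction=0.0)
        rng = np.random.default_rng(99)
        calls = cross.matrix.calls.copy()
        foreign = rng.integers(0, 2, size=calls.shape[1]).astype(float)
        foreign[94:] = np.nan
        calls.loc["foreign"] = foreign
        from polylink import MarkerMatrix

        gmap = two_stage_build(MarkerMatrix(calls=calls))
        assert "foreign" in gmap.unplaced

    def test_map_length_invariant_under_progeny_relabeling(self):
        cross = self._cross()
        from polylink import MarkerMatrix

        perm = np.random.default_rng(7).permutation(cross.matrix.n_progeny)
        shuffled = MarkerMatrix(calls=cross.matrix.calls.iloc[:, perm])
        a = two_stage_build(cross.matrix)
        b = two_stage_build(shuffled)
        assert a.total_length == pytest.approx(b.total_length)
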