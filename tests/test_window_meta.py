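import numpy as np
import pandas as pd
import pytest

from spatialnb.popdata_io import Dataset, Patch
from spatialnb.spatial_structure import Autocorrelogram
from spatialnb.window_meta import (
    Window,
    breeding_window_from_autocorr,
    build_windows,
    default_n_neighbourhoods,
    estimate_na,
    meta_nb,
    neighbourhood_size,
    random_window_sampling,
    window_profile,
)
from conftest import make_dataset, make_table


def patch(pid, x, counted=None, sampled=0, pct=None):
    return Patch(pid, float(x), 0.0, counted, sampled, pct)


class TestBuildWindows:
    def test_single_patch_collapses_to_one_window(self):
        ws = build_windows([patch("A", 0)])
        assert len(ws) == 1
        assert ws[0].patch_ids == frozenset({"A"})
        assert ws[0].radius == 100.0

    def test_three_collinear_patches_hand_enumeration(self):
        """Patches at 0/250/600 m produce exactly the six hand-enumerated
        windows; the all-patch set keeps its smallest generating radius."""
        ws = build_windows([patch("A", 0), patch("B", 250), patch("C", 600)],
                           radii=[100 * k for k in range(1, 7)])
        by_set = {w.patch_ids: w for w in ws}
        assert len(ws) == 6
        assert by_set[frozenset("A")].radius == 100
        assert by_set[frozenset("B")].radius == 100
        assert by_set[frozenset("C")].radius == 100
        assert by_set[frozenset(["A", "B"])].radius == 300
        assert by_set[frozenset(["A", "B"])].focal == "A"  # tie broken by id
        assert by_set[frozenset(["B", "C"])].radius == 400
        assert by_set[frozenset(["A", "B", "C"])].radius == 400
        assert by_set[frozenset(["A", "B", "C"])].focal == "B"

    def test_dedup_idempotence(self):
        patches = [patch(c, x) for c, x in zip("ABCDE", (0, 150, 340, 560, 900))]
        w1 = build_windows(patches)
        w2 = build_windows(patches)
        assert [(w.focal, w.radius, w.patch_ids) for w in w1] == [
            (w.focal, w.radius, w.patch_ids) for w in w2
        ]

    def test_membership_monotone_in_radius(self):
        patches = [patch(c, x) for c, x in zip("ABCD", (0, 220, 470, 810))]
        for focal in "ABCD":
            prev = set()
            for r in (100.0, 300.0, 500.0, 900.0):
                members = {
                    p.id for p in patches
                    if abs(p.x - next(q.x for q in patches if q.id == focal)) <= r
                }
                assert prev <= members
                prev = members

    def test_no_patches_rejected(self):
        with pytest.raises(ValueError):
            build_windows([])


class TestEstimateNa:
    def _dataset(self):
        table = make_table([[(100, 102)]], patches=["P2"])
        patches = [
            Patch("P2", 0.0, 0.0, 70, 31, 0.10),
            Patch("P3", 500.0, 0.0, 40, 10, 0.0),
        ]
        return Dataset(table, patches)

    def test_census_arithmetic(self):
        # 70 counted x 10% target = 7 mothers; / 0.48 females -> 14.6 adults
        ds = self._dataset()
        w = Window("w", "P2", 100.0, frozenset({"P2"}))
        assert estimate_na(w, ds, 0.48) == pytest.approx(70 * 0.10 / 0.48)

    def test_zero_target_fraction_gives_zero(self):
        ds = self._dataset()
        w = Window("w", "P3", 100.0, frozenset({"P3"}))
        assert estimate_na(w, ds, 0.48) == 0.0

    def test_even_sex_ratio_doubles_mothers(self):
        ds = self._dataset()
        w = Window("w", "P2", 100.0, frozenset({"P2"}))
        assert estimate_na(w, ds, 0.5) == pytest.approx(14.0)

    def test_degenerate_female_fraction_rejected(self):
        ds = self._dataset()
        w = Window("w", "P2", 100.0, frozenset({"P2"}))
        with pytest.raises(ValueError):
            estimate_na(w, ds, 0.0)


class TestMetaNb:
    def test_island_model_reproduces_published_aggregates(self):
        """Summed per-patch LD Nb of 676.9 with FST 0.0162 gives the island
        meta-Nb of 688; the sPCA-group level (509, FST 0.0121) gives 515."""
        from spatialnb.cli_pipeline import example_patch_estimates

        df = example_patch_estimates()
        est = meta_nb(df.ld_nb.dropna().to_numpy(), fst=0.0162, mode="island")
        assert est.value == pytest.approx(688, abs=1.0)
        est2 = meta_nb([509.0], fst=0.0121, mode="island")
        assert est2.value == pytest.approx(515, abs=1.0)

    def test_zero_fst_island_equals_sum(self):
        locals_ = [10.0, 20.0, np.inf, 30.0]
        assert meta_nb(locals_, fst=0.0, mode="island").value == meta_nb(
            locals_, mode="sum_local"
        ).value == 60.0

    def test_extrapolation_arithmetic(self):
        assert meta_nb([150.0], k=4, mode="extrapolation").value == 600.0

    def test_island_exceeds_sum_for_positive_fst(self):
        locals_ = [25.0, 40.0]
        assert (
            meta_nb(locals_, fst=0.05, mode="island").value
            > meta_nb(locals_, mode="sum_local").value
        )

    def test_invalid_fst_rejected(self):
        with pytest.raises(ValueError):
            meta_nb([10.0], fst=1.0, mode="island")


class TestNeighbourhoodSize:
    def test_zero_dispersal_gives_zero(self):
        assert neighbourhood_size(0.0, 0.01) == 0.0

    def test_closed_form_value(self):
        assert neighbourhood_size(100.0, 0.005) == pytest.approx(628.3, abs=0.05)

    def test_doubling_sigma_quadruples(self):
        assert neighbourhood_size(200.0, 0.005) == pytest.approx(
            4 * neighbourhood_size(100.0, 0.005)
        )

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            neighbourhood_size(-1.0, 0.1)


class TestBreedingWindow:
    def _ac(self, moran, mean_distance):
        moran = np.asarray(moran, float)
        return Autocorrelogram(
            bounds=np.asarray(mean_distance, float),
            mean_distance=np.asarray(mean_distance, float),
            moran=moran,
            p_values=np.full(moran.size, np.nan),
            n_pairs=np.ones(moran.size, int),
            zero_crossing=None,
        )

    def test_crossing_at_460_gives_radius_230(self):
        ac = self._ac([0.05, 0.01, -0.01, -0.02], [100, 380, 540, 800])
        # linear interpolation between 380 m (+0.01) and 540 m (-0.01)
        ac.zero_crossing = 460.0
        diameter, radius = breeding_window_from_autocorr(ac)
        assert diameter == 460.0
        assert radius == 230.0

    def test_no_positive_first_class_rejected(self):
        ac = self._ac([-0.01, -0.02], [100, 300])
        with pytest.raises(ValueError, match="no positive autocorrelation"):
            breeding_window_from_autocorr(ac)

    def test_simulated_ibd_radius_positive_and_bounded(self, small_metapop):
        from spatialnb.spatial_structure import autocorrelogram

        ds, _ = small_metapop
        ac = autocorrelogram(ds, n_perm=0)
        diameter, radius = breeding_window_from_autocorr(ac)
        assert 0 < radius < 900


class TestWindowProfile:
    def test_identical_sample_sets_give_identical_estimates(self, small_metapop):
        ds, _ = small_metapop
        pids = [p.id for p in ds.patches[:2]]
        w1 = Window("a", pids[0], 300.0, frozenset(pids))
        w2 = Window("b", pids[1], 500.0, frozenset(pids))
        est = window_profile(ds, [w1, w2])
        assert est[0].ld.nb_point == est[1].ld.nb_point
        assert est[0].sibship_nb == est[1].sibship_nb

    def test_small_windows_skipped_with_reason(self, small_metapop):
        ds, _ = small_metapop
        w = Window("tiny", "none", 100.0, frozenset({"not-a-patch"}))
        est = window_profile(ds, [w], min_individuals=6)
        assert est[0].skipped is not None

    def test_panmictic_profile_flat(self, panmictic_pop):
        ds, _ = panmictic_pop
        w = Window("all", "full", 1000.0, frozenset(p.id for p in ds.patches))
        est = window_profile(ds, [w])[0]
        assert est.ld is not None and est.n == ds.genotypes.n_individuals


class TestRandomWindowSampling:
    def test_deterministic_under_seed(self, small_metapop):
        ds, _ = small_metapop
        kw = dict(radius=400.0, n_samples=30, n_buffers=3, n_reps=1, seed=5)
        r1 = random_window_sampling(ds, **kw)
        r2 = random_window_sampling(ds, **kw)
        pd.testing.assert_frame_equal(r1.per_replicate, r2.per_replicate)

    def test_impossible_qualification_raises(self, small_metapop):
        ds, _ = small_metapop
        with pytest.raises(RuntimeError, match="qualifying buffers"):
            random_window_sampling(
                ds, radius=10.0, n_samples=500, n_buffers=5, max_rejections=200
            )

    def test_extrapolation_uses_k(self, small_metapop):
        ds, _ = small_metapop
        res = random_window_sampling(
            ds, radius=400.0, n_samples=30, n_buffers=3, n_reps=2, k=4, seed=1
        )
        usable = res.per_replicate[res.per_replicate.usable]
        if len(usable):
            assert np.allclose(usable.extrapolated, usable.nb * 4)

    def test_default_k_heuristic_positive(self, small_metapop):
        ds, _ = small_metapop
        assert default_n_neighbourhoods(ds, 230.0) >= 1
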