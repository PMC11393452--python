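import numpy as np
import pytest

from spatialnb.popdata_io import Dataset, Patch
from spatialnb.spatial_structure import (
    _individual_freq_matrix,
    _row_normalized_w,
    autocorrelogram,
    group_patches,
    nei_fis,
    pairwise_moran,
    spca,
    wc_fst,
)
from conftest import make_dataset, make_table


def anova_theta_oracle(table, patch_labels):
    """Weir-Cockerham theta via three-level ANOVA sums of squares.

    Independent route: per allele, mean squares among populations (MSP),
    among individuals within populations (MSI) and within individuals
    (MSG) give a = (MSP - MSI) / (2 n_c), b = (MSI - MSG) / 2, c = MSG;
    theta is the multilocus ratio of sums.
    """
    patch_labels = np.asarray(patch_labels)
    pops = np.unique(patch_labels)
    num = den = 0.0
    for l in range(table.n_loci):
        calls = table.calls[:, l, :]
        typed = calls[:, 0] != -1
        alleles = sorted({int(a) for a in calls[typed].ravel()})
        ns = np.array([int((typed & (patch_labels == p)).sum()) for p in pops], float)
        keep = ns > 0
        if keep.sum() < 2:
            continue
        ns = ns[keep]
        r = ns.size
        n_tot = ns.sum()
        n_c = (n_tot - (ns**2).sum() / n_tot) / (r - 1)
        for a in alleles:
            x = []  # per population: list of per-individual dosage/2 pairs
            for p in pops[keep.tolist()] if isinstance(keep, np.ndarray) else pops:
                rows = typed & (patch_labels == p)
                x.append((calls[rows] == a).astype(float))
            grand = np.concatenate([xi.reshape(-1) for xi in x]).mean()
            ssp = sum(2 * len(xi) * (xi.mean() - grand) ** 2 for xi in x)
            ssi = sum(
                2 * ((xi.mean(axis=1) - xi.mean()) ** 2).sum() for xi in x
            )
            ssg = sum(((xi - xi.mean(axis=1, keepdims=True)) ** 2).sum() for xi in x)
            msp = ssp / (r - 1)
            msi = ssi / (n_tot - r)
            msg = ssg / n_tot
            a_comp = (msp - msi) / (2 * n_c)
            b_comp = (msi - msg) / 2.0
            num += a_comp
            den += a_comp + b_comp + msg
    return num / den


class TestPairwiseMoran:
    def _dataset(self, seed=0, n=20, n_patches=4):
        rng = np.random.default_rng(seed)
        rows = rng.choice([100, 102, 104], size=(n, 5, 2)).tolist()
        patches = [f"P{i % n_patches}" for i in range(n)]
        return make_dataset(make_table(rows, patches=patches))

    def test_pair_mean_identity(self):
        """Mean over all ordered pairs a != b is exactly -1/(n-1)."""
        for seed in range(5):
            ds = self._dataset(seed)
            I = pairwise_moran(ds)
            n = I.shape[0]
            off = I[~np.eye(n, dtype=bool)]
            assert off.mean() == pytest.approx(-1.0 / (n - 1), abs=1e-12)

    def test_identical_pair_is_maximal(self):
        rng = np.random.default_rng(1)
        rows = rng.choice(100 + 2 * np.arange(8), size=(15, 8, 2))
        rows[1] = rows[0]
        ds = make_dataset(make_table(rows.tolist()))
        I = pairwise_moran(ds)
        iu = np.triu_indices(15, k=1)
        assert I[0, 1] == I[iu].max()

    def test_four_individual_hand_computation(self):
        # one locus, two alleles; x = (1, 1, 0.5, 0); p = 0.625
        rows = [[(100, 100)], [(100, 100)], [(100, 102)], [(102, 102)]]
        ds = make_dataset(make_table(rows))
        x = np.array([1.0, 1.0, 0.5, 0.0])
        z = x - x.mean()
        denom = (z**2).mean()
        expected = np.outer(z, z) / denom
        assert np.allclose(pairwise_moran(ds), expected)

    def test_monomorphic_only_rejected(self):
        ds = make_dataset(make_table([[(100, 100)]] * 4))
        with pytest.raises(ValueError):
            pairwise_moran(ds)


class TestAutocorrelogram:
    def _spread_dataset(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        rows = rng.choice([100, 102, 104, 106], size=(n, 6, 2)).tolist()
        patches = [f"P{i}" for i in range(n)]
        table = make_table(rows, patches=patches)
        coords = {p: tuple(rng.uniform(0, 1000, 2)) for p in sorted(set(patches))}
        return make_dataset(table, coords=coords)

    def test_single_class_equals_overall_pair_mean(self):
        ds = self._spread_dataset()
        ac = autocorrelogram(ds, n_classes=1, n_perm=0)
        n = ds.genotypes.n_individuals
        assert ac.moran[0] == pytest.approx(-1.0 / (n - 1), abs=1e-12)

    def test_classes_partition_pairs(self):
        ds = self._spread_dataset(1)
        ac = autocorrelogram(ds, n_classes=10, n_perm=0)
        n = ds.genotypes.n_individuals
        assert ac.n_pairs.sum() == n * (n - 1) // 2

    def test_randomised_locations_rarely_significant(self):
        """Type-I calibration: spatially random genotypes give class
        p-values above 0.05 at close to the nominal rate."""
        sig = total = 0
        for seed in range(30):
            ds = self._spread_dataset(seed, n=30)
            ac = autocorrelogram(ds, n_classes=5, n_perm=199, seed=seed)
            sig += int((ac.p_values <= 0.05).sum())
            total += 5
        assert sig / total < 0.12  # nominal 5% two-sided, binomial slack

    def test_ibd_population_first_class_positive(self, small_metapop):
        ds, _ = small_metapop
        ac = autocorrelogram(ds, n_perm=199, seed=3)
        assert ac.moran[0] > 0
        assert ac.p_values[0] <= 0.05
        assert ac.zero_crossing is not None
        assert 0 < ac.zero_crossing < 900


class TestSpca:
    def test_eigenvalue_variance_moran_identity(self, small_metapop):
        """Every sPCA eigenvalue equals var(score) x Moran's I(score)."""
        ds, _ = small_metapop
        res = spca(ds, d_max=400.0, n_perm=0)
        X, _ = _individual_freq_matrix(ds.genotypes)
        X = X - X.mean(axis=0)
        W = _row_normalized_w(ds.coordinates(), 400.0)
        Ws = (W + W.T) / 2.0
        n = X.shape[0]
        for k in range(res.scores.shape[1]):
            s = res.scores[:, k]
            var = (s**2).sum() / n
            moran = s @ Ws @ s / (s**2).sum()
            lam_set = res.eigenvalues
            assert np.min(np.abs(lam_set - var * moran)) < 1e-8

    def test_clinal_population_global_structure(self, small_metapop):
        ds, _ = small_metapop
        res = spca(ds, d_max=400.0, n_perm=99, seed=2)
        assert res.global_p <= 0.05

    def test_spatially_random_genotypes_not_significant(self):
        rng = np.random.default_rng(0)
        hits = 0
        for seed in range(10):
            rows = rng.choice([100, 102, 104, 106], size=(40, 6, 2)).tolist()
            patches = [f"P{i}" for i in range(40)]
            coords = {p: tuple(rng.uniform(0, 1000, 2)) for p in patches}
            ds = make_dataset(make_table(rows, patches=patches), coords=coords)
            res = spca(ds, d_max=400.0, n_perm=99, seed=seed)
            hits += res.global_p <= 0.05
        assert hits <= 3


class TestGroupPatches:
    def test_singleton_groups_at_k_equals_n(self, small_metapop):
        ds, _ = small_metapop
        res = spca(ds, d_max=400.0, n_perm=0)
        groups = group_patches(ds, res, k=len(ds.patches))
        assert len(set(groups.values())) == len(ds.patches)

    def test_single_group(self, small_metapop):
        ds, _ = small_metapop
        res = spca(ds, d_max=400.0, n_perm=0)
        groups = group_patches(ds, res, k=1)
        assert set(groups.values()) == {0}

    def test_k_exceeding_patches_rejected(self, small_metapop):
        ds, _ = small_metapop
        res = spca(ds, d_max=400.0, n_perm=0)
        with pytest.raises(ValueError):
            group_patches(ds, res, k=100)

    def test_separated_clusters_recovered(self):
        """Four well-separated patch clusters with distinct allele pools are
        recovered by the contiguity-constrained clustering."""
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(3)
        centres = [(0, 0), (5000, 0), (0, 5000), (5000, 5000)]
        rows, patches, coords, truth = [], [], {}, {}
        pools = [100 + 2 * np.arange(4) + 40 * g for g in range(4)]
        for g, (cx, cy) in enumerate(centres):
            for p in range(3):
                pid = f"G{g}P{p}"
                coords[pid] = (cx + 100.0 * p, cy)
                truth[pid] = g
                for _ in range(6):
                    rows.append(rng.choice(pools[g], size=(6, 2)).tolist())
                    patches.append(pid)
        ds = make_dataset(make_table(rows, patches=patches), coords=coords)
        res = spca(ds, d_max=1500.0, n_perm=0)
        groups = group_patches(ds, res, k=4)
        pids = sorted(groups)
        ari = adjusted_rand_score([truth[p] for p in pids], [groups[p] for p in pids])
        assert ari > 0.9


class TestWcFst:
    def test_fixed_demes_theta_one(self):
        rows = [[(100, 100)]] * 6 + [[(102, 102)]] * 6
        patches = ["A"] * 6 + ["B"] * 6
        ds = make_dataset(make_table(rows, patches=patches))
        res = wc_fst(ds, n_boot=10, pairwise=False)
        assert res.theta == pytest.approx(1.0)

    def test_matches_anova_oracle_to_1e10(self):
        """Moment-formula theta equals the independent sums-of-squares
        oracle on random toy tables."""
        rng = np.random.default_rng(7)
        for trial in range(4):
            n = 30
            rows = rng.choice([100, 102, 104], size=(n, 4, 2)).tolist()
            patches = [f"P{i % 3}" for i in range(n)]
            ds = make_dataset(make_table(rows, patches=patches))
            res = wc_fst(ds, min_n=2, n_boot=10, pairwise=False)
            oracle = anova_theta_oracle(ds.genotypes, ds.genotypes.patch_ids)
            assert res.theta == pytest.approx(oracle, abs=1e-10)

    def test_panmictic_ci_covers_zero(self):
        rng = np.random.default_rng(11)
        covered = 0
        for seed in range(10):
            rows = rng.choice(100 + 2 * np.arange(6), size=(60, 8, 2)).tolist()
            patches = [f"P{i % 4}" for i in range(60)]
            ds = make_dataset(make_table(rows, patches=patches))
            res = wc_fst(ds, n_boot=200, seed=seed, pairwise=False)
            covered += res.ci[0] <= 0.0 <= max(res.ci[1], 0.0)
        assert covered >= 9

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        rows = rng.choice([100, 102, 104], size=(24, 3, 2))
        patches = [f"P{i % 2}" for i in range(24)]
        ds1 = make_dataset(make_table(rows.tolist(), patches=patches))
        relabeled = np.where(rows == 100, 900, rows)
        ds2 = make_dataset(make_table(relabeled.tolist(), patches=patches))
        t1 = wc_fst(ds1, n_boot=10, pairwise=False).theta
        t2 = wc_fst(ds2, n_boot=10, pairwise=False).theta
        assert t1 == pytest.approx(t2, abs=1e-12)

    def test_too_few_patches_rejected(self):
        ds = make_dataset(make_table([[(100, 102)]] * 6))
        with pytest.raises(ValueError):
            wc_fst(ds)


class TestNeiFis:
    def test_all_heterozygotes_strongly_negative(self):
        ds = make_dataset(make_table([[(100, 102)]] * 30))
        assert nei_fis(ds) < -0.9

    def test_hwe_sample_near_zero(self):
        rng = np.random.default_rng(2)
        rows = rng.choice([100, 102, 104, 106], size=(200, 10, 2)).tolist()
        ds = make_dataset(make_table(rows))
        assert abs(nei_fis(ds)) < 0.03

    def test_no_heterozygosity_rejected(self):
        ds = make_dataset(make_table([[(100, 100)]] * 5))
        with pytest.raises(ValueError):
            nei_fis(ds)
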