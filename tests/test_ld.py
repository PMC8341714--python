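import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dpprs.errors import ConfigError
from dpprs.ld import (
    BandedR2,
    BlockPartition,
    LDReference,
    banded_r2,
    partition_blocks,
    shrink_correlation,
    validate_partition,
)
from dpprs.simulate import simulate_panel


def band_from_dense(r2: np.ndarray, window: int) -> BandedR2:
    m = len(r2)
    band = np.zeros((m, window))
    for d in range(1, window + 1):
        band[: m - d, d - 1] = np.diag(r2, d)
    return BandedR2(band, window)


class TestBandedR2:
    def test_duplicated_column_gives_r2_one(self, rng):
        x = rng.standard_normal((200, 1))
        X = np.hstack([x, x, rng.standard_normal((200, 1))])
        band = banded_r2(X, window=2)
        assert band.r2(0, 1) == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        X = rng.standard_normal((2000, 60))
        band = banded_r2(X, window=10)
        vals = band.band[band.band > 0]
        assert np.quantile(vals, 0.99) < 0.05

    def test_constructed_correlation_recovered(self, rng):
        # SNPs 1-2 correlated at 0.9, SNP 3 independent
        n = 5000
        z = rng.standard_normal((n, 3))
        x1 = z[:, 0]
        x2 = 0.9 * z[:, 0] + np.sqrt(1 - 0.81) * z[:, 1]
        band = banded_r2(np.column_stack([x1, x2, z[:, 2]]), window=2)
        assert band.r2(0, 1) == pytest.approx(0.81, abs=0.05)
        assert band.r2(0, 2) < 0.05 and band.r2(1, 2) < 0.05

    def test_window_below_one_rejected(self, rng):
        with pytest.raises(ConfigError):
            banded_r2(rng.standard_normal((10, 4)), window=0)

    def test_cross_chromosome_pairs_zeroed(self, rng):
        x = rng.standard_normal((100, 1))
        X = np.hstack([x, x])
        band = banded_r2(X, window=1, chrom=np.array([1, 2]))
        assert band.r2(0, 1) == 0.0


class TestPartitionBlocks:
    def test_two_clear_blocks(self):
        r2 = np.eye(4)
        r2[0, 1] = r2[1, 0] = 0.5
        r2[2, 3] = r2[3, 2] = 0.5
        r2[r2 == 0] = 0.01
        band = band_from_dense(r2, window=3)
        part = partition_blocks(band, r2_threshold=0.1)
        assert part.bounds == [(0, 2), (2, 4)]
        assert part.forced_cuts == []

    def test_fully_linked_single_block(self):
        r2 = np.full((4, 4), 0.5)
        band = band_from_dense(r2, window=3)
        part = partition_blocks(band, r2_threshold=0.1, max_block_size=10)
        assert part.bounds == [(0, 4)]

    def test_forced_cut_minimizes_max_crossing(self):
        r2 = np.full((4, 4), 0.5)
        band = band_from_dense(r2, window=3)
        part = partition_blocks(band, r2_threshold=0.1, max_block_size=2)
        assert part.sizes.max() <= 2
        assert len(part.bounds) == 2
        assert len(part.forced_cuts) >= 1
        # every cut position ties at max crossing r2 0.5; the log records it
        assert part.forced_cuts[0].max_crossing_r2 == pytest.approx(0.5)

    def test_forced_cut_picks_weakest_link(self):
        # chain 0-1-2-3 with a weak link between 1 and 2
        r2 = np.eye(4)
        for i, j, v in [(0, 1, 0.8), (1, 2, 0.15), (2, 3, 0.8)]:
            r2[i, j] = r2[j, i] = v
        band = band_from_dense(r2, window=3)
        part = partition_blocks(band, r2_threshold=0.1, max_block_size=3)
        assert (0, 2) in part.bounds and (2, 4) in part.bounds
        assert part.forced_cuts[0].max_crossing_r2 == pytest.approx(0.15)


class TestValidatePartition:
    def test_unforced_partition_certifies(self, rng):
        X, _, _ = simulate_panel(1500, [20, 30, 25], rho=0.6, rng=rng)
        band = banded_r2(X, window=40)
        part = partition_blocks(band, r2_threshold=0.1)
        assert part.forced_cuts == []
        assert validate_partition(part, band, 0.1) == []

    def test_cut_inside_high_ld_pair_reported(self):
        r2 = np.eye(4)
        r2[1, 2] = r2[2, 1] = 0.9
        band = band_from_dense(r2, window=3)
        bad = BlockPartition([(0, 2), (2, 4)])
        viol = validate_partition(bad, band, 0.1)
        assert viol == [(1, 2, pytest.approx(0.9))]

    def test_counts_match_brute_force_on_random_partitions(self, rng):
        m = 40
        X, _, _ = simulate_panel(800, [10, 10, 10, 10], rho=0.7, rng=rng)
        band = banded_r2(X, window=12)
        for _ in range(5):
            cuts = np.sort(rng.choice(np.arange(1, m), size=3, replace=False))
            bounds = []
            prev = 0
            for c in list(cuts) + [m]:
                bounds.append((prev, int(c)))
                prev = int(c)
            part = BlockPartition(bounds)
            block = part.block_of()
            brute = sum(
                1
                for i in range(m)
                for j in range(i + 1, min(m, i + 12 + 1))
                if band.r2(i, j) > 0.1 and block[i] != block[j]
            )
            assert len(validate_partition(part, band, 0.1)) == brute


class TestShrinkCorrelation:
    def test_intensity_zero_is_identity_map(self, rng):
        R = np.corrcoef(rng.standard_normal((50, 4)), rowvar=False)
        out, lam = shrink_correlation(R, 50, 0.0)
        assert lam == 0.0 and np.allclose(out, R)

    def test_intensity_one_gives_identity_matrix(self, rng):
        R = np.corrcoef(rng.standard_normal((50, 4)), rowvar=False)
        out, _ = shrink_correlation(R, 50, 1.0)
        assert np.allclose(out, np.eye(4))

    def test_rank_deficient_matrix_lifted(self):
        # correlation of 3 SNPs carried by 2 haplotype patterns: rank 2
        hap = np.array([[1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        X = np.repeat(hap, [30, 20], axis=0)
        X = X - X.mean(0)
        R = np.corrcoef(X, rowvar=False)
        out, _ = shrink_correlation(R, 50, 0.1)
        assert np.linalg.eigvalsh(out).min() >= 0.1 - 1e-12

    def test_out_of_range_intensity_rejected(self):
        with pytest.raises(ConfigError):
            shrink_correlation(np.eye(2), 10, 1.5)

    def test_auto_floor_for_small_panels(self, rng):
        X = rng.standard_normal((200, 6))
        R = np.corrcoef(X, rowvar=False)
        _, lam = shrink_correlation(R, 200, "auto")
        assert 0.05 <= lam <= 1.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        lam=st.floats(0.01, 1.0),
        seed=st.integers(0, 10_000),
        m=st.integers(2, 8),
    )
    def test_eigmin_at_least_lambda(self, lam, seed, m):
        g = np.random.default_rng(seed)
        X = g.standard_normal((3 * m, m))
        R = np.corrcoef(X, rowvar=False)
        out, used = shrink_correlation(R, 3 * m, lam)
        assert np.linalg.eigvalsh(out).min() >= used - 1e-10
        assert np.allclose(np.diag(out), 1.0, atol=1e-10)
        assert np.allclose(out, out.T)


class TestLDReference:
    def test_from_panel_blocks_unit_diagonal_pd(self, rng):
        X, _, meta = simulate_panel(600, [15, 10], rho=0.5, rng=rng)
        from dpprs.plinkio import PanelGenotypes

        panel = PanelGenotypes(X, meta)
        ref = LDReference.from_panel(panel, window=20)
        for R in ref.blocks:
            assert np.allclose(np.diag(R), 1.0, atol=1e-10)
            assert np.linalg.eigvalsh(R).min() > 0

    def test_save_load_roundtrip(self, tmp_path, rng):
        X, _, meta = simulate_panel(400, [8, 12], rho=0.5, rng=rng)
        from dpprs.plinkio import PanelGenotypes

        ref = LDReference.from_panel(PanelGenotypes(X, meta), window=15)
        ref.save(tmp_path / "ld")
        back = LDReference.load(tmp_path / "ld")
        assert back.partition.bounds == ref.partition.bounds
        for a, b in zip(ref.blocks, back.blocks):
            assert np.allclose(a, b)
        assert list(back.meta["snp_id"]) == list(ref.meta["snp_id"])

    def test_restrict_preserves_structure(self, rng):
        R_blocks = [np.eye(3), np.eye(4)]
        ref = LDReference.from_matrices(R_blocks)
        keep = np.array([True, False, True, True, True, False, True])
        sub = ref.restrict(keep)
        assert sub.n_snps == 5
        assert [len(b) for b in sub.blocks] == [2, 3]
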