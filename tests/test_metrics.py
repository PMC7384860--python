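"""Pattern quantification: straightness, widths, pseudo-stripes, PCF."""
import numpy as np
import pytest

import stripesim as ss
from stripesim.lattice import CellKind
from stripesim.metrics import _ring_pair_totals

from conftest import small_random_state


def band_state(rows=30, cols=40, band=(28, 38), kind=CellKind.ID):
    st = small_random_state(0, rows=rows, cols=cols, density=0.0)
    st.i[band[0]:band[1], :] = kind
    return st


class TestStraightness:
    def test_straight_line_scores_one(self):
        line = ss.Polyline(np.arange(10.0), np.full(10, 2.0))
        assert ss.stripe_straightness(line) == pytest.approx(1.0)

    def test_hand_computed_tent(self):
        line = ss.Polyline([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert ss.stripe_straightness(line) == pytest.approx(2 / (2 * np.sqrt(2)))

    def test_never_exceeds_one_and_rigid_motion_invariant(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.random(20) + 0.1)
        y = rng.normal(size=20)
        base = ss.stripe_straightness(ss.Polyline(x, y))
        assert base <= 1.0 + 1e-12
        shifted = ss.stripe_straightness(ss.Polyline(x, y + 5.0))
        mirrored = ss.stripe_straightness(ss.Polyline(x, -y))
        assert shifted == pytest.approx(base)
        assert mirrored == pytest.approx(base)

    def test_polyline_validation(self):
        with pytest.raises(ValueError):
            ss.Polyline([0.0], [0.0])
        with pytest.raises(ValueError):
            ss.Polyline([0.0, 0.0], [0.0, 1.0])


class TestCenterlineAndWidth:
    def test_horizontal_band_gives_flat_centerline(self):
        st = band_state()
        line = ss.interstripe_centerline(st)
        mid_mm = (28 + 38) / 2 * 0.01
        assert np.allclose(line.y, mid_mm, atol=0.006)
        assert ss.stripe_straightness(line) == pytest.approx(1.0, abs=1e-6)

    def test_displaced_half_band_steps(self):
        st = band_state()
        half = st.i.shape[1] // 2
        st.i[28:38, half:] = 0
        st.i[38:48, half:] = CellKind.ID
        line = ss.interstripe_centerline(st)
        assert line.y[-1] - line.y[0] == pytest.approx(0.10, abs=0.01)

    def test_ten_row_band_width(self):
        st = band_state(band=(28, 38))
        assert ss.x0_width(st) == pytest.approx(0.10)

    def test_width_invariant_under_horizontal_shift(self):
        a = band_state(band=(20, 30))
        b = band_state(band=(40, 50))
        assert ss.x0_width(a) == pytest.approx(ss.x0_width(b))

    def test_no_interstripe_raises(self):
        st = small_random_state(0, density=0.0)
        with pytest.raises(ValueError):
            ss.interstripe_centerline(st)


class TestPseudoStripes:
    def test_no_melanophores(self):
        st = small_random_state(0, density=0.0)
        assert ss.count_pseudo_stripes(st) == 0
        assert ss.longest_melanophore_stretch(st) == 0.0

    def test_two_bands_counted(self):
        st = small_random_state(0, rows=50, cols=40, density=0.0)
        st.m[10:14, :] = CellKind.M
        st.m[35:39, :] = CellKind.M
        assert ss.count_pseudo_stripes(st) == 2

    def test_full_row_stretch_is_one(self):
        st = small_random_state(0, rows=50, cols=40, density=0.0)
        st.m[20:23, :] = CellKind.M
        assert ss.longest_melanophore_stretch(st) == pytest.approx(1.0)

    def test_partial_contiguous_row(self):
        st = small_random_state(0, rows=50, cols=40, density=0.0)
        st.m[20:23, 0:12] = CellKind.M   # 30% of 40 columns
        assert ss.longest_melanophore_stretch(st) == pytest.approx(0.30)

    def test_significant_break_splits_run(self):
        st = small_random_state(0, rows=50, cols=60, density=0.0)
        st.m[20:23, 0:20] = CellKind.M
        st.m[20:23, 30:45] = CellKind.M   # 0.2 mm gap > 0.1 mm tolerance
        assert ss.longest_melanophore_stretch(st) == pytest.approx(20 / 60)


class TestCountsAndRatios:
    def test_synthetic_ratio(self):
        st = small_random_state(0, rows=30, cols=40, density=0.0)
        st.i[10:20, :] = CellKind.ID       # interstripe rows
        st.i[40:50, ::7] = CellKind.IL     # loose elsewhere -> stripe rows
        xs = np.argwhere(st.x[10:20] == 0)[:40]
        for r, c in xs:
            st.x[10 + r, c] = CellKind.X
        ms = 0
        for r in range(25, 30):
            for c in range(0, 2):
                st.m[r, c] = CellKind.M
                ms += 1
        counts = ss.cell_counts_and_ratio(st)
        assert counts["x_interstripe"] == 40
        assert counts["m_stripe"] == ms
        assert counts["x_to_m_ratio"] == pytest.approx(40 / ms)

    def test_errors_without_region_structure(self):
        st = small_random_state(0, density=0.0)
        with pytest.raises(ValueError):
            ss.cell_counts_and_ratio(st)

    @pytest.mark.parametrize("mut,wt,real,expect", [
        (50, 80, 100, 62.5), (7, 7, 55, 55.0), (0, 9, 99, 0.0)])
    def test_normalisation(self, mut, wt, real, expect):
        assert ss.normalize_melanocyte_counts(mut, wt, real) == expect

    def test_normalisation_requires_wt(self):
        with pytest.raises(ZeroDivisionError):
            ss.normalize_melanocyte_counts(1, 0, 1)


def brute_pcf(grid, kind, mmax):
    """Brute-force Square Uniform PCF on one small lattice (oracle)."""
    occ = np.argwhere(grid == kind)
    nr, nc = grid.shape
    n = len(occ)
    S = nr * nc
    p = n * (n - 1) / (S * (S - 1))
    obs = np.zeros(mmax + 1)
    for a in occ:
        for b in occ:
            if (a == b).all():
                continue
            m = max(abs(a[0] - b[0]), abs(a[1] - b[1]))
            if m <= mmax:
                obs[m] += 1
    totals = _ring_pair_totals(nr, nc, mmax)
    with np.errstate(invalid="ignore", divide="ignore"):
        return obs[1:] / (totals[1:] * p)


class TestSquareUniformPCF:
    def test_full_lattice_is_exactly_one(self):
        st = small_random_state(0, rows=8, cols=8, density=0.0)
        st.m[:, :] = CellKind.M
        curve = ss.square_uniform_pcf(st, CellKind.M, max_ring=5)
        assert np.allclose(curve.values, 1.0)

    def test_random_placement_is_near_one(self):
        vals = []
        for seed in range(20):
            st = small_random_state(seed, rows=20, cols=20, density=0.3)
            c = ss.square_uniform_pcf(st, CellKind.M, max_ring=6)
            vals.append(c.values)
        mean = np.nanmean(vals, axis=0)
        assert np.allclose(mean, 1.0, atol=0.1)

    def test_matches_brute_force_oracle(self):
        st = small_random_state(11, rows=10, cols=12, density=0.3)
        curve = ss.square_uniform_pcf(st, CellKind.M, max_ring=6)
        oracle = brute_pcf(np.asarray(st.m), CellKind.M, 6)
        assert np.allclose(curve.values, oracle, equal_nan=True)

    def test_observed_pairs_sum_to_total(self):
        st = small_random_state(4, rows=10, cols=10, density=0.4)
        n = int((st.m == CellKind.M).sum())
        mmax = max(st.m.shape)
        curve = ss.square_uniform_pcf(st, CellKind.M, max_ring=mmax)
        assert curve.observed.sum() == n * (n - 1)

    def test_striped_pattern_oscillates_with_stripe_period(self):
        st = small_random_state(0, rows=40, cols=30, density=0.0)
        period = 10
        for r0 in range(0, 80, period):
            st.i[r0:r0 + period // 2, :] = CellKind.ID
        curve = ss.square_uniform_pcf(st, CellKind.ID, max_ring=25)
        v = curve.values
        assert v[1] > 1.0                      # short-range aggregation
        assert v[period // 2 - 1] < 1.0        # anti-phase trough
        assert v[period - 1] > 1.0             # in-phase peak at one period
        period_mm = ss.dominant_period(v, curve.distances)
        assert period_mm == pytest.approx(period * 0.01, rel=0.25)

    def test_too_few_agents_rejected(self):
        st = small_random_state(0, density=0.0)
        with pytest.raises(ValueError):
            ss.square_uniform_pcf(st, CellKind.M)

    def test_heterotypic_cross_layer(self):
        st = small_random_state(2, rows=12, cols=12, density=0.2)
        curve = ss.square_uniform_pcf(st, CellKind.M, CellKind.ID, max_ring=6)
        assert curve.pair == "M-ID"
        assert np.isfinite(curve.values).all()
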