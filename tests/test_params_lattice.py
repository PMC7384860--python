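"""Parameters, staging, lattice initialisation and domain growth."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stripesim as ss
from stripesim.lattice import CellKind


class TestSLMapping:
    def test_initial_domain_maps_to_initial_sl(self):
        p = ss.Params()
        assert p.simulated_sl(2.0) == pytest.approx(7.6)

    def test_proportional_variant(self):
        p = ss.Params(sl_mapping="proportional")
        assert p.simulated_sl(4.0) == pytest.approx(15.2)

    def test_affine_anchors_metamorphosis_duration(self):
        # end SL is reached after growth_h * metamorphosis_days of growth
        p = ss.Params()
        end_len = p.length_at_sl(p.end_sl)
        assert end_len == pytest.approx(2.0 + 0.13 * 20.0)

    def test_mapping_roundtrip(self):
        for mapping in ("affine", "proportional"):
            p = ss.Params(sl_mapping=mapping)
            for sl in (7.6, 9.0, 13.5):
                assert p.simulated_sl(p.length_at_sl(sl)) == pytest.approx(sl)


class TestStaging:
    @pytest.mark.parametrize("sl,stage", [
        (7.6, "PB"), (8.0, "PB"), (8.6, "PR"), (10.6, "SA"),
        (13.5, "Jplus"), (20.0, "Jplus")])
    def test_stage_thresholds(self, sl, stage):
        assert ss.stage_of(sl) == stage

    def test_nonpositive_sl_rejected(self):
        with pytest.raises(ValueError):
            ss.stage_of(0.0)


class TestPerturbation:
    def test_identity_bounds(self):
        p = ss.Params()
        same = ss.perturb_parameters(p, np.random.default_rng(0), lo=1, hi=1)
        assert same == p

    def test_perturbed_rates_stay_in_band(self):
        p = ss.Params()
        q = ss.perturb_parameters(p, np.random.default_rng(1))
        from stripesim.params import RATE_FIELDS
        changed = 0
        for f in RATE_FIELDS:
            base, new = getattr(p, f), getattr(q, f)
            assert 0.75 * abs(base) - 1e-12 <= abs(new) <= 1.25 * abs(base) + 1e-12
            changed += new != base
        assert changed > len(RATE_FIELDS) * 0.9
        # structural constants untouched
        assert q.pitch_m == p.pitch_m
        assert q.short_radius == p.short_radius
        assert q.init_m_density == p.init_m_density

    def test_same_rng_reproduces(self):
        p = ss.Params()
        a = ss.perturb_parameters(p, np.random.default_rng(42))
        b = ss.perturb_parameters(p, np.random.default_rng(42))
        assert a == b


class TestValidation:
    def test_radius_ordering_enforced(self):
        with pytest.raises(ValueError):
            ss.Params(short_radius=0.3)

    def test_iridophore_signal_dominates_xanthophore(self):
        with pytest.raises(ValueError):
            ss.Params(diff_m_irid=0.1, diff_m_xan=0.2)

    def test_density_bounds(self):
        with pytest.raises(ValueError):
            ss.Params(init_m_density=1.5)


class TestSiteGeometry:
    def test_coarse_site_center(self):
        assert ss.site_center_mm(0.02, (0, 0)) == pytest.approx((0.01, 0.01))

    def test_fine_site_center(self):
        assert ss.site_center_mm(0.01, (1, 1)) == pytest.approx((0.015, 0.015))

    def test_two_to_one_nesting(self):
        # coarse site (r, c) spans exactly fine sites (2r..2r+1, 2c..2c+1)
        r, c = 3, 5
        cy, cx = ss.site_center_mm(0.02, (r, c))
        for i in (2 * r, 2 * r + 1):
            for j in (2 * c, 2 * c + 1):
                fy, fx = ss.site_center_mm(0.01, (i, j))
                assert abs(fy - cy) < 0.01 and abs(fx - cx) < 0.01

    def test_out_of_bounds_rejected(self):
        with pytest.raises(IndexError):
            ss.site_center_mm(0.02, (-1, 0))


class TestInitialisation:
    def test_wild_type_initial_condition(self):
        st_ = ss.init_state(ss.Params(), ss.make_genotype("WT"), seed=5)
        rows_f = st_.i.shape[0]
        mid = rows_f // 2
        band = st_.i[mid - 1: mid + 2]
        assert (band == CellKind.ID).all()
        c = st_.counts()
        n_m_sites = st_.m.size
        assert c[CellKind.M] == pytest.approx(0.04 * n_m_sites, rel=0.25)
        assert c[CellKind.X] == 0
        assert c[CellKind.XB] == pytest.approx(0.4 * st_.x.size, rel=0.1)
        assert st_.length == pytest.approx(2.0)
        assert st_.height == pytest.approx(1.0)
        assert ss.simulated_SL(st_) == pytest.approx(7.6)
        assert ss.simulated_HAA(st_) == pytest.approx(1.0)

    def test_shd_removes_iridophores_and_halves_melanophores(self):
        st_ = ss.init_state(ss.Params(), ss.make_genotype("shd"), seed=5)
        assert (st_.i == 0).all()
        assert st_.counts()[CellKind.M] == pytest.approx(
            0.02 * st_.m.size, rel=0.3)

    def test_cho_has_no_initial_band(self):
        st_ = ss.init_state(ss.Params(), ss.make_genotype("cho"), seed=5)
        assert (st_.i == 0).all()

    def test_rse_band_is_one_fifth(self):
        wt = ss.init_state(ss.Params(), ss.make_genotype("WT"), seed=5)
        rse = ss.init_state(ss.Params(), ss.make_genotype("rse"), seed=5)
        assert rse.counts()[CellKind.ID] == pytest.approx(
            wt.counts()[CellKind.ID] / 5, rel=0.25)

    def test_unknown_genotype_rejected(self):
        with pytest.raises(KeyError):
            ss.make_genotype("definitely-not-a-fish")


class TestGrowth:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.sampled_from(["horizontal", "vertical"]),
                              st.integers(0, 10 ** 6)),
                    min_size=1, max_size=12))
    def test_growth_preserves_counts_and_alignment(self, moves):
        state = ss.init_state(ss.Params(), ss.make_genotype("WT"), seed=2)
        before = state.counts()
        r0, c0 = state.rows, state.cols
        nh = nv = 0
        for axis, idx in moves:
            n = state.rows if axis == "vertical" else state.cols
            ss.grow_domain(state, axis, index=idx % (n + 1))
            nv += axis == "vertical"
            nh += axis == "horizontal"
        assert state.rows == r0 + nv and state.cols == c0 + nh
        assert state.x.shape == state.i.shape == (2 * state.rows,
                                                  2 * state.cols)
        assert state.counts() == before

    def test_insertion_bookkeeping(self):
        state = ss.init_state(ss.Params(), ss.make_genotype("WT"), seed=2)
        cols = state.cols
        ss.grow_domain(state, "horizontal", index=0)
        assert state.cols == cols + 1
        assert state.length == pytest.approx(0.02 * (cols + 1))
        # inserted lines are empty
        assert (state.m[:, 0] == 0).all()
        assert (state.i[:, :2] == 0).all()

    def test_unknown_axis(self):
        state = ss.init_state(ss.Params(), ss.make_genotype("WT"), seed=2)
        with pytest.raises(ValueError):
            ss.grow_domain(state, "diagonal")

    def test_sl_monotone_over_trajectory(self, tiny_run):
        sls = [sl for (_s, _t, sl, _st) in tiny_run.checkpoints]
        sls.append(tiny_run.final_sl)
        assert all(b >= a for a, b in zip(sls, sls[1:]))
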