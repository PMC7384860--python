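"""Event propensities and eligibility predicates on constructed states."""
import numpy as np
import pytest

import stripesim as ss
from stripesim.lattice import CellKind

from conftest import small_random_state


def blank_state(rows=14, cols=14, genotype="WT"):
    st = small_random_state(0, rows=rows, cols=cols, density=0.0)
    st.genotype_name = genotype
    return st


class TestPropensities:
    def test_absent_population_has_zero_propensity(self):
        st = blank_state()
        a = ss.propensities(st)
        assert a["move-M"] == 0 and a["die-M"] == 0
        assert a["move-Il"] == 0 and a["proliferate-Xb"] == 0

    def test_melanophore_step_rate_matches_speed(self):
        # 0.11 mm/day over 0.02 mm sites = 5.5 attempted steps per day
        st = blank_state()
        st.m[3, 3] = CellKind.M
        st.x[0, 0] = CellKind.X   # keep the lineage-alone term out
        a = ss.propensities(st)
        assert a["move-M"] == pytest.approx(5.5)

    def test_nac_never_attempts_melanophore_birth(self):
        st = blank_state(genotype="nac")
        st.i[3, 3] = CellKind.ID
        assert ss.propensities(st)["differentiate-M"] == 0.0

    def test_growth_propensities_constant(self):
        st = blank_state()
        a = ss.propensities(st)
        assert a["grow-horizontal"] == pytest.approx(0.13 / 0.02)
        assert a["grow-vertical"] == pytest.approx(0.033 / 0.02)

    def test_event_table_has_fifteen_entries(self):
        table = ss.event_table()
        assert len(table) == 15
        assert {e["label"] for e in table} == set(ss.EVENT_LABELS)
        import json
        json.dumps(table)   # serialisable for provenance


class TestDenseToLoose:
    def test_melanophore_contact_promotes(self):
        st = blank_state()
        st.i[10, 10] = CellKind.ID
        st.m[5, 5] = CellKind.M      # coarse (5,5) is within 0.04 mm
        assert ss.dense_to_loose_eligible(st, (10, 10))

    def test_isolated_dense_cell_cannot_change_shape(self):
        # no melanophores and no xanthophores anywhere: the dense sheet in
        # a melanophore-and-xanthophore-free fish persists
        st = blank_state(genotype="nac;pfe")
        st.i[10, 10] = CellKind.ID
        assert not ss.dense_to_loose_eligible(st, (10, 10))

    @staticmethod
    def _ring_state(with_short_x=False):
        st = blank_state(rows=26, cols=26)
        st.i[25, 25] = CellKind.ID
        ring = [(23, 0), (23, 3), (23, -3), (23, 6), (23, -6), (22, 8)]
        assert all(22 < np.hypot(dy, dx) <= 24 for dy, dx in ring)
        for dy, dx in ring:
            st.x[25 + dy, 25 + dx] = CellKind.X
        if with_short_x:
            st.x[26, 26] = CellKind.X
        return st

    def test_many_long_range_xanthophores_promote(self):
        st = self._ring_state()
        assert ss.dense_to_loose_eligible(st, (25, 25))

    def test_local_xanthophores_inhibit(self):
        # identical annulus crowd, plus one xanthophore in the short range
        st = self._ring_state(with_short_x=True)
        assert not ss.dense_to_loose_eligible(st, (25, 25))


class TestLooseToDense:
    def test_reaggregates_without_any_xanthophores(self):
        # the pfe situation: no xanthophores anywhere, no melanophores close
        st = blank_state(genotype="pfe")
        st.i[10, 10] = CellKind.IL
        assert ss.loose_to_dense_eligible(st, (10, 10))

    def test_melanophore_contact_blocks(self):
        st = blank_state()
        st.i[10, 10] = CellKind.IL
        st.m[5, 5] = CellKind.M
        assert not ss.loose_to_dense_eligible(st, (10, 10))

    def test_many_local_xanthophores_promote(self):
        st = blank_state(rows=26, cols=26)
        st.i[25, 25] = CellKind.IL
        st.x[26, 26] = CellKind.X
        st.x[24, 24] = CellKind.X
        # xanthophores in the long annulus too: short-range crowd wins
        st.x[25 + 23, 25] = CellKind.X
        assert ss.loose_to_dense_eligible(st, (25, 25))


class TestXanthoblastDifferentiation:
    def test_requires_consolidated_sheet(self):
        st = blank_state()
        st.x[10, 10] = CellKind.XB
        st.i[11, 10] = CellKind.ID        # a lone pioneer is not enough
        ok, _ = ss.xanthoblast_diff_eligible(st, (10, 10))
        assert not ok

    def test_sheet_with_reachable_field_runs_fast(self):
        st = blank_state()
        st.x[10, 10] = CellKind.XB
        st.i[8:13, 8:13] = CellKind.ID
        st.x[12, 12] = CellKind.X
        ok, rate = ss.xanthoblast_diff_eligible(st, (10, 10))
        assert ok and rate == st.params.diff_xb_rate

    def test_iridophore_free_fish_gated_by_melanophores(self):
        st = blank_state(genotype="shd")
        st.x[10, 10] = CellKind.XB
        ok, rate = ss.xanthoblast_diff_eligible(st, (10, 10))
        assert ok and rate == st.params.diff_xb_auto_rate
        st.m[5, 5] = CellKind.M
        ok, rate = ss.xanthoblast_diff_eligible(st, (10, 10))
        assert not ok and rate == 0.0


class TestMelanophoreDeath:
    def test_isolated_in_xanthophore_field_dies(self):
        st = blank_state()
        st.m[5, 5] = CellKind.M
        st.x[11, 11] = CellKind.X
        assert ss.melanophore_death_eligible(st, (5, 5))

    def test_aggregate_survives_xanthophore_contact(self):
        st = blank_state()
        st.m[5, 5] = CellKind.M
        st.m[5, 6] = CellKind.M
        st.x[11, 11] = CellKind.X
        assert not ss.melanophore_death_eligible(st, (5, 5))

    def test_leo_h2_removes_survival_support(self):
        st = blank_state(genotype="leo-H2")
        st.m[5, 5] = CellKind.M
        st.m[5, 6] = CellKind.M
        st.x[11, 11] = CellKind.X
        assert ss.melanophore_death_eligible(st, (5, 5))

    def test_no_signals_no_death(self):
        # melanophore-only fish never lose melanophores
        st = blank_state(genotype="shd;pfe")
        st.m[5, 5] = CellKind.M
        assert not ss.melanophore_death_eligible(st, (5, 5))

    def test_dense_iridophore_contact_kills(self):
        st = blank_state()
        st.m[5, 5] = CellKind.M
        st.m[5, 6] = CellKind.M
        st.i[11, 11] = CellKind.ID
        assert ss.melanophore_death_eligible(st, (5, 5))


class TestMelanophoreDifferentiation:
    def test_dense_sheet_vetoes(self):
        st = blank_state()
        st.i[8:13, 8:13] = CellKind.ID
        assert ss.melanophore_diff_weight(st, (5, 5)) == 0.0

    def test_leo_h4_lifts_the_veto(self):
        st = blank_state(genotype="leo-H4")
        st.i[8:13, 8:13] = CellKind.ID
        assert ss.melanophore_diff_weight(st, (5, 5)) > 0.0

    def test_lineage_alone_differentiates_freely(self):
        st = blank_state(genotype="shd;pfe")
        assert ss.melanophore_diff_weight(st, (5, 5)) == 1.0

    def test_long_range_iridophores_give_largest_weight(self):
        p = ss.Params()
        st_i = blank_state(rows=16, cols=16)
        st_i.i[8 + 23, 16] = CellKind.ID     # in the annulus, not the disk
        w_irid = ss.melanophore_diff_weight(st_i, (4, 8))
        st_x = blank_state(rows=16, cols=16)
        st_x.x[8 + 23, 16] = CellKind.X
        w_xan = ss.melanophore_diff_weight(st_x, (4, 8))
        assert w_irid > w_xan > 0
        assert w_irid == pytest.approx(
            (p.diff_m_base + p.diff_m_irid)
            / (p.diff_m_base + p.diff_m_irid + p.diff_m_xan + p.diff_m_loose))
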