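"""The fifteen continuous-time events and their eligibility predicates.

The simulator advances by attempting one of fifteen event classes:

========================  =======================================================
event                     base rate (per day)
========================  =======================================================
move-M                    speed_m / coarse pitch, per melanophore
move-X                    speed_x / fine pitch, per xanthophore
move-Id / move-Il         speed_i / fine pitch, per S-iridophore
proliferate-Xb/X/Id/Il    prolif_* per agent
differentiate-M           diff_m_per_id*N_Id + diff_m_per_x*N_X (domain total),
                          plus diff_m_solo per empty site when the melanophore
                          lineage is alone on the domain
differentiate-Xb          diff_xb_rate per xanthoblast (thinned by context)
die-M                     death_m_rate per melanophore
transition-Id->Il         trans_d2l_rate per dense S-iridophore
transition-Il->Id         trans_l2d_rate per loose S-iridophore
grow-horizontal           growth_h / coarse pitch (one column inserted)
grow-vertical             growth_v / coarse pitch (one row inserted)
========================  =======================================================

An attempt only changes the state when its eligibility predicate holds on
the pre-attempt state (null-event semantics).  The predicates below are the
reference implementations used by the tests and documentation; the
event kernel applies the same rules in compiled form.
"""
from __future__ import annotations

from typing import Optional

from .lattice import CellKind, DomainState
from .neighbourhoods import count_in_annulus, count_in_disk, site_center
from .params import Params
from ._kernel import EVENT_LABELS

__all__ = [
    "EVENT_LABELS", "event_table", "propensities",
    "dense_to_loose_eligible", "loose_to_dense_eligible",
    "xanthoblast_diff_eligible", "melanophore_death_eligible",
    "melanophore_diff_weight",
]


def propensities(state: DomainState, params: Optional[Params] = None,
                 genotype=None) -> dict:
    """Current propensity of each of the fifteen events (per day)."""
    from .genotypes import make_genotype
    params = params or state.params
    geno = make_genotype(genotype if genotype is not None
                         else state.genotype_name)
    params = geno.apply_params(params)
    c = state.counts()
    nM, nX, nXb = c[CellKind.M], c[CellKind.X], c[CellKind.XB]
    nId, nIl = c[CellKind.ID], c[CellKind.IL]
    solo = (nX + nXb + nId + nIl) == 0
    diff_m = params.diff_m_per_id * nId + params.diff_m_per_x * nX
    if solo:
        diff_m += params.diff_m_solo * (state.rows * state.cols - nM)
    if not geno.has("melanophore"):
        diff_m = 0.0
    a = {
        "move-M": nM * params.speed_m / params.pitch_m,
        "move-X": nX * params.speed_x / params.pitch_f,
        "move-Id": nId * params.speed_i / params.pitch_f,
        "move-Il": nIl * params.speed_i / params.pitch_f,
        "proliferate-Xb": nXb * params.prolif_xb,
        "proliferate-X": nX * params.prolif_x,
        "proliferate-Id": nId * params.prolif_id,
        "proliferate-Il": nIl * params.prolif_il,
        "differentiate-M": diff_m,
        "differentiate-Xb": nXb * max(params.diff_xb_rate,
                                      params.diff_xb_auto_rate),
        "die-M": nM * params.death_m_rate,
        "transition-Id-Il": nId * params.trans_d2l_rate,
        "transition-Il-Id": nIl * params.trans_l2d_rate,
        "grow-horizontal": params.growth_h / params.pitch_m,
        "grow-vertical": params.growth_v / params.pitch_m,
    }
    assert set(a) == set(EVENT_LABELS)
    return a


def event_table(params: Optional[Params] = None) -> list:
    """JSON-serialisable description of the event inventory (provenance)."""
    p = params or Params()
    return [
        {"label": "move-M", "rate": p.speed_m / p.pitch_m, "per": "melanophore"},
        {"label": "move-X", "rate": p.speed_x / p.pitch_f, "per": "xanthophore"},
        {"label": "move-Id", "rate": p.speed_i / p.pitch_f, "per": "dense S-iridophore"},
        {"label": "move-Il", "rate": p.speed_i / p.pitch_f, "per": "loose S-iridophore"},
        {"label": "proliferate-Xb", "rate": p.prolif_xb, "per": "xanthoblast"},
        {"label": "proliferate-X", "rate": p.prolif_x, "per": "xanthophore"},
        {"label": "proliferate-Id", "rate": p.prolif_id, "per": "dense S-iridophore"},
        {"label": "proliferate-Il", "rate": p.prolif_il, "per": "loose S-iridophore"},
        {"label": "differentiate-M",
         "rate": [p.diff_m_per_id, p.diff_m_per_x, p.diff_m_solo],
         "per": "domain totals (N_Id, N_X; solo per empty site)"},
        {"label": "differentiate-Xb",
         "rate": [p.diff_xb_rate, p.diff_xb_solo_rate, p.diff_xb_auto_rate],
         "per": "xanthoblast (sheet / seed / autonomous paths)"},
        {"label": "die-M", "rate": p.death_m_rate, "per": "melanophore"},
        {"label": "transition-Id-Il", "rate": p.trans_d2l_rate,
         "per": "dense S-iridophore"},
        {"label": "transition-Il-Id", "rate": p.trans_l2d_rate,
         "per": "loose S-iridophore"},
        {"label": "grow-horizontal", "rate": p.growth_h / p.pitch_m,
         "per": "domain"},
        {"label": "grow-vertical", "rate": p.growth_v / p.pitch_m,
         "per": "domain"},
    ]


def _counts_around(state: DomainState, center):
    p = state.params
    return {
        "m_short": count_in_disk(state, "M", center, p.short_radius,
                                 {CellKind.M}),
        "x_short": count_in_disk(state, "X", center, p.short_radius,
                                 {CellKind.X}),
        "id_short": count_in_disk(state, "I", center, p.short_radius,
                                  {CellKind.ID}),
        "il_short": count_in_disk(state, "I", center, p.short_radius,
                                  {CellKind.IL}),
        "x_long": count_in_annulus(state, "X", center, p.long_inner,
                                   p.long_outer, {CellKind.X}),
        "id_long": count_in_annulus(state, "I", center, p.long_inner,
                                    p.long_outer, {CellKind.ID}),
    }


def dense_to_loose_eligible(state: DomainState, site, genotype=None) -> bool:
    """A dense S-iridophore may become loose if there are melanophores in
    the short range, OR there are no xanthophores in the short range AND
    many (>= theta_XL) xanthophores in the long range."""
    from .genotypes import make_genotype
    geno = make_genotype(genotype if genotype is not None
                         else state.genotype_name)
    if state.i[site] != CellKind.ID:
        raise ValueError("site does not hold a dense S-iridophore")
    c = _counts_around(state, site_center(state.params.pitch_f, site))
    if c["m_short"] >= 1:
        return True
    if "d2l_no_xlong" in geno.toggles:
        return False
    gate = True if "d2l_no_xshort" in geno.toggles else c["x_short"] == 0
    return gate and c["x_long"] >= state.params.theta_xl


def loose_to_dense_eligible(state: DomainState, site, genotype=None) -> bool:
    """A loose S-iridophore may become dense if there are no melanophores
    in the short range AND (many xanthophores in the short range OR no
    xanthophores in the long range)."""
    from .genotypes import make_genotype
    geno = make_genotype(genotype if genotype is not None
                         else state.genotype_name)
    if state.i[site] != CellKind.IL:
        raise ValueError("site does not hold a loose S-iridophore")
    c = _counts_around(state, site_center(state.params.pitch_f, site))
    if "l2d_no_mshort" not in geno.toggles and c["m_short"] >= 1:
        return False
    if ("l2d_no_xshort" not in geno.toggles
            and c["x_short"] >= state.params.theta_xs):
        return True
    return c["x_long"] == 0


def xanthoblast_diff_eligible(state: DomainState, site) -> tuple:
    """Differentiation context of a xanthoblast: (eligible, rate per day).

    Over a consolidated dense S-iridophore sheet (>= theta_xb_id dense
    cells in the short disk) differentiation runs at the full rate when the
    existing xanthophore field is in reach (short disk or long annulus) and
    at the rare seeding rate otherwise.  With no S-iridophores anywhere on
    the domain the autonomous programme applies wherever no melanophores
    are in the short range."""
    p = state.params
    if state.x[site] != CellKind.XB:
        raise ValueError("site does not hold a xanthoblast")
    c = _counts_around(state, site_center(p.pitch_f, site))
    n_irid = int((state.i == CellKind.ID).sum() + (state.i == CellKind.IL).sum())
    if n_irid == 0:
        ok = c["m_short"] == 0
        return ok, (p.diff_xb_auto_rate if ok else 0.0)
    if c["id_short"] >= p.theta_xb_id:
        if c["x_short"] >= 1 or c["x_long"] >= 1:
            return True, p.diff_xb_rate
        return True, p.diff_xb_solo_rate
    return False, 0.0


def melanophore_death_eligible(state: DomainState, site, genotype=None) -> bool:
    """A melanophore dies if dense S-iridophores are in its short range, or
    if xanthophores are in the short range while no fellow melanophores are
    (isolated cells in xanthophore-rich territory); under leo-H2 the
    long-range xanthophore survival support is lost and xanthophore contact
    is lethal regardless of melanophore neighbours."""
    from .genotypes import make_genotype
    geno = make_genotype(genotype if genotype is not None
                         else state.genotype_name)
    if state.m[site] != CellKind.M:
        raise ValueError("site does not hold a melanophore")
    c = _counts_around(state, site_center(state.params.pitch_m, site))
    if c["id_short"] >= 1:
        return True
    if c["x_short"] >= 1:
        if "h2" in geno.toggles:
            return True
        return c["m_short"] == 0
    return False


def melanophore_diff_weight(state: DomainState, site, genotype=None) -> float:
    """Success probability of a melanophore-differentiation attempt at an
    empty M-layer site: 0 when vetoed by local dense S-iridophores (unless
    leo-H4), otherwise the signal weight over the weight cap."""
    from .genotypes import make_genotype
    p = state.params
    geno = make_genotype(genotype if genotype is not None
                         else state.genotype_name)
    if state.m[site] != 0:
        raise ValueError("site is occupied")
    c = _counts_around(state, site_center(p.pitch_m, site))
    b = {"diff_m_base": p.diff_m_base, "diff_m_irid": p.diff_m_irid,
         "diff_m_xan": p.diff_m_xan, "diff_m_loose": p.diff_m_loose}
    for z in geno.zero_weights:
        if z in b:
            b[z] = 0.0
    cap = sum(b.values())
    n_other = int((state.x != 0).sum() + (state.i != 0).sum())
    if n_other == 0:
        return 1.0
    if "h4" not in geno.toggles and c["id_short"] >= 1:
        return 0.0
    w = b["diff_m_base"]
    if c["id_long"] >= 1:
        w += b["diff_m_irid"]
    if c["x_long"] >= 1:
        w += b["diff_m_xan"]
    if c["il_short"] >= 1 and c["x_short"] == 0:
        w += b["diff_m_loose"]
    return w / cap
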