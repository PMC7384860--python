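"""Quantification of simulated patterns.

Implements the summary statistics used to compare simulated fish with real
ones: the central-interstripe centerline and its straightness SS = C/L, the
X0 interstripe width, pseudo-stripe counts and the longest unbroken
melanophore stretch, per-region cell counts and the interstripe-X to
stripe-M density ratio, melanophore-count normalisation against wild type,
and the Square Uniform pair correlation function (an on-lattice PCF over
Chebyshev distance rings, equal to 1 in expectation under complete spatial
randomness).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .lattice import CellKind, DomainState

__all__ = [
    "Polyline", "PCFCurve", "interstripe_centerline", "stripe_straightness",
    "x0_width", "longest_melanophore_stretch", "count_pseudo_stripes",
    "melanophore_row_profile", "region_masks", "cell_counts_and_ratio",
    "normalize_melanocyte_counts", "square_uniform_pcf", "first_trough",
    "dominant_period", "pattern_features", "classify_pattern",
    "metrics_report",
]


@dataclass
class Polyline:
    """Ordered (x, y) points in mm, one per sampled column."""
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) < 2:
            raise ValueError("polyline needs at least two points")
        if not np.all(np.diff(self.x) > 0):
            raise ValueError("polyline x must be strictly increasing")


@dataclass
class PCFCurve:
    """Square Uniform PCF sampled on Chebyshev rings m = 1..m*."""
    pair: str
    rings: np.ndarray        # ring index (lattice units)
    distances: np.ndarray    # ring distance in mm
    values: np.ndarray
    observed: np.ndarray     # ordered pair counts per ring


# ---------------------------------------------------------------------------
# centerline, straightness, width
# ---------------------------------------------------------------------------

def _central_component(state: DomainState, kind: int) -> np.ndarray:
    """Connected component of ``kind`` on its fine layer closest to
    mid-height among components spanning a substantial part of the length;
    falls back to the largest component."""
    layer = "I" if kind in (CellKind.ID, CellKind.IL) else "X"
    mask = state.layer(layer) == kind
    if not mask.any():
        raise ValueError("no interstripe cells present")
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    mid = mask.shape[0] / 2.0
    best, best_d = None, np.inf
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    spans = ndimage.find_objects(lab)
    min_span = 0.3 * mask.shape[1]
    for k in range(n):
        sl = spans[k]
        if (sl[1].stop - sl[1].start) < min_span:
            continue
        rows = np.nonzero(lab == k + 1)[0]
        d = abs(rows.mean() - mid)
        if d < best_d:
            best, best_d = k + 1, d
    if best is None:
        best = int(np.argmax(sizes)) + 1
    return lab == best


def interstripe_centerline(state: DomainState,
                           kind: Optional[int] = None) -> Polyline:
    """Line representation of the central (X0) interstripe.

    For each coarse column, the mean height of the connected dense
    S-iridophore component nearest mid-height (xanthophores are used for
    genotypes without iridophores); columns the component misses are linearly
    interpolated.
    """
    if kind is None:
        kind = CellKind.ID if (state.i == CellKind.ID).any() else CellKind.X
    comp = _central_component(state, kind)
    pf, pm = state.params.pitch_f, state.params.pitch_m
    cols = state.cols
    xs = (np.arange(cols) + 0.5) * pm
    ys = np.full(cols, np.nan)
    rows_idx, cols_idx = np.nonzero(comp)
    coarse_c = cols_idx // 2
    for c in range(cols):
        sel = coarse_c == c
        if sel.any():
            ys[c] = (rows_idx[sel].mean() + 0.5) * pf
    good = ~np.isnan(ys)
    if good.sum() < 2:
        raise ValueError("interstripe component spans fewer than two columns")
    ys = np.interp(xs, xs[good], ys[good])
    return Polyline(xs, ys)


def stripe_straightness(line: Polyline) -> float:
    """SS = C / L: end-to-end distance over arc length; 1 for a straight
    stripe, smaller for tortuous ones."""
    dx = np.diff(line.x)
    dy = np.diff(line.y)
    L = float(np.hypot(dx, dy).sum())
    if L == 0:
        raise ValueError("zero-length centerline")
    C = float(math.hypot(line.x[-1] - line.x[0], line.y[-1] - line.y[0]))
    return C / L


def x0_width(state: DomainState, kind: Optional[int] = None) -> float:
    """Mean vertical extent (mm) of the X0 interstripe component, averaged
    over the columns it spans."""
    if kind is None:
        kind = CellKind.ID if (state.i == CellKind.ID).any() else CellKind.X
    comp = _central_component(state, kind)
    pf = state.params.pitch_f
    widths = []
    rows_idx, cols_idx = np.nonzero(comp)
    for c in np.unique(cols_idx):
        r = rows_idx[cols_idx == c]
        widths.append((r.max() - r.min() + 1) * pf)
    return float(np.mean(widths))


# ---------------------------------------------------------------------------
# pseudo-stripes
# ---------------------------------------------------------------------------

def melanophore_row_profile(state: DomainState, window: float = 0.1) -> np.ndarray:
    """Melanophore count per coarse row, smoothed with a moving average of
    physical width ``window`` mm."""
    prof = (state.m == CellKind.M).sum(axis=1).astype(float)
    w = max(1, int(round(window / state.params.pitch_m)))
    if w > 1:
        kern = np.ones(w) / w
        prof = np.convolve(prof, kern, mode="same")
    return prof


def _pseudo_stripe_bands(state: DomainState, peak_frac: float = 0.3,
                         window: float = 0.1):
    """Row intervals of detected pseudo-stripes.

    Peaks of the smoothed row profile exceeding ``peak_frac`` of its global
    maximum count as distinct pseudo-stripes when separated by troughs below
    half that threshold; each band extends while the profile stays above the
    trough level.
    """
    prof = melanophore_row_profile(state, window)
    gmax = prof.max()
    if gmax <= 0:
        return [], prof
    th = peak_frac * gmax
    tr = 0.5 * th
    bands = []
    above = prof >= tr
    start = None
    for r in range(len(prof) + 1):
        if r < len(prof) and above[r]:
            if start is None:
                start = r
        else:
            if start is not None:
                seg = prof[start:r]
                if seg.max() >= th:
                    # split at interior troughs below tr-level (cannot occur
                    # inside a contiguous above-tr run) -> one band per run
                    bands.append((start, r))
                start = None
    return bands, prof


def count_pseudo_stripes(state: DomainState, peak_frac: float = 0.3,
                         window: float = 0.1) -> int:
    """Number of pseudo-stripes: maxima of the smoothed melanophore row
    profile above ``peak_frac`` of the global maximum, separated by troughs
    below half that level."""
    bands, _ = _pseudo_stripe_bands(state, peak_frac, window)
    return len(bands)


def longest_melanophore_stretch(state: DomainState, gap_tol: float = 0.1,
                                peak_frac: float = 0.3,
                                window: float = 0.1) -> float:
    """Longest stretch of melanophores in a row without significant breaks.

    For every lattice row inside a detected pseudo-stripe band, the longest
    run of occupied columns tolerating gaps up to ``gap_tol`` mm; the
    maximum over rows, as a fraction of the domain length — the widest
    'spot' or pseudo-stripe width."""
    bands, _ = _pseudo_stripe_bands(state, peak_frac, window)
    if not bands:
        return 0.0
    m = state.m == CellKind.M
    tol = max(0, int(round(gap_tol / state.params.pitch_m)))
    best = 0
    for r0, r1 in bands:
        for r in range(r0, r1):
            occ = m[r]
            run_start = None
            last_occ = None
            for c in range(len(occ) + 1):
                if c < len(occ) and occ[c]:
                    if run_start is None:
                        run_start = c
                    last_occ = c
                elif run_start is not None:
                    gap = c - last_occ
                    if c == len(occ) or gap > tol:
                        best = max(best, last_occ - run_start + 1)
                        run_start = None
    return best / state.cols


# ---------------------------------------------------------------------------
# regions, counts, ratios
# ---------------------------------------------------------------------------

def region_masks(state: DomainState):
    """Interstripe/stripe row classification from S-iridophore occupancy.

    A fine row is interstripe when dense S-iridophores are at least as
    numerous there as loose ones (and present at all); ties break toward
    interstripe.  Returns (fine_interstripe_rows, coarse_interstripe_rows).
    """
    idc = (state.i == CellKind.ID).sum(axis=1)
    ilc = (state.i == CellKind.IL).sum(axis=1)
    fine_inter = (idc > 0) & (idc >= ilc)
    coarse_inter = fine_inter[0::2] | fine_inter[1::2]
    return fine_inter, coarse_inter


def cell_counts_and_ratio(state: DomainState) -> dict:
    """Per-region cell counts and the interstripe-X : stripe-M ratio."""
    fine_inter, coarse_inter = region_masks(state)
    if not fine_inter.any() or fine_inter.all():
        raise ValueError("cannot identify both stripe and interstripe regions")
    x = state.x == CellKind.X
    m = state.m == CellKind.M
    out = {
        "x_interstripe": int(x[fine_inter].sum()),
        "x_stripe": int(x[~fine_inter].sum()),
        "m_interstripe": int(m[coarse_inter].sum()),
        "m_stripe": int(m[~coarse_inter].sum()),
        "id_total": int((state.i == CellKind.ID).sum()),
        "il_total": int((state.i == CellKind.IL).sum()),
    }
    if out["m_stripe"] == 0:
        raise ValueError("no melanophores in stripe regions")
    out["x_to_m_ratio"] = out["x_interstripe"] / out["m_stripe"]
    return out


def normalize_melanocyte_counts(sim_mut: float, sim_wt: float,
                                real_wt: float) -> float:
    """Scale a simulated mutant melanophore count to real-fish units:
    sim_mut * real_wt / sim_wt."""
    if sim_wt == 0:
        raise ZeroDivisionError("wild-type simulation has no melanophores")
    return sim_mut * real_wt / sim_wt


# ---------------------------------------------------------------------------
# Square Uniform pair correlation function
# ---------------------------------------------------------------------------

def _ring_pair_totals(nr: int, nc: int, mmax: int) -> np.ndarray:
    """Ordered site-pair counts at each Chebyshev ring of an nr x nc lattice."""
    totals = np.zeros(mmax + 1)
    for m in range(1, mmax + 1):
        tot = 0
        for dr in range(-m, m + 1):
            for dc in range(-m, m + 1):
                if max(abs(dr), abs(dc)) == m:
                    tot += max(nr - abs(dr), 0) * max(nc - abs(dc), 0)
        totals[m] = tot
    return totals


def _ring_observed(A: np.ndarray, B: np.ndarray, mmax: int) -> np.ndarray:
    corr = signal.fftconvolve(A, B[::-1, ::-1])
    corr = np.rint(corr)
    r0, c0 = A.shape[0] - 1, A.shape[1] - 1
    obs = np.zeros(mmax + 1)
    for m in range(1, mmax + 1):
        tot = 0.0
        for dr in range(-m, m + 1):
            for dc in range(-m, m + 1):
                if max(abs(dr), abs(dc)) != m:
                    continue
                rr, cc = r0 + dr, c0 + dc
                if 0 <= rr < corr.shape[0] and 0 <= cc < corr.shape[1]:
                    tot += corr[rr, cc]
        obs[m] = tot
    return obs


def square_uniform_pcf(state: DomainState, kind_a: int,
                       kind_b: Optional[int] = None,
                       max_ring: int = 30) -> PCFCurve:
    """Square Uniform PCF over Chebyshev rings on the lattice.

    PCF(m) is the observed number of A-B pairs at ring m divided by the
    number expected were the same numbers of agents placed uniformly at
    random; 1 indicates no correlation at that distance.  Homotypic when
    ``kind_b`` is None/equal; heterotypic pairs across layers of different
    pitch are computed on the fine lattice with coarse agents mapped to the
    first site of their 2x2 fine footprint.
    """
    kind_a = CellKind(kind_a)
    homo = kind_b is None or CellKind(kind_b) == kind_a
    kind_b = kind_a if homo else CellKind(kind_b)
    from .lattice import LAYER_OF_KIND
    la, lb = LAYER_OF_KIND[kind_a], LAYER_OF_KIND[kind_b]

    def _indicator(kind, layer, fine):
        g = state.layer(layer) == kind
        if layer == "M" and fine:
            out = np.zeros((2 * state.rows, 2 * state.cols), dtype=float)
            out[::2, ::2] = g
            return out
        return g.astype(float)

    use_fine = not (la == "M" and lb == "M")
    pitch = state.params.pitch_f if use_fine else state.params.pitch_m
    A = _indicator(kind_a, la, use_fine)
    B = A if homo else _indicator(kind_b, lb, use_fine)
    nA, nB = A.sum(), B.sum()
    if (homo and nA < 2) or (not homo and (nA < 1 or nB < 1)):
        raise ValueError("too few agents for a pair correlation")
    S = A.size
    p = nA * (nA - 1) / (S * (S - 1)) if homo else nA * nB / (S * S)
    totals = _ring_pair_totals(A.shape[0], A.shape[1], max_ring)
    obs = _ring_observed(A, B, max_ring)
    expected = totals * p
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(expected > 0, obs / expected, np.nan)
    rings = np.arange(1, max_ring + 1)
    label = f"{kind_a.name}" if homo else f"{kind_a.name}-{kind_b.name}"
    return PCFCurve(label, rings, rings * pitch, vals[1:], obs[1:])


def first_trough(values: np.ndarray, distances: np.ndarray,
                 smooth: int = 3) -> float:
    """Distance (mm) of the first local minimum of a PCF curve."""
    v = np.asarray(values, dtype=float)
    if smooth > 1:
        kern = np.ones(smooth) / smooth
        v = np.convolve(v, kern, mode="same")
    for m in range(1, len(v) - 1):
        if v[m] < v[m - 1] and v[m] <= v[m + 1]:
            return float(distances[m])
    return float(distances[np.nanargmin(v)])


def dominant_period(values: np.ndarray, distances: np.ndarray) -> float:
    """Dominant oscillation period (mm) of a PCF curve via the discrete
    Fourier transform of its deviation from 1."""
    v = np.asarray(values, dtype=float) - np.nanmean(values)
    v = np.nan_to_num(v)
    n = len(v)
    amp = np.abs(np.fft.rfft(v, n=4 * n))
    amp[0] = 0.0
    k = int(np.argmax(amp))
    if k == 0:
        return float("nan")
    step = distances[1] - distances[0]
    return float(4 * n * step / k)


# ---------------------------------------------------------------------------
# qualitative classification
# ---------------------------------------------------------------------------

def pattern_features(state: DomainState) -> dict:
    """Quantitative features used for qualitative pattern classification."""
    fine_inter, _ = region_masks(state) if (state.i != 0).any() \
        else (np.zeros(2 * state.rows, dtype=bool), None)
    # contiguous interstripe row-bands at least 0.04 mm tall
    min_rows = max(1, int(round(0.04 / state.params.pitch_f)))
    bands = 0
    run = 0
    for v in np.append(fine_inter, False):
        if v:
            run += 1
        else:
            if run >= min_rows:
                bands += 1
            run = 0
    m = state.m == CellKind.M
    x = state.x == CellKind.X
    idm = state.i == CellKind.ID
    ilm = state.i == CellKind.IL
    feats = {
        "n_interstripe_bands": bands,
        "n_pseudo_stripes": count_pseudo_stripes(state),
        "stretch": longest_melanophore_stretch(state),
        "m_fill": m.mean(),
        "x_fill": x.mean(),
        "xb_fill": (state.x == CellKind.XB).mean(),
        "id_fill": idm.mean(),
        "il_fill": ilm.mean(),
        "n_m": int(m.sum()),
        "n_x": int(x.sum()),
        "n_id": int(idm.sum()),
        "n_il": int(ilm.sum()),
    }
    if fine_inter.any() and not fine_inter.all():
        feats["il_in_stripe_frac"] = (
            ilm[~fine_inter].sum() / max(1, ilm.sum()))
        feats["id_in_interstripe_frac"] = (
            idm[fine_inter].sum() / max(1, idm.sum()))
    return feats


def classify_pattern(state: DomainState) -> str:
    """Coarse phenotype label: 'striped', 'spotted', 'dense_sheet',
    'uniform_<kind>' or 'unpatterned'."""
    f = pattern_features(state)
    kinds_present = {k: n for k, n in
                     (("M", f["n_m"]), ("X", f["n_x"]), ("Id", f["n_id"]),
                      ("Il", f["n_il"])) if n > 0}
    if len(kinds_present) == 1:
        k = next(iter(kinds_present))
        fill = {"M": f["m_fill"], "X": f["x_fill"], "Id": f["id_fill"],
                "Il": f["il_fill"]}[k]
        if fill >= 0.9:
            return f"uniform_{k}"
    if f["id_fill"] > 0.6 and f["il_fill"] < 0.05:
        return "dense_sheet"
    if f["n_interstripe_bands"] >= 2 and f["n_pseudo_stripes"] >= 2:
        return "striped" if f["stretch"] >= 0.7 else "broken_stripes"
    if f["n_pseudo_stripes"] >= 1 and f["n_m"] > 0 and f["stretch"] < 0.7:
        return "spotted"
    if f["n_pseudo_stripes"] >= 2:
        return "striped"
    return "unpatterned"


def interstripe_orientation_anisotropy(state: DomainState) -> float:
    """1 for perfectly horizontal interstripes, ~0.5 for labyrinths: share
    of dense S-iridophore projection variance carried by the row axis."""
    idm = (state.i == CellKind.ID).astype(float)
    if idm.sum() == 0:
        return float("nan")
    rv = idm.mean(axis=1).var()
    cv = idm.mean(axis=0).var()
    if rv + cv == 0:
        return 0.5
    return float(rv / (rv + cv))


def metrics_report(state: DomainState) -> dict:
    """One-stop JSON-friendly report used by the CLI."""
    rep = dict(pattern_features(state))
    rep["classification"] = classify_pattern(state)
    try:
        line = interstripe_centerline(state)
        rep["stripe_straightness"] = stripe_straightness(line)
        rep["x0_width_mm"] = x0_width(state)
    except ValueError:
        rep["stripe_straightness"] = None
        rep["x0_width_mm"] = None
    try:
        rep.update({k: v for k, v in cell_counts_and_ratio(state).items()})
    except ValueError:
        pass
    rep = {k: (float(v) if isinstance(v, (np.floating,)) else v)
           for k, v in rep.items()}
    return rep
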