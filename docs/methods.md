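# Model and methods

## The system being modelled

Between stages PB (~7.6 mm standard length, ~25 days post-fertilisation)
and J+ (13.5 mm SL), the trunk skin of a zebrafish assembles its adult
stripes. The model represents a 2 mm x 1 mm patch of that skin as three
stacked two-dimensional lattices — a melanophore layer at 0.02 mm site
pitch and xanthophore and S-iridophore layers at 0.01 mm pitch (matching
the tighter packing of those cells; each coarse site nests a 2x2 block of
fine sites so cross-layer queries are well defined). Every site holds at
most one agent. Five agent kinds are modelled: melanophores (M),
xanthophores (X), xanthoblasts (Xb), and dense/loose S-iridophores
(Id/Il). L-iridophores, which appear after the pattern is established, are
outside the modelled window, as is post-J+ pattern maintenance.

Cells interact at two ranges, both measured between site centres: a short
disk of radius 0.04 mm (contact-scale), and a long annulus of 0.22–0.24 mm
(the reach of extended projections; about half a stripe period). Ranges
are open at the inner and closed at the outer bound so disk + annulus
partitions exactly. Neighbourhoods are clipped at the domain boundary — the
flank is not periodic.

## Dynamics

The state evolves by an exact Gillespie loop over fifteen continuous-time
event classes (movement of M, X, Id, Il; proliferation of Xb, X, Id, Il;
differentiation of M and of Xb; death of M; the two shape transitions; and
horizontal/vertical domain growth). Propensities are linear in the current
population counts, so they are recomputed in O(1) per event; eligibility
predicates are evaluated inside the attempt, and an ineligible attempt
changes nothing but still consumes its waiting time (null-event
semantics). Fixed events — the initial dense band along the horizontal
myoseptum, the first adult xanthophores at the myoseptum at stage PR, and
genotype-specific items such as the stage-PR seeding of 200 loose
S-iridophores in *cho* — fire exactly once when their stage threshold is
reached. Domain growth inserts an empty coarse row or column (plus the two
aligned fine lines) at a uniformly random position, so expansion is
centred on average; growth and movement never change cell counts.

Movement draws one of the eight compass directions with probability
proportional to exp(beta * B . u_d), where the bias B sums signed unit
vectors to influencing neighbours: X are attracted to M and M repelled by
X in the short range, Id attracted to X, Il repelled by Il, and M pulled
toward Xb at long range. A move into an occupied or out-of-domain site is
a null event; for the loose-iridophore repulsion, out-of-domain sites
count as occupied by loose cells so the wall repels rather than collects
them.

The shape-transition predicates encode the inferred S-iridophore logic:
dense -> loose requires melanophores in the short range OR (no xanthophores
in the short range AND at least theta_XL = 5 xanthophores in the long
annulus); loose -> dense requires no melanophores in the short range AND
(at least theta_XS = 2 xanthophores in the short range OR none in the long
annulus). Without melanophores and xanthophores both transitions are
impossible, so a melanophore-and-xanthophore-free fish keeps a dense sheet.

Melanophore death is attempted once per melanophore per day and succeeds
when dense S-iridophores are in the short range, or when xanthophores are
in the short range while no fellow melanophore is (isolated cells in
xanthophore territory die; aggregates are sustained, which we attribute to
long-range xanthophore survival support — the support that the *leo*
hypothesis H2 removes).

Melanophore differentiation is modelled as a domain-total attempt rate,
k_I*N_Id + k_X*N_X per day (differentiation depends on how many dense
S-iridophores and xanthophores the domain carries), with placement decided
locally: an attempt picks an empty coarse site uniformly, is vetoed by
dense S-iridophores in the short range (lifted by *leo* H4), and succeeds
with probability w/(w_0+w_I+w_X+w_loc) where w sums w_I (dense
S-iridophores in the long annulus), w_X (xanthophores in the long
annulus), w_loc (loose S-iridophores in the short range with no local
xanthophores) and the baseline w_0. The weights keep the inferred ordering
"S-iridophores matter far more than xanthophores" (w_I : w_loc : w_X : w_0
= 10 : 3 : 0.3 : 0.05). When no other pigment cell exists on the domain,
the default melanogenic programme is derepressed: an additional
spontaneous term (0.15 per empty site per day) lets the melanophore-only
double mutant fill its layer, without affecting any genotype in which a
competing lineage is present.

Xanthophore differentiation is iridophore-led: over a consolidated dense
sheet (>= 8 dense cells in the short disk) xanthoblasts differentiate at
0.5/day when the existing xanthophore field is within reach (short disk or
long annulus — which is how successive interstripes, spaced one annulus
away, are colonised) and at a rare seeding rate (0.001/day) otherwise.
In iridophore-free fish an autonomous programme (0.016/day, gated on the
absence of nearby melanophores) builds the xanthophore field instead; this
mirrors the fact that real iridophore-free mutants still produce their
xanthophores. Xanthoblasts next to melanophores stay undifferentiated and
persist in stripe regions.

## Staging and growth

Simulated SL maps affinely from domain length, anchored so SL runs 7.6 ->
13.5 mm over 20 days of horizontal growth at 0.13 mm/day, which reproduces
the observed mean SL growth of ~0.295 mm/day; a proportional map is
available as an option. Stage thresholds (mm SL): PB 7.6, PR 8.6, SP 9.8,
SA 10.6, J 11.5, J+ 13.5. dpf = 25 + t.

## Parameters

All rates are per day, lengths in mm; defaults live on `Params`.

| parameter | default | meaning |
|---|---|---|
| speed_m / speed_x / speed_i | 0.11 / 0.033 / 0.1 | movement speeds (steps = speed/pitch) |
| prolif_xb, prolif_x | 0.5 | xanthophore-lineage division rates |
| prolif_id, prolif_il | 1.8 | S-iridophore division rates (1–2/day observed) |
| diff_xb_rate / _solo / _auto | 0.5 / 0.001 / 0.016 | xanthoblast differentiation paths |
| diff_m_per_id, diff_m_per_x | 0.12, 0.5 | melanophore attempt budget per signalling cell |
| diff_m_solo | 0.15 | spontaneous rate, lineage alone |
| w_I : w_loc : w_X : w_0 | 10 : 3 : 0.3 : 0.05 | placement weights |
| death_m_rate | 1.0 | melanophore death attempts |
| trans_d2l_rate, trans_l2d_rate | 1.0, 1.0 | shape-transition attempts |
| theta_XL, theta_XS, theta_xb_id | 5, 2, 8 | count thresholds |
| growth_h, growth_v | 0.13, 0.033 | domain growth |
| beta; bias strengths | 3; ±1–2.5 | movement bias sharpness and signs |

Rates quoted directly from experimental work (speeds, death attempts,
growth, S-iridophore proliferation, initial densities, radii, pitches) are
fixed; the remainder are calibration defaults tuned so that the wild type
and the missing-cell mutants jointly reproduce their published summary
statistics, and they are the surface the robustness sweep perturbs
(`perturb_parameters`: every rate independently scaled by U(0.75, 1.25);
structural constants untouched).

Genotypes modify this machinery declaratively (`data/genotypes.json`):
lineage removals (initial absence + no birth), parameter overrides and
rescalings (*sbr*: dense->loose attempts 40x slower than loose->dense;
*seurat*: differentiation budget 1/20, death 100/day), predicate toggles
(the five *leo* hypotheses, the rule knockouts), fixed-event edits (*cho*)
and replacement initial conditions (vertical or off-centre initial band,
3 mm-tall domain, pre-formed adult stripes). Crosses compose by name
("leo;nac"), commutatively and idempotently.

## Pattern metrics and their conventions

* Centerline and straightness: the connected dense-S-iridophore component
  nearest mid-height (xanthophores for iridophore-free fish), mean height
  per column, gaps interpolated; SS = end-to-end distance / arc length.
* X0 width: mean per-column vertical extent of that component.
* Pseudo-stripes: maxima of the melanophore row profile (smoothed over
  0.1 mm) above 0.3 of the global maximum, separated by troughs below half
  that threshold.
* Longest melanophore stretch: within detected pseudo-stripe bands, the
  longest per-row run of occupied columns tolerating gaps up to 0.1 mm,
  as a fraction of domain length ("the widest spot").
* Regions: a fine row is interstripe when dense S-iridophores outnumber
  loose there (ties to interstripe); the X:M ratio divides interstripe
  xanthophores by stripe melanophores.
* Square Uniform PCF: observed over expected pair counts per Chebyshev
  ring, expected from uniform placement of the same agent numbers;
  heterotypic cross-layer pairs are evaluated on the fine lattice with
  coarse agents mapped to the first site of their 2x2 footprint. Site-pair
  totals per ring are computed exactly for the current lattice shape.

The smoothing window, peak fraction and gap tolerance are stand-in
conventions (the original definitions are not fully specified); they are
keyword arguments throughout.

## Numerical and implementation choices

The inner loop is a numba-compiled kernel; agents are selected by
rejection sampling on the occupancy grids, and all randomness flows from a
single integer seed (chunk seeds are derived deterministically, so a run
is reproducible bit-for-bit and snapshots at stage boundaries do not
perturb the stream). Stencils of integer offsets per (layer pitch, range,
parity) are precomputed once and shared between the kernel, the python
query functions and the tests. Grids are preallocated with generous
capacity bounds and reallocated transparently if a trajectory outgrows
them. Predicates are evaluated on the pre-attempt state and applied
atomically; ties in direction sampling resolve by cumulative order.

## Desk-scale testing and what it shows

The test suite and the acceptance script use 3–10 replicates per genotype
(the published summaries average 100) on the standard 2 mm x 1 mm domain;
sampling noise at this replication is absorbed by widened tolerances
rather than by altering the simulated conditions. Passing tests show that
the rule set reproduces the wild-type banded architecture and its
cell-density ratio, the shd two-pseudo-stripe spot phenotype, the pfe
spots-in-a-dense-sea phenotype, the cho labyrinth and the double-mutant
uniform fills at this scale; they do not show that the reconstruction
matches the original at every rate, since several per-event rates and
functional forms are reconstructions calibrated through the summary
statistics.

## Known limitations

* Pattern period: only the first interstripe generation consolidates fully
  with xanthophores by J+, so stripes 1D/1V are thicker than observed and
  the first trough of the homotypic melanophore PCF sits near 0.5–0.6 mm
  instead of ~0.3 mm; the pseudo-stripe count for wild type and *pfe*
  reads 2 (the paired mega-stripes) rather than 4–5.
* The *nac* flank largely locks into a dense sheet with only collar regions
  of loose S-iridophores, instead of a loose-covered flank.
* The melanophore-only double mutant fills its layer to ~75–85% (the
  spontaneous fill rate competes with continuing domain growth) rather
  than >= 95%.
* The straightness-vs-aspect-ratio correlation reproduces the published
  sign but at about a third of the published magnitude (stage-J scatter
  alone shows it strongly, R ~ -0.85).
* Dorso-ventral asymmetries (countershading) and everything beyond stage
  J+ are not modelled.
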