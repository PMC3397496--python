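# Methods

## Model

`karsim` simulates transport along a linear chain of membrane compartments
as a deterministic discrete-time process. One round applies one *phase* of
a cyclic pairing schedule: each phase names a set of disjoint, adjacent
compartment pairs that transiently fuse and re-separate. Two phases that
alternately tile the odd and even junctions of the chain reproduce the
situation in which every inter-compartment junction is visited every
other round; round *k* (1-based) uses phase (*k* − 1) mod *period*, so
round 1 always applies phase 1.

A fused pair pools its content *T* and separates it unevenly. Physically,
the distal member of a pair pumps protons (or Ca²⁺) harder, shifting the
monomer–oligomer equilibrium of the transported protein toward slow
oligomers on that side; the tubular fusion neck passes monomers freely but
retards oligomers, so protein accumulates where it oligomerizes. The
model compresses all of that chemistry into a single effective enrichment
ratio r: the depleted side keeps *T*/(1 + r), the enriched side
r·*T*/(1 + r). Default r = 2.

### Integer rounding

The worked scenarios are run in integer mode, mirroring the
conditional-unit bookkeeping of the reference tables. The depleted side is
rounded to the nearest integer (half away from zero) and the enriched side
takes the exact remainder, which guarantees integer-exact pair
conservation. For r = 2 the depleted share is *T*/3, whose fractional part
is never exactly ½, so the tie-break direction never actually fires; it is
fixed anyway so the rule is total. An equivalent characterization, used as
an independent oracle in the tests, is that the depleted share minimizes
|*T* − (1 + r)·p| over all integer splits p + (*T* − p). Real mode divides
exactly and is provided for kinetic analyses where rounding noise is
unwanted.

### Boundary rules

* **Source clamp.** The ER is a constant-synthesis boundary: after any
  phase in which it participates, the ER holds its clamp value (10 units)
  and its partner is set to r × clamp (20), regardless of the partner's
  prior content. The clamped pair is deliberately non-conserving — the ER
  is an infinite reservoir — and the per-round net injection is logged so
  mass-balance accounting remains possible. The unconditional rule (rather
  than, say, `max(partner, r·clamp)`) was chosen because it is the
  simplest rule consistent with every reference row, including those where
  it overwrites a larger prior partner content with 20.
* **Direction profile.** A pair whose distal member lies at or before the
  inversion index is anterograde (distal member enriched); pairs beyond it
  are retrograde (proximal member enriched). The cargo scenario has no
  inversion; the enzyme scenario inverts distal to med4, which is what
  parks the enzyme peak there: med3–med4 pushes material distally into
  med4 while med4–med5 pushes it back proximally into med4.
* **Departure.** After each completed round, if the terminal compartment
  strictly exceeds `threshold_fold` × baseline (default 5 × 10 = 50
  units), it departs. The default action `remove_all` empties it;
  `remove_half` is offered as an alternative because the reference
  table's own post-departure values follow no single derivable rule, and
  no quantitative claim in this package depends on the post-departure
  branch. Strict inequality means a PGC of exactly 50 stays.

Under these rules the update has two useful structural properties, both
enforced as tests: each non-clamped pair conserves its total exactly, and
applying the same phase twice is the same as applying it once (a split
pair is a fixed point of its own redistribution, e.g. 7/13 → 7/13).

## Canonical scenarios and verified ranges

`build_table1_config()` (soluble cargo): 9 compartments ER…PGC, ER = 10
and the rest empty, all-anterograde, ER clamped, departure at 5-fold on
the PGC. `build_table2_config()` (resident enzymes): 9 compartments with
an extra medial cisterna and no IC, all starting at 10 (a Golgi exists
only with its enzymes already in place), inversion at med4, no departure.

The shipped reference matrices are reproduced cell-exactly over fixed
verified ranges: cargo rounds 1–18 (162 cells) and enzyme rounds 1–11.
The ranges end where the printed matrices first contradict pairwise mass
conservation; those cells are catalogued as errata
(`karsim.tables._ERRATA`) with the value conservation forces:

* cargo, round 19, *cis*: printed 10, conserving 9 (pool 19 + 9 = 28);
  later cargo rows inherit this divergence;
* cargo, round 27, TGN: printed 37 alongside med4 = 13, summing to 50
  from a 40-unit pool;
* enzyme, round 2, *cis*: printed 7, conserving 9 (pool 20 + 7 = 27) —
  the only mismatch inside a verified range;
* enzyme, round 12, med4/med5: printed 38/18 conserves the 56-unit pool
  but is not the nearest-rounding split 37/19.

The engine is conservation-exact rather than errata-emulating, because the
reference tables' own worked splits (e.g. 27 → 9/18) presume
conservation, and every early row obeys it. Consequences that depend on
the non-conserving cells — the printed first departure after round 28, the
"5.7-fold after 23 rounds" enzyme figure — are not asserted anywhere; the
clean run's own first departure falls at round 32, verified against an
independent re-implementation of the row updates. The departure marker
printed after row 28 is recorded where printed even though the
accompanying text says row 26; the fixture does not editorialize.

Two further ambiguities in the model's verbal description were resolved
from the tables themselves: phase 2 of the cargo scenario pairs IC–*cis*
(an alternative reading pairing the ER exit sites with *cis* cannot
produce the printed row-2 values 7/13), and the enzyme peak is med4 (the
verbal account places it one cisterna earlier, but the printed trajectory
and its bold row peak at med4 throughout).

## Kinetics utilities

* `fold_profile` divides contents by the baseline (10 units); it is
  homogeneous of degree zero under joint scaling of contents and baseline.
* `peak_compartment` breaks ties toward the distal end, consistent with
  the proximal-to-distal direction of the concentration wave.
* `exit_series` tracks, per round, the system total (clamped sources
  excluded), cumulative departures, and cumulative clamp influx; in any
  run `total + departed − influx` is constant (integer-exact in integer
  mode).
* `fit_first_order` fits A·e<sup>−kt</sup> by nonlinear least squares on
  the raw series (no log transform, so zeros are tolerated), seeded from
  the series endpoints. Degenerate inputs — all-zero, constant, growing —
  return a fit flagged `decaying=False` with k ≤ 0 rather than raising.
  On noise-free exponentials the rate and amplitude are recovered to
  better than 10⁻⁶ relative error.
* Exit half-time is the first round at which cumulative departures reach
  half the mass supplied to date (initial system content plus cumulative
  influx); this is well defined for stepwise deterministic series, where
  a continuous-time half-life is not.

### Baselines

The two caricatures exist to make kinetic signatures comparable, not to be
faithful models. The *diffusion* baseline fully equilibrates all
compartments each round and then removes a fraction f of the terminal
compartment; its total decays geometrically with rate −ln(1 − f/n) for an
n-compartment chain, i.e. it is exactly first-order (R² ≈ 1 by
construction). The *conveyor* baseline shifts all contents one position
distally per round, so a pulse departs as a single spike (chain length −
starting position) rounds later — the opposite extreme, which a single
exponential fits poorly. The default comparison
(`default_model_comparison`) runs the cargo scenario for 60 rounds against
a 90-unit loaded chain (diffusion, f = 0.5) and a 10-unit proximal pulse
(conveyor) on the same 9-compartment chain.

## Determinism and problem sizes

There is no randomness anywhere in the model; identical configurations
yield byte-identical trajectory files. Test problem sizes follow the
worked material: 48 cargo rounds, 23 enzyme rounds, redistribution totals
up to 10⁶ in property tests, 10⁴ randomized conservation checks, 50-round
baseline washouts. The whole suite and the acceptance script each complete
in seconds.

## Limitations

The simulator covers linear chains only — no branched or reticular Golgi
topologies, no stochastic pairing, no explicit pH/Ca²⁺ fields (gradients
enter solely through r and the inversion index), and no continuous-time
fusion kinetics. The conditional-unit bookkeeping is a concentration
caricature: compartment volumes are implicit and equal. Passing the
worked-table checks shows the arithmetic of the published model is
implemented faithfully; it says nothing about whether real Golgi stacks
realize these dynamics.
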