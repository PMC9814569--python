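# Model and methods

`catchsim` simulates the co-assembly of charge-complementary β-sheet
peptides with discontinuous (event-driven) molecular dynamics and
analyzes the resulting assembly kinetics. This note documents the
model, its parameters and their defaults, the numerical machinery, what
the synthetic scenarios do and do not emulate, and the known
limitations.

## The coarse-grained model

Each residue is four beads: three backbone spheres (NH, Cα, CO) and one
sidechain sphere (R). Covalent connectivity and backbone geometry are
maintained by *pseudo-bonds*: hard distance windows
`ideal·(1 ± tolerance)` covering the covalent bonds (N–Cα, Cα–C, C–N′,
Cα–R), the next-nearest-neighbour angular constraints (N–C, Cα–N′,
C–Cα′, Cα–Cα′) and the sidechain orientation constraints (R–N, R–C).
Ideal lengths are measured on a canonical extended chain built from
fixed bond lengths (1.46 / 1.51 / 1.33 Å) and planar all-trans angles
(111° / 116° / 122°), so the template satisfies every constraint
exactly. Within one chain, non-bonded beads of the same or adjacent
residues interact only through hard cores reduced to 75 % of contact
(the local "squeeze" that keeps the backbone flexible).

All energies are in units of the hydrogen-bond well depth
ε_HB = 12.47 kJ/mol; the reduced temperature is T\* = k_B·T/ε_HB.
Masses are chemical group masses (NH 15, Cα 13, CO 28 amu; sidechains
their group masses), lengths are in Å, and the reduced time unit is
Å·√(amu/ε_HB).

### Interactions

* **Hydrogen bond.** Backbone NH–CO pairs carry a directional square
  well: depth 1 ε_HB, capture distance 4.6 Å, with auxiliary
  constraints requiring the four beads flanking the NH and CO (Cα and
  the preceding CO; Cα and the following NH) to stay at least 4.6 Å
  from the partner at formation time. Both numbers derive from the
  model's own extended-chain geometry: two in-register parallel strands
  offset by (−2.55, 4.15) Å form ten symmetric NH–CO pairs at 4.44 Å
  with flanking distances ≥ 4.87 Å. Each NH and CO can hold one bond;
  escape requires the radial kinetic energy to pay the well depth.
  Hydrogen bonds are intermolecular only (below).
* **Sidechain square wells.** A class-based table: hydrophobic pairs
  (F, W, …) −0.30 ε_HB; opposite-charge pairs (K/R/ornithine vs E/D)
  −0.40; like-charge pairs +0.40 (a repulsive shoulder); polar–polar
  (Q–Q) −0.08. Well edges sit at 1.5 × the hard-core contact distance,
  except the charge-class wells at 2.0 × — their extra reach stands in
  for the longer range of Coulomb interactions relative to contact
  forces. A complete per-residue-pair table can be supplied as
  whitespace-delimited text and overrides the class defaults.
* **Everything else** (backbone–backbone other than NH–CO,
  backbone–sidechain) is a pure hard sphere.

With all well depths zero the system reduces to a hard-sphere chain
fluid, which is used as an engine test limit.

### Desk-scale calibration

The published parameter set behind the full-scale studies of this
peptide family (hundreds of pair-specific widths and depths) is not
bundled; the class-based defaults above are calibrated for the regime
this package actually runs in — tens of peptides advanced for millions
of collisions on one CPU, versus ~100 peptides and ~2·10¹¹ collisions
at production scale. Three deliberate departures from the classic
conventions of this model family follow from that regime:

* **Bond tolerance 4.75 %** (classic: 2.375 %). Pseudo-bond rattling
  accounts for over 99 % of all events; doubling the free window halves
  the cost of a unit of reduced time while leaving assembly behaviour
  qualitatively unchanged.
* **Andersen thermostat rate 1 per bead per 500 time units** (classic
  choices are ~10× higher). Internal collisions conserve each chain's
  momentum, so chain diffusion is rate-limited by ghost collisions; at
  higher rates the peptides effectively freeze in place at this system
  size and never encounter one another.
* **No intramolecular hydrogen bonds.** For isolated 11-mers at this
  scale the hairpin channel sequesters most backbone donors before any
  two chains meet, which the large production systems do not suffer
  from; the model therefore treats these fibrillizing 11-mers as
  strands without the intramolecular channel. The analysis-side
  geometric detector is independent and merely excludes same/adjacent
  residue pairs.

Sidechain well depths were chosen within these constraints so that the
charge-complementary pair systems enter the fibrillization regime at
T\* = 0.20 on desk budgets: at the statistics-derived magnitudes of the
production force field (~0.1–0.2 ε_HB) nothing assembles within an
affordable horizon, while much deeper wells (≥ 0.55) make any contact
permanent and erase the dependence on the number of charged residues.

## The event-driven engine

Between events every bead flies ballistically; positions are stored
lazily at each bead's last event time and advanced analytically
(asynchronous DMD). Event times for a pair are the roots of
|Δr + Δv·t|² = d² for each discontinuity d (hard core, well edge, bond
window limit, hydrogen-bond capture distance) under the minimum-image
convention. A pair already at a threshold while approaching collides
immediately — without this rule round-off lets pairs tunnel through
discontinuities.

Scheduling keeps one candidate event per bead (its earliest upcoming
discontinuity or cell-list crossing) in a binary heap, with per-bead
counters that are bumped on every velocity change. A popped entry whose
owner counter is stale is discarded; one whose *partner* counter is
stale triggers a recompute of the owner's candidate (discarding it
would lose real events; bumping the owner's counter instead can
livelock two beads into mutual invalidation). Cell crossings carry a
separate epoch counter so duplicates cannot re-fire while pair
predictions — which crossings do not invalidate — stay live.

Collision rules are the standard impulsive ones along the line of
centres: elastic reflection at cores and bond limits; well crossings
exchange radial kinetic energy against the potential step, with an
elastic bounce when the step cannot be paid; hydrogen-bond formation
additionally checks the registry and the directional constraints and
otherwise lets the pair pass transparently. Ghost collisions resample
one bead's velocity from the Maxwell–Boltzmann distribution at T\*.
Between ghosts, energy and momentum are conserved to floating-point
accumulation (measured ~10⁻¹⁷ ε_HB per event).

The collision budget counts two-body events; ghost collisions and cell
crossings are tracked separately. Reduced time is the internal clock;
an optional reporting constant (16 µs ≈ 2·10¹¹ collisions at the
4224-bead production scale, scaled linearly in bead count) gives rough
physical-time estimates.

Initial states place each chain as its extended template at a uniformly
random position and orientation, rejecting hard-core overlaps;
velocities are Maxwell–Boltzmann with the centre-of-mass drift removed.
Everything is deterministic for a given seed.

## Assembly analysis

Hydrogen bonds are detected geometrically per snapshot (NH–CO within
the capture distance, auxiliary constraints satisfied, same/adjacent
residues of one chain excluded, closest-pair-wins uniqueness). Two
peptides are *joined* if a majority of their backbone hydrogen-bonding
sites are occupied — interpreted per pair as ⌈(L+1)/2⌉ bonds for
L-residue chains, i.e. 6 for 11-mers, configurable — or if they share
at least one hydrophobic sidechain contact (hydrophobic-class residues
inside their attractive well). Connected components of joined pairs are
classified by size: 1 free, 2–5 oligomer, >5 fibril. Kinetics are
reported on the snapshot grid without smoothing.

Strand-order statistics (alternating versus like-charge neighbours)
count only pairs that meet the hydrogen-bond majority — strand order is
a backbone-registry concept — while hydrophobic-only (bilayer) contacts
are reported separately; the cation fraction of a cluster is the
model-side comparator for experimentally estimated cationic:anionic
content ratios.

## Synthetic scenarios

The generator produces every input the pipeline needs: the
charge-patterned 11-mer family (K or E substituted into a Q/F scaffold
at canonical positions, growing outward from the hydrophobic F core),
random-gas initial states, ideal in-register sheets and F-face-apposed
bilayers with hydrogen bonds and cluster membership known by
construction, and schedule-driven toy trajectories whose cluster time
series is known exactly. Fixtures are validated against the engine's
own state invariants and the force-field ranges at build time.

These scenarios emulate the *structure* of real data (β-sheet registry,
bilayer burial of the hydrophobic face, assembly time series), not its
imperfections: no conformational disorder within sheets, no
experimental noise beyond optional additive Gaussian terms, and no
solvent or ionic-strength effects. Tests passing on them demonstrate
the correctness of the detection and classification machinery, not the
realism of the force field.

## Experimental-side calculations

Mean residue ellipticity is computed exactly as
`ellipticity / (amide_bonds · concentration · 10⁻⁷) · 10⁻³` with
concentration in µM (the convention of the CD protocols this mirrors;
path length is folded into the constants, with an optional explicit
variant). The MRE(212 nm)/MRE(202 nm) ratio marks β-sheet content; the
random-coil / transition / β-sheet region bounds (0.6 and 1.0) are
package conventions for the qualitative ordering, not measured
constants. Secondary chemical shifts are observed minus random-coil
reference shifts, with negative carbonyl- and α-carbon means flagged as
β-strand-consistent; reference tables are user-supplied.

## Problem sizes and what the desk-scale study shows

The bundled "paper-mini" study runs 8+8 peptides (or 16 of one species)
at 20 mM — a 110.06 Å box — for a few million collisions over five
seeds, at T\* = 0.20 and 0.18. At this size the directional tendencies
are visible (charge-complementary pairs nucleate hydrogen-bonded
dimers; single species with ≥4 like charges remain dispersed), but the
time to 50 % free-peptide depletion is encounter-limited at roughly
6 000–10 000 reduced time units, beyond the default budgets, and
seed-to-seed variance at 16 peptides is comparable to the difference
between the 6± and 4± systems. The corresponding acceptance checks are
therefore expected to remain unmet at desk scale; they are asserted
as stated, and their failure is a property of the scale, not a bug
indicator. The single-species stability check does pass.

## Numerical choices and degenerate inputs

Event-time ties are processed in heap order with no special handling —
tie order does not affect the invariants. The edge-side ambiguity at a
discontinuity (a pair exactly at a well edge) is resolved by the sign
of the radial velocity with a 10⁻⁹ Å² tolerance. Cells are at least as
large as the longest interaction range, and the box must exceed twice
that range for the minimum-image convention to be valid (enforced).
Zero-velocity relative motion yields no event; a system that can never
produce another event terminates rather than spinning. Empty sequences,
unknown residue codes, non-positive temperatures and concentrations,
packing failures and inconsistent sheet geometries raise errors that
name the offending input.

## Known limitations

* The interaction table is a four-class reduction, not the published
  per-pair production force field; quantitative rates and equilibrium
  populations are not comparable with production-scale results.
* Charge is contact physics here (widened square wells); there is no
  explicit electrostatics, solvent, or ionic strength, so salt effects
  on co-assembly cannot be represented.
* Intramolecular hydrogen bonding is disabled, so β-hairpin and
  monomer-collapse physics is out of scope.
* The engine is single-threaded and reaches ~10⁵ events/s at
  ~700 beads; production-scale budgets (10¹¹ collisions) are out of
  reach by design.
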