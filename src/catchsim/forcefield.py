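"""Coarse-grained force-field parameters and bead topology.

Four beads per residue: three backbone spheres (NH, Ca, CO) and one
sidechain sphere (R).  Covalent bonds and the next-nearest-neighbour
angular constraints are "pseudo-bonds": hard distance windows
``ideal * (1 +/- tolerance)`` within which beads move freely.
Sidechain-sidechain pairs interact through square wells
(attractive, repulsive, or absent); backbone NH-CO pairs carry the
directional hydrogen-bond well; every other non-bonded pair is a pure
hard sphere.

Energies are expressed in units of the hydrogen-bond well depth
``eps_HB`` = 12.47 kJ/mol; the reduced temperature is
``T* = kB*T / eps_HB``.

The complete published parameter set for this model family (210 pair
widths, 19 depths) is intentionally not bundled.  The default table is
a documented class-based reduction -- one attractive hydrophobic well,
one attractive (+/-) charge well, one repulsive like-charge shoulder,
one weak polar well -- and :meth:`InteractionTable.from_text` accepts a
complete user-supplied pair table in plain whitespace-delimited text.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .sequence_model import RESIDUES, PeptideSequence, ResidueSpec

__all__ = [
    "EPS_HB_KJ_MOL",
    "KB_KJ_MOL_K",
    "InteractionTable",
    "PairPotential",
    "BeadTopology",
    "SystemTopology",
    "default_table",
    "build_topology",
    "build_system_topology",
    "reduced_temperature",
    "kelvin_of",
    "backbone_template",
    "chain_template",
    "sidechain_backbone_distances",
]

#: Hydrogen-bond well depth, kJ/mol (the energy unit of the model).
EPS_HB_KJ_MOL = 12.47
#: Boltzmann constant, kJ/(mol K).
KB_KJ_MOL_K = 8.314462618e-3

# Backbone geometry (Angstrom / degrees): bond lengths N-Ca, Ca-C, C-N'
# and the planar all-trans bond angles at Ca, C and N.
BOND_N_CA = 1.46
BOND_CA_C = 1.51
BOND_C_N = 1.33
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.0
ANGLE_C_N_CA = 122.0

#: Backbone bead hard-sphere diameters (Angstrom).
BACKBONE_DIAMETERS = {"NH": 3.3, "CA": 3.7, "CO": 4.0}
#: Backbone bead masses (amu): chemical group masses NH, CH, C=O.
BACKBONE_MASSES = {"NH": 15.0, "CA": 13.0, "CO": 28.0}

# Bead kind codes used throughout the engine and analysis.
KIND_NH, KIND_CA, KIND_CO, KIND_R = 0, 1, 2, 3
KIND_NAMES = ("NH", "CA", "CO", "R")


def reduced_temperature(T_kelvin: float) -> float:
    """Reduced temperature ``T* = kB*T / eps_HB`` for ``T`` in kelvin."""
    if T_kelvin <= 0:
        raise ValueError(f"temperature must be positive, got {T_kelvin}")
    return KB_KJ_MOL_K * T_kelvin / EPS_HB_KJ_MOL


def kelvin_of(T_star: float) -> float:
    """Inverse of :func:`reduced_temperature`."""
    if T_star <= 0:
        raise ValueError(f"reduced temperature must be positive, got {T_star}")
    return T_star * EPS_HB_KJ_MOL / KB_KJ_MOL_K


@dataclass(frozen=True)
class PairPotential:
    """Descriptor of a piecewise-constant pair potential.

    ``hard_core`` is the contact distance (Angstrom); ``well_edge`` is
    the outer discontinuity of the square well, or None for a pure hard
    sphere; ``depth`` is the well energy in eps_HB units with the sign
    convention depth < 0 attractive, > 0 repulsive shoulder.
    ``is_hbond`` marks the directional NH-CO well.
    """

    hard_core: float
    well_edge: float | None = None
    depth: float = 0.0
    is_hbond: bool = False


@dataclass
class InteractionTable:
    """Square-well/hard-sphere parameter set for the four-bead model."""

    # depth (eps_HB units, <0 attractive) per unordered pair of
    # interaction classes {hydrophobic, cation, anion, polar}
    class_depths: dict[frozenset, float] = field(default_factory=dict)
    #: well outer edge = well_width_ratio * hard-core contact distance
    well_width_ratio: float = 1.5
    #: per-class-pair overrides of the width ratio (charge-charge wells
    #: are wider: they stand in for longer-range Coulomb steering)
    class_width_ratios: dict[frozenset, float] = field(default_factory=dict)
    #: per-residue-pair overrides: (codeA, codeB) sorted -> (edge_A, depth)
    pair_overrides: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )
    # hydrogen bond: NH-CO capture distance, well depth (eps_HB), and the
    # minimum distance each flanking bead must keep at formation time
    # (the auxiliary directionality constraint)
    hb_distance: float = 4.6
    hb_depth: float = 1.0
    hb_aux_min: float = 4.6
    #: fractional free fluctuation of pseudo-bonds (twice the classic
    #: 2.375% convention: halves the bond-event rate per unit time, the
    #: dominant cost at desk scale, at a minor cost in backbone rigidity)
    bond_tolerance: float = 0.0475
    #: hard-core reduction factor for non-bonded beads of the same or
    #: adjacent residues (local squeeze, keeps the backbone flexible)
    squeeze_factor: float = 0.75
    eps_hb_kj_mol: float = EPS_HB_KJ_MOL

    # -- lookups ---------------------------------------------------------

    def sidechain_depth(self, res_a: ResidueSpec, res_b: ResidueSpec) -> float:
        key = tuple(sorted((res_a.code, res_b.code)))
        if key in self.pair_overrides:
            return self.pair_overrides[key][1]
        return self.class_depths.get(
            frozenset((res_a.interaction_class, res_b.interaction_class)), 0.0
        )

    def sidechain_well(
        self, res_a: ResidueSpec, res_b: ResidueSpec
    ) -> PairPotential:
        contact = 0.5 * (res_a.sidechain_diameter + res_b.sidechain_diameter)
        key = tuple(sorted((res_a.code, res_b.code)))
        if key in self.pair_overrides:
            edge, depth = self.pair_overrides[key]
        else:
            depth = self.sidechain_depth(res_a, res_b)
            ckey = frozenset((res_a.interaction_class, res_b.interaction_class))
            ratio = self.class_width_ratios.get(ckey, self.well_width_ratio)
            edge = ratio * contact
        if depth == 0.0:
            return PairPotential(hard_core=contact)
        if edge <= contact:
            raise ValueError(
                f"well edge {edge} not beyond contact {contact} for {key}"
            )
        return PairPotential(hard_core=contact, well_edge=edge, depth=depth)

    def lookup_pair_potential(self, bead_a: str, bead_b: str) -> PairPotential:
        """Potential descriptor for two bead labels.

        Labels are ``"NH"``, ``"CA"``, ``"CO"`` or ``"R:<code>"``.
        Symmetric in its arguments.  NH-CO returns the hydrogen-bond
        well; backbone pairs otherwise are hard spheres; R-R pairs are
        square wells (or hard spheres at zero depth); R-backbone pairs
        are hard spheres.
        """
        a, b = sorted((bead_a, bead_b))

        def diameter(lbl: str) -> float:
            if lbl.startswith("R:"):
                return RESIDUES[lbl[2:]].sidechain_diameter
            return BACKBONE_DIAMETERS[lbl]

        contact = 0.5 * (diameter(a) + diameter(b))
        if a.startswith("R:") and b.startswith("R:"):
            return self.sidechain_well(RESIDUES[a[2:]], RESIDUES[b[2:]])
        if {a, b} == {"NH", "CO"}:
            return PairPotential(
                hard_core=contact,
                well_edge=self.hb_distance,
                depth=-self.hb_depth,
                is_hbond=True,
            )
        return PairPotential(hard_core=contact)

    # -- plain-text round trip ------------------------------------------

    def to_text(self) -> str:
        """Serialize as whitespace-delimited pair rows with a version header."""
        buf = io.StringIO()
        buf.write("# catchsim-interaction-table v1\n")
        buf.write(f"# meta well_width_ratio {self.well_width_ratio}\n")
        buf.write(f"# meta hb_distance {self.hb_distance}\n")
        buf.write(f"# meta hb_depth {self.hb_depth}\n")
        buf.write(f"# meta hb_aux_min {self.hb_aux_min}\n")
        buf.write(f"# meta bond_tolerance {self.bond_tolerance}\n")
        buf.write("# bead_type_a bead_type_b width depth\n")
        for key in sorted(self.class_depths, key=sorted):
            pair = sorted(key) if len(key) == 2 else [min(key), min(key)]
            ratio = self.class_width_ratios.get(key, self.well_width_ratio)
            buf.write(
                f"class:{pair[0]} class:{pair[1]} "
                f"ratio:{ratio} {self.class_depths[key]}\n"
            )
        for (a, b), (edge, depth) in sorted(self.pair_overrides.items()):
            buf.write(f"R:{a} R:{b} {edge} {depth}\n")
        return buf.getvalue()

    @classmethod
    def from_text(cls, text: str) -> "InteractionTable":
        table = cls()
        for line in text.splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                toks = line[1:].split()
                if len(toks) == 3 and toks[0] == "meta":
                    setattr(table, toks[1], float(toks[2]))
                continue
            ta, tb, width, depth = line.split()
            depth = float(depth)
            if ta.startswith("class:"):
                key = frozenset((ta[6:], tb[6:]))
                table.class_depths[key] = depth
                if width.startswith("ratio:"):
                    ratio = float(width[6:])
                    if ratio != table.well_width_ratio:
                        table.class_width_ratios[key] = ratio
            else:
                a, b = sorted((ta[2:], tb[2:]))
                table.pair_overrides[(a, b)] = (float(width), depth)
        return table

    @classmethod
    def load(cls, path: str | Path) -> "InteractionTable":
        return cls.from_text(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def default_table() -> InteractionTable:
    """The documented class-based default interaction table.

    Depths in eps_HB units (negative = attractive): a hydrophobic well
    (F-F and other hydrophobic pairs), an opposite-charge attraction
    (K-E), a like-charge repulsive shoulder (K-K, E-E), and a weak
    polar-polar well (Q-Q).  Magnitudes are a fraction of the
    hydrogen-bond energy, as in intermediate-resolution peptide models;
    the charge-charge wells are wider than the contact wells because
    they stand in for longer-range Coulomb forces.  The set is
    calibrated for the desk-scale regime in which the charged pair
    systems fibrillize within millions (not hundreds of billions) of
    collisions; it is not the published production parameter set.
    """
    t = InteractionTable()
    t.class_depths = {
        frozenset(("hydrophobic",)): -0.30,
        frozenset(("cation", "anion")): -0.40,
        frozenset(("cation",)): +0.40,
        frozenset(("anion",)): +0.40,
        frozenset(("polar",)): -0.08,
    }
    t.class_width_ratios = {
        frozenset(("cation", "anion")): 2.0,
        frozenset(("cation",)): 2.0,
        frozenset(("anion",)): 2.0,
    }
    return t


# -- canonical extended-chain geometry ----------------------------------


def backbone_template(n_residues: int) -> np.ndarray:
    """Positions of the 3*n backbone beads of an ideal extended chain.

    Planar all-trans zig-zag in the xy-plane built from the fixed bond
    lengths and angles above; the chain propagates along +x.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    bonds = [BOND_N_CA, BOND_CA_C, BOND_C_N]
    angles = [
        math.radians(ANGLE_C_N_CA),   # interior angle at N
        math.radians(ANGLE_N_CA_C),   # at CA
        math.radians(ANGLE_CA_C_N),   # at C
    ]
    n_atoms = 3 * n_residues
    pos = np.zeros((n_atoms, 3))
    phi = 0.0
    sgn = 1.0
    for i in range(n_atoms - 1):
        b = bonds[i % 3]
        pos[i + 1] = pos[i] + b * np.array([math.cos(phi), math.sin(phi), 0.0])
        # turn at the new atom; its interior angle depends on its kind
        th = angles[(i + 1) % 3]
        phi += sgn * (math.pi - th)
        sgn = -sgn
    return pos


def chain_template(p: PeptideSequence) -> np.ndarray:
    """Template coordinates for all 4L beads of a peptide.

    Bead order is ``[NH, CA, CO, R]`` per residue.  Sidechain beads sit
    perpendicular to the backbone plane at the canonical Ca-R distance,
    alternating sides along the chain as in an extended beta-strand.
    """
    L = len(p)
    bb = backbone_template(L)
    pos = np.zeros((4 * L, 3))
    for i, res in enumerate(p.residues):
        pos[4 * i + 0] = bb[3 * i + 0]
        pos[4 * i + 1] = bb[3 * i + 1]
        pos[4 * i + 2] = bb[3 * i + 2]
        side = 1.0 if i % 2 == 0 else -1.0
        pos[4 * i + 3] = bb[3 * i + 1] + np.array(
            [0.0, 0.0, side * res.r_calpha_distance]
        )
    return pos


def sidechain_backbone_distances(res: ResidueSpec) -> tuple[float, float, float]:
    """(R-NH, R-Ca, R-CO) pseudo-bond lengths implied by the template.

    The sidechain bead sits perpendicular to the backbone plane above
    Ca, so the flanking distances follow by Pythagoras from the
    covalent bond lengths.
    """
    d = res.r_calpha_distance
    return (
        math.hypot(d, BOND_N_CA),
        d,
        math.hypot(d, BOND_CA_C),
    )


# -- topology ------------------------------------------------------------


@dataclass
class BeadTopology:
    """Bead list and pseudo-bond constraints for one peptide chain."""

    sequence: PeptideSequence
    bead_kind: np.ndarray        # int8, KIND_* per bead
    residue_index: np.ndarray    # int32, residue of each bead
    masses: np.ndarray           # float64, amu
    hs_diameters: np.ndarray     # float64, Angstrom
    pseudo_bonds: list[tuple[int, int, float, float]]  # (i, j, ideal, tol)
    template: np.ndarray         # (4L, 3) reference coordinates

    @property
    def n_beads(self) -> int:
        return self.bead_kind.size


def build_topology(
    p: PeptideSequence, table: InteractionTable | None = None
) -> BeadTopology:
    """Build the four-bead topology of a peptide.

    Pseudo-bonds cover covalent connectivity (N-Ca, Ca-C, C-N', Ca-R),
    the next-nearest-neighbour angular constraints along the backbone
    (N-C, Ca-N', C-Ca', Ca-Ca') and the sidechain orientation
    constraints (R-N, R-C).  Ideal lengths are measured on the extended
    template so the template satisfies every constraint exactly.
    """
    table = table or default_table()
    L = len(p)
    tol = table.bond_tolerance
    tmpl = chain_template(p)

    kinds = np.tile([KIND_NH, KIND_CA, KIND_CO, KIND_R], L).astype(np.int8)
    resix = np.repeat(np.arange(L, dtype=np.int32), 4)
    masses = np.empty(4 * L)
    diam = np.empty(4 * L)
    for i, res in enumerate(p.residues):
        masses[4 * i : 4 * i + 4] = [
            BACKBONE_MASSES["NH"],
            BACKBONE_MASSES["CA"],
            BACKBONE_MASSES["CO"],
            res.sidechain_mass,
        ]
        diam[4 * i : 4 * i + 4] = [
            BACKBONE_DIAMETERS["NH"],
            BACKBONE_DIAMETERS["CA"],
            BACKBONE_DIAMETERS["CO"],
            res.sidechain_diameter,
        ]

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(tmpl[i] - tmpl[j]))

    bonds: list[tuple[int, int, float, float]] = []

    def add(i: int, j: int) -> None:
        bonds.append((i, j, d(i, j), tol))

    for i in range(L):
        n, ca, co, r = 4 * i, 4 * i + 1, 4 * i + 2, 4 * i + 3
        add(n, ca)
        add(ca, co)
        add(ca, r)
        add(n, co)      # angular: fixes the N-Ca-C angle
        add(r, n)       # sidechain orientation
        add(r, co)
        if i + 1 < L:
            n2, ca2 = 4 * (i + 1), 4 * (i + 1) + 1
            add(co, n2)       # peptide bond
            add(ca, n2)       # angular at C
            add(co, ca2)      # angular at N'
            add(ca, ca2)      # trans-planarity of the peptide unit

    return BeadTopology(
        sequence=p,
        bead_kind=kinds,
        residue_index=resix,
        masses=masses,
        hs_diameters=diam,
        pseudo_bonds=bonds,
        template=tmpl,
    )


@dataclass
class SystemTopology:
    """Concatenated topology of every chain in a simulation box."""

    chains: list[PeptideSequence]
    chain_topologies: list[BeadTopology]
    bead_kind: np.ndarray       # int8
    residue_index: np.ndarray   # int32, residue within its chain
    chain_id: np.ndarray        # int32
    itype: np.ndarray           # int32 interaction type (see build)
    masses: np.ndarray
    hs_diameters: np.ndarray
    bonds: np.ndarray           # (nb, 2) int64 bead pairs
    bond_lo: np.ndarray         # (nb,) min allowed length
    bond_hi: np.ndarray         # (nb,) max allowed length
    # matrices over itype: well outer edge (0 = no well) and depth (eps_HB)
    well_edge: np.ndarray
    well_depth: np.ndarray
    type_labels: list[str]
    table: InteractionTable

    @property
    def n_beads(self) -> int:
        return self.bead_kind.size

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def chain_charges(self) -> np.ndarray:
        return np.array([c.net_charge for c in self.chains], dtype=int)

    def chain_slice(self, c: int) -> slice:
        start = sum(t.n_beads for t in self.chain_topologies[:c])
        return slice(start, start + self.chain_topologies[c].n_beads)


def build_system_topology(
    species: Sequence[tuple[PeptideSequence, int]],
    table: InteractionTable | None = None,
) -> SystemTopology:
    """Replicate per-chain topologies into one system-level topology.

    Interaction types: 0/1/2 for backbone NH/Ca/CO, then one type per
    distinct sidechain residue code present in the system.  The square
    well matrices are dense over these types; backbone rows are zero
    (backbone pairs are hard spheres; the NH-CO hydrogen bond is
    handled by the engine's directional mechanism, not these wells).
    """
    table = table or default_table()
    chains: list[PeptideSequence] = []
    for pep, count in species:
        if count < 0:
            raise ValueError("negative species count")
        chains.extend([pep] * count)
    if not chains:
        raise ValueError("no chains in system")

    topos = [build_topology(p, table) for p in chains]

    codes = sorted({r.code for p in chains for r in p.residues})
    type_labels = ["NH", "CA", "CO"] + [f"R:{c}" for c in codes]
    code_type = {c: 3 + k for k, c in enumerate(codes)}

    kind = np.concatenate([t.bead_kind for t in topos])
    resix = np.concatenate([t.residue_index for t in topos])
    chain_id = np.concatenate(
        [np.full(t.n_beads, c, dtype=np.int32) for c, t in enumerate(topos)]
    )
    masses = np.concatenate([t.masses for t in topos])
    diam = np.concatenate([t.hs_diameters for t in topos])

    itype = np.empty(kind.size, dtype=np.int32)
    itype[kind == KIND_NH] = 0
    itype[kind == KIND_CA] = 1
    itype[kind == KIND_CO] = 2
    offset = 0
    for t in topos:
        for i, res in enumerate(t.sequence.residues):
            itype[offset + 4 * i + 3] = code_type[res.code]
        offset += t.n_beads

    bonds, lo, hi = [], [], []
    offset = 0
    for t in topos:
        for i, j, ideal, tol in t.pseudo_bonds:
            bonds.append((offset + i, offset + j))
            lo.append(ideal * (1.0 - tol))
            hi.append(ideal * (1.0 + tol))
        offset += t.n_beads

    nt = len(type_labels)
    well_edge = np.zeros((nt, nt))
    well_depth = np.zeros((nt, nt))
    for a in codes:
        for b in codes:
            pot = table.sidechain_well(RESIDUES[a], RESIDUES[b])
            ia, ib = code_type[a], code_type[b]
            if pot.well_edge is not None:
                well_edge[ia, ib] = well_edge[ib, ia] = pot.well_edge
                well_depth[ia, ib] = well_depth[ib, ia] = pot.depth

    return SystemTopology(
        chains=chains,
        chain_topologies=topos,
        bead_kind=kind,
        residue_index=resix,
        chain_id=chain_id,
        itype=itype,
        masses=masses,
        hs_diameters=diam,
        bonds=np.array(bonds, dtype=np.int64),
        bond_lo=np.array(lo),
        bond_hi=np.array(hi),
        well_edge=well_edge,
        well_depth=well_depth,
        type_labels=type_labels,
        table=table,
    )
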