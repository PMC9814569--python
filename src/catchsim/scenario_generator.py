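"""Synthetic-scenario generation: every input the pipeline needs.

Provides the charge-patterned 11-mer sequences (Q/F scaffold with K or E
substitutions), random-gas initial states, idealized beta-sheet and
bilayer fixtures with known ground truth (hydrogen bonds, neighbour
pairs, cluster partition), and schedule-driven toy trajectories for
validating the kinetics analysis.  Everything is deterministic given a
seed; nothing is downloaded.
"""

from __future__ import annotations

import importlib.resources as resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .dmd_engine import SimulationState, Trajectory, init_system
from .forcefield import (
    InteractionTable,
    SystemTopology,
    build_system_topology,
    chain_template,
    default_table,
)
from .sequence_model import PeptideSequence, parse_sequence, read_fasta

__all__ = [
    "ScenarioConfig",
    "make_scenario",
    "catch_family",
    "default_scaffold",
    "make_charge_variant",
    "make_random_gas",
    "make_ideal_sheet",
    "make_bilayer",
    "make_kinetics_toy",
    "SheetFixture",
]

@dataclass
class ScenarioConfig:
    """Declarative description of a synthetic scenario.

    ``kind`` selects the fixture family; ``pattern`` is the charge
    placement (substitution count or strand pattern depending on kind);
    ``counts`` are per-species chain counts for gas scenarios.
    """

    kind: str = "random_gas"  # random_gas | ideal_sheet | bilayer | kinetics_toy
    pattern: str = "+-+-+-"
    counts: dict = field(default_factory=dict)
    box_side: float = 110.0
    T_star: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("random_gas", "ideal_sheet", "bilayer",
                             "kinetics_toy"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("species counts must be non-negative")


def make_scenario(config: ScenarioConfig, table=None):
    """Build the fixture described by a :class:`ScenarioConfig`."""
    if config.kind == "ideal_sheet":
        return make_ideal_sheet(config.pattern, table=table)
    if config.kind == "bilayer":
        return make_bilayer(pattern=config.pattern.replace("-", "-"),
                            table=table)
    if config.kind == "kinetics_toy":
        return make_kinetics_toy(max(sum(config.counts.values()), 1), [])
    fam = catch_family()
    species = [(fam[name], count) for name, count in config.counts.items()]
    return make_random_gas(species, config.box_side, config.T_star,
                           config.seed, table=table)


#: Canonical substitution positions (1-based) on the Q/F scaffold for
#: each charge count: the pattern grows symmetrically outwards from the
#: hydrophobic core.
SUBSTITUTION_POSITIONS = {2: (5, 7), 4: (3, 5, 7, 9), 6: (1, 3, 5, 7, 9, 11)}

#: Default two-strand registry shift (x, y, Angstrom) between adjacent
#: in-register strands; derived from the bead model's own extended-chain
#: geometry so that ten NH-CO pairs sit inside the hydrogen-bond well.
STRAND_OFFSET = (-2.55, 4.15)


def default_scaffold() -> PeptideSequence:
    """The neutral 11-mer Q/F scaffold with the hydrophobic F core."""
    return parse_sequence("QQQFQFQFQQQ", peptide_id="QF-scaffold")


def catch_family(path: str | Path | None = None) -> dict[str, PeptideSequence]:
    """The bundled charge-complementary peptide family, keyed by label."""
    if path is None:
        ref = resources.files("catchsim").joinpath("data/catch_sequences.fasta")
        with resources.as_file(ref) as p:
            peps = read_fasta(p)
    else:
        peps = read_fasta(path)
    return {p.id: p for p in peps}


def make_charge_variant(
    scaffold: PeptideSequence,
    positions: Sequence[int],
    sign: str,
) -> PeptideSequence:
    """Substitute K (sign '+') or E (sign '-') at 1-based Q positions.

    The hydrophobic (F) positions may not be touched; the resulting net
    charge is +/- len(positions).
    """
    if sign not in ("+", "-"):
        raise ValueError(f"sign must be '+' or '-', got {sign!r}")
    sub = "K" if sign == "+" else "E"
    seq = list(scaffold.sequence)
    for p in positions:
        if not 1 <= p <= len(seq):
            raise ValueError(f"position {p} out of range 1..{len(seq)}")
        if seq[p - 1] == "F":
            raise ValueError(
                f"position {p} holds the hydrophobic core residue F"
            )
        seq[p - 1] = sub
    label = f"{scaffold.id}({len(positions)}{sign})"
    return parse_sequence(
        "".join(seq),
        peptide_id=label,
        n_term_acetylated=scaffold.n_term_acetylated,
        c_term_amidated=scaffold.c_term_amidated,
    )


def make_random_gas(
    species: Sequence[tuple[PeptideSequence, int]],
    box_side: float,
    T_star: float = 0.2,
    seed: int = 0,
    table: InteractionTable | None = None,
) -> SimulationState:
    """Random-gas initial state (thin wrapper over the engine's packer)."""
    return init_system(species, box_side, T_star, seed, table=table)


# ---------------------------------------------------------------------------
# ideal sheets and bilayers


@dataclass
class SheetFixture:
    """A constructed assembly with known ground truth."""

    topology: SystemTopology
    positions: np.ndarray
    box_side: float
    hbonds: list[tuple[int, int]]             # (NH bead, CO bead)
    neighbor_pairs: list[tuple[int, int]]     # adjacent strand chain ids
    expected_free: set[int] = field(default_factory=set)
    expected_oligomers: list[set[int]] = field(default_factory=list)
    expected_fibrils: list[set[int]] = field(default_factory=list)

    def as_state(self, T_star: float = 0.2, seed: int = 0) -> SimulationState:
        rng = np.random.default_rng(seed)
        from .dmd_engine import maxwell_boltzmann_velocities

        return SimulationState(
            positions=self.positions.copy(),
            velocities=maxwell_boltzmann_velocities(
                self.topology.masses, T_star, rng
            ),
            box_side=self.box_side,
            T_star=T_star,
            seed=seed,
            topology=self.topology,
        )


def _intended_hbonds(
    pos: np.ndarray,
    topo: SystemTopology,
    box_side: float,
    ci: int,
    cj: int,
    table: InteractionTable,
) -> list[tuple[int, int]]:
    """NH-CO pairs between chains ci, cj inside the well with aux ok."""
    from .assembly_analysis import detect_hbonds

    out = []
    for nh, co in detect_hbonds(pos, topo, box_side, table):
        a, b = int(topo.chain_id[nh]), int(topo.chain_id[co])
        if {a, b} == {ci, cj}:
            out.append((nh, co))
    return out


def _strand_stack(
    strands: Sequence[PeptideSequence],
    table: InteractionTable,
    offset: tuple[float, float] = STRAND_OFFSET,
) -> tuple[SystemTopology, np.ndarray]:
    topo = build_system_topology([(p, 1) for p in strands], table)
    coords = []
    for k, p in enumerate(strands):
        tmpl = chain_template(p)
        coords.append(tmpl + np.array([k * offset[0], k * offset[1], 0.0]))
    return topo, np.concatenate(coords, axis=0)


def make_ideal_sheet(
    strands: Sequence[PeptideSequence] | str,
    table: InteractionTable | None = None,
    offset: tuple[float, float] = STRAND_OFFSET,
    box_margin: float = 30.0,
) -> SheetFixture:
    """An in-register parallel beta-sheet with known hydrogen bonds.

    ``strands`` is either a list of peptides (one per strand, first
    strand at the origin, each next strand shifted by ``offset``) or a
    pattern string such as ``"+-+-+-"`` using the bundled 6+/6- pair.
    Adjacent strands satisfy the hydrogen-bond well and directionality
    constraints by construction; the builder verifies this against the
    interaction table and raises if the geometry is inconsistent with
    the force-field ranges.
    """
    table = table or default_table()
    if isinstance(strands, str):
        fam = catch_family()
        lookup = {"+": fam["CATCH(6+)"], "-": fam["CATCH(6-)"]}
        try:
            strands = [lookup[ch] for ch in strands]
        except KeyError as e:
            raise ValueError(f"unknown pattern symbol {e}") from None
    strands = list(strands)
    if len(strands) < 1:
        raise ValueError("need at least one strand")

    topo, pos = _strand_stack(strands, table, offset)
    # centre in a periodic box with clearance on all sides
    span = pos.max(axis=0) - pos.min(axis=0)
    box = float(max(span.max() + 2 * box_margin, 4 * table.hb_distance))
    pos = pos - pos.min(axis=0) + box_margin

    from .dmd_engine import SimulationState, check_state

    probe = SimulationState(
        positions=pos.copy(),
        velocities=np.zeros_like(pos),
        box_side=box,
        topology=topo,
    )
    problems = check_state(probe)
    if problems:
        raise ValueError(
            f"sheet geometry violates state invariants: {problems[:3]}"
        )

    hbonds: list[tuple[int, int]] = []
    neighbor_pairs: list[tuple[int, int]] = []
    from .assembly_analysis import default_hb_majority_threshold

    thr = default_hb_majority_threshold(topo)
    for k in range(len(strands) - 1):
        hb = _intended_hbonds(pos, topo, box, k, k + 1, table)
        if len(hb) < thr:
            raise ValueError(
                f"strands {k} and {k + 1} form only {len(hb)} hydrogen "
                f"bonds (majority threshold {thr}); offset inconsistent "
                "with the hydrogen-bond well geometry"
            )
        hbonds.extend(hb)
        neighbor_pairs.append((k, k + 1))

    n = len(strands)
    fixture = SheetFixture(
        topology=topo,
        positions=pos,
        box_side=box,
        hbonds=hbonds,
        neighbor_pairs=neighbor_pairs,
    )
    members = set(range(n))
    if n == 1:
        fixture.expected_free = members
    elif n <= 5:
        fixture.expected_oligomers = [members]
    else:
        fixture.expected_fibrils = [members]
    return fixture


def make_bilayer(
    strands_per_leaflet: int = 4,
    table: InteractionTable | None = None,
    pattern: str | None = None,
    box_margin: float = 30.0,
) -> SheetFixture:
    """Two apposed sheets joined leaflet-to-leaflet by F-F contacts.

    The second sheet is rotated half a turn about the strand axis so the
    phenylalanine faces of the leaflets point at each other, and the
    stacking distance is chosen (by a deterministic scan) so that at
    least one hydrophobic contact joins each pair of facing strands
    while no hard cores overlap.
    """
    table = table or default_table()
    fam = catch_family()
    if pattern is None:
        pattern = "+-" * (strands_per_leaflet // 2) + (
            "+" if strands_per_leaflet % 2 else ""
        )
    lookup = {"+": fam["CATCH(6+)"], "-": fam["CATCH(6-)"]}
    leaflet = [lookup[ch] for ch in pattern]
    n = len(leaflet)

    topo = build_system_topology([(p, 1) for p in leaflet * 2], table)
    sheet1 = []
    for k, p in enumerate(leaflet):
        sheet1.append(
            chain_template(p)
            + np.array([k * STRAND_OFFSET[0], k * STRAND_OFFSET[1], 0.0])
        )
    sheet1 = np.concatenate(sheet1, axis=0)

    # flip the second leaflet: rotate pi about the y axis (x,z -> -x,-z)
    # so strand y-positions stay aligned and the F face points up
    flip = sheet1 * np.array([-1.0, 1.0, -1.0])
    tx0 = float(sheet1[:, 0].min() + sheet1[:, 0].max())

    from .assembly_analysis import hydrophobic_contacts
    from .dmd_engine import SimulationState, check_state

    candidates = [
        (dz, tx0 + sx)
        for dz in np.arange(8.0, 16.01, 0.25)
        for sx in np.arange(-3.0, 3.01, 0.5)
    ]
    best = None
    for dz, tx in candidates:
        pos = np.concatenate([sheet1, flip + np.array([tx, 0.0, -dz])])
        span = pos.max(axis=0) - pos.min(axis=0)
        box = float(span.max() + 2 * box_margin)
        shifted = pos - pos.min(axis=0) + box_margin
        probe = SimulationState(
            positions=shifted.copy(),
            velocities=np.zeros((len(shifted), 3)),
            box_side=box,
            topology=topo,
        )
        if check_state(probe):
            continue
        contacts = hydrophobic_contacts(shifted, topo, box)
        # cross-leaflet contacts per facing strand pair
        cross = {}
        for a, b in contacts:
            ca, cb = int(topo.chain_id[a]), int(topo.chain_id[b])
            if (ca < n) != (cb < n):
                key = (min(ca, cb), max(ca, cb))
                cross[key] = cross.get(key, 0) + 1
        n_linked_chains = len({c for pair in cross for c in pair})
        score = (n_linked_chains, len(contacts))
        if best is None or score > best[0]:
            best = (score, shifted, box)
        if n_linked_chains == 2 * n:
            break
    if best is None or best[0][0] < 2 * n:
        raise ValueError(
            "could not appose leaflets: no stacking distance links every "
            "facing strand without core overlap"
        )
    _, pos, box = best

    hbonds = []
    neighbor_pairs = []
    for base in (0, n):
        for k in range(n - 1):
            hb = _intended_hbonds(pos, topo, box, base + k, base + k + 1, table)
            hbonds.extend(hb)
            neighbor_pairs.append((base + k, base + k + 1))

    fixture = SheetFixture(
        topology=topo,
        positions=pos,
        box_side=box,
        hbonds=hbonds,
        neighbor_pairs=neighbor_pairs,
    )
    members = set(range(2 * n))
    if len(members) <= 5:
        fixture.expected_oligomers = [members]
    else:
        fixture.expected_fibrils = [members]
    return fixture


# ---------------------------------------------------------------------------
# schedule-driven toy trajectories


def make_kinetics_toy(
    n_peptides: int,
    schedule: Sequence[tuple[float, int, int]],
    peptide: PeptideSequence | None = None,
    table: InteractionTable | None = None,
) -> tuple[Trajectory, "AssemblyKineticsGroundTruth"]:
    """Synthetic trajectory whose cluster time series is known exactly.

    ``schedule`` is a list of association events ``(time, i, j)``: at
    ``time`` the free peptide ``i`` joins the cluster containing ``j``.
    Snapshots are emitted at t=0 and after each event; clusters are laid
    out as ideal sheets on a sparse lattice so the association graph
    reproduces the schedule exactly.

    Returns the trajectory plus the ground-truth series.
    """
    table = table or default_table()
    peptide = peptide or default_scaffold()
    if n_peptides < 1:
        raise ValueError("need at least one peptide")

    # validate schedule and build the partition after each event
    parent = list(range(n_peptides))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    partitions = []
    joined_once: set[int] = set()
    last_t = -math.inf
    current = [{i} for i in range(n_peptides)]

    def snapshot_partition():
        roots: dict[int, set[int]] = {}
        for i in range(n_peptides):
            roots.setdefault(find(i), set()).add(i)
        return list(roots.values())

    partitions.append((0.0, snapshot_partition()))
    for t, i, j in schedule:
        if t < last_t:
            raise ValueError("schedule times must be non-decreasing")
        last_t = t
        if not (0 <= i < n_peptides and 0 <= j < n_peptides):
            raise ValueError(f"peptide index out of range in event {(t, i, j)}")
        if i in joined_once:
            raise ValueError(f"peptide {i} joins twice")
        if find(i) == find(j):
            raise ValueError(f"peptides {i} and {j} already connected")
        joined_once.add(i)
        parent[find(i)] = find(j)
        partitions.append((float(t), snapshot_partition()))

    topo = build_system_topology([(peptide, n_peptides)], table)
    tmpl = chain_template(peptide)
    n_beads_chain = 4 * len(peptide)

    # lattice spacing comfortably beyond every interaction range even
    # for the largest possible cluster (strand stacking grows linearly)
    spacing = 60.0 + 4.2 * n_peptides
    side_cells = int(math.ceil(math.sqrt(n_peptides))) + 1

    times = []
    frames = []
    for t, parts in partitions:
        pos = np.zeros((topo.n_beads, 3))
        for c_idx, members in enumerate(sorted(parts, key=min)):
            cx = (c_idx % side_cells) * spacing
            cy = (c_idx // side_cells) * spacing
            for s_idx, pep_id in enumerate(sorted(members)):
                strand = tmpl + np.array(
                    [
                        cx + s_idx * STRAND_OFFSET[0],
                        cy + s_idx * STRAND_OFFSET[1],
                        0.0,
                    ]
                )
                pos[
                    pep_id * n_beads_chain : (pep_id + 1) * n_beads_chain
                ] = strand
        pos -= pos.min(axis=0)
        times.append(t)
        frames.append(pos)

    span = max(f.max() for f in frames)
    box = float(span + 60.0)
    frames = [f + 30.0 for f in frames]
    S = len(frames)
    traj = Trajectory(
        topology=topo,
        box_side=box,
        times=np.array(times),
        positions=np.array(frames),
        hb_partner=np.full((S, topo.n_beads), -1, dtype=np.int64),
        kinetic=np.zeros(S),
        potential=np.zeros(S),
        collisions=np.zeros(S, dtype=np.int64),
    )

    gt_free, gt_olig, gt_fib = [], [], []
    for _, parts in partitions:
        sizes = [len(p) for p in parts]
        gt_free.append(sum(1 for s in sizes if s == 1))
        gt_olig.append(sum(s for s in sizes if 2 <= s <= 5))
        gt_fib.append(sum(s for s in sizes if s > 5))
    gt = AssemblyKineticsGroundTruth(
        times=np.array(times),
        n_free=np.array(gt_free),
        n_in_oligomers=np.array(gt_olig),
        n_in_fibrils=np.array(gt_fib),
    )
    return traj, gt


@dataclass(frozen=True)
class AssemblyKineticsGroundTruth:
    times: np.ndarray
    n_free: np.ndarray
    n_in_oligomers: np.ndarray
    n_in_fibrils: np.ndarray
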