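"""Event-driven molecular dynamics in the canonical ensemble.

Beads fly ballistically between analytically predicted events -- hard
core collisions, square-well edge crossings, pseudo-bond limits,
directional hydrogen-bond formation/breakage -- in a cubic periodic box
under the minimum-image convention.  An Andersen thermostat (stochastic
"ghost" velocity resampling) maintains the reduced temperature
``T* = kB*T/eps_HB``.

Reduced units: length A, energy eps_HB, mass amu; velocities are in
A per reduced time unit with kB = 1, so Maxwell-Boltzmann components
have variance ``T*/m``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _core
from .forcefield import (
    InteractionTable,
    SystemTopology,
    build_system_topology,
    default_table,
)
from .sequence_model import PeptideSequence

__all__ = [
    "SimulationState",
    "Event",
    "Trajectory",
    "concentration",
    "init_system",
    "next_event",
    "resolve_event",
    "run",
    "check_state",
    "kinetic_temperature",
    "microseconds_estimate",
]

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Reporting-only calibration: at the full experimental simulation scale
#: (96 x 11-mer peptides, 4224 beads) 2e11 collisions correspond to
#: roughly 16 us of physical time.  Internal logic never uses this.
US_PER_COLLISION_FULL_SCALE = 16.0 / 2.0e11
FULL_SCALE_BEADS = 4224

_EVENT_NAMES = {
    _core.EV_CORE: "core_collision",
    _core.EV_BOND_LO: "bond_limit",
    _core.EV_BOND_HI: "bond_limit",
    _core.EV_WELL_IN: "well_capture",
    _core.EV_WELL_OUT: "well_escape",
    _core.EV_HB_IN: "hb_form",
    _core.EV_HB_OUT: "hb_break",
    _core.EV_CELL: "cell_crossing",
}


def concentration(n_peptides: int, box_side: float) -> float:
    """Peptide concentration in mM for a cubic box side in Angstrom."""
    if box_side <= 0:
        raise ValueError("box_side must be positive")
    litres = (box_side * 1.0e-9) ** 3  # A^3 -> dm^3
    return 1.0e3 * n_peptides / (N_AVOGADRO * litres)


@dataclass
class SimulationState:
    """Instantaneous microstate of the simulation."""

    positions: np.ndarray       # (N, 3) A, wrapped into [0, box)
    velocities: np.ndarray      # (N, 3) reduced
    box_side: float
    time: float = 0.0
    collision_count: int = 0
    ghost_count: int = 0
    hb_partner: np.ndarray | None = None  # (N,) bead index or -1
    T_star: float = 0.2
    seed: int = 0
    topology: SystemTopology | None = None

    def __post_init__(self) -> None:
        if self.hb_partner is None:
            self.hb_partner = np.full(len(self.positions), -1, dtype=np.int64)

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    def copy(self) -> "SimulationState":
        return replace(
            self,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            hb_partner=self.hb_partner.copy(),
        )


@dataclass(frozen=True)
class Event:
    """A predicted discontinuity: absolute time, kind, participant beads."""

    time: float
    kind: str
    participants: tuple[int, ...]


@dataclass
class Trajectory:
    """Snapshots plus counters emitted by :func:`run`."""

    topology: SystemTopology
    box_side: float
    times: np.ndarray           # (S,)
    positions: np.ndarray       # (S, N, 3)
    hb_partner: np.ndarray      # (S, N)
    kinetic: np.ndarray         # (S,) eps_HB
    potential: np.ndarray       # (S,) eps_HB
    collisions: np.ndarray      # (S,) cumulative two-body events
    n_collisions: int = 0
    n_ghosts: int = 0
    n_crossings: int = 0
    n_hb_form: int = 0
    n_hb_break: int = 0
    final_state: SimulationState | None = None

    @property
    def n_snapshots(self) -> int:
        return len(self.times)

    def total_energy(self) -> np.ndarray:
        return self.kinetic + self.potential


# ---------------------------------------------------------------------------
# packing the topology for the kernels


class _Packed:
    """Flat array view of a SystemTopology for the numba kernels."""

    def __init__(self, topo: SystemTopology):
        table = topo.table
        N = topo.n_beads
        self.itype = topo.itype.astype(np.int64)
        self.kind = topo.bead_kind.astype(np.int64)
        self.chain_id = topo.chain_id.astype(np.int64)
        self.resix = topo.residue_index.astype(np.int64)
        self.mass = topo.masses.astype(np.float64)

        # core contact matrix over interaction types
        labels = topo.type_labels
        nt = len(labels)
        diam = np.empty(nt)
        from .forcefield import BACKBONE_DIAMETERS
        from .sequence_model import RESIDUES

        for k, lbl in enumerate(labels):
            if lbl.startswith("R:"):
                diam[k] = RESIDUES[lbl[2:]].sidechain_diameter
            else:
                diam[k] = BACKBONE_DIAMETERS[lbl]
        contact = 0.5 * (diam[:, None] + diam[None, :])
        self.core2 = contact**2
        self.well_edge2 = topo.well_edge**2
        self.well_depth = topo.well_depth.copy()
        self.squeeze2 = table.squeeze_factor**2
        self.hbd2 = table.hb_distance**2
        self.hb_depth = table.hb_depth
        self.aux_min2 = table.hb_aux_min**2

        # bonds -> CSR, both directions
        adj: list[list[tuple[int, float, float]]] = [[] for _ in range(N)]
        for (i, j), lo, hi in zip(topo.bonds, topo.bond_lo, topo.bond_hi):
            adj[i].append((j, lo, hi))
            adj[j].append((i, lo, hi))
        self.bnd_ptr = np.zeros(N + 1, dtype=np.int64)
        idx, lo2, hi2 = [], [], []
        for i in range(N):
            for j, lo, hi in adj[i]:
                idx.append(j)
                lo2.append(lo * lo)
                hi2.append(hi * hi)
            self.bnd_ptr[i + 1] = len(idx)
        self.bnd_idx = np.array(idx, dtype=np.int64)
        self.bnd_lo2 = np.array(lo2)
        self.bnd_hi2 = np.array(hi2)

        # same/adjacent-residue non-bonded pairs -> reduced-core exclusions
        bonded = {tuple(sorted(p)) for p in map(tuple, topo.bonds)}
        exc: list[list[int]] = [[] for _ in range(N)]
        offset = 0
        for t in topo.chain_topologies:
            n = t.n_beads
            for a in range(n):
                for b in range(a + 1, n):
                    if abs(int(t.residue_index[a]) - int(t.residue_index[b])) <= 1:
                        gi, gj = offset + a, offset + b
                        if (gi, gj) not in bonded:
                            exc[gi].append(gj)
                            exc[gj].append(gi)
            offset += n
        self.exc_ptr = np.zeros(N + 1, dtype=np.int64)
        eidx = []
        for i in range(N):
            eidx.extend(exc[i])
            self.exc_ptr[i + 1] = len(eidx)
        self.exc_idx = np.array(eidx, dtype=np.int64)

        # hydrogen-bond flanking beads (directionality constraint)
        self.flank1 = np.full(N, -1, dtype=np.int64)
        self.flank2 = np.full(N, -1, dtype=np.int64)
        offset = 0
        for t in topo.chain_topologies:
            L = len(t.sequence)
            for r in range(L):
                nh = offset + 4 * r
                co = offset + 4 * r + 2
                self.flank1[nh] = nh + 1  # CA of same residue
                if r > 0:
                    self.flank2[nh] = nh - 2  # CO of previous residue
                self.flank1[co] = co - 1  # CA of same residue
                if r < L - 1:
                    self.flank2[co] = co + 2  # NH of next residue
            offset += t.n_beads

        self.max_range = float(
            np.sqrt(
                max(
                    self.hbd2,
                    self.core2.max(),
                    self.well_edge2.max(),
                    self.bnd_hi2.max(),
                )
            )
        )

    def check_box(self, box_side: float) -> None:
        if box_side < 2.0 * self.max_range:
            raise ValueError(
                f"box side {box_side} too small for interaction range "
                f"{self.max_range} under minimum image"
            )


def _packed(topo: SystemTopology) -> _Packed:
    cached = getattr(topo, "_packed_cache", None)
    if cached is None:
        cached = _Packed(topo)
        topo._packed_cache = cached
    return cached


# ---------------------------------------------------------------------------
# system construction


def maxwell_boltzmann_velocities(
    masses: np.ndarray, T_star: float, rng: np.random.Generator
) -> np.ndarray:
    """MB velocities at T* with the centre-of-mass drift removed."""
    v = rng.normal(size=(len(masses), 3)) * np.sqrt(T_star / masses)[:, None]
    p = (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v - p[None, :]


def init_system(
    species: Sequence[tuple[PeptideSequence, int]],
    box_side: float,
    T_star: float,
    seed: int,
    table: InteractionTable | None = None,
    max_retries: int = 5000,
) -> SimulationState:
    """Place peptides at random positions/orientations in a periodic box.

    Each chain is inserted as its extended template with a uniformly
    random rotation; insertions that overlap any already-placed bead's
    hard core are rejected and retried.  Velocities are drawn from the
    Maxwell-Boltzmann distribution at ``T*`` with zero net momentum.
    Deterministic for a given seed.
    """
    table = table or default_table()
    topo = build_system_topology(species, table)
    pk = _packed(topo)
    pk.check_box(box_side)
    rng = np.random.default_rng(seed)

    placed: list[np.ndarray] = []
    placed_diam: list[np.ndarray] = []
    for c, chain_topo in enumerate(topo.chain_topologies):
        tmpl = chain_topo.template - chain_topo.template.mean(axis=0)
        diam_c = chain_topo.hs_diameters
        ok = False
        for _ in range(max_retries):
            # uniform random rotation from a random unit quaternion
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            R = np.array(
                [
                    [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                    [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                    [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
                ]
            )
            centre = rng.uniform(0.0, box_side, size=3)
            coords = (tmpl @ R.T + centre) % box_side
            clash = False
            for other, od in zip(placed, placed_diam):
                d = coords[:, None, :] - other[None, :, :]
                d -= box_side * np.round(d / box_side)
                dist = np.sqrt((d**2).sum(axis=2))
                cont = 0.5 * (diam_c[:, None] + od[None, :])
                if (dist < cont + 0.05).any():
                    clash = True
                    break
            if not clash:
                placed.append(coords)
                placed_diam.append(diam_c)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"packing failed after {max_retries} retries: placed "
                f"{len(placed)} of {topo.n_chains} chains in box {box_side} A"
            )

    pos = np.concatenate(placed, axis=0)
    vel = maxwell_boltzmann_velocities(topo.masses, T_star, rng)
    return SimulationState(
        positions=pos,
        velocities=vel,
        box_side=box_side,
        T_star=T_star,
        seed=int(seed),
        topology=topo,
    )


# ---------------------------------------------------------------------------
# event prediction / resolution API


def next_event(
    state: SimulationState,
    topology: SystemTopology | None = None,
    include_crossings: bool = True,
) -> Event:
    """Globally earliest upcoming event (excluding thermostat ghosts).

    Runs the engine's own scheduler path (cell-list pruned pair
    prediction); cell-boundary crossings of the neighbour bookkeeping
    are reported with kind ``cell_crossing`` unless
    ``include_crossings`` is false.
    """
    topo = topology or state.topology
    pk = _packed(topo)
    pk.check_box(state.box_side)
    local_t = np.full(state.n_beads, state.time)
    te, i, j, code = _core.first_event_core(
        state.positions.astype(np.float64),
        state.velocities.astype(np.float64),
        local_t,
        pk.itype, pk.kind, pk.chain_id, pk.resix,
        pk.bnd_ptr, pk.bnd_idx, pk.bnd_lo2, pk.bnd_hi2,
        pk.exc_ptr, pk.exc_idx,
        pk.core2, pk.well_edge2, pk.squeeze2,
        pk.hbd2, state.hb_partner,
        float(state.box_side), float(state.time), include_crossings,
    )
    if i < 0:
        return Event(time=math.inf, kind="none", participants=())
    participants = (int(i),) if j < 0 else (int(i), int(j))
    return Event(time=float(te), kind=_EVENT_NAMES[code], participants=participants)


def _min_image(d: np.ndarray, L: float) -> np.ndarray:
    return d - L * np.round(d / L)


def resolve_event(
    state: SimulationState,
    event: Event,
    topology: SystemTopology | None = None,
) -> SimulationState:
    """Apply the impulsive update for a two-body event; returns a new state.

    Reference implementation of the collision rules in plain numpy:
    elastic reflection at hard cores and pseudo-bond limits; square-well
    crossings exchange kinetic and well energy along the line of
    centres, with an elastic bounce when the radial kinetic energy
    cannot pay the step; hydrogen-bond formation additionally checks the
    directional auxiliary constraints and the one-bond-per-site
    registry.  Momentum is conserved exactly; energy for all non-ghost
    events.
    """
    topo = topology or state.topology
    pk = _packed(topo)
    new = state.copy()
    dt = event.time - state.time
    if dt < 0:
        raise ValueError("event lies in the past")
    new.positions = (new.positions + new.velocities * dt) % state.box_side
    new.time = event.time
    if event.kind in ("cell_crossing", "none"):
        return new
    if len(event.participants) != 2:
        raise ValueError(f"cannot resolve event of kind {event.kind}")
    i, j = event.participants
    L = state.box_side
    d = _min_image(new.positions[i] - new.positions[j], L)
    r = np.linalg.norm(d)
    n = d / r
    vrel = new.velocities[i] - new.velocities[j]
    vr = float(vrel @ n)
    mi, mj = pk.mass[i], pk.mass[j]
    mu = mi * mj / (mi + mj)

    def reflect() -> None:
        p = -2.0 * mu * vr
        new.velocities[i] += p * n / mi
        new.velocities[j] -= p * n / mj

    def cross(dU: float) -> bool:
        need = vr * vr - 2.0 * dU / mu
        if dU > 0.0 and need <= 0.0:
            reflect()
            return False
        vr_new = math.sqrt(need) * (1.0 if vr > 0 else -1.0)
        p = mu * (vr_new - vr)
        new.velocities[i] += p * n / mi
        new.velocities[j] -= p * n / mj
        return True

    kind = event.kind
    if kind in ("core_collision", "bond_limit", "well_bounce"):
        reflect()
    elif kind == "well_capture":
        cross(float(pk.well_depth[pk.itype[i], pk.itype[j]]))
    elif kind == "well_escape":
        cross(-float(pk.well_depth[pk.itype[i], pk.itype[j]]))
    elif kind == "hb_form":
        nh, co = (i, j) if topo.bead_kind[i] == 0 else (j, i)
        free = new.hb_partner[nh] < 0 and new.hb_partner[co] < 0
        aux_ok = True
        for f in (pk.flank1[nh], pk.flank2[nh]):
            if f >= 0:
                df = _min_image(new.positions[f] - new.positions[co], L)
                if (df @ df) < pk.aux_min2:
                    aux_ok = False
        for f in (pk.flank1[co], pk.flank2[co]):
            if f >= 0:
                df = _min_image(new.positions[f] - new.positions[nh], L)
                if (df @ df) < pk.aux_min2:
                    aux_ok = False
        if free and aux_ok:
            if cross(-pk.hb_depth):
                new.hb_partner[nh] = co
                new.hb_partner[co] = nh
        # else: transparent crossing, no impulse
    elif kind == "hb_break":
        if new.hb_partner[i] != j:
            raise RuntimeError(
                "registry inconsistency: escape of an unoccupied hydrogen "
                f"bond between beads {i} and {j}"
            )
        if cross(pk.hb_depth):
            new.hb_partner[i] = -1
            new.hb_partner[j] = -1
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    return new


# ---------------------------------------------------------------------------
# the event loop


def run(
    state: SimulationState,
    n_collisions: int,
    snapshot_every: int = 0,
    topology: SystemTopology | None = None,
    ghost_rate: float = 0.002,
    count_ghosts: bool = False,
    seed: int | None = None,
) -> Trajectory:
    """Advance the event loop for ``n_collisions`` two-body events.

    ``ghost_rate`` is the Andersen resampling rate per bead per reduced
    time unit (0 disables the thermostat); ghost collisions are counted
    separately unless ``count_ghosts``.  ``snapshot_every = 0`` records
    only the initial and final snapshots.  The input state is not
    modified; the returned trajectory carries the final state.
    Deterministic given the seed (defaults to the state's seed).
    """
    if n_collisions < 0:
        raise ValueError("n_collisions must be >= 0")
    topo = topology or state.topology
    pk = _packed(topo)
    pk.check_box(state.box_side)
    core_seed = int(
        (state.seed if seed is None else seed) % (2**31 - 1)
    )

    work = state.copy()
    pos = work.positions.astype(np.float64)
    vel = work.velocities.astype(np.float64)
    local_t = np.full(work.n_beads, float(work.time))
    hb = work.hb_partner.astype(np.int64)

    (
        snap_t, snap_pos, snap_hb, snap_ke, snap_pe, snap_coll,
        t_end, n_coll, n_ghost, n_cross, n_hb_form, n_hb_break,
        n_iters, n_stale_owner, n_stale_partner, kind_counts,
    ) = _core.run_core(
        pos, vel, local_t, pk.mass,
        pk.itype, pk.kind, pk.chain_id, pk.resix,
        pk.bnd_ptr, pk.bnd_idx, pk.bnd_lo2, pk.bnd_hi2,
        pk.exc_ptr, pk.exc_idx,
        pk.core2, pk.well_edge2, pk.well_depth, pk.squeeze2,
        pk.hbd2, pk.hb_depth, pk.aux_min2, pk.flank1, pk.flank2, hb,
        float(state.box_side), float(state.T_star), float(ghost_rate),
        int(n_collisions), int(snapshot_every), bool(count_ghosts),
        core_seed, float(state.time),
    )

    final = SimulationState(
        positions=pos % state.box_side,
        velocities=vel,
        box_side=state.box_side,
        time=float(t_end),
        collision_count=state.collision_count + int(n_coll),
        ghost_count=state.ghost_count + int(n_ghost),
        hb_partner=hb,
        T_star=state.T_star,
        seed=state.seed,
        topology=topo,
    )
    return Trajectory(
        topology=topo,
        box_side=state.box_side,
        times=snap_t,
        positions=snap_pos % state.box_side,
        hb_partner=snap_hb,
        kinetic=snap_ke,
        potential=snap_pe,
        collisions=snap_coll,
        n_collisions=int(n_coll),
        n_ghosts=int(n_ghost),
        n_crossings=int(n_cross),
        n_hb_form=int(n_hb_form),
        n_hb_break=int(n_hb_break),
        final_state=final,
    )


# ---------------------------------------------------------------------------
# diagnostics


def kinetic_temperature(state: SimulationState) -> float:
    """Instantaneous kinetic temperature 2*KE/(3N) in eps_HB units."""
    m = state.topology.masses
    ke = 0.5 * float((m[:, None] * state.velocities**2).sum())
    return 2.0 * ke / (3.0 * state.n_beads)


def microseconds_estimate(n_collisions: int, n_beads: int) -> float:
    """Rough physical-time estimate from the full-scale calibration.

    Scales the collisions-per-microsecond rate of the full 4224-bead
    systems linearly with bead count.  Reporting only.
    """
    return n_collisions * US_PER_COLLISION_FULL_SCALE * FULL_SCALE_BEADS / n_beads


def check_state(
    state: SimulationState,
    topology: SystemTopology | None = None,
    tol: float = 1.0e-7,
) -> list[str]:
    """Verify the hard invariants of a microstate; returns violations.

    Checks: no non-bonded pair inside its hard core (reduced core for
    same/adjacent-residue pairs), every pseudo-bond inside its window.
    An empty list means the state is valid.
    """
    topo = topology or state.topology
    pk = _packed(topo)
    L = state.box_side
    pos = state.positions
    N = len(pos)
    out: list[str] = []

    d = pos[:, None, :] - pos[None, :, :]
    d -= L * np.round(d / L)
    dist = np.sqrt((d**2).sum(axis=2))

    bonded = np.zeros((N, N), dtype=bool)
    for (i, j), lo, hi in zip(topo.bonds, topo.bond_lo, topo.bond_hi):
        bonded[i, j] = bonded[j, i] = True
        r = dist[i, j]
        if r < lo * (1 - tol) or r > hi * (1 + tol):
            out.append(f"bond {i}-{j}: length {r:.4f} outside [{lo:.4f}, {hi:.4f}]")

    excluded = np.zeros((N, N), dtype=bool)
    for i in range(N):
        for k in range(pk.exc_ptr[i], pk.exc_ptr[i + 1]):
            excluded[i, pk.exc_idx[k]] = True

    contact = np.sqrt(pk.core2[pk.itype[:, None], pk.itype[None, :]])
    limit = np.where(excluded, contact * np.sqrt(pk.squeeze2), contact)
    iu, ju = np.triu_indices(N, k=1)
    mask = ~bonded[iu, ju]
    bad = mask & (dist[iu, ju] < limit[iu, ju] * (1 - tol))
    for i, j in zip(iu[bad], ju[bad]):
        out.append(
            f"core overlap {i}-{j}: {dist[i, j]:.4f} < {limit[i, j]:.4f}"
        )
    return out
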