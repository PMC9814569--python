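"""Independent brute-force oracles shared by the test suite.

These deliberately re-derive event times and cluster partitions with
straightforward all-pairs / flood-fill logic, independent of the
engine's cell-list scheduler and of networkx.
"""

import math

import numpy as np

from catchsim import dmd_engine as de
from catchsim.forcefield import KIND_CO, KIND_NH
from catchsim.sequence_model import parse_sequence


# ---------------------------------------------------------------------------
# brute-force all-pairs event oracle (independent of the engine's
# cell-list / heap scheduler path)


def _mic(d, L):
    return d - L * np.round(d / L)


def _hit_inner(r2, b, a, d2):
    """First time |r + v t|^2 = d2 while approaching, else None."""
    if b >= 0 or a == 0:
        return None
    if r2 <= d2:
        return 0.0
    disc = b * b - a * (r2 - d2)
    if disc <= 0:
        return None
    return (r2 - d2) / (-b + math.sqrt(disc))


def _hit_outer(r2, b, a, d2):
    disc = b * b + a * (d2 - r2)
    return (-b + math.sqrt(max(disc, 0.0))) / a


def brute_force_next_event(state):
    """Earliest two-body discontinuity by scanning every bead pair."""
    topo = state.topology
    table = topo.table
    pk = de._packed(topo)
    L = state.box_side
    N = state.n_beads
    pos, vel = state.positions, state.velocities
    bonds = {}
    for (i, j), lo, hi in zip(topo.bonds, topo.bond_lo, topo.bond_hi):
        bonds[(min(i, j), max(i, j))] = (lo * lo, hi * hi)

    best = (math.inf, None)
    for i in range(N):
        for j in range(i + 1, N):
            d = _mic(pos[i] - pos[j], L)
            v = vel[i] - vel[j]
            a = float(v @ v)
            if a < 1e-30:
                continue
            r2 = float(d @ d)
            b = float(d @ v)
            contact2 = float(pk.core2[pk.itype[i], pk.itype[j]])
            same_chain = topo.chain_id[i] == topo.chain_id[j]
            dres = abs(int(topo.residue_index[i]) - int(topo.residue_index[j]))

            if (i, j) in bonds:
                lo2, hi2 = bonds[(i, j)]
                t = _hit_inner(r2, b, a, lo2)
                if t is None:
                    t = _hit_outer(r2, b, a, hi2)
                cand = t
            elif same_chain and dres <= 1:
                cand = _hit_inner(r2, b, a, pk.squeeze2 * contact2)
            else:
                ki, kj = topo.bead_kind[i], topo.bead_kind[j]
                is_hb_pair = {ki, kj} == {KIND_NH, KIND_CO}
                if is_hb_pair and same_chain and dres < 4:
                    cand = _hit_inner(r2, b, a, contact2)
                elif is_hb_pair:
                    hbd2 = table.hb_distance**2
                    if state.hb_partner[i] == j:
                        cand = _hit_inner(r2, b, a, contact2)
                        if cand is None:
                            cand = _hit_outer(r2, b, a, hbd2)
                    elif r2 < hbd2:
                        cand = _hit_inner(r2, b, a, contact2)
                    else:
                        cand = _hit_inner(r2, b, a, hbd2)
                else:
                    e2 = float(pk.well_edge2[pk.itype[i], pk.itype[j]])
                    if e2 > 0:
                        if r2 < e2:
                            cand = _hit_inner(r2, b, a, contact2)
                            if cand is None:
                                cand = _hit_outer(r2, b, a, e2)
                        else:
                            cand = _hit_inner(r2, b, a, e2)
                    else:
                        cand = _hit_inner(r2, b, a, contact2)
            if cand is not None and state.time + cand < best[0]:
                best = (state.time + cand, (i, j))
    return best


def small_state(seed, box=46.0):
    """A randomized few-chain state: short peptides, random velocities."""
    species = [
        (parse_sequence("QF", peptide_id="QF"), 1),
        (parse_sequence("K", peptide_id="K"), 1),
        (parse_sequence("E", peptide_id="E"), 1),
    ]
    st = de.init_system(species, box_side=box, T_star=0.2, seed=seed)
    rng = np.random.default_rng(seed + 77)
    st.velocities = rng.normal(scale=0.3, size=st.velocities.shape)
    return st




def flood_fill_partition(n_nodes, edges):
    """Brute-force connected components by breadth-first flood fill."""
    adj = {i: set() for i in range(n_nodes)}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    seen = set()
    comps = []
    for start in range(n_nodes):
        if start in seen:
            continue
        comp = set()
        queue = [start]
        while queue:
            x = queue.pop()
            if x in comp:
                continue
            comp.add(x)
            queue.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)
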