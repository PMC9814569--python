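"""Peptide sequences, formal charges, and charge-based design metrics.

The co-assembly design space studied here is built from 11-mer
glutamine/phenylalanine scaffolds (the Q11 / CATCH family) in which
glutamines are swapped for lysine (+) or glutamate (-) to set the net
charge of each species.  This module represents such sequences, assigns
formal charges at neutral pH, and computes the simple Coulomb-law
metrics used to reason about co-assembly versus self-association.

Charges are integer formal charges at pH 7.4: K/R/ornithine(O) = +1,
E/D = -1, everything else (including histidine) 0.  No pKa titration is
performed; termini contribute +1/-1 only when uncapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ResidueSpec",
    "PeptideSequence",
    "RESIDUES",
    "parse_sequence",
    "net_charge",
    "coulomb_attraction_ratio",
    "self_association_risk",
    "read_fasta",
]


@dataclass(frozen=True)
class ResidueSpec:
    """Per-residue data: chemistry (charge, class) and coarse-grained geometry.

    Geometry fields feed the four-bead model: one sidechain sphere per
    residue with a hard-sphere diameter, a canonical Ca-to-sidechain
    distance, and a per-bead sidechain mass.  The R-NH / R-Ca / R-CO
    pseudo-bond lengths are derived from the canonical extended-backbone
    geometry (see :func:`catchsim.forcefield.backbone_template`).
    """

    code: str
    name: str
    formal_charge: int
    hydrophobic: bool
    interaction_class: str  # hydrophobic | cation | anion | polar
    sidechain_diameter: float  # Angstrom, hard-sphere
    r_calpha_distance: float  # Angstrom, Ca -> sidechain centroid
    sidechain_mass: float  # amu

    def __post_init__(self) -> None:
        if self.sidechain_diameter <= 0 or self.r_calpha_distance <= 0:
            raise ValueError(f"non-positive geometry for residue {self.code!r}")
        if self.sidechain_mass <= 0:
            raise ValueError(f"non-positive mass for residue {self.code!r}")


def _spec(code, name, charge, hydro, iclass, diam, rca, mass):
    return ResidueSpec(code, name, charge, hydro, iclass, diam, rca, mass)


# Class-level defaults: effective van-der-Waals sidechain diameters,
# Ca-sidechain-centroid distances, and chemical-group masses.  These are
# plausible coarse-grained values for the four-bead representation; a
# user-supplied interaction table can override the energetics entirely.
RESIDUES: dict[str, ResidueSpec] = {
    s.code: s
    for s in [
        _spec("A", "alanine", 0, True, "hydrophobic", 2.7, 1.55, 15.0),
        _spec("C", "cysteine", 0, True, "hydrophobic", 3.2, 2.0, 47.0),
        _spec("D", "aspartate", -1, False, "anion", 3.5, 2.5, 59.0),
        _spec("E", "glutamate", -1, False, "anion", 3.8, 3.1, 73.0),
        _spec("F", "phenylalanine", 0, True, "hydrophobic", 4.4, 3.4, 91.0),
        _spec("G", "glycine", 0, False, "polar", 2.0, 1.0, 1.0),
        _spec("H", "histidine", 0, False, "polar", 4.0, 3.1, 81.0),
        _spec("I", "isoleucine", 0, True, "hydrophobic", 3.9, 2.3, 57.0),
        _spec("K", "lysine", +1, False, "cation", 3.9, 3.5, 72.0),
        _spec("L", "leucine", 0, True, "hydrophobic", 3.9, 2.6, 57.0),
        _spec("M", "methionine", 0, True, "hydrophobic", 3.9, 2.9, 75.0),
        _spec("N", "asparagine", 0, False, "polar", 3.6, 2.5, 58.0),
        _spec("O", "ornithine", +1, False, "cation", 3.7, 3.0, 58.0),
        _spec("P", "proline", 0, False, "polar", 3.6, 1.9, 41.0),
        _spec("Q", "glutamine", 0, False, "polar", 3.9, 3.1, 72.0),
        _spec("R", "arginine", +1, False, "cation", 4.3, 4.1, 100.0),
        _spec("S", "serine", 0, False, "polar", 2.9, 1.9, 31.0),
        _spec("T", "threonine", 0, False, "polar", 3.4, 1.9, 45.0),
        _spec("V", "valine", 0, True, "hydrophobic", 3.6, 2.0, 43.0),
        _spec("W", "tryptophan", 0, True, "hydrophobic", 4.8, 3.9, 130.0),
        _spec("Y", "tyrosine", 0, False, "polar", 4.5, 3.8, 107.0),
    ]
}


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide species: ordered residues plus terminal-cap state.

    Both caps default to True (N-terminal acetylation, C-terminal
    amidation), matching how fibrillizing designer peptides in this
    family are synthesized.
    """

    id: str
    residues: tuple[ResidueSpec, ...]
    n_term_acetylated: bool = True
    c_term_amidated: bool = True

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("empty sequence")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.code for r in self.residues)

    @property
    def residue_charges(self) -> tuple[int, ...]:
        return tuple(r.formal_charge for r in self.residues)

    @property
    def net_charge(self) -> int:
        q = sum(self.residue_charges)
        if not self.n_term_acetylated:
            q += 1
        if not self.c_term_amidated:
            q -= 1
        return q

    def with_id(self, new_id: str) -> "PeptideSequence":
        return replace(self, id=new_id)


def parse_sequence(
    seq: str,
    *,
    peptide_id: str | None = None,
    n_term_acetylated: bool = True,
    c_term_amidated: bool = True,
) -> PeptideSequence:
    """Parse a one-letter sequence string into a :class:`PeptideSequence`.

    Accepts the 20 standard residues plus ``O`` (ornithine, +1).

    Raises
    ------
    ValueError
        If the sequence is empty or contains an unknown residue code;
        the message names the offending character and its 1-based
        position.
    """
    seq = seq.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    residues = []
    for pos, ch in enumerate(seq, start=1):
        try:
            residues.append(RESIDUES[ch])
        except KeyError:
            raise ValueError(
                f"unknown residue code {ch!r} at position {pos}"
            ) from None
    return PeptideSequence(
        id=peptide_id or seq,
        residues=tuple(residues),
        n_term_acetylated=n_term_acetylated,
        c_term_amidated=c_term_amidated,
    )


def net_charge(p: PeptideSequence) -> int:
    """Formal net charge (e) at pH 7.4, including uncapped-termini charges."""
    return p.net_charge


def coulomb_attraction_ratio(
    pair1: tuple[PeptideSequence, PeptideSequence],
    pair2: tuple[PeptideSequence, PeptideSequence],
) -> float:
    """Ratio of Coulombic attraction magnitudes between two peptide pairs.

    By Coulomb's law at equal separation and medium, the force magnitude
    between two point charges is proportional to ``|q_A * q_B|``; the
    returned value is ``|q1A*q1B| / |q2A*q2B|`` using formal net charges.
    For the (+6, -6) pair versus the (+4, -4) pair this is 36/16 = 2.25.

    Raises
    ------
    ValueError
        If either pair has a zero charge product (the comparison is
        undefined; the denominator case is the division by zero).
    """
    q1 = net_charge(pair1[0]) * net_charge(pair1[1])
    q2 = net_charge(pair2[0]) * net_charge(pair2[1])
    if q2 == 0:
        raise ValueError("zero charge product in denominator pair")
    if q1 == 0:
        raise ValueError("zero charge product in numerator pair")
    return abs(q1) / abs(q2)


def self_association_risk(p: PeptideSequence) -> str:
    """Heuristic self-association label: ``resists``/``prone``/``indeterminate``.

    Encodes the empirical design rule observed for this peptide family:
    in ionic aqueous buffer, two glutamates are already enough to keep a
    peptide from self-associating, whereas two lysines are not (three or
    more cationic residues are needed).  Mixed/zwitterionic sequences
    fall outside the rule.  This is a documented heuristic, not a
    physical model.
    """
    n_plus = sum(1 for q in p.residue_charges if q > 0)
    n_minus = sum(1 for q in p.residue_charges if q < 0)
    if n_plus > 0 and n_minus > 0:
        return "indeterminate"
    if n_minus >= 2 and n_plus == 0:
        return "resists"
    if n_plus >= 3 and n_minus == 0:
        return "resists"
    if n_plus == 2 and n_minus == 0:
        return "prone"
    return "indeterminate"


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in {"1", "true", "yes", "y"}


def read_fasta(path: str | Path) -> list[PeptideSequence]:
    """Read peptides from FASTA.

    The record id is the species label; optional ``key=value`` tags in
    the description set the cap flags, e.g.::

        >CATCH(6+) n_term_acetylated=true c_term_amidated=true
        KQKFKFKFKQK
    """
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = {}
        for tok in rec.description.split()[1:]:
            if "=" in tok:
                k, v = tok.split("=", 1)
                tags[k] = v
        out.append(
            parse_sequence(
                str(rec.seq),
                peptide_id=rec.id,
                n_term_acetylated=_parse_bool(tags.get("n_term_acetylated", "true")),
                c_term_amidated=_parse_bool(tags.get("c_term_amidated", "true")),
            )
        )
    return out
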