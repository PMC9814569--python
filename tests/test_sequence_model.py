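"""Sequence parsing, formal charges and Coulomb design metrics."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catchsim.sequence_model import (
    RESIDUES,
    coulomb_attraction_ratio,
    net_charge,
    parse_sequence,
    self_association_risk,
)

CODES = "".join(RESIDUES)


class TestParse:
    def test_known_sequence(self):
        p = parse_sequence("EQEFEWEFEQE")
        assert len(p) == 11
        assert p.sequence.count("E") == 6

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            parse_sequence("")

    def test_unknown_code_names_position(self):
        with pytest.raises(ValueError, match=r"'X' at position 3"):
            parse_sequence("QQXFQ")

    def test_lowercase_accepted(self):
        assert parse_sequence("qqkf").sequence == "QQKF"


class TestNetCharge:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("EQEFEWEFEQE", -6),
            ("QQOFOWOFOQQ", +4),
            ("EEFKWKFKEE", -1),
            ("KKEFEWEFKK", +1),
            ("QQQQQQQQQQQ", 0),
        ],
    )
    def test_capped_charges(self, seq, expected):
        assert net_charge(parse_sequence(seq)) == expected

    def test_uncapped_termini_contribute(self):
        p = parse_sequence(
            "QQQQ", n_term_acetylated=False, c_term_amidated=False
        )
        assert net_charge(p) == 0  # +1 - 1
        p = parse_sequence("QQQQ", n_term_acetylated=False)
        assert net_charge(p) == +1

    @given(st.text(alphabet=CODES, min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_reversal_invariance(self, seq):
        assert net_charge(parse_sequence(seq)) == net_charge(
            parse_sequence(seq[::-1])
        )

    @given(
        st.text(alphabet=CODES, min_size=1, max_size=15),
        st.text(alphabet=CODES, min_size=1, max_size=15),
    )
    @settings(max_examples=200, deadline=None)
    def test_additive_under_concatenation(self, a, b):
        assert net_charge(parse_sequence(a + b)) == net_charge(
            parse_sequence(a)
        ) + net_charge(parse_sequence(b))


class TestCoulombRatio:
    def test_six_vs_four(self, family):
        pair6 = (family["CATCH(6+)"], family["CATCH(6-)"])
        pair4 = (family["CATCH(4+)"], family["CATCH(4-)"])
        assert coulomb_attraction_ratio(pair6, pair4) == 2.25

    def test_identity(self, family):
        pair = (family["CATCH(4+)"], family["CATCH(4-)"])
        assert coulomb_attraction_ratio(pair, pair) == 1.0

    def test_two_vs_four(self, family):
        pair2 = (family["CATCH(2+)"], family["CATCH(2-)"])
        pair4 = (family["CATCH(4+)"], family["CATCH(4-)"])
        assert coulomb_attraction_ratio(pair2, pair4) == 0.25

    def test_reciprocal_product_is_one(self, family):
        a = (family["CATCH(6+)"], family["CATCH(6-)"])
        b = (family["CATCH(2+)"], family["CATCH(4-)"])
        assert coulomb_attraction_ratio(a, b) * coulomb_attraction_ratio(
            b, a
        ) == pytest.approx(1.0)

    def test_zero_denominator_rejected(self, family):
        neutral = parse_sequence("QQQQQ")
        pair6 = (family["CATCH(6+)"], family["CATCH(6-)"])
        with pytest.raises(ValueError, match="denominator"):
            coulomb_attraction_ratio(pair6, (neutral, family["CATCH(6-)"]))


class TestSelfAssociationRisk:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("CATCH(2+)", "prone"),        # two lysines are not enough
            ("CATCH(2-)", "resists"),      # two glutamates are
            ("CATCH(4+)", "resists"),
            ("CATCH(6-)", "resists"),
            ("Q11", "indeterminate"),      # zwitterion, outside the rule
        ],
    )
    def test_family_rule(self, family, label, expected):
        assert self_association_risk(family[label]) == expected


class TestResidueTable:
    def test_charge_assignments(self):
        assert {c: RESIDUES[c].formal_charge for c in "KROED"} == {
            "K": 1, "R": 1, "O": 1, "E": -1, "D": -1
        }
        assert RESIDUES["H"].formal_charge == 0

    def test_hydrophobic_classes(self):
        assert RESIDUES["F"].hydrophobic
        assert not any(RESIDUES[c].hydrophobic for c in "QKE")

    def test_geometry_positive(self):
        for spec in RESIDUES.values():
            assert spec.sidechain_diameter > 0
            assert spec.r_calpha_distance > 0
            assert spec.sidechain_mass > 0


def test_fasta_roundtrip(tmp_path, family):
    from catchsim.sequence_model import read_fasta

    path = tmp_path / "seqs.fasta"
    with open(path, "w") as fh:
        for pep in family.values():
            fh.write(
                f">{pep.id} n_term_acetylated=true c_term_amidated=true\n"
                f"{pep.sequence}\n"
            )
    loaded = {p.id: p for p in read_fasta(path)}
    assert loaded.keys() == family.keys()
    for k in family:
        assert loaded[k].sequence == family[k].sequence
        assert loaded[k].net_charge == family[k].net_charge
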