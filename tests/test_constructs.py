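"""Construct modelling: masses, CK2 scanning, substitutions, heptads."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import phosdim as P
from phosdim.chem import UnknownResidueError, WATER_AVERAGE, peptide_mass

AA = "ACDEFGHIKLMNPQRSTVWY"
sequences = st.text(alphabet=AA, min_size=1, max_size=60)


# ---------------------------------------------------------------------------
# Intact mass
# ---------------------------------------------------------------------------

def test_glycine_free_amino_acid_mass():
    g = P.Construct("G", "G")
    assert P.compute_intact_mass(g) == pytest.approx(75.07, abs=0.01)


def test_serine_alanine_residue_difference_is_one_oxygen():
    s = P.compute_intact_mass(P.Construct("S", "S"), P.MassOptions(include_water=False))
    a = P.compute_intact_mass(P.Construct("A", "A"), P.MassOptions(include_water=False))
    assert s - a == pytest.approx(15.9994, abs=1e-3)


@settings(deadline=None, max_examples=50)
@given(sequences, sequences)
def test_mass_additivity(s1, s2):
    """mass(s1 + s2) = mass(s1) + mass(s2) - water, to 1e-6 Da."""
    m12 = peptide_mass(s1 + s2)
    assert m12 == pytest.approx(peptide_mass(s1) + peptide_mass(s2) - WATER_AVERAGE, abs=1e-6)


def test_unknown_residue_reports_position():
    with pytest.raises(UnknownResidueError, match="position 3"):
        P.Construct("bad", "AAXA")


def test_monoisotopic_below_average():
    c = P.Construct("pep", "PEPTIDE")
    avg = P.compute_intact_mass(c, P.MassOptions(scale="average"))
    mono = P.compute_intact_mass(c, P.MassOptions(scale="monoisotopic"))
    assert mono < avg


def test_modification_shifts():
    base = P.Construct("m", "AKSA")
    phos = P.Construct("m", "AKSA", modifications=[P.Modification("phospho", 3)])
    acet = P.Construct("m", "AKSA", modifications=[P.Modification("acetyl", 2)])
    m0 = P.compute_intact_mass(base)
    assert P.compute_intact_mass(phos) - m0 == pytest.approx(79.98, abs=1e-6)
    assert P.compute_intact_mass(acet) - m0 == pytest.approx(42.04, abs=1e-6)
    with pytest.raises(ValueError, match="requires S/T/Y"):
        P.Construct("m", "AKSA", modifications=[P.Modification("phospho", 1)])
    with pytest.raises(ValueError, match="requires K"):
        P.Construct("m", "AKSA", modifications=[P.Modification("acetyl", 3)])


# ---------------------------------------------------------------------------
# Published construct-mass consistency (the checks the packaged sequence
# supports; absolute Table-type values live in the acceptance suite)
# ---------------------------------------------------------------------------

def test_bid_segment_mass_matches_construct_difference(brd4):
    """Residues 531-579 weigh the difference between the published 1-579 and
    1-530 theoretical construct masses (66,376.5 - 60,512.7 Da)."""
    seg = peptide_mass(brd4.subsequence(531, 579)) - WATER_AVERAGE
    assert seg == pytest.approx(66376.5 - 60512.7, abs=0.15)


def test_et_cps_segment_mass_matches_construct_difference(brd4):
    """Residues 580-722 weigh the published 1-722 minus 1-579 difference."""
    seg = peptide_mass(brd4.subsequence(580, 722)) - WATER_AVERAGE
    assert seg == pytest.approx(82415.3 - 66376.5, abs=0.15)


def test_nps_cps_phosphodeficient_mutant_mass_deltas(brd4):
    """7 NPS and 6 CPS serine-to-alanine substitutions lower the intact mass
    by exactly 7x and 6x the S->A difference (112.0 / 96.0 Da)."""
    m0 = P.compute_intact_mass(brd4)
    nps = P.find_ck2_consensus_in_region(brd4, "NPS")
    cps = P.find_ck2_consensus_in_region(brd4, "CPS")
    assert len(nps) == 7 and all(r == "S" for _, r in nps)
    assert len(cps) == 6 and all(r == "S" for _, r in cps)
    m7a = P.compute_intact_mass(
        P.apply_substitutions(brd4, [(pos, "S", "A") for pos, _ in nps], "7A")
    )
    m6a = P.compute_intact_mass(
        P.apply_substitutions(brd4, [(pos, "S", "A") for pos, _ in cps], "6A")
    )
    assert m0 - m7a == pytest.approx(7 * 15.9994, abs=0.01)
    assert m0 - m6a == pytest.approx(6 * 15.9994, abs=0.01)


def test_k519_is_lysine(brd4):
    assert brd4.residue_at(519) == "K"


def test_coiled_coil_deletion_mass_delta(brd4):
    """Replacing residues 506-530 with a (GGGS)x3 flexible linker lowers the
    intact mass by the published difference between the 1-722 and the
    deletion construct (82,472.3 - 80,404.9 = 2,067.4 Da).  The published
    values determine the linker's G/S composition uniquely (9 Gly + 3 Ser);
    (GGGS)x3 realizes it."""
    dcc = P.replace_region(brd4, 506, 530, "GGGSGGGSGGGS")
    delta = P.compute_intact_mass(brd4) - P.compute_intact_mass(dcc)
    assert delta == pytest.approx(82472.3 - 80404.9, abs=0.15)


# ---------------------------------------------------------------------------
# CK2 consensus
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ASDDE", [(2, "S")]),
        ("SPPA", []),
        ("TXX".replace("X", "A") + "D", [(1, "T")]),
        ("SSSDDE", [(1, "S"), (2, "S"), (3, "S")]),  # overlapping matches
    ],
)
def test_ck2_consensus_examples(seq, expected):
    assert P.find_ck2_consensus(seq) == expected


def _ck2_oracle(seq, offset=1):
    out = []
    for i in range(len(seq)):
        if seq[i] in "ST" and i + 3 < len(seq) and seq[i + 3] in "DE":
            out.append((i + offset, seq[i]))
    return out


def test_ck2_consensus_matches_window_oracle():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        n = int(rng.integers(4, 200))
        seq = "".join(rng.choice(list(AA), size=n))
        assert P.find_ck2_consensus(seq) == _ck2_oracle(seq)


# ---------------------------------------------------------------------------
# Substitutions & region replacement
# ---------------------------------------------------------------------------

def test_empty_substitution_is_identity(brd4):
    assert P.apply_substitutions(brd4, []).sequence == brd4.sequence


def test_substitution_mass_change_and_reversal(brd4):
    mut = P.apply_substitutions(brd4, [(484, "S", "A")])
    m0, m1 = P.compute_intact_mass(brd4), P.compute_intact_mass(mut)
    assert m0 - m1 == pytest.approx(15.9994, abs=1e-3)
    back = P.apply_substitutions(mut, [(484, "A", "S")])
    assert P.compute_intact_mass(back) == m0  # exact restoration


def test_substitution_errors(brd4):
    with pytest.raises(IndexError):
        P.apply_substitutions(brd4, [(9999, "A")])
    with pytest.raises(ValueError, match="expected"):
        P.apply_substitutions(brd4, [(519, "S", "A")])  # 519 is K


def test_replace_region_linker():
    c = P.Construct("c", "MAAAKKKKWWWW")
    linker = "GSGSGS"
    out = P.replace_region(c, 5, 8, linker)
    assert out.sequence == "MAAA" + linker + "WWWW"
    assert len(out.sequence) == len(c.sequence) - 4 + len(linker)


# ---------------------------------------------------------------------------
# Heptads
# ---------------------------------------------------------------------------

def test_heptad_count_examples():
    assert P.count_complete_heptads(506, 527) == 3
    assert P.count_complete_heptads(1, 6) == 0


@given(st.integers(-500, 500), st.integers(0, 100))
def test_heptad_count_translation_invariant(start, length):
    end = start + length - 1
    if length == 0:
        return
    assert P.count_complete_heptads(start, end) == length // 7
    assert P.count_complete_heptads(start + 7, end + 7) == length // 7


def test_polyleucine_scores_one_every_register():
    seq = "L" * 21
    phase, score = P.heptad_register_score(seq, 1, 21)
    assert (phase, score) == (0, 1.0)  # ties break to the smallest phase


def test_heptad_score_interval_validation():
    with pytest.raises(ValueError):
        P.heptad_register_score("LLLL", 1, 10)


# ---------------------------------------------------------------------------
# FASTA and fixtures
# ---------------------------------------------------------------------------

def test_fasta_round_trip(tmp_path, brd4):
    path = tmp_path / "x.fasta"
    P.write_fasta([brd4.truncate(1, 50, "head")], path)
    (back,) = P.read_fasta(path)
    assert back.sequence == brd4.subsequence(1, 50)


def test_region_table_loads(brd4):
    regions = P.load_brd4_regions()
    assert {r.label for r in regions["domains"]} >= {"BD1", "BD2", "NPS", "motif_B", "BID", "ET", "CPS", "PDD"}
    assert brd4.region("PDD").start == 484 and brd4.region("PDD").end == 579


def test_region_outside_construct_rejected():
    with pytest.raises(ValueError, match="outside"):
        P.Construct("c", "MAAA", regions=[P.RegionAnnotation("x", 1, 10)])
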