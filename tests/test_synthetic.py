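"""Exchange simulator: peptide maps, uptake kinetics, envelopes."""

import numpy as np
import pytest

import phosdim as P
from phosdim.envelopes import natural_envelope

from conftest import random_construct


@pytest.fixture()
def flat_model():
    """Single-state model with uniform rates, no protection, no EX1."""
    c = P.Construct("c", "MKLVEFGHIKLMNQRS")
    k = np.full(len(c.sequence), 1.0)  # 1/min
    return c, P.ExchangeModel(c, k, {"apo": np.ones(len(c.sequence))})


# ---------------------------------------------------------------------------
# Peptide map
# ---------------------------------------------------------------------------

def test_map_deterministic_under_seed():
    rng = np.random.default_rng(7)
    c = random_construct(rng, 100)
    m1 = P.generate_peptide_map(c, (6, 20), 3, seed=7)
    m2 = P.generate_peptide_map(c, (6, 20), 3, seed=7)
    assert [p.key for p in m1.peptides] == [p.key for p in m2.peptides]
    m3 = P.generate_peptide_map(c, (6, 20), 3, seed=8)
    assert [p.key for p in m3.peptides] != [p.key for p in m1.peptides]


def test_map_meets_redundancy_by_counting():
    rng = np.random.default_rng(3)
    c = random_construct(rng, 120)
    pmap = P.generate_peptide_map(c, (6, 20), 3, seed=3)
    # brute-force per-residue count over coverable residues
    coverable = [
        j for j in range(c.first_residue + 1, c.last_residue + 1)
        if c.residue_at(j) != "P"
    ]
    counts = {j: 0 for j in coverable}
    for pep in pmap.peptides:
        for j in range(pep.start + 1, pep.end + 1):
            if c.residue_at(j) != "P":
                counts[j] += 1
    mean = sum(counts.values()) / len(coverable)
    assert mean >= 3
    assert mean == pytest.approx(pmap.mean_coverage())


def test_single_covering_peptide_ok_for_low_redundancy():
    c = P.Construct("small", "MKLVEFGHIK")
    pmap = P.generate_peptide_map(c, (6, 20), target_redundancy=1, seed=0)
    assert len(pmap) >= 1
    assert pmap.mean_coverage() >= 1


def test_map_impossible_length_raises():
    c = P.Construct("tiny", "MKV")
    with pytest.raises(ValueError):
        P.generate_peptide_map(c, (6, 20), 1, seed=0)


def test_exchangeable_amides_excludes_first_residue_and_prolines():
    pep = P.Peptide(10, 17, "MKPLVPGH")
    # positions 11..17 minus prolines at 12 and 15
    assert pep.exchanging_positions() == [11, 13, 14, 16, 17]
    assert pep.exchangeable_amides == 5


# ---------------------------------------------------------------------------
# Uptake kinetics
# ---------------------------------------------------------------------------

def test_uptake_zero_at_t0(flat_model):
    c, model = flat_model
    prot = P.LabelingProtocol()
    pep = P.Peptide(1, len(c.sequence), c.sequence)
    assert P.noiseless_uptake(model, pep, prot, "apo", 0.0) == 0.0


def test_uptake_saturates_at_fd_times_amides(flat_model):
    c, model = flat_model
    prot = P.LabelingProtocol(back_exchange=0.0)
    pep = P.Peptide(1, len(c.sequence), c.sequence)
    up = P.noiseless_uptake(model, pep, prot, "apo", 1e9)
    assert up == pytest.approx(prot.f_d * pep.exchangeable_amides, rel=1e-9)


def test_half_life_identity():
    """A single site at k_obs = 1/min is half-exchanged at t = ln 2."""
    c = P.Construct("aa", "AA")
    model = P.ExchangeModel(c, np.array([1.0, 1.0]), {"apo": np.array([1.0, 1.0])})
    prot = P.LabelingProtocol(back_exchange=0.1)
    pep = P.Peptide(1, 2, "AA")  # one exchanging amide
    up = P.noiseless_uptake(model, pep, prot, "apo", np.log(2))
    assert up == pytest.approx(0.5 * prot.f_d * (1 - prot.back_exchange), rel=1e-12)


def test_uptake_monotone_in_time_and_bounded(study):
    construct, model, protocol, pmap = study
    for pep in pmap.peptides[::7]:
        ts = [0.0, 0.05, 0.5, 5, 50, 180, 1e6]
        ups = [P.noiseless_uptake(model, pep, protocol, "unphos", t) for t in ts]
        assert all(b >= a - 1e-12 for a, b in zip(ups, ups[1:]))
        bound = (1 - protocol.back_exchange) * protocol.f_d * pep.exchangeable_amides
        assert ups[-1] <= bound + 1e-9


def test_protection_never_increases_uptake(study):
    construct, _, protocol, pmap = study
    n = len(construct.sequence)
    base = P.ExchangeModel.two_state(construct, seed=5, protected_interval=(101, 122),
                                     protection_factor=20.0)
    for pep in pmap.peptides[::5]:
        for t in protocol.times:
            u_lo = P.noiseless_uptake(base, pep, protocol, "unphos", t)
            u_hi = P.noiseless_uptake(base, pep, protocol, "phos", t)
            assert u_hi <= u_lo + 1e-12


def test_uptake_table_byte_identical_under_seed(study):
    construct, model, protocol, pmap = study
    a = P.simulate_uptake(model, pmap, protocol, "unphos").to_csv(index=False)
    b = P.simulate_uptake(model, pmap, protocol, "unphos").to_csv(index=False)
    assert a == b


def test_states_have_independent_noise(study):
    construct, model, protocol, pmap = study
    a = P.simulate_uptake(model, pmap, protocol, "unphos")
    b = P.simulate_uptake(model, pmap, protocol, "phos")
    t0a = a[a.Exposure == 0.0].Center.to_numpy()
    t0b = b[b.Exposure == 0.0].Center.to_numpy()
    assert not np.allclose(t0a, t0b)


# ---------------------------------------------------------------------------
# Envelopes
# ---------------------------------------------------------------------------

def test_envelope_normalized_and_centroid_matches_uptake(study):
    construct, model, protocol, pmap = study
    for pep in pmap.peptides[::6]:
        env0 = P.simulate_envelope(model, pep, protocol, "unphos", 0.0)
        for t in protocol.times:
            env = P.simulate_envelope(model, pep, protocol, "unphos", t)
            assert env.intensities.sum() == pytest.approx(1.0, abs=1e-9)
            up = P.noiseless_uptake(model, pep, protocol, "unphos", t)
            assert env.centroid() - env0.centroid() == pytest.approx(up, abs=1e-6)


def test_no_deuteration_gives_natural_envelope(flat_model):
    c, model = flat_model
    prot = P.LabelingProtocol(f_d=0.0)
    pep = P.Peptide(1, len(c.sequence), c.sequence)
    env = P.simulate_envelope(model, pep, prot, "apo", 180.0)
    nat = natural_envelope(pep.sequence)
    assert np.allclose(env.intensities[: nat.size], nat, atol=1e-12)


def test_ex1_half_open_gives_equal_mixture():
    """A whole-peptide EX1 segment at exp(-k_op t) = 0.5 yields two modes of
    equal weight: half natural, half fully-exchanged."""
    seq = "MKLVEFGHIKLMNQ"
    c = P.Construct("c", seq)
    n = len(seq)
    k_op = 0.1
    model = P.ExchangeModel(
        c, np.full(n, 1.0), {"apo": np.ones(n)},
        {"apo": (P.Ex1Segment(1, n, k_op),)},
    )
    prot = P.LabelingProtocol(back_exchange=0.0)
    t_half = np.log(2) / k_op
    pep = P.Peptide(1, n, seq)
    env = P.simulate_envelope(model, pep, prot, "apo", t_half)
    nat = natural_envelope(seq)
    from phosdim.envelopes import binomial_envelope, convolve
    open_part = convolve(nat, binomial_envelope(pep.exchangeable_amides, prot.f_d))
    expected = 0.5 * np.pad(nat, (0, open_part.size - nat.size)) + 0.5 * open_part
    assert np.allclose(env.intensities, expected[: env.n_channels], atol=1e-9)


def test_envelope_series_deterministic(study):
    construct, model, protocol, pmap = study
    pep = pmap.peptides[0]
    e1 = P.simulate_envelopes(model, pep, protocol, "unphos")
    e2 = P.simulate_envelopes(model, pep, protocol, "unphos")
    for a, b in zip(e1, e2):
        assert np.array_equal(a.intensities, b.intensities)


def test_model_validation():
    c = P.Construct("c", "MKLV")
    with pytest.raises(ValueError, match="protection"):
        P.ExchangeModel(c, np.ones(4), {"apo": np.full(4, 0.5)})
    with pytest.raises(ValueError, match="overlap"):
        P.ExchangeModel(
            c, np.ones(4), {"apo": np.ones(4)},
            {"apo": (P.Ex1Segment(1, 3, 0.1), P.Ex1Segment(2, 4, 0.1))},
        )
    model = P.ExchangeModel(c, np.ones(4), {"apo": np.ones(4)})
    with pytest.raises(KeyError):
        P.noiseless_uptake(model, P.Peptide(1, 4, "MKLV"), P.LabelingProtocol(), "holo", 1.0)
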