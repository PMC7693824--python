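"""Mass, charge, pI, hydropathy, hydrophobic moment and MIC conversion."""

import math

import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings
from hypothesis import strategies as st

import ocellatin as oc
from ocellatin.constants import HYDROPHOBIC_SET, KYTE_DOOLITTLE

peptides = st.text(
    alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=32
)


@pytest.mark.parametrize(
    "sequence,amidated,expected",
    [
        ("GVLDIFKDAAKQILAHAAEKI", True, 2250.67),   # ocellatin-11
        ("GVVDILKDTGKKLLSHLMEKV", True, 2322.84),   # ocellatin-8
        ("GVLDIFKDAAKQILAHAAEQI", True, 2250.63),   # ocellatin-2
        ("GLLDFLKAAGKGLVSNLIEKV", True, 2184.65),   # ocellatin-10
        ("GLLDFLKAAGKGLVSNLLEK", True, 2085.52),    # P3-Lla-2085
        ("G", False, 75.07),                        # glycine free acid
    ],
)
def test_average_mass(sequence, amidated, expected):
    assert oc.average_mass(sequence, amidated) == pytest.approx(
        expected, abs=0.02
    )


def test_average_mass_cross_checks_biopython():
    """Independent oracle: Biopython's average-mass calculation."""
    for seq in ("GVLDIFKDAAKQILAHAAEKI", "GVFDIIKGAGKQLIAHAMEKIAEKVGLNKDGN"):
        assert oc.average_mass(seq, False) == pytest.approx(
            ProteinAnalysis(seq).molecular_weight(), abs=0.05
        )


def test_invalid_residue_named():
    with pytest.raises(ValueError, match="'B'"):
        oc.average_mass("GB")


@settings(max_examples=50, deadline=None)
@given(peptides)
def test_amidation_deltas(seq):
    """Amidation removes 0.9847 Da and one unit of negative charge."""
    assert oc.average_mass(seq, True) == pytest.approx(
        oc.average_mass(seq, False) - 0.9847, abs=0.011
    )
    assert (
        oc.net_charge_formal(seq, True)
        == oc.net_charge_formal(seq, False) + 1
    )


@pytest.mark.parametrize(
    "sequence,amidated,expected",
    [
        ("GVVDILKDTGKKLLSHLMEKI", True, 2),   # ocellatin-7
        ("GVLDIFKDAAKQILAHAAEQI", True, 0),   # ocellatin-2
        ("GVLDIFKDAAKQILAHAAEKI", True, 1),   # ocellatin-11
        ("AAAA", True, 1),                    # N-terminus only
    ],
)
def test_net_charge_formal(sequence, amidated, expected):
    assert oc.net_charge_formal(sequence, amidated) == expected


def test_novel_peptides_charges(by_name):
    expected = {"ocellatin-7": 2, "ocellatin-8": 2, "ocellatin-9": 2,
                "ocellatin-10": 2, "ocellatin-11": 1}
    for name, charge in expected.items():
        rec = by_name[name]
        assert oc.net_charge_formal(rec.sequence, rec.amidated) == charge


def test_family_charges_are_low_cationic(family):
    for rec in family:
        amidated = rec.amidated if rec.amidated is not None else True
        assert oc.net_charge_formal(rec.sequence, amidated) in (0, 1, 2, 3)


def test_continuous_charge_monotone_and_zero_at_pI():
    seq = "GVLDIFKDAAKQILAHAAEKI"
    charges = [oc.net_charge_continuous(seq, True, ph) for ph in range(15)]
    assert all(a > b for a, b in zip(charges, charges[1:]))
    pI = oc.compute_pI(seq, True)
    assert 9.0 <= pI <= 11.5
    assert abs(oc.net_charge_continuous(seq, True, pI)) < 1e-4


def test_pI_per_group_summation_oracle():
    """Recompute the charge at the solver's root by independent per-group
    Henderson-Hasselbalch summation and check it vanishes."""
    seq = "GVLDIFKDAAKQILAHAAEKI"
    pka = {"Nterm": 8.6, "K": 10.8, "H": 6.0, "D": 3.9, "E": 4.1}
    pI = oc.compute_pI(seq, True)
    pos = [pka["Nterm"]] + [pka[a] for a in seq if a in "KH"]
    neg = [pka[a] for a in seq if a in "DE"]
    total = sum(1 / (1 + 10 ** (pI - p)) for p in pos) - sum(
        1 / (1 + 10 ** (p - pI)) for p in neg
    )
    assert abs(total) < 1e-4


def test_amidated_pI_exceeds_free_acid():
    seq = "GVLDIFKDAAKQILAHAAEKI"
    assert oc.compute_pI(seq, True) > oc.compute_pI(seq, False)


@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("GVFDIIKGAGKQLIAHAMEKIAEKVGLNKDGN", -0.103),  # ocellatin-PT6
        ("GLLDFVTGVGKDIFAQLIKQI", 0.81),               # ocellatin-4
        ("GG", -0.4),
    ],
)
def test_gravy(sequence, expected):
    assert oc.gravy(sequence) == pytest.approx(expected, abs=5e-4)


@settings(max_examples=50, deadline=None)
@given(peptides)
def test_gravy_and_moment_reversal_invariance(seq):
    assert oc.gravy(seq) == oc.gravy(seq[::-1])
    assert oc.hydrophobic_moment(seq) == pytest.approx(
        oc.hydrophobic_moment(seq[::-1]), abs=1e-9
    )


@pytest.mark.parametrize(
    "sequence,expected",
    [
        ("AVLDILKDVGKGLLSHFMEKV", 52),  # ocellatin-5
        ("GVVDILKDTGKKLLSHLMEKI", 42),  # ocellatin-7
        ("DDDD", 0),
    ],
)
def test_hydrophobic_fraction(sequence, expected):
    assert oc.hydrophobic_fraction(sequence) == expected


def test_hydrophobic_moment_homopolymer_vanishes():
    # uniform hydropathy cancels over a full 100-degree wheel period (18)
    assert oc.hydrophobic_moment("L" * 18) < 1e-9
    assert oc.hydrophobic_moment("L" * 36) < 1e-9


def test_hydrophobic_moment_family_bracket(family):
    values = [oc.hydrophobic_moment(r.sequence) for r in family]
    assert all(0.5 <= v <= 1.6 for v in values)


def test_hydrophobic_moment_alternating_oracle():
    """With a 180-degree step an alternating peptide's moment equals the
    hand-computed |sum of alternating-signed hydropathies| / n."""
    seq = "LK" * 9
    expected = abs(
        sum(
            (1 if i % 2 == 0 else -1) * KYTE_DOOLITTLE[a]
            for i, a in enumerate(seq)
        )
    ) / len(seq)
    assert oc.hydrophobic_moment(seq, delta=180) == pytest.approx(expected)


def test_hydrophobic_moment_vector_sum_oracle(family):
    """Brute-force vector summation reproduces the implementation."""
    for rec in family[:5]:
        x = sum(
            KYTE_DOOLITTLE[a] * math.cos(math.radians(100 * i))
            for i, a in enumerate(rec.sequence)
        )
        y = sum(
            KYTE_DOOLITTLE[a] * math.sin(math.radians(100 * i))
            for i, a in enumerate(rec.sequence)
        )
        assert oc.hydrophobic_moment(rec.sequence) == pytest.approx(
            math.hypot(x, y) / len(rec.sequence)
        )


def test_helical_wheel_geometry():
    wheel = oc.helical_wheel("GVLDIFKDAAKQILAHAA")
    assert wheel[0][1] == 0.0 and wheel[1][1] == 100.0
    # an 18-mer on a 100-degree wheel hits every multiple of 20 degrees
    assert {angle for _, angle, _ in wheel} == {20.0 * k for k in range(18)}


def test_ocellatin_11_lysines_cluster_on_one_face():
    """Exhaustive half-plane search: some 180-degree arc contains K7, K11
    and K20 together — the cationic face of the amphipathic helix."""
    seq = "GVLDIFKDAAKQILAHAAEKI"
    wheel = oc.helical_wheel(seq)
    lys_angles = [angle for (res, angle, _), pos in zip(wheel, range(1, 22))
                  if res == "K" and pos in (7, 11, 20)]
    assert len(lys_angles) == 3

    def in_arc(angle, start):  # closed 180-degree arc starting at `start`
        return (angle - start) % 360.0 <= 180.0

    assert any(
        all(in_arc(a, start) for a in lys_angles)
        for start in range(0, 360)
    )


@pytest.mark.parametrize(
    "ug,mw,um",
    [(32, 2273.77, 14), (64, 2311.82, 28), (31, 2085.52, 15)],
)
def test_mic_conversion(ug, mw, um):
    assert round(oc.mic_to_um(ug, mw)) == um


def test_mic_conversion_round_trip():
    mw = 2250.67
    assert oc.mic_to_ug_ml(oc.mic_to_um(64.0, mw), mw) == pytest.approx(64.0)


def test_profile_panel_consistency(by_name):
    rec = by_name["ocellatin-11"]
    panel = oc.profile(rec.sequence, rec.amidated, name=rec.name)
    assert panel.mw == 2250.67
    assert panel.net_charge_formal == 1
    assert panel.hydrophobic_pct == 57
    assert len(panel.wheel) == 21
    assert -4.5 <= panel.gravy <= 4.5
    assert panel.mu_h >= 0
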