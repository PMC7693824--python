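"""Per-peptide physicochemical panel.

Average mass with C-terminal amidation accounting, formal and
Henderson-Hasselbalch net charge, isoelectric point, GRAVY, hydrophobic
residue percentage, Eisenberg hydrophobic moment on the Kyte-Doolittle
scale, helical-wheel geometry, and MIC unit conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy.optimize import brentq

from .constants import (
    AMIDATION_DELTA,
    AVERAGE_RESIDUE_MASS,
    HELIX_ANGLE,
    HYDROPHOBIC_SET,
    KYTE_DOOLITTLE,
    PKA,
    WATER_MASS,
    validate_sequence,
)


def average_mass(sequence: str, amidated: bool = False) -> float:
    """Average (isotope-averaged) molecular mass in Da.

    Sum of residue masses plus one water; C-terminal amidation replaces
    the terminal -OH by -NH2 (-0.9847 Da). Reported to 2 decimals.
    """
    seq = validate_sequence(sequence)
    mass = sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_MASS
    if amidated:
        mass += AMIDATION_DELTA
    return round(mass, 2)


def net_charge_formal(sequence: str, amidated: bool = False) -> int:
    """Integer net charge at pH 7.

    +1 for the N-terminus and each K/R, -1 for each D/E, His neutral;
    the C-terminus contributes -1 unless amidated.
    """
    seq = validate_sequence(sequence)
    charge = 1  # N-terminus
    charge += sum(a in "KR" for a in seq)
    charge -= sum(a in "DE" for a in seq)
    if not amidated:
        charge -= 1
    return charge


def net_charge_continuous(sequence: str, amidated: bool, pH: float) -> float:
    """Henderson-Hasselbalch net charge at the given pH.

    Monotonically decreasing in pH; uses the packaged EMBOSS-style pKa set.
    """
    if not 0.0 <= pH <= 14.0:
        raise ValueError(f"pH out of range: {pH}")
    seq = validate_sequence(sequence)
    basic = [PKA["Nterm"]] + [PKA[a] for a in seq if a in "KRH"]
    acidic = [PKA[a] for a in seq if a in "DECY"]
    if not amidated:
        acidic.append(PKA["Cterm"])
    positive = sum(1.0 / (1.0 + 10.0 ** (pH - pka)) for pka in basic)
    negative = sum(1.0 / (1.0 + 10.0 ** (pka - pH)) for pka in acidic)
    return positive - negative


def compute_pI(sequence: str, amidated: bool = False, tol: float = 1e-4) -> float:
    """Isoelectric point: the pH at which the continuous net charge is zero.

    Solved by bracketed root finding on [0, 14]; the charge function is
    strictly decreasing so the root is unique. A fully basic peptide whose
    charge never crosses zero raises ``ValueError``.
    """
    lo = net_charge_continuous(sequence, amidated, 0.0)
    hi = net_charge_continuous(sequence, amidated, 14.0)
    if lo < 0 or hi > 0:
        raise ValueError("net charge does not cross zero in [0, 14]")
    pI = brentq(
        lambda ph: net_charge_continuous(sequence, amidated, ph),
        0.0, 14.0, xtol=tol / 10,
    )
    assert abs(net_charge_continuous(sequence, amidated, pI)) < tol
    return float(pI)


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    seq = validate_sequence(sequence)
    # fsum: exact summation, so the mean is independent of residue order
    return round(math.fsum(KYTE_DOOLITTLE[a] for a in seq) / len(seq), 3)


def hydrophobic_fraction(sequence: str) -> int:
    """Percentage of residues in {A,C,F,I,L,M,V,W}, truncated toward zero."""
    seq = validate_sequence(sequence)
    count = sum(a in HYDROPHOBIC_SET for a in seq)
    return int(100 * count / len(seq))


def hydrophobic_moment(sequence: str, delta: float = HELIX_ANGLE) -> float:
    """Eisenberg hydrophobic moment per residue, Kyte-Doolittle scale.

    Magnitude of the vector sum of residue hydropathies placed at
    ``delta``-degree steps around the helix, divided by peptide length.
    """
    seq = validate_sequence(sequence)
    if len(seq) < 2:
        raise ValueError("hydrophobic moment needs at least 2 residues")
    x = y = 0.0
    for i, a in enumerate(seq):
        angle = math.radians(i * delta)
        h = KYTE_DOOLITTLE[a]
        x += h * math.cos(angle)
        y += h * math.sin(angle)
    return math.hypot(x, y) / len(seq)


def helical_wheel(
    sequence: str, delta: float = HELIX_ANGLE
) -> list[tuple[str, float, str]]:
    """Schiffer-Edmundson wheel geometry as (residue, angle, face) rows.

    Residue i (1-based) sits at (i-1)*delta mod 360 degrees; the face label
    reflects membership in the hydrophobic residue set.
    """
    seq = validate_sequence(sequence)
    if len(seq) < 2:
        raise ValueError("helical wheel needs at least 2 residues")
    return [
        (
            a,
            (i * delta) % 360.0,
            "hydrophobic" if a in HYDROPHOBIC_SET else "hydrophilic",
        )
        for i, a in enumerate(seq)
    ]


def mic_to_um(value_ug_ml: float, mw: float) -> float:
    """ug/mL -> uM for a peptide of average mass ``mw`` (Da)."""
    if value_ug_ml <= 0 or mw <= 0:
        raise ValueError("MIC and mass must be positive")
    return 1000.0 * value_ug_ml / mw


def mic_to_ug_ml(value_um: float, mw: float) -> float:
    """uM -> ug/mL, the inverse of :func:`mic_to_um`."""
    if value_um <= 0 or mw <= 0:
        raise ValueError("MIC and mass must be positive")
    return value_um * mw / 1000.0


@dataclass(frozen=True)
class PhyschemProfile:
    """The full per-peptide panel at pH 7."""

    name: str
    sequence: str
    amidated: Optional[bool]
    mw: float
    net_charge_formal: int
    net_charge_continuous: float
    pI: float
    gravy: float
    hydrophobic_pct: int
    mu_h: float
    wheel: tuple[tuple[str, float, str], ...]


def profile(sequence: str, amidated: Optional[bool] = True,
            name: str = "", pH: float = 7.0) -> PhyschemProfile:
    """Compute the whole panel for one peptide.

    An ambiguous amidation state (``None``) is profiled as amidated, the
    family-typical form.
    """
    am = True if amidated is None else amidated
    return PhyschemProfile(
        name=name,
        sequence=sequence.upper(),
        amidated=amidated,
        mw=average_mass(sequence, am),
        net_charge_formal=net_charge_formal(sequence, am),
        net_charge_continuous=net_charge_continuous(sequence, am, pH),
        pI=compute_pI(sequence, am),
        gravy=gravy(sequence),
        hydrophobic_pct=hydrophobic_fraction(sequence),
        mu_h=hydrophobic_moment(sequence),
        wheel=tuple(helical_wheel(sequence)),
    )
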