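"""cDNA translation and tripartite prepro-peptide parsing.

Ocellatin precursors follow the canonical frog-skin AMP architecture:
a ~21-residue signal peptide ending in the family's single Cys, an acidic
spacer ending in the Lys-Arg prohormone processing site, and the mature
peptide, whose C-terminal Gly (when present) is the amidation signal and
is removed from the mature product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

from Bio.Seq import Seq


class NoOrfError(ValueError):
    """No ATG...stop open reading frame in any requested frame."""


class PrecursorParseError(ValueError):
    """The protein does not fit the tripartite precursor architecture."""


@dataclass(frozen=True)
class PrecursorStructure:
    """Parsed segmentation of a translated precursor (1-based coordinates)."""

    protein: str
    signal: str
    acidic: str
    mature_raw: str
    mature: str
    amidated: bool
    signal_end: int  # index of the signal-terminal Cys
    kr_site: int     # index of the K of the K-R processing site

    def __post_init__(self) -> None:
        assert self.signal + self.acidic + self.mature_raw == self.protein
        assert self.signal.endswith("C")
        assert self.acidic.endswith("KR")


def _translate_from_atg(cds_frame: str) -> str:
    """Translate from the first in-frame ATG to the first stop codon."""
    start = -1
    for i in range(0, len(cds_frame) - 2, 3):
        if cds_frame[i:i + 3] == "ATG":
            start = i
            break
    if start < 0:
        raise NoOrfError("no ATG in frame")
    protein = []
    for i in range(start, len(cds_frame) - 2, 3):
        codon = cds_frame[i:i + 3]
        aa = str(Seq(codon).translate())
        if aa == "*":
            return "".join(protein)
        protein.append(aa)
    raise NoOrfError("no stop codon in frame")


def translate_cds(nucleotides: str, frame: Union[int, str] = "auto") -> str:
    """Translate a cDNA to the precursor protein.

    With an explicit frame (0-2) translation runs from the first ATG in
    that frame to the first stop. ``frame='auto'`` picks the frame whose
    translation starts with Met and contains the K-R processing dipeptide,
    breaking ties by the longest open reading frame.
    """
    seq = nucleotides.upper().replace("U", "T")
    if len(seq) < 3:
        raise ValueError("nucleotide sequence shorter than one codon")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"invalid nucleotide(s): {sorted(bad)}")
    if frame != "auto":
        if frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1, 2 or 'auto', got {frame!r}")
        return _translate_from_atg(seq[frame:])
    candidates = []
    for f in (0, 1, 2):
        try:
            protein = _translate_from_atg(seq[f:])
        except NoOrfError:
            continue
        if protein.startswith("M") and "KR" in protein:
            candidates.append((len(protein), -f, protein))
    if not candidates:
        raise NoOrfError(
            "no frame yields an ORF with a leading Met and a KR site"
        )
    return max(candidates)[2]


# Window (1-based) in which the signal-terminal Cys may fall.
SIGNAL_CYS_WINDOW = (15, 25)
# Acceptable acidic spacer length (the described range is 19-22).
ACIDIC_LENGTH_RANGE = (15, 30)
# Minimum residues the mature peptide must keep after the K-R site.
MIN_MATURE_LENGTH = 15


def parse_precursor(protein: str) -> PrecursorStructure:
    """Segment a precursor protein into signal / acidic / mature parts.

    The signal peptide ends at the first Cys in the 15-25 window; the
    acidic spacer ends at the last K-R dipeptide that leaves at least 15
    residues of mature peptide; a mature-terminal Gly marks amidation and
    is removed from the mature sequence.
    """
    protein = protein.upper()
    if not protein.startswith("M"):
        raise PrecursorParseError("precursor must start with Met")
    if len(protein) < 45:
        raise PrecursorParseError("precursor too short for the architecture")
    lo, hi = SIGNAL_CYS_WINDOW
    signal_end = 0
    for k in range(lo, min(hi, len(protein)) + 1):
        if protein[k - 1] == "C":
            signal_end = k
            break
    if not signal_end:
        raise PrecursorParseError(
            f"no signal-terminal Cys in window {lo}-{hi}"
        )
    kr_site = 0
    for j in range(len(protein) - 1, signal_end, -1):
        if protein[j - 1:j + 1] == "KR" and len(protein) - (j + 1) >= MIN_MATURE_LENGTH:
            kr_site = j
            break
    if not kr_site:
        raise PrecursorParseError(
            "no K-R processing site leaving a plausible mature peptide"
        )
    signal = protein[:signal_end]
    acidic = protein[signal_end:kr_site + 1]
    mature_raw = protein[kr_site + 1:]
    if not ACIDIC_LENGTH_RANGE[0] <= len(acidic) <= ACIDIC_LENGTH_RANGE[1]:
        raise PrecursorParseError(
            f"acidic spacer length {len(acidic)} outside "
            f"{ACIDIC_LENGTH_RANGE[0]}-{ACIDIC_LENGTH_RANGE[1]}"
        )
    amidated = mature_raw.endswith("G")
    mature = mature_raw[:-1] if amidated else mature_raw
    return PrecursorStructure(
        protein=protein,
        signal=signal,
        acidic=acidic,
        mature_raw=mature_raw,
        mature=mature,
        amidated=amidated,
        signal_end=signal_end,
        kr_site=kr_site,
    )
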