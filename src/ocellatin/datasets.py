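"""Packaged ocellatin family catalogue, fragment records and MIC table.

The catalogue holds the 28 mature family peptides described across ten
Leptodactylus species, plus the synthetic hybrid analog P3-Lla-2085.
Fragment records are stored as (parent, span) pairs and their sequences
derived from the parent at load time. The MIC table keeps the published
activity values verbatim, including the non-numeric qualifiers.
"""

from __future__ import annotations

import csv
import unicodedata
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

from .constants import validate_sequence

PathLike = Union[str, Path]

#: The five peptides newly cloned from L. latrans skin cDNA.
NOVEL_PEPTIDES = (
    "ocellatin-7",
    "ocellatin-8",
    "ocellatin-9",
    "ocellatin-10",
    "ocellatin-11",
)

#: MIC-table rows whose printed uM value carries the original source's own
#: rounding (to the nearest 5 or 10, or a legacy mass) and therefore does not
#: reproduce at integer rounding from the printed ug/mL and the computed mass.
#: All deviations are <= 4.2% relative.
MIC_SOURCE_ROUNDED = frozenset({
    ("ocellatin-5", "S_aureus"),
    ("ocellatin-F", "E_coli"),
    ("ocellatin-PT1", "E_coli"),
    ("ocellatin-PT3", "E_coli"),
    ("ocellatin-PT4", "E_coli"),
    ("ocellatin-PT6", "E_coli"),
    ("ocellatin-PT7", "E_coli"),
    ("ocellatin-PT7", "S_aureus"),
    ("ocellatin-PT8", "S_aureus"),
})


class Group(str, Enum):
    family_member = "family_member"
    fragment = "fragment"
    analog = "analog"
    novel = "novel"


class Qualifier(str, Enum):
    exact = "exact"
    greater_than = "greater_than"
    inactive = "inactive"
    not_tested = "not_tested"
    not_informed = "not_informed"


@dataclass(frozen=True)
class PeptideRecord:
    """One mature peptide with provenance and amidation state.

    ``amidated`` is ``None`` when the published record is internally
    inconsistent about the C-terminal state (only ocellatin-6).
    """

    name: str
    sequence: str
    amidated: Optional[bool]
    species: str = ""
    group: Group = Group.family_member
    printed_mw: Optional[float] = None
    printed_net_charge: Optional[int] = None
    source_ref: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_sequence(self.sequence, self.name)
        )


@dataclass(frozen=True)
class ActivityRecord:
    """One MIC measurement for one peptide against one organism."""

    peptide_name: str
    organism: str  # "E_coli" | "S_aureus"
    qualifier: Qualifier
    mic_ug_ml: Optional[float] = None
    mic_um: Optional[float] = None

    def usable(self) -> bool:
        return self.qualifier is Qualifier.exact


def _normalize(text: str) -> str:
    """Fold unicode dash/minus variants to ASCII."""
    text = unicodedata.normalize("NFKC", text)
    return text.replace("–", "-").replace("—", "-").replace("−", "-")


def _data_path(name: str) -> Path:
    return Path(resources.files("ocellatin").joinpath("data", name))  # type: ignore[arg-type]


def catalogue_path() -> Path:
    return _data_path("ocellatins.tsv")


def activity_path() -> Path:
    return _data_path("activity_mic.tsv")


def fragments_path() -> Path:
    return _data_path("fragments.tsv")


_AMIDATED = {"yes": True, "true": True, "no": False, "false": False,
             "ambiguous": None}


def load_catalogue(path: Optional[PathLike] = None) -> list[PeptideRecord]:
    """Load the peptide catalogue TSV (family members plus analogs).

    Validates residue letters row by row and enforces unique names.
    """
    path = Path(path) if path is not None else catalogue_path()
    records: list[PeptideRecord] = []
    seen: set[str] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            name = _normalize(row["name"]).strip()
            if name in seen:
                raise ValueError(f"{path} row {i}: duplicate name {name!r}")
            seen.add(name)
            try:
                seq = validate_sequence(_normalize(row["sequence"]).strip(), name)
            except ValueError as exc:
                raise ValueError(f"{path} row {i}: {exc}") from exc
            mw = _normalize(row.get("printed_mw") or "").strip()
            charge = _normalize(row.get("printed_charge") or "").strip()
            records.append(
                PeptideRecord(
                    name=name,
                    sequence=seq,
                    amidated=_AMIDATED[row["amidated"].strip().lower()],
                    species=row.get("species", "").strip(),
                    group=Group(row["group"].strip()),
                    printed_mw=float(mw) if mw else None,
                    printed_net_charge=int(charge) if charge else None,
                    source_ref=row.get("source", "").strip(),
                )
            )
    return records


def family_members(
    records: Optional[Sequence[PeptideRecord]] = None,
) -> list[PeptideRecord]:
    """The 28 described family peptides, in catalogue (alignment) order."""
    if records is None:
        records = load_catalogue()
    return [r for r in records if r.group is Group.family_member]


def get_peptide(name: str,
                records: Optional[Sequence[PeptideRecord]] = None) -> PeptideRecord:
    if records is None:
        records = load_catalogue()
    wanted = name.lower()
    for rec in records:
        if rec.name.lower() == wanted:
            return rec
    raise KeyError(name)


def load_fragments(
    path: Optional[PathLike] = None,
    catalogue: Optional[Sequence[PeptideRecord]] = None,
) -> list[PeptideRecord]:
    """Fragment records; sequences are sliced from the parent peptide."""
    path = Path(path) if path is not None else fragments_path()
    catalogue = list(catalogue) if catalogue is not None else load_catalogue()
    out: list[PeptideRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            parent = get_peptide(row["parent"], catalogue)
            start, end = int(row["start"]), int(row["end"])
            if not (1 <= start <= end <= len(parent.sequence)):
                raise ValueError(f"fragment {row['name']}: span outside parent")
            out.append(
                PeptideRecord(
                    name=_normalize(row["name"]).strip(),
                    sequence=parent.sequence[start - 1:end],
                    amidated=False,
                    species=row.get("species", "").strip(),
                    group=Group.fragment,
                    source_ref=row.get("source", "").strip(),
                )
            )
    return out


def _parse_mic_token(token: str) -> tuple[Optional[float], Optional[Qualifier]]:
    """One table cell -> (value, qualifier hint)."""
    token = _normalize(token).strip()
    if token in ("", "-"):
        return None, None
    if token == "*":
        return None, Qualifier.not_informed
    if token == "NT":
        return None, Qualifier.not_tested
    if token == "NI":
        return None, Qualifier.not_informed
    if token == "I":
        return None, Qualifier.inactive
    if token.startswith(">"):
        return float(token[1:]), Qualifier.greater_than
    try:
        return float(token), Qualifier.exact
    except ValueError:
        raise ValueError(f"unknown MIC qualifier token {token!r}") from None


def load_activity(path: Optional[PathLike] = None) -> list[ActivityRecord]:
    """Load the MIC table as one record per (peptide, organism).

    A row whose two unit cells disagree in kind (a number next to a '>'
    bound) is conservatively recorded as greater_than.
    """
    path = Path(path) if path is not None else activity_path()
    records: list[ActivityRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            name = _normalize(row["name"]).strip()
            for organism, ug_col, um_col in (
                ("E_coli", "ecoli_ug_ml", "ecoli_um"),
                ("S_aureus", "saureus_ug_ml", "saureus_um"),
            ):
                ug, q_ug = _parse_mic_token(row[ug_col])
                um, q_um = _parse_mic_token(row[um_col])
                quals = {q for q in (q_ug, q_um) if q is not None}
                if not quals:
                    continue
                if Qualifier.greater_than in quals:
                    qualifier = Qualifier.greater_than
                elif quals == {Qualifier.exact}:
                    qualifier = Qualifier.exact
                elif len(quals) == 1:
                    qualifier = quals.pop()
                else:
                    raise ValueError(
                        f"{name}/{organism}: conflicting qualifiers {quals}"
                    )
                if qualifier not in (Qualifier.exact, Qualifier.greater_than):
                    ug = um = None
                records.append(
                    ActivityRecord(
                        peptide_name=name,
                        organism=organism,
                        qualifier=qualifier,
                        mic_ug_ml=ug,
                        mic_um=um,
                    )
                )
    return records


def to_fasta(records: Sequence[PeptideRecord], path: PathLike) -> None:
    """Write any record set as uncompressed FASTA."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.sequence}\n")
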