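"""Similarity-based antimicrobial-activity projection.

A peptide without a measured MIC inherits the MIC of its most similar
catalogue neighbour that has an exact measurement — a deterministic
nearest-measured-neighbour transfer, the operational form of comparing a
new family member with its closest described relatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .compare import global_align
from .datasets import ActivityRecord, PeptideRecord, Qualifier
from .physchem import hydrophobic_moment, net_charge_formal


@dataclass(frozen=True)
class ActivityProjection:
    query: str
    neighbor: str
    similarity_pct: float
    identity_pct: float
    #: organism -> (MIC in uM, qualifier); carried verbatim from the neighbour
    projected_mic_um: dict[str, tuple[Optional[float], Qualifier]]

    def mic_um(self, organism: str = "E_coli") -> Optional[float]:
        value = self.projected_mic_um.get(organism)
        return value[0] if value else None


def _measured_exactly(
    activity: Sequence[ActivityRecord], organism: str
) -> set[str]:
    return {
        rec.peptide_name
        for rec in activity
        if rec.organism == organism and rec.qualifier is Qualifier.exact
    }


def project_activity(
    query: PeptideRecord,
    catalogue: Sequence[PeptideRecord],
    activity: Sequence[ActivityRecord],
    organism: str = "E_coli",
) -> ActivityProjection:
    """Transfer the MIC of the most similar exactly-measured neighbour.

    Ties on similarity resolve by higher identity, then name. Peptides whose
    measurement is a bound (>) or a qualitative flag are not eligible donors.
    """
    eligible_names = _measured_exactly(activity, organism)
    candidates = [p for p in catalogue if p.name in eligible_names]
    if not candidates:
        raise ValueError(f"no catalogue peptide with an exact {organism} MIC")
    scored = []
    for peptide in candidates:
        res = global_align(query.sequence, peptide.sequence)
        scored.append(
            (res.similarity_pct, res.identity_pct, peptide.name, peptide)
        )
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    similarity, identity, _, neighbor = scored[0]
    projected: dict[str, tuple[Optional[float], Qualifier]] = {}
    for rec in activity:
        if rec.peptide_name == neighbor.name:
            projected[rec.organism] = (rec.mic_um, rec.qualifier)
    return ActivityProjection(
        query=query.name,
        neighbor=neighbor.name,
        similarity_pct=similarity,
        identity_pct=identity,
        projected_mic_um=projected,
    )


def rank_novel(
    queries: Sequence[PeptideRecord],
    catalogue: Sequence[PeptideRecord],
    activity: Sequence[ActivityRecord],
    organism: str = "E_coli",
) -> list[tuple[PeptideRecord, ActivityProjection]]:
    """Rank queries by ascending projected MIC (most active first).

    Ties resolve by higher formal net charge, then higher hydrophobic
    moment, then name — charge and amphipathicity being the features the
    family's structure-activity picture weighs most.
    """
    ranked = []
    for query in queries:
        projection = project_activity(query, catalogue, activity, organism)
        amidated = query.amidated if query.amidated is not None else True
        ranked.append(
            (
                projection.mic_um(organism) or float("inf"),
                -net_charge_formal(query.sequence, amidated),
                -hydrophobic_moment(query.sequence),
                query.name,
                (query, projection),
            )
        )
    ranked.sort(key=lambda t: t[:4])
    return [item[-1] for item in ranked]
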