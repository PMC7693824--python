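"""End-to-end run: parse -> profile -> compare -> conserve -> tree -> project.

The combined report has one row per peptide: parsed precursor fields where
the input was cDNA, the physicochemical panel, the nearest family
neighbour, and the projected MIC. Output formatting follows the published
precisions: 2 decimals for Da, 1 for percentages, 3 for GRAVY and the
hydrophobic moment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from Bio import SeqIO

from . import activity as activity_mod
from . import datasets, phylo, physchem
from .compare import conservation_profile, global_align, motif_scan
from .datasets import Group, PeptideRecord
from .precursor import parse_precursor, translate_cds

logger = logging.getLogger("ocellatin")

_KNOWN_KEYS = None  # populated after RunConfig definition


@dataclass
class RunConfig:
    """Configuration for one pipeline run; unknown keys are rejected."""

    input_fasta: Optional[Union[str, Path]] = None  # mature peptides
    cdna_fasta: Optional[Union[str, Path]] = None   # precursors to parse
    out_dir: Union[str, Path] = "results"
    seed: int = 0
    frame: Union[int, str] = "auto"
    wheel_delta: float = 100.0
    pH: float = 7.0
    tree_method: str = "upgma"
    organism: str = "E_coli"
    stages: tuple[str, ...] = ("profile", "compare", "conserve", "tree", "project")

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = dict(mapping)
        if "stages" in cfg:
            cfg["stages"] = tuple(cfg["stages"])
        return cls(**cfg)


def _read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _fmt(value, kind: str) -> str:
    if value is None:
        return ""
    if kind == "da":
        return f"{value:.2f}"
    if kind == "pct":
        return f"{value:.1f}"
    if kind == "f3":
        return f"{value:.3f}"
    return str(value)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the written file paths."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalogue = datasets.load_catalogue()
    activity = datasets.load_activity()

    queries: list[dict] = []
    if config.cdna_fasta is not None:
        for name, cdna in _read_fasta(config.cdna_fasta):
            protein = translate_cds(cdna, config.frame)
            parsed = parse_precursor(protein)
            queries.append(
                {
                    "name": name,
                    "sequence": parsed.mature,
                    "amidated": parsed.amidated,
                    "signal": parsed.signal,
                    "acidic": parsed.acidic,
                }
            )
    elif config.input_fasta is not None:
        for name, seq in _read_fasta(config.input_fasta):
            queries.append(
                {"name": name, "sequence": seq, "amidated": True,
                 "signal": "", "acidic": ""}
            )
    else:
        queries = [
            {"name": r.name, "sequence": r.sequence,
             "amidated": r.amidated if r.amidated is not None else True,
             "signal": "", "acidic": ""}
            for r in datasets.family_members(catalogue)
        ]

    if not queries:
        logger.warning("empty input: writing empty report")

    rows = []
    for q in queries:
        row = dict(q)
        if "profile" in config.stages:
            panel = physchem.profile(
                q["sequence"], q["amidated"], name=q["name"], pH=config.pH
            )
            row.update(
                mw=panel.mw,
                net_charge=panel.net_charge_formal,
                pI=round(panel.pI, 2),
                gravy=panel.gravy,
                hydrophobic_pct=panel.hydrophobic_pct,
                mu_h=panel.mu_h,
                motif=motif_scan(q["sequence"])[0] if len(q["sequence"]) >= 7 else False,
            )
        if "compare" in config.stages:
            best = None
            for rec in datasets.family_members(catalogue):
                if rec.name == q["name"]:
                    continue
                res = global_align(q["sequence"], rec.sequence)
                key = (res.similarity_pct, res.identity_pct, rec.name)
                if best is None or key > best[0]:
                    best = (key, rec.name, res)
            if best is not None:
                row.update(
                    nearest_family=best[1],
                    nearest_identity_pct=best[2].identity_pct,
                    nearest_similarity_pct=best[2].similarity_pct,
                )
        if "project" in config.stages:
            try:
                projection = activity_mod.project_activity(
                    PeptideRecord(
                        name=q["name"], sequence=q["sequence"],
                        amidated=q["amidated"], group=Group.novel,
                    ),
                    catalogue, activity, organism=config.organism,
                )
                row.update(
                    mic_neighbor=projection.neighbor,
                    projected_mic_um=projection.mic_um(config.organism),
                )
            except ValueError as exc:
                logger.error("project stage failed for %s: %s", q["name"], exc)
                raise
        rows.append(row)

    written: dict[str, Path] = {}

    columns = [
        "name", "sequence", "amidated", "signal", "acidic", "mw",
        "net_charge", "pI", "gravy", "hydrophobic_pct", "mu_h", "motif",
        "nearest_family", "nearest_identity_pct", "nearest_similarity_pct",
        "mic_neighbor", "projected_mic_um",
    ]
    kinds = {"mw": "da", "gravy": "f3", "mu_h": "f3",
             "nearest_identity_pct": "pct", "nearest_similarity_pct": "pct"}
    report_tsv = out_dir / "report.tsv"
    with open(report_tsv, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    _fmt(row.get(c), kinds.get(c, "")) for c in columns
                )
                + "\n"
            )
    written["report.tsv"] = report_tsv

    report_json = out_dir / "report.json"
    with open(report_json, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(rows, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    written["report.json"] = report_json

    if "conserve" in config.stages and len(queries) >= 2:
        profile = conservation_profile([q["sequence"] for q in queries])
        conserve_tsv = out_dir / "conservation.tsv"
        residues = sorted({a for col in profile.columns for a in col})
        with open(conserve_tsv, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("position\t" + "\t".join(residues) + "\n")
            for i, col in enumerate(profile.columns, start=1):
                fh.write(
                    f"{i}\t"
                    + "\t".join(f"{col.get(a, 0.0):.4f}" for a in residues)
                    + "\n"
                )
        written["conservation.tsv"] = conserve_tsv

    if "tree" in config.stages and len(queries) >= 3:
        records = [
            PeptideRecord(name=q["name"], sequence=q["sequence"],
                          amidated=q["amidated"], group=Group.novel)
            for q in queries
        ]
        tree = phylo.build_tree(
            phylo.distance_matrix(records), method=config.tree_method
        )
        newick = out_dir / "tree.nwk"
        newick.write_text(phylo.to_newick(tree) + "\n", encoding="utf-8")
        written["tree.nwk"] = newick

    return written
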