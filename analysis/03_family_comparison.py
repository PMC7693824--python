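"""Pairwise comparison of the five novel peptides against the family,
plus positional conservation and the GXXDXXK motif scan.

Writes results/pairwise_novel.tsv and results/conservation.tsv.
"""

from pathlib import Path

import ocellatin as oc
from ocellatin.datasets import NOVEL_PEPTIDES

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    catalogue = oc.load_catalogue()
    family = oc.family_members(catalogue)
    by_name = {r.name: r for r in catalogue}
    OUT.mkdir(exist_ok=True)

    pairwise = OUT / "pairwise_novel.tsv"
    with open(pairwise, "w", encoding="utf-8") as fh:
        fh.write("novel\tother\tidentity_pct\tsimilarity_pct\n")
        for novel in NOVEL_PEPTIDES:
            for other in catalogue:
                if other.name == novel:
                    continue
                res = oc.global_align(by_name[novel].sequence, other.sequence)
                fh.write(
                    f"{novel}\t{other.name}\t{res.identity_pct:.1f}\t"
                    f"{res.similarity_pct:.1f}\n"
                )
    print(f"wrote {pairwise}")

    res = oc.global_align(
        by_name["ocellatin-11"].sequence, by_name["ocellatin-2"].sequence
    )
    print(f"ocellatin-11 vs -2: {res.identity_pct}/{res.similarity_pct}")
    res = oc.global_align(
        by_name["ocellatin-10"].sequence, by_name["P3-Lla-2085"].sequence
    )
    print(f"ocellatin-10 vs P3-Lla-2085: {res.identity_pct}/{res.similarity_pct}")

    novel_profile = oc.conservation_profile(
        [by_name[n].sequence for n in NOVEL_PEPTIDES]
    )
    print(f"novel invariant positions: {novel_profile.invariant_positions}")
    family_profile = oc.conservation_profile([r.sequence for r in family])
    print(f"family invariant positions: {family_profile.invariant_positions}")

    conservation = OUT / "conservation.tsv"
    residues = sorted({a for col in family_profile.columns for a in col})
    with open(conservation, "w", encoding="utf-8") as fh:
        fh.write("position\t" + "\t".join(residues) + "\n")
        for i, col in enumerate(family_profile.columns, start=1):
            fh.write(
                f"{i}\t" + "\t".join(f"{col.get(a, 0):.4f}" for a in residues)
                + "\n"
            )
    print(f"wrote {conservation}")

    strict_hits = [
        r.name for r in family if oc.motif_scan(r.sequence, strict=True)[0]
    ]
    print(f"strict GXXDXXK motif: {len(strict_hits)}/28 family peptides")


if __name__ == "__main__":
    main()
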