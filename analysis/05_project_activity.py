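"""Project MICs for the five novel peptides and rank them.

Each novel peptide inherits the MIC of its most similar exactly-measured
family neighbour; the ranking orders the novel set by expected activity.
Writes results/activity_projection.tsv.
"""

from pathlib import Path

import ocellatin as oc
from ocellatin.datasets import NOVEL_PEPTIDES

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    catalogue = oc.load_catalogue()
    activity = oc.load_activity()
    queries = [oc.get_peptide(n, catalogue) for n in NOVEL_PEPTIDES]
    ranked = oc.rank_novel(queries, catalogue, activity)

    OUT.mkdir(exist_ok=True)
    path = OUT / "activity_projection.tsv"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "rank\tname\tneighbor\tsimilarity_pct\tprojected_mic_um_ecoli\n"
        )
        for rank, (query, proj) in enumerate(ranked, start=1):
            mic = proj.mic_um("E_coli")
            fh.write(
                f"{rank}\t{query.name}\t{proj.neighbor}\t"
                f"{proj.similarity_pct:.1f}\t{mic:g}\n"
            )
            print(
                f"{rank}. {query.name}: ~{mic:g} uM against E. coli "
                f"(from {proj.neighbor}, {proj.similarity_pct:.1f}% similar)"
            )
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
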