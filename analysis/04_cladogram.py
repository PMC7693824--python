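"""Similarity cladogram over the 28 family peptides.

Writes results/family_cladogram.nwk (UPGMA, identity distance) and
reports the cluster memberships of the L. latrans peptides.
"""

from pathlib import Path

import ocellatin as oc
from ocellatin.phylo import leaf_depths

OUT = Path(__file__).resolve().parent.parent / "results"

CLUSTERS = [
    ["ocellatin-10", "ocellatin-6"],
    ["ocellatin-9", "ocellatin-7", "ocellatin-8", "ocellatin-5"],
    ["ocellatin-11", "ocellatin-2", "ocellatin-3"],
]


def main() -> None:
    family = oc.family_members()
    tree = oc.build_tree(oc.distance_matrix(family), method="upgma")
    OUT.mkdir(exist_ok=True)
    path = OUT / "family_cladogram.nwk"
    path.write_text(oc.to_newick(tree) + "\n", encoding="utf-8")
    print(f"wrote {path}")

    for cluster in CLUSTERS:
        mono = oc.is_monophyletic(tree, cluster)
        print(f"{'clade' if mono else 'NOT a clade'}: {', '.join(cluster)}")
    depths = leaf_depths(tree).values()
    print(f"ultrametricity spread: {max(depths) - min(depths):.2e}")


if __name__ == "__main__":
    main()
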