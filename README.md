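# ocellatin

Analysis toolkit for **ocellatins**, the family of antimicrobial peptides (AMPs)
found exclusively in the skin of *Leptodactylus* frogs. Ocellatins are short
(21/25/32-residue), weakly cationic (net charge 0 to +3), mostly C-terminally
amidated peptides that act on bacterial membranes. The package implements the
complete in-silico characterization workflow used when new family members are
cloned from skin cDNA:

1. **Precursor parsing** — translate a cloned cDNA and segment the prepro-peptide
   into its tripartite architecture: a 21-residue signal peptide ending in the
   family's single Cys, a D/E-rich acidic spacer ending in the Lys-Arg prohormone
   processing site, and the mature peptide. A mature-terminal Gly marks
   C-terminal amidation (the amide is ~1 Da lighter than the free acid and one
   charge unit more basic).
2. **Physicochemical profiling** — average mass with amidation accounting
   (Σ residue masses + H₂O − 0.9847 Da if amidated), formal net charge at pH 7,
   Henderson–Hasselbalch continuous charge and pI, GRAVY
   (mean Kyte–Doolittle hydropathy), hydrophobic residue percentage, the
   Eisenberg hydrophobic moment μH = |Σᵢ hᵢ·(cos iδ, sin iδ)|/N at δ = 100°,
   Schiffer–Edmundson helical-wheel geometry, and μg/mL ↔ μM MIC conversion.
3. **Family comparison** — Needleman–Wunsch global alignment (BLOSUM62,
   gap open 10 / extend 0.5) with identity/similarity over total alignment
   length, positional conservation of the left-flush family alignment,
   the GXXDXXK N-terminal motif scan, and fragment classification.
4. **Cladogram** — UPGMA (default) or neighbor-joining on 1 − identity
   distances, exported as Newick.
5. **Activity projection** — a peptide without a measured minimal inhibitory
   concentration (MIC) inherits the MIC of its most similar exactly-measured
   family neighbour, and novel peptides are ranked by projected activity.

The 28 described family peptides, the fragment records, and the published MIC
table are packaged as TSV data (`src/ocellatin/data/`). A synthetic-precursor
generator emulates the cDNA architecture with ground truth, so the parser is
testable end to end without any database access.

Intended users: peptide chemists and molecular biologists doing AMP
bioprospection who need the standard characterization panel to be
reproducible and scriptable.

## Worked example

```python
>>> import ocellatin as oc
>>> rec = oc.get_peptide("ocellatin-11")
>>> rec.sequence
'GVLDIFKDAAKQILAHAAEKI'
>>> oc.average_mass(rec.sequence, amidated=True)
2250.67
>>> oc.net_charge_formal(rec.sequence, amidated=True)
1
>>> res = oc.global_align(rec.sequence, oc.get_peptide("ocellatin-2").sequence)
>>> res.identity_pct, res.similarity_pct
(95.2, 100.0)
```

The mass is the theoretical average mass of the amidated 21-mer in Da; the +1
charge reflects 3 Lys against 2 Asp + 1 Glu with a neutral amidated C-terminus;
ocellatin-11 differs from ocellatin-2 in a single conservative K↔Q substitution
(20/21 identical columns → 95.2% identity, 100% similarity).

The numbered scripts under `analysis/` run the full study:

```text
$ python analysis/05_project_activity.py
1. ocellatin-10: ~15 uM against E. coli (from P3-Lla-2085, 95.2% similar)
2. ocellatin-7: ~28 uM against E. coli (from ocellatin-5, 81.0% similar)
3. ocellatin-8: ~28 uM against E. coli (from ocellatin-5, 81.0% similar)
4. ocellatin-9: ~28 uM against E. coli (from ocellatin-5, 76.2% similar)
5. ocellatin-11: ~300 uM against E. coli (from ocellatin-PT1, 72.0% similar)
```

i.e. among the five newly cloned peptides, ocellatin-10 is projected the most
active (its nearest measured neighbour, the hybrid analog P3-Lla-2085, differs
by a single conservative I↔L substitution and has a 15 μM MIC), followed by
ocellatin-7, -8, -9 and -11.

A `ocellatin` console command exposes each stage
(`synth`, `parse`, `profile`, `compare`, `conserve`, `tree`, `project`, `run`).

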