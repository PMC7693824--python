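# Methods

## Precursor model

Frog-skin AMP genes encode a tripartite prepro-peptide: signal peptide,
acidic propiece, mature peptide. The parser encodes the family-specific
form of that architecture as explicit rules:

- the signal peptide runs from the initiator Met to the **first Cys** found
  at positions 15–25 (the family signal is 21 residues long and its Cys is
  the only one in the precursor, so "first" is safe and keeps the signal
  N-terminal);
- the acidic propiece extends to the **last Lys-Arg dipeptide that leaves at
  least 15 residues** of mature peptide. Only the literal K-R site is
  accepted — not KK or RR dibasic pairs, which this family does not use. The
  last-eligible rule reflects the K-R sitting at the carboxyl end of the
  acidic domain and makes decoy K-R pairs earlier in the spacer harmless;
  a K-R inside the mature region closer than 15 residues to the C-terminus
  is ineligible and also harmless. The accepted spacer length is 15–30,
  a slack band around the observed 19–22;
- a mature-terminal Gly is the amidation donor: it is removed and the
  peptide flagged amidated.

Translation (standard genetic code, first ATG to first stop) offers
`frame=auto`, which picks the frame whose product starts with Met and
contains a K-R dipeptide, breaking ties by ORF length. Codons containing N
translate to X and fail residue validation downstream rather than being
silently dropped.

All coordinates are 1-based inclusive, matching residue-numbering style
(Gly¹, Asp⁴).

## Physicochemical panel

- **Mass.** Average (isotope-averaged) residue masses from the ExPASy
  ProtParam table plus one water (18.01524 Da); amidation subtracts
  0.9847 Da (-OH → -NH₂). Average rather than monoisotopic masses are used
  because they are what the family's published theoretical masses are;
  all eight published masses reproduce to ≤ 0.011 Da. A mass-accounting
  aside: ocellatin-6's published 2273.77 Da equals the *amidated* 22-mer
  with the terminal Gly still in place — chemically inconsistent (the Gly
  is the amidation donor), which is why its amidation flag is stored as
  ambiguous and it is excluded from mass checks.
- **Formal charge** at pH 7: +1 N-terminus, +1 per K/R, −1 per D/E, His
  neutral, −1 C-terminus unless amidated. This integer model reproduces
  every published family charge.
- **Continuous charge / pI.** Henderson–Hasselbalch summation with an
  EMBOSS-style pKa set (C-term 3.6, D 3.9, E 4.1, H 6.0, N-term 8.6,
  K 10.8, R 12.5, Y 10.1, C 8.5), pI by bracketed root finding (Brent) on
  [0, 14] to |z| < 1e-4; the charge is strictly decreasing in pH so the
  root is unique. Published pI values came from unidentified tools, so
  they are validated as brackets (9–11.5 for the cationic members), not
  pinned.
- **GRAVY**: mean Kyte–Doolittle hydropathy, computed with exact (`fsum`)
  summation so it is invariant under residue reordering, reported to
  3 decimals.
- **Hydrophobic percentage**: residues in {A,C,F,I,L,M,V,W} over length,
  ×100, truncated toward zero. Truncation (not rounding) is the only
  convention reproducing both published values 42% (9/21) and 52% (11/21).
- **Hydrophobic moment**: Eisenberg vector sum on the Kyte–Doolittle scale
  (the scale the published range was computed on), δ = 100°, normalized per
  residue. Note a uniform-hydropathy homopolymer only cancels exactly over
  full 18-residue wheel periods; at other lengths a partial-period residual
  remains. The family's values land in 0.59–1.49, bracketing the published
  0.6–1.49 range.
- **MIC conversion**: μM = 1000·(μg/mL)/Mw, reported at integer rounding.

## Alignment conventions

Needleman–Wunsch global alignment, BLOSUM62, gap open 10 / extend 0.5,
terminal gaps penalized as ordinary gaps (Biopython `PairwiseAligner`
is the engine). Identity counts identical columns over the **total**
alignment length — gap columns stay in the denominator, which is what
reproduces 19/21 = 90.5% for the 21-mer vs 20-mer pair. Similarity
additionally counts substitutions with strictly positive BLOSUM62 score
(so K↔Q and I↔L are conservative). Two published cells involving
ocellatin-5 (71.4/76.2 and 57.1/76.2) do not reproduce under any simple
convention — the original online tool's exact settings are not recoverable —
and are documented as non-reproduced; all robust pairs are pinned in tests.

Conservation across the mixed-length family uses the left-flush layout of
the published alignment (no internal gaps), profiling columns up to the
shortest member (21). Under it, Asp4 is the single invariant family
position, while the five novel peptides share invariant
{Gly1, Asp4, Lys7, Lys11, Glu19, Lys20}.

## Cladogram

Distance = 1 − identity fraction, no substitution-model correction: the
published figure displays raw similarity clustering, not an evolutionary
model fit. UPGMA is the default (the published tree is an ultrametric-style
cladogram); neighbor-joining is provided for completeness and is validated
by exact recovery of an additive 6-leaf matrix built from hand-computed
path lengths. Labels are sorted before agglomeration so the tree does not
depend on input order. Cluster-membership claims are tested; the exact
topology is not, since the original tree-building tool is unstated.

## Activity projection

The published activity reasoning is qualitative ("expected to behave like
its closest measured relative"). It is operationalized as deterministic
nearest-measured-neighbour transfer: the neighbour is the catalogue peptide
with maximal similarity among those with an *exact* MIC for the reference
organism (bounds, inactive, untested and zone-assay-only records are
excluded as donors), ties broken by identity then name. Ranking of novel
peptides is by ascending projected E. coli MIC with ties broken by higher
formal charge, then higher hydrophobic moment, then name — charge and
amphipathicity being the family's activity-relevant parameters. The
tie-break is a package decision, not a published rule; with it, the
projected order is ocellatin-10 (15 μM), then -7, -8, -9 (28 μM), then -11.

MIC rows whose published μM value was quoted from an earlier source with
coarser rounding (nearest 5 or 10, or a legacy mass) are listed in
`datasets.MIC_SOURCE_ROUNDED`; their conversions agree within 4.2%
relative but not at integer rounding, and tests treat them accordingly.

## Synthetic data generator

The generator emulates the precursor architecture statistically: signal =
Met + hydrophobic-biased core + single Cys at position 21; acidic spacer of
19–22 residues with ≥ 40% D/E ending in the only K-R; mature peptide of
21–32 residues sampled per-position from the family's positional frequency
profile (padded with overall family residue frequencies beyond column 21),
rejected if it contains Cys or a K-R pair, ends in Gly, or leaves the
family's formal-charge envelope of [−1, +4]; amidation with probability 0.9
(the family default — only the three longest members are free acids).
cDNAs are uniform synonymous-codon back-translations with a 5′ UTR drawn
from {C,G,T} (so no spurious upstream ATG), a random stop codon, a 3′ UTR
and poly-A. The rare codon randomization whose off-frame reading would
yield a longer spurious ORF is rejected and redrawn, keeping fixtures
unambiguous by construction. `adversarial=True` plants a decoy K-R inside
the spacer (and, for long matures, an ineligible one near the C-terminus)
to exercise the last-eligible-site rule.

What the generator does **not** model: real codon usage or GC content of
Leptodactylus, UTR structure, sequencing errors, and polymorphism between
precursor copies. Passing round-trip tests therefore show the parser is
correct for the family architecture as described, not that it is robust to
arbitrary real-world cloning artefacts.

## Problem sizes and determinism

All computations are closed-form or small-matrix; the full test suite runs
in seconds. The parser round-trip is exercised on 500 generated precursors
plus 50 adversarial ones; the cladogram on all 28 family members (378
alignments). Every random draw flows through a seeded NumPy generator;
batch records use per-record sub-seeds derived from the batch seed, so
fixture files are byte-stable.

## Known limitations

- The two non-reproduced published alignment cells and nine
  source-rounded MIC conversions, documented above.
- Fragments whose sequences were never printed (P2-Ll-1298, the 17-residue
  ocellatin-5* variant) and ocellatin-F1 (MIC known, sequence not printed)
  cannot be packaged; ocellatin-F1's rows are kept but cannot serve as
  projection donors.
- No α-helix content prediction, 3D structure, aggregation or hemolysis
  modelling; logo and wheel outputs are numeric tables, not figures.
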