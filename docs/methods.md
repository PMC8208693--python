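# Methods

## Alien index

The alien index for a query protein is

    AI = ln(best recipient E value + ε) − ln(best donor E value + ε),  ε = 1e-200

with natural logarithms. "Recipient" is the query's own lineage (here
typically the tRNA nucleotidyltransferase paralogue of a related species);
"donor" is the candidate source lineage. E values are taken from the
homology-search table as given and never recomputed from alignments. Two
conventions matter and are fixed here:

* **Missing hits.** A lineage with no hit contributes E = 1. This is the
  only convention under which the stated maximum of the index, 460.5,
  follows from the formula: ln(1 + ε) − ln(0 + ε) = 200·ln 10 ≈ 460.517.
* **Rounding.** Reported integers round half away from zero
  (`round_half_up`); full precision is kept in JSON output.

Best hits per lineage are the minimal-E rows, with ties broken by larger
bit score, then larger percent identity, then lexicographic subject id —
a deterministic rule so reruns are byte-identical.

Classification: AI > 30 → `very_likely_hgt`; 0 < AI ≤ 30 → `possible_hgt`;
AI ≤ 0 → `no_hgt_signal`. The optional identity rule (donor identity ≥70 %
with positive AI → `likely_contamination`) exists for prokaryote-to-
eukaryote screens and is off by default for prokaryote-to-prokaryote
comparisons, where near-identity to the donor is the expected signature of
a recent transfer rather than of contamination.

The package ships the fifteen published donor/recipient E-value pairs as a
regression dataset. Recomputing them reproduces thirteen printed integers
exactly; the Mesorhizobium and Campylobacter rows recompute to 416 (printed
413) and 401 (printed 400). The package follows the formula and documents
the two discrepancies (`datasets.KNOWN_DISCREPANCIES`) rather than
special-casing those cells.

## Signature-motif scanning

Patterns use a PROSITE-like grammar: bracketed residue sets, bare residues,
`x` (any), `h` (hydrophobic), hyphens ignored as cosmetic separators. The
PAP I consensus therefore has exactly 11 positions, and both 13-residue
example signatures align to an 11-position window under that reading. The
hydrophobic class defaults to the conventional aliphatic + aromatic set
{A,V,L,I,M,F,W,C}; it is an argument everywhere because "hydrophobic" has
no single standard definition. Scanning tests every window (overlaps
included, no masking) and counts class violations; `scan` returns windows
within a tolerance (default 0), `best_window` always returns the
minimal-violation window (ties to the smallest start) so near-matches can
be reported with their mismatch count. Note the second published signature
(IIGRFFVIHVHIL) violates the strict consensus at ≥2 positions under any
standard hydrophobic set; the package reports its best-window mismatch
count rather than guessing a looser matching criterion.

## G+C composition

mol% G+C uses Biopython's weighted ambiguous-base convention: G, C and S
count 1; A, T, U, W count 0; other IUPAC codes contribute their expected
G+C fraction (R = N = 0.5, B = V = 2/3, D = H = 1/3); the denominator is
the full sequence length. With plain ACGT input this is the direct count.
Affinity compares |gene − donor orthologue| against |gene − host genome|;
exact ties are reported as `tie`, not resolved. Fold ratios
(element/genome) are reported to one decimal in TSV, full precision in
JSON. Gene G+C is computed on the annotated 1-based inclusive span and is
strand-invariant.

## Trees and congruence

Newick parsing and patristic distances are delegated to dendropy; internal
node labels are read as support values, auto-declared per-mille when any
value exceeds 100 (phylip-style of-1000 bootstrap scores), else percent.
Missing branch lengths are imputed as 1 and flagged.

`collapse_low_support` contracts each internal edge whose child support is
below the threshold, re-attaching the children to the parent (leaves are
never removed). Consensus-style collapsing is a topological operation, so
the contracted edge's length is discarded by default and a warning notes
that post-collapse patristic distances are topology-biased; with
`redistribute=True` the length is added to every re-attached child edge,
which preserves all leaf paths that crossed the collapsed edge (paths
wholly inside the collapsed clade gain twice the edge length). The
pipeline uses `redistribute=True` so the nearest-neighbour computation
after collapsing remains meaningful.

`congruence_check` finds the patristic-nearest candidate leaf (ties broken
lexicographically and flagged, because the congruence claim should not
rest on silent tie-breaking) and compares it with the blast-best subject;
the query's sister-clade leaf set is reported alongside, so a
clade-sisterhood reading of "closest neighbour" can be checked against the
patristic one. The check is invariant under re-rooting since patristic
distances are.

## MGE proximity

Flanking windows (default 5 kb) are 1-based inclusive, clipped at the
contig, with upstream/downstream defined on the gene's strand. Distance
follows the terminal-base convention — from the gene's 3′-terminal base to
the element's proximal base on the 3′ side, and from the 5′-terminal base
on the 5′ side — counted as the simple coordinate difference, so an
abutting element is at distance 1; the two named bases could also be read
as a gap count (abutting = 0), and the package fixes the difference
convention once and states it. Overlapping elements get distance 0 and a
flag. The report filters strictly at the configured flank; published
tables of this kind occasionally include elements slightly beyond the
nominal window because their search region spanned the full flank + gene
interval, so a caller wanting that behaviour should widen `flank`.

## Synthetic data generator

`TransferScenario` defaults define the study conditions: recipient genome
33 mol% G+C, donor 71 mol% (the most dramatic published genome/gene
contrast, ≈33 vs ≈71), genome 100 kb, gene 900 bp, donor-orthologue
identity drawn uniformly in [80, 100] %, same-lineage identity in
[29, 38] %, eight tree leaves, two MGEs inside and one outside the 5 kb
flank. Genomes draw bases i.i.d. at the target composition; the focal gene
is instead a shuffled exact-composition multiset so its mol% is pinned to
the scenario target (sampling noise at 900 bp would otherwise be ~1.5
percentage points SD), with the signature motif's codons optionally
spliced in at a codon boundary. The gene replaces a recipient-genome
segment, keeping genome length constant. The translated query protein
masks incidental stop codons with L: the generator controls composition,
not ORF validity, and no pipeline stage translates the genome.

E values come from a Karlin–Altschul-shaped map
E = K·m·n·exp(−λ·S) with K = 0.041, λ = 0.267, m = n = 450 and a
match/mismatch score S = L·(2·p − 0.3·(1 − p)) per gene of length L and
fractional identity p. The mismatch penalty (−0.3 per residue) makes the
map span the realistic range — E < 1e-180 at 100 % identity and
E > 1e-40 at 30 % for a 900 bp gene; a through-the-origin linear score
cannot cover both ends. Only monotonicity in identity matters downstream:
the alien index consumes E values, not alignments.

Trees are random binary joins over a donor clade and a recipient clade
(branch lengths uniform in [0.2, 0.5], supports uniform in [700, 1000] so
every node survives collapse at 700); the focal leaf is grafted on 0.01
branches sister to the donor leaf (transfer) or to a recipient leaf
(null), which guarantees the constructed nearest neighbour. All outputs
are pure functions of the scenario, seed included.

What the generator does **not** emulate: codon usage, post-transfer
amelioration of composition toward the host, indels and partial-coverage
alignments, paralogous gene families, or tree-inference noise. Passing the
recovery tests therefore shows the pipeline's logic is sound under
idealized signals of realistic magnitude, not that the thresholds are
well-calibrated for noisy real genomes.

## Pipeline aggregation

`hgt_supported` requires AI category `very_likely_hgt` **and** at least one
corroborating signal (donor-consistent composition **or** tree
congruence); `no_support` is exactly a non-positive AI; everything else is
`ambiguous`. The published analyses aggregate these signals narratively;
this rule is the package's explicit codification, with the thresholds
(`ai_very_likely`, `collapse_support`, `flank`, the identity rule) exposed
in the `[thresholds]` section of the run configuration. Motif presence and
MGE proximity are reported but deliberately excluded from the verdict:
the motif defines the gene family rather than its origin, and MGE
proximity is supportive context whose absence should not veto a call.

## Problem sizes and determinism

The recovery analysis runs 100 transfer and 100 null scenarios at the
default 100 kb genome / 900 bp gene scale (about 5 s total); the motif
oracle comparison uses 1000 random proteins of length 11–60. Property
tests are seeded (hypothesis runs derandomized), and reports are written
with deterministic ordering so a rerun on the same inputs is
byte-identical.

## Known limitations

* Lineage assignment (donor/recipient grouping of subjects) is caller
  input; the package does no taxonomy inference.
* E values are trusted as given; different search tools' E-value scales
  are not reconciled.
* `collapse_low_support` assumes supports annotate the child node of each
  edge (the common Newick convention); trees annotated otherwise must be
  converted first.
* Coverage is accepted as a 13th column (`qcovs`) without committing to
  query vs subject semantics; it is labelled simply "coverage".
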