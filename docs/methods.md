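# Methods

## Domain scanning

A GATA-type zinc finger is detected as the literal cysteine scaffold
Cys-X₂-Cys-Xₙ-Cys-X₂-Cys with n ∈ {17, 18, 19, 20}. Coordinates are
0-based and end-exclusive everywhere; for a hit starting at `s` the four
cysteines sit at `s`, `s+3`, `s+n+4` and `s+n+7`, and `end − start =
n + 8`. Spacing classifies family: 17 → canonical GATA, 18 → WC-2-like,
19/20 → Ash1-like. All overlapping hits are reported; choosing one
representative per protein is a separate, explicit step (`best_domain`),
which scores each candidate against a consensus by global alignment and
keeps the maximum (ties → smallest start). The default consensus is the
canonical scaffold with neutral filler; callers studying a specific clade
should supply an anchor domain instead.

The strict retention pattern
(C-X₂-C-X₄-T-(P/S)-(L/V)-W-R-(R/K)-X₇-C-N-X-C followed by ≥ 25 residues)
implies inter-cysteine spacing 4+1+1+1+1+1+1+7 = 17, so every strict match
is also a generic X₁₇ hit — an invariant the tests enforce on random
sequence. The X₂₅ tail is read as "at least 25 residues remain", since the
pattern delimits a retained alignment block and an exact-length reading
would reject full-length proteins. The ambiguity code X in input proteins
satisfies only unconstrained positions, never a required C/T/P/S/L/V/W/R/K/N:
an unknown residue is not evidence for a conserved one. Duplicate removal
within a species collapses byte-identical *domain* substrings (not whole
proteins); identical domains in different species are kept, since
cross-species recurrence is the signal of interest.

## Alignment, distances, neighbor-joining

Pairwise global alignment uses the Gotoh three-state recursion with affine
gaps; a gap of length L costs `gap_open + (L−1)·gap_extend` with defaults
+1/−1/−2/−1 (match/mismatch/open/extend) — no scoring scheme is canonical
for 25-residue domains, so the simplest edit-like scheme is the default
and all four numbers are configurable. Traceback ties resolve
deterministically: diagonal, then gap-in-second-sequence, then
gap-in-first. p-distance is the mismatch fraction over gap-free columns;
an alignment with no such columns is a degenerate-input error rather than
0 or 1.

Trees come from standard neighbor-joining on the p-distance matrix:
iteratively join the pair minimising Q(i,j) = (r−2)·d(i,j) − Σₖd(i,k) −
Σₖd(j,k), with branch lengths from the usual closed form and the final
three nodes resolved analytically into a trifurcating (unrooted) root.
Ties in Q are broken by the lexicographically smallest pair of subtree
labels, so runs are reproducible. Negative branch estimates are clamped
to zero with the deficit moved to the sibling branch, preserving the path
length between the joined pair. Multiple alignment (and likelihood
methods) are deliberately out of scope: the tree is a clustering aid for
family assignment, and on additive matrices pairwise distances already
recover the generating topology exactly, which is what the round-trip
tests require (Robinson–Foulds 0, tip-to-tip paths within 1e−9). Family
labels propagate from anchor leaves by minimum path length, ties to the
smallest anchor id.

## Promoter motif windows

Motifs are IUPAC strings (GATAA; GYGGGG with Y = C/T). Windows live in a
gene-oriented frame with the TSS at 0 and upstream negative; for a
minus-strand gene "upstream" is genomic rightward, and both genome
strands are always scanned (a site's function is not assumed to depend on
which strand carries it, matching how the motif maps mark sites on both
strands). A site belongs to a window iff its 5′-most base in the gene
frame lies inside the half-open interval — an unambiguous edge rule for
sites straddling a boundary, implemented by extending the scanned
sequence by motif-length − 1 past the downstream edge. Windows truncated
at contig edges are flagged rather than silently shortened.

The default grid is ±200…±2000 bp in 200-bp steps (10 upstream, 10
downstream windows) and counts are capped at 2 ("2 or more"), combined
over both strands; a per-strand mode records per-strand capped counts
separately for users who read the 0–2 range as per strand. The combined
reading is the default because it is the simpler interpretation and the
capped categories are what the downstream statistic consumes. Uncapped
counts are retained alongside, and widening a window can only grow them
(a tested monotonicity invariant). Genomic distance from the TSS is used
for downstream windows (no transcript-relative coordinates); TSSs default
to the annotated 5′ transcript end (GFF3) or BED interval end by strand.

## Expression statistics

Fold changes are log₂((mean FPKM num + ε)/(mean FPKM den + ε)) with
ε = 0.1 FPKM by default, computed as a difference of logs so that
swapping the contrast negates the value exactly. Replicates are averaged
on the FPKM scale before the ratio; mean-of-per-replicate-ratios is
available as an option. Per-gene differential q-values, when present in
input tables, are carried through untouched — this package does not
re-implement a differential-expression model.

The motif-count statistic bins genes by capped category per window and
reports the mean fold change and bin size; empty bins carry n = 0 and an
undefined mean rather than an error, and the bin means always average
back to the global mean (a tested identity). "Average difference in
expression" is implemented as the mean of per-gene log₂ fold changes (not
the difference of group mean log-expressions); with the difference-of-logs
definition the two agree up to the ε terms.

Distribution shifts of a gene set use a two-sided Mann–Whitney U test of
the set against its complement within the background — set-vs-complement
rather than set-vs-all keeps the null exact when the set is part of the
background. Exact enumeration is used when the smaller group has ≤ 20
members, the normal approximation with tie correction otherwise. Top-N
enrichment uses the hypergeometric upper tail (enrichment only), N = 500
by default, with Bonferroni correction over the number of sets tested;
zero-hit sets are reported with fold enrichment 0 rather than dropped.
The default gene universe is all genes with mean FPKM > 0 across samples.

## Synthetic data

The generators define the conditions every recovery test runs under:

* **Genome**: one contig of uniform-random ACGT, rejection-resampled
  until zero occurrences of any configured motif remain on either strand.
  This makes planted-count recovery a sharp (exact-equality) test instead
  of a statistical one. Genes alternate strands at random with TSSs ≥
  4200 bp apart and ≥ 2200 bp from contig edges, so neighbouring ±2000 bp
  windows never overlap and no window is clipped.
* **Planted motifs**: per-gene site counts drawn from {0,1,2,3} (uniform
  by default), offsets uniform in a configured gene-frame range — GATAA
  in (−200, 0) so every upstream window contains all of a gene's sites,
  GYGGGG across (−2000, 0) — each instance on a uniformly chosen genome
  strand. After every insertion the gene's ±2 kb span is rescanned for
  all motifs and must match the recorded truth exactly; junction-created
  or clobbered sites trigger a resample.
* **Expression**: baseline log₂ FPKM ~ Normal(5, 2) per gene (an FPKM
  scale typical of moderately expressed genes); every sample adds
  Normal(0, σ) replicate noise and mutant samples add
  Σ_motif β·min(count, 2). Defaults β = 0.5 for GATAA only (GYGGGG
  unresponsive), σ = 0.5, 4 replicates per strain — chosen as a
  realistically noisy but detectable effect at 2,000 genes, where the
  recovered slope has a standard error well under the 0.1 reporting
  tolerance.
* **Proteome**: cysteine-free random backgrounds (so a planted domain
  yields exactly one hit), planted generic or strict domains, and decoys:
  spacings 16/21, broken conserved Thr/Trp/Arg, and tails shorter than 25
  residues. Plain spacing-17 plants force a non-Thr at the strict
  pattern's Thr slot so their strict/generic status is deterministic.

All generators are pure functions of (parameters, seed); a master seed
fans out to per-component streams seeded by (seed, CRC32 of a component
tag). What the simulation does **not** model: realistic base or codon
composition, introns and alternative TSSs, overlapping genes, dispersed
motif positions correlated with function, FPKM mean–variance coupling,
or mapping noise. Passing recovery tests therefore demonstrate that the
machinery is correct and calibrated, not that real promoters behave this
cleanly.

## Problem sizes

The shipped checks use 500 random 200-residue proteins (scanner oracle),
10,000 sequences (strict-pattern consistency), 200 random trees of 4–12
leaves (NJ round-trip), a 2,000-gene genome (count recovery, effect
slope, strand symmetry), 1,000 null simulations of 50-gene sets in a
2,000-gene universe (type-I error), and the complete (K, n, k) lattice at
N = 20 (enrichment oracle) — sizes at which every statistical tolerance
is comfortably resolved while the whole suite runs in well under a
minute of compute per check.

## Known limitations

* The scanner is a literal pattern matcher by design; it will not find
  degenerate domains a profile HMM would, and it reports no homology
  statistics.
* NJ on non-additive (noisy) distance matrices returns a valid tree but
  with no optimality guarantee; branch clamping can distort lengths when
  the matrix is far from additive.
* The enrichment model treats gene sets as flat (no ontology
  propagation) and the list as an unordered draw.
* With ε = 0.1, fold changes of genes with FPKM near or below ε are
  compressed toward zero; this is intentional shrinkage of unreliable
  ratios.
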