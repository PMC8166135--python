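# Methods

`nlrmap` re-creates, as a tested pipeline, an intra-species analysis of
NLR (nucleotide-binding, leucine-rich-repeat receptor) gene divergence
across accessions of one plant species: classify NLRs by NB-ARC motif
content, place every accession's NLRs on one reference coordinate system,
partition ortholog groups into core / dispensable / specific, test
physical gene clusters for copy-number variation (CNV), and explain CNVs
mechanistically through premature stop codons, frameshifts and large
insertions. This note documents the models, the defaults and why they
are what they are, and what the simulation-based validation does and
does not establish.

## NB-ARC classification (`nbarc`)

The NB-ARC domain (Pfam PF00931) carries four diagnostic motifs. The
default detector uses curated consensus regular expressions:

| motif   | pattern          | role                       |
|---------|------------------|----------------------------|
| P-loop  | `G.{4}GK[ST]`    | Walker A nucleotide binding|
| Kinase2 | `[LIVMF]{3,4}DD` | Walker B                   |
| GLPL    | `GLPL[AST]`      | ARC1 signature             |
| MHDV    | `MHD[VLIA]`      | ARC2 signature             |

A candidate NLR is any protein with at least one hit. A candidate is
**intact** when at least three of the four motifs occur with strictly
increasing starts in the canonical order P-loop < Kinase2 < GLPL < MHDV
and the span from the first selected hit's start to the last selected
hit's end covers at least 160 aa; otherwise it is **partial**. Per motif
at most one hit enters the order test (best score, ties leftmost);
overlapping same-motif matches collapse the same way. The NB-ARC region
of an intact NLR is defined as exactly that first-hit-to-last-hit span —
a deliberate, documented convention, since motif hits do not delimit the
Pfam domain boundary precisely. Position-weight-matrix scoring can be
substituted for the regex patterns through the same `motif_set`
interface without touching the rule logic; the rule (count, order,
length), not the motif model, is what this package contributes and what
the tests pin down.

## Subgroup assignment (`grouping`)

Intact NLRs are assigned to phylogenetic subgroups (G1, G2, G8, G10, GT,
GR, ...) by supported monophyly with labelled references:

1. NB-ARC regions are aligned (built-in progressive aligner: 3-mer
   Jaccard guide tree by average-linkage, profile-profile
   Needleman-Wunsch merges with mean BLOSUM62 column scores, linear gap
   -6 per column; or any externally produced FASTA alignment).
2. Columns with a gap fraction strictly above 0.92 are removed.
3. Pairwise identity distances (1 − identical/comparable over gap-free
   column pairs) feed neighbor joining (Saitou–Nei), with ties in the
   Q-criterion resolved to the lexicographically smallest cluster-name
   pair so input order never changes the topology.
4. Edge support is a nonparametric column bootstrap (resample columns
   with replacement, recompute distances and NJ, count bipartitions),
   1000 replicates by default, 100 in the orchestrated pipeline run.
5. Each unlabelled leaf takes the subgroup of the smallest clade —
   either side of an internal edge with support ≥ 90 — whose labelled
   members are unanimous; no such clade means unassigned.

A maximum-likelihood tree with ultrafast bootstrap can be dropped in as
Newick (supports as internal node labels) via `tree_from_newick` or the
pipeline's `imported_tree` option; the assignment rule is agnostic to
where the supports came from. Re-implementing ML inference itself is a
non-goal: the assignment *rule* is the contribution under test, and NJ
on identity distances is consistent (tested against additive matrices)
and cheap.

Partial NLRs are assigned by a similarity vote against the intact
NB-ARC regions: a "match" is a local BLOSUM62 alignment (affine
−11/−1) with ≥ 50% positives among aligned pairs and ≥ 30% coverage of
the intact reference; the group with the most matches wins, ties going
to the single most similar match, then the lexicographically smallest
group label. "Positives" and "subject coverage" are one concrete
reading of BLASTp-style similarity/coverage; both thresholds and both
definitions are parameters.

## The NLR map (`anchors`)

Query accessions are anchored to the reference with MUM-style seeds:
maximal runs of 21-mers that occur exactly once in each sequence, on
both strands. Repeated regions — including duplicated genes — therefore
produce no anchors, which is precisely the 1-to-1 semantics wanted for
copy-number work. Per sequence pair and strand, the highest-weight
collinear chain (weight = matched bp, longest-increasing-subsequence
dynamic program) becomes the anchor chain; minimap2/NUCmer-style PAF
blocks can be imported instead.

A gene projects through the chain by its midpoint: inside a block, a
rigid shift; between blocks less than 100 kb apart, proportional
interpolation into the target-side gap ("bridged"), or — when the
target side is gapless — collapse to a zero-length point flagged
"inserted" (the material exists only in the source genome, e.g. an
accession-specific insertion); otherwise unmapped. The midpoint
convention makes cluster membership robust to partial overlap with
chain gaps. On simulated panels, projected midpoints sit within the
local planted-indel slack of the true locus (observed median 0, max
≈ 1.4 kb under default mutation rates).

## Clusters, orthologs and the pan-NLR catalog (`catalog`)

Mapped NLRs merge into **physical clusters** wherever consecutive genes
on the reference are separated by strictly less than 50 kb (bedtools
`merge -d 49999` semantics; a gap of exactly 50 kb splits). Ortholog
groups are inferred within clusters only — synteny-constrained
orthology, mirroring the map-then-cluster order of the original
procedure — as reciprocal best hits: candidates ranked by global
alignment score (a sparse all-positive alignment at negligible coverage
must not outrank a true ortholog carrying one substitution), edges kept
at ≥ 50% positives and ≥ 30% mutual coverage, connected components
split greedily at the weakest-similarity edge until no group holds two
genes of one accession. Leftovers are singletons.

Groups are **core** (members in all accessions), **specific** (exactly
one accession — this takes precedence in the degenerate one-accession
panel), or **dispensable** (in between). Percentages are reported
against the full candidate count including unmapped genes, rounded
half-up to one decimal: with the published five-accession composition
(391 core groups, 555 dispensable groups totalling 1,670 genes,
specific counts 161/43/44/160/245, 4,357 candidates) the catalog
arithmetic yields 1,955 core genes (44.9%), 38.3% dispensable, 4,278
categorized (98.2%). Pan/core accumulation curves enumerate all k!
accession orderings up to six accessions and seeded random orderings
beyond.

## CNV statistics (`cnv`)

Per-cluster NLR counts across accessions are screened by sample
standard deviation (ddof = 1; the accessions are a sample) with
retention at SD > 2, then tested for departure from **equal copy
number**: expected count = row mean, χ² = Σ(o−e)²/e on n−1 degrees of
freedom. Only one margin exists — accession totals differ for reasons
(assembly completeness) the analysis deliberately ignores — so the
goodness-of-fit-to-uniform form is the right reading. Benjamini–
Hochberg correction runs across the tested rows (statsmodels step-up
behind `bh_adjust`); significance is q < 0.05. Expected counts below 5
attach a `low_expected` warning rather than a refusal, since small
clusters were tested in the original procedure too. The worked
16:15:1:9:12 count profile gives SD 6.02, χ² 13.70 (df 4), p 8.3×10⁻³.

Subgroup enrichment is computed per non-overlapping 1 Mb reference
window with an exact hypergeometric upper tail (k of n window genes in
a subgroup with K of N genome-wide), BH-corrected across all emitted
(window, subgroup) tests. A binomial tail would serve as well at these
sizes; hypergeometric is the default because it is exact and
parameter-free.

## Pseudogene mechanics (`pseudo`)

An intact protein is aligned to a syntenic genomic window in codon
space by an exact dynamic program whose states allow: codon
match/substitution (BLOSUM62 on the translated codon), whole-codon gaps
on either side (affine, open 11 / extend 1 per codon), frameshift steps
consuming 1, 2, 4 or 5 bases for one residue (penalty 20), and stop
codons at a flat read-through penalty of 20 — so every premature stop
along the optimal path is observed, not only the first (regions with a
dozen stops are countable). The protein is global; flanking DNA is
free, so padded windows cost nothing.

Two scoring choices matter and were set from the contract the events
must satisfy, not from convention:

- **Frameshift penalty 20, below twice the gap-open cost.** A ±1/±2
  event cannot be absorbed by a protein-gap + DNA-gap pair (the
  arithmetic mod 3 forbids it), but near sequence ends a free-flank
  detour can outcompete an expensive frameshift; at 20 a planted
  single-base indel in mid-protein is always reported as exactly one
  frameshift op.
- **DNA-gap cost capped at a flat 60** (≈ open + 50 codons). With
  uncapped affine gaps an 8 kb insertion costs ~2,600 while threading
  the remaining protein through the inserted sequence costs ~2 per
  residue, so the optimal path would never bridge the insertion; the
  cap — the same idea as an intron state in spliced aligners — makes
  long insertions appear as codon-gap runs, reported as
  `large_insertion` above 1,000 bp.

Frameshift breakpoints are defined only up to score-tie equivalence
inside local sequence repeats; ties resolve to the leftmost equivalent
breakpoint, which can sit up to about two codons from the mutated base.
Premature-stop positions are codon-exact.

`compare_region` projects a reference gene into another accession,
pads by 10 kb, aligns both strands, and issues a verdict: **absent**
when nothing projects, the best alignment scores ≤ 0 or covers < 50% of
residues with matches/substitutions, or the alignment does not overlap
the projected locus (NLR clusters are full of near-identical paralogs;
without the locus check a deleted gene's window "finds" its neighbor);
**pseudogenized** when premature stops, frameshifts or large insertions
are on the path; **conserved** otherwise. Alignment is intronless —
the simulator's genes are single-CDS, and spliced alignment is a
declared non-goal of this version.

## The synthetic panel (`simulate`)

The generator emulates a five-accession panel of one species: a
reference with clustered, intronless NLR genes and derived accessions
mutated from it with fully logged truth.

- **Genes.** Each protein is `M` + head(20 aa) + P-loop + linker(55) +
  Kinase2 + linker(55) + GLPL + linker(55) + MHDV + tail(30): the
  motif-to-motif span is 189 aa ≥ 160, so every simulated gene is
  intact by construction (verified by re-scanning at build time, with
  resampling if a barcode segment ever spoofs a motif). Subgroup
  identity lives in the linkers: each subgroup draws its barcode
  segments from a template over a subgroup-specific amino-acid alphabet
  (ILVM / FYW / KRQ / DEN / STA / GPHC), chosen so different alphabets
  almost never score positive under BLOSUM62. Genes of one subgroup are
  ~97% identical (3% per-gene jitter within the alphabet); genes of
  different subgroups share only the motif cores. This makes both the
  tree route and the similarity vote cleanly decidable — and is also
  the generator's main departure from real NLRs, whose subgroups form a
  similarity continuum. Passing recovery tests therefore demonstrates
  the correctness of the assignment rules, not their power on
  borderline real clades.
- **Layout.** Genes sit in clusters with intra-cluster gaps of 3–8 kb
  and inter-cluster gaps of 60–90 kb, on 700 kb chromosomes (2 by
  default, 8 clusters of 4–8 genes). Clusters destined for planted CNV
  are built with 16 genes — the scale of the strongly variable cluster
  the method is meant to flag; at 4–8 genes the same relative effect
  cannot pass the SD > 2 screen, which is a property of the screen, not
  of the implementation.
- **Mutation.** Per derived accession (child seeds by fixed arithmetic
  from one panel seed): background SNVs at 5×10⁻⁴/bp and small 1–10 bp
  indels at 2×10⁻⁵/bp genome-wide; per-gene exclusive events — whole-
  gene deletion, duplication placed < 50 kb away (inside the cluster),
  an in-CDS insertion of 7.5–8.5 kb (multiple of 3), or a targeted
  single-base substitution creating a premature stop in the 20–40%
  codon window (upstream of Kinase2, so the truncated protein drops to
  partial). Planted CNV clusters apply per-accession keep-fractions
  16:15:1:9:12 by forced deletions. Derived coordinates are lifted
  through all length-changing edits; proteins are re-translated from
  the mutated genome. Everything is bit-reproducible from (config,
  seed).
- **What is not simulated.** Repeats, heterozygosity, assembly gaps,
  introns, base-composition bias, and gene-model mis-annotation. The
  anchoring stage in particular sees an easier genome than reality
  (unique background sequence), so the 100% map-assignment rate on
  simulations is an upper bound, not a field expectation.

`simulate_cluster_counts` is the generator's count-level shadow —
reference counts plus binomial per-accession gene loss/gain — used for
the statistical calibration suites (200 null panels, 100 planted-power
replicates) where sequence-level simulation would add nothing to a
count-level test. Because binomial thinning is underdispersed relative
to the χ² null, the observed null false-positive rate is far below
α = 0.05: the test is conservative under this loss model.

## Orchestration (`pipeline`, CLI `nlrmap`)

`nlrmap run` executes scan → subgroup assignment → map → catalog → CNV
→ pseudogene scan (the last only on significant clusters), writing
self-describing TSV/BED/Newick outputs and a JSON manifest of
parameters, seeds and per-stage record counts; `nlrmap simulate` writes
a panel with truth tables; `nlrmap report` renders a run summary
including the planted-truth comparison in simulate mode. Identical
config + seed reproduces identical outputs.

## Problem sizes

Defaults are desk-scale: panels of 2 × 700 kb chromosomes across five
accessions (~250 NLRs), 100–200 bootstrap replicates, 200 + 100
calibration replicates at count level, and a 100-event pseudogene
battery. A full pipeline run completes in about a minute on one CPU;
the complete test suite in well under a minute apart from the
end-to-end fixtures.

## Known limitations

- Regex motif models are a stand-in for profile-based NB-ARC detection;
  sensitivity on real proteomes depends on the supplied motif set.
- Orthology is synteny-constrained; genes relocated across clusters
  will surface as specific rather than orthologous.
- The chain model handles collinear divergence, insertions and
  deletions, but not inversions or translocations within a chromosome
  beyond choosing the better strand.
- χ² on small clusters is approximate (warned, as `low_expected`); an
  exact multinomial or Monte-Carlo p-value is a natural extension.
- Frameshift positions are leftmost representatives of score-tie
  classes; downstream consumers should treat them as codon-resolution.
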