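# Methods

This note documents the models and conventions prophagekit implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Coordinates and input model

All intervals are 0-based half-open internally; every emitted table is
1-based inclusive (GFF/NCBI style), and the conversion lives only in
`genome_io`.  A `Replicon` carries explicit topology (`circular`/`linear`),
an explicit `oric_offset` (0-based position of the replication origin on
the stored sequence) and a `central_ori` flag.  The origin position is
metadata, not something the package infers: for circular replicons it
defaults to 0 (the usual convention for deposited chromosomes that start
near *oriC*) and for linear replicons to the sequence midpoint, the layout
of *Streptomyces* chromosomes.  Predictor intervals are treated as linear
substrings of the stored sequence and may not wrap the circular origin —
that is how prediction tools report fragments.

Prophage prediction, ORF calling, domain search, tRNA detection,
defense-system and BGC detection are all out of scope: the package
consumes their tabular outputs (regions TSV/GFF3, domain-hit TSV, tRNA
GFF3, DefenseFinder/antiSMASH-style hit tables).

## Classification

A prophage is **intact** iff it retains ≥ 1 integrase-class domain *and*
≥ 1 structural (capsid/tail/portal) domain; it is **remnant** ("cryptic")
if it has retained domains but fails either requirement, and **discarded**
if it has no conserved domain at all.  The seeded category map names the
diagnostic Pfam accessions (integrase `pfam00589`, rve `pfam00665` —
treated as integrase-qualifying because rve is the integrase core domain —
capsid `pfam05065`, minor tail `pfam10145`, portal `pfam05133`,
`pfam04860`) and is user-extensible via YAML; curated extensions (e.g.
PHROG-derived structural terms) can be added without code changes.

Hits are retained at e-value ≤ 0.01 by default — conventional for
RPS-BLAST-style searches; no cutoff is canonical, so it is configurable.
Intact/remnant percentages are always reported over *annotated*
(non-discarded) prophages, with the discarded count separate.  Domain
abundance tables count each accession once per prophage by default
(`dedupe_per_region=True`, i.e. "number of prophages carrying the
domain"); per-occurrence counting is available.  Ties rank
lexicographically so output is deterministic.

## GC, prophage fraction and tests

GC% is computed over unambiguous A/C/G/T only; ambiguity codes are kept in
the sequence but excluded from both numerator and denominator.  Prophage
fraction merges overlapping regions before summation, so double-predicted
intervals never inflate coverage.  A plasmid whose merged prophage
fraction exceeds 50% (strictly) is flagged as a putative phage-plasmid;
the rule deliberately applies to plasmids only.

The prophage-vs-host GC comparison is an unpaired two-sided Mann–Whitney U
test on the pooled GC distributions (tie-corrected normal approximation
with continuity correction), with per-prophage deltas reported alongside.
Pairing is biologically natural, so a Wilcoxon signed-rank mode exists,
but unpaired is the default since the two distributions have different
sizes in a survey.  P-values map to star codes `ns` (> 0.05), `*`
(≤ 0.05), `**` (≤ 0.01) and `****` (≤ 1e-4); there is deliberately no
`***` tier, matching the legend convention of the figures this mirrors.
Genome-size binning uses equal-width bins over the observed size range
(the last bin right-closed); identical sizes collapse into the first bin.

## ANI estimation and greedy clustering

ANI is estimated without alignment, from full canonical k-mer sets
(default k = 16, no MinHash subsampling — prophage/phage genomes are small
enough): with Jaccard similarity *j*,

    d = -(1/k) · ln(2j / (1 + j)),     ANI = max(0, 1 - d).

Alignment coverage of the shorter sequence is proxied by k-mer containment
*corrected for divergence*: a fully homologous sequence at identity *a*
shares only ≈ *a*^k of its k-mers, so coverage = min(1, containment /
ANI^k).  Without this correction a genuine full-length relative at 2%
divergence (containment ≈ 0.98^16 ≈ 0.72) would fail an 80% coverage
threshold that alignment-based tools would comfortably pass; the corrected
quantity estimates the aligned fraction rather than the identity.  Raw
containment is still reported.

Clustering is greedy and longest-first (ties by id): each sequence joins
the first cluster whose *representative* it matches at ANI ≥ 0.95 and
coverage ≥ 0.80, else founds a new cluster.  This reproduces the standard
viral species-level dereplication procedure; because membership is tested
against representatives only, the output is a deterministic partition and
removing a non-representative member never changes other assignments.

## k-mer phylogeny

Composition profiles use overlapping k-mers on the given strand (default
k = 4, 256 features — the standard genome-signature resolution; k is
configurable 1–8, and profiles can optionally be symmetrized with the
reverse complement).  Windows containing ambiguity codes are skipped.
Pairwise dissimilarity is the Jensen–Shannon divergence with base-2
entropies, bounded in [0, 1]; its square root is a true metric and is
available as `sqrt_jsd` where a metric matters.  Trees are built by UPGMA
(size-weighted proportional averaging, node height = merge distance / 2,
ties broken by the smallest current index pair, children ordered by first
input appearance), with neighbor joining as the non-ultrametric
alternative.  The pipeline builds the tree over one representative per ANI
cluster, mirroring the dereplicate-then-compare procedure used in genome
surveys.  Clade recovery is scored strictly: a planted group counts as
recovered only if some node's tip set equals it exactly.

## Integration sites

A prophage's position is its interval midpoint (`floor((start+end)/2)`) —
symmetric, and stable against boundary uncertainty — normalized by
replicon length.  Circular replicons are rotated so *oriC* sits at 0%;
linear replicons are not rotated.  The **ori half** is 0–25% ∪ 75–100%
(the quarter flanking the origin on each side) and the **ter half** is
25–75%; replicons flagged `central_ori` (Streptomyces-style linear
chromosomes) invert the assignment.  The flag is explicit per-replicon
metadata, never inferred from genus names.  Flanks default to 2 kb, wrap
across circular origins (capped so a flank never re-enters the prophage),
and truncate at linear ends.  A tRNA gene is adjacent if it overlaps the
region expanded by the window (default 2 kb, half-open), i.e. gap <
window; distances wrap around circular replicons.  Positional analyses can
be dereplicated to ANI-cluster representatives to suppress near-identical
genomes.

## Synthetic data generator

The generator emulates the structure of a lysogeny survey in a high-GC
phylum: i.i.d. host sequences at 66 ± 2 GC% (circular chromosomes,
a 25% share of central-origin linear chromosomes assigned to
*Streptomyces*, circular plasmids), prophages of 5–60 kb *inserted* (never
overwritten — matching integration biology) with GC 5 points below the
host, 0–8 prophages per genome, terminus bias 0.6, tRNA genes (76 bp) at
the upstream boundary of 15% of prophages, intact probability 0.53 with a
0.003 discarded fraction, and 10% of prophages drawn as substitution-only
mutated copies (2% per-base) of reference phage genomes (14–80 kb).
Insertion anchors are computed in post-insertion coordinates so cumulative
length growth does not drag realized positions out of their drawn ori/ter
half; the truth table records the *realized* half, position, GC and label,
and is exactly consistent with the emitted files.  Everything is a pure
function of the seed; re-emitting a bundle is byte-identical.

What it does **not** emulate: codon/oligomer structure (hosts are i.i.d.,
so composition-based clade recovery relies on shared ancestry, not
realistic genome signatures), indels and rearrangements (substitution-only
mutation keeps planted divergence ↔ expected ANI exact), att-site
duplication, gene content, or read-level noise.  Passing recovery tests
therefore demonstrates the correctness of the computations under the
stated generative model, not predictor performance on real genomes.

## Numerical choices and degenerate inputs

- Percentages print round-half-up, integer by default and one decimal
  below 2% (small shares like "1.3%" lose meaning at integer precision);
  every percent is stored next to its numerator and denominator and the
  report audits itself.
- Rank-sum tests with zero variance (all ties) report p = 1; an all-zero
  paired comparison is an error, as is a zero-length sample.
- Empty sketches (sequences shorter than k, or all-ambiguous) are errors
  at estimation time; the pipeline skips such regions with a logged count.
- Newick branch lengths are rounded to 10 decimals on output to suppress
  binary-float noise; tip labels are underscore-escaped.
- All-zero distance matrices, single-bin histograms and all-equal
  genome-size vectors degrade to documented degenerate outputs rather than
  errors.

## Problem sizes

The bundled tests and the acceptance script run the generator at compact
sizes chosen to exercise every code path with tight statistical targets:
2,000 labeled prophages for classification agreement, 20 × 100 kb
replicates for ANI recovery, 3 × 5 sequences at 2% divergence for clade
recovery, 500 planted prophages for terminus-bias and GC-offset recovery,
and a 16-replicon default pipeline run.  These sizes are the package's
own benchmark conditions; all recoveries are scored against the
generator's truth tables at pre-stated tolerances (binomial confidence
intervals, ±1 GC point, exact label agreement).

## Known limitations

- ANI is k-mer-estimated, not alignment-based; it is accurate in the
  90–100% identity regime the 95% threshold cares about but is not a
  substitute for nucmer/BLAST identity at low similarity, and the coverage
  correction assumes divergence is spread uniformly rather than
  concentrated in indel blocks.
- The intact/remnant rule is purely domain-presence-based; it cannot see
  frameshifts or truncations inside retained domains, so "intact" is an
  upper bound on inducibility.
- UPGMA assumes a molecular clock (ultrametricity); for deeply diverged
  phage sets the NJ option is more appropriate.
- The pipeline holds all replicon sequences in memory; it targets surveys
  of thousands of bacterial genomes on a workstation, not metagenome-scale
  assemblies.
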