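# Methods

## Scope and model

`amplindel` analyzes one PCR amplicon that co-amplifies a multi-copy,
high-homology gene family (the shipped defaults target a ~300 bp
α-gliadin amplicon carrying two sgRNA sites, amplified by aGli900F1 /
33mer1R2).  The unit of analysis is the **Amp**: a denoised, unique
amplicon sequence with per-line read counts.  Wild-type plants yield one
Amp per distinguishable paralog; Cas9 editing adds new Amps (edited
alleles) and removes wild-type ones (homozygous edits, large deletions).
The pipeline is reference-free in the usual sense: each edited Amp is
interpreted against the *closest wild-type Amp of its own background*,
selected via a neighbor-joining dendrogram, not against a fixed reference.

Assumptions worth stating explicitly:

- Paralogs differ mainly by substitutions; the primer landing sites and
  sgRNA target sites are conserved across copies (this is what makes a
  single-amplicon family assay possible at all).
- Editing outcomes are small NHEJ InDels near the cut (3 bp 5′ of the NGG
  PAM) or whole-copy losses; substitution-only outcomes are invisible to
  the classification logic and out of scope.
- Read pairs overlap enough to merge (2×280 bp reads over a ≤ ~540 bp
  amplicon).

## Read processing

**Merging.**  The best ungapped overlap between R1 and the reverse
complement of R2 maximizes `matches − 2·mismatches` (ties go to the longer
overlap); a pair is rejected if the overlap is shorter than `min_overlap`
(default 16 bp), has more than `floor(maxdiffs)` mismatches, or exceeds
`maxdiffpct` percent mismatches.  Posterior base qualities in the overlap
follow the standard two-observation model: agreeing bases get
`p' = (p1·p2/3) / (1 − p1 − p2 + 4·p1·p2/3)`, disagreeing columns keep the
higher-quality base with `p' = p_min(1 − p_max/3)/(p_min + p_max −
4·p_min·p_max/3)`; posterior qualities are capped at Q41.

**Expected-error filter.**  A merged read is kept iff
`Σ 10^(−Q_i/10) ≤ maxee`.  This is the only quality filter; there is no
positional trimming.

**Dereplication.**  Exact-string collapse, sorted by abundance descending
with lexicographic tie-break (the tie rule matters for determinism of the
greedy denoiser).

**Denoising.**  Greedy centroid pass in abundance order.  A unique with
abundance `a_U` joins an existing centroid (founding abundance `a_C`,
edit distance `d > 0`) iff `a_U/a_C ≤ β(d) = 2^−(α·d+1)`; among eligible
centroids the smallest `d` wins (ties: larger centroid, then earlier
centroid).  Otherwise it founds a centroid if `a_U ≥ floor(minampsize)`,
else it is discarded.  The skew test uses the *founding* abundance, not
the accumulated size, so join decisions do not depend on how many
error-reads were absorbed earlier.

**Chimera removal.**  A de novo pass removes centroids that are perfect
left/right concatenations of two distinct parent centroids, under two
guards that encode the PCR-crossover model: parents must be at least
`chimera_abskew` (default 2×) more abundant than the candidate (chimeras
form in late cycles and stay rare), and parents must have the candidate's
own length (a template switch between homologous same-length templates
yields a same-length product).  The length guard is essential in this
application: without it, a deletion allele is "explained" as
prefix-of-its-own-wild-type plus the identical tail of any other paralog
and silently removed — observed directly on simulated families.

**Assignment.**  Per-line counts come from assigning each line's merged
reads (dereplicated, abundance-weighted) to the pooled Amp set at
`identity ≥ 0.99` (configurable; an exact-match mode exists).  Identity is
matches over alignment columns with terminal gaps excluded, computed as a
semi-global alignment of the shorter sequence inside the longer.  This
also lets Amps that still carry primer bases match a primer-trimmed
database: the primers become free terminal overhangs.  Amps keep their
primers; because the forward primer is 21 nt — a multiple of 3 — the
design reading frame is preserved for motif translation either way.

### Tunable parameters

| knob | stage | default | note |
|---|---|---|---|
| maxdiffs | merge | 58.94 → 58 | mismatch cap in overlap |
| maxdiffpct | merge | 24.66 | % mismatch cap |
| min_overlap | merge | 16 | not optimized |
| maxee | filter | 1.13 | expected errors per merged read |
| minampsize | denoise | 22.47 → 22 | centroid seeding threshold |
| alpha | denoise | 2.0 | β(d) steepness; the published UNOISE default |
| identity | search | 0.99 | global identity threshold |

The first five defaults are the optimized values published for this assay;
they were tuned on real MiSeq data and are kept as defaults because they
are the assay's operating point.  Optimizer bounds default to the
published search intervals; identity, listed there as the discrete choice
"0.99 and 1", is explored over (0.9, 1.0).  Real-valued settings of
integer knobs are floored at use.

## Parameter optimization

The objective runs the whole chain and returns the negative number of
reads contained in Amps that match a curated amplicon database; tuning on
wild-type samples only is supported via a flag (edited material would
reward parameters that destroy real variants).  The optimizer is
sequential model-based: after `max(5, d+1)` seeded random points, a
Gaussian-process surrogate (Matern 5/2, normalized inputs and outputs)
proposes each next point by expected improvement maximized over a seeded
candidate cloud (1024 uniform + 256 local points around the incumbent).
A pure random-search method is selectable, and everything is reproducible
from one seed.  Default budget: 50 evaluations.  `OptResult.best_score`
is the minimized objective, i.e. −(matched reads).

## Normalization and presence

TMM follows the published method with its standard defaults: reference
column by upper-quartile closest to the mean, 30%/5% two-sided trims on
M/A values, precision weighting, factors renormalized to geometric mean 1.
The implementation reproduces `edgeR::calcNormFactors` to < 1e−8 (checked
in the test suite via Rscript).  Normalized values are reported as
counts-per-million: `count / (library size × factor) × 1e6`; the CPM
constant is a display choice and cancels in frequencies.  Frequencies are
percentages per line; presence uses a *strict* threshold
(`freq > 0.3%`).  One nuance: with precision weighting, TMM factors are
invariant to rescaling a single column only approximately (the weights
depend on absolute counts); the unweighted variant (`weighted=False`) is
exactly invariant.

## Classification

WT Amp membership is the union over a background's WT replicates; the
*reported* WT count is the rounded mean of per-replicate totals (that is
what the offspring tables print for the WT row).  For an edited line:
CRISPR Amps = present ∖ WT set; non-targeted = present ∩ WT set; putative
targeted = WT set ∖ present.  When a line has **no** CRISPR Amps, WT
presence is re-checked at a stricter (lower) secondary threshold, default
0.1%, before any WT Amp is declared targeted — without edits there is no
mechanism for losing a WT Amp, so near-threshold dropouts are treated as
noise.  The 0.1% value is this package's choice; the rule itself (not the
value) comes from the published workflow.  Offspring tables order lines
by pedigree (T0, its T1s, their T2s) and flag a line as non-segregating
when its non-targeted and CRISPR sets equal its parent's.

Subgenome assignment translates the amplicon in the design frame and
looks for diagnostic peptide motifs; exactly one matching subgenome gives
the call, zero or several give NA.  The shipped motif table is a
synthetic placeholder — real diagnostic motifs are a curation input the
user supplies.

## Dendrogram, reference picking, InDel calling

Pairwise distances: global alignment (match +1, mismatch −1, gap open −2,
gap extend −0.5); `d = (mismatched columns + gap runs) / columns`.
Counting a gap *run* once keeps a 9 bp NHEJ deletion from dominating the
substitution signal that actually separates paralogs.  Neighbor joining
is the classic Q-matrix algorithm with Saitou–Nei branch lengths,
negative lengths clamped to zero with a warning, and ties broken on the
smallest contained label; it reconstructs additive matrices exactly
(property-tested to n = 8, cross-checked against scikit-bio).

Clusters are maximal subtrees under a height cut of the midpoint-rooted
tree; the cut defaults to the median internal-node depth (the published
figures drew cluster bars manually, so some convention was needed).  A
CRISPR Amp's reference is the minimum-distance WT Amp in its cluster,
falling back to the globally nearest WT Amp when the cluster has none;
distance ties go to the lexicographically smallest id, and the function
can never return a non-WT Amp.

InDels are maximal gap runs in the pairwise alignment, reported at their
left-normalized 1-based reference position (gaps shifted maximally left —
repeat-rich sequence makes gap placement ambiguous, and left-alignment is
the standard convention).  Cut sites are indexed for *every*
protospacer+NGG occurrence on both strands (≤ 2 protospacer mismatches by
default; the repeat region can carry a site more than once) and an InDel
is attributed to the nearest cut within ±10 bp.  Left-normalization can
move a call a few bases 5′ of the simulated offset in repeat context;
type, length and site attribution are exact.

## qPCR copy-number model

`E = E_CFX/100 + 1`; `ratio = N · E_ref^MCq_ref / E_target^MCq_target`
with N the reference gene's copies per haploid genome (default 2).  Fold
change between edited and wild-type lines is the ratio of mean ratios per
reference gene; multiple reference genes are pooled by geometric mean on
the ratio scale.  Note the algebra: *lowering* MCq_target (more target
template) *raises* the ratio.

## What the simulator emulates — and what it does not

The generator builds an ancestral amplicon with the real primer pair and
both sgRNA protospacers+PAM embedded, plus an in-frame subgenome motif
slot, inside a longer gene (default 800 bp).  Paralogs are created by
independent substitutions at half the target pairwise divergence (default
2%), with primers, target sites and motif codons conserved; disabling
primer conservation makes primer-site destruction an explicit error.
Edits are applied at the cut site with exact truth tables; zygosity is a
molecular mixture (fraction of molecules edited), and large deletions
remove copies outright.  Reads are 2×280 with a truncated-normal quality
profile whose mean decays linearly (default 8 Q units across the read)
and is calibrated so the mean implied error probability equals the
requested substitution rate (default 0.2%); errors are then injected per
base with probability `10^(−Q/10)`, so qualities and errors are
consistent by construction.  All randomness derives from one integer seed
via `numpy.random.SeedSequence` spawning.

Not emulated: PCR chimeras (the chimera filter is exercised on
constructed cases only), indel sequencing errors, length-dependent
amplification bias, quality-by-cycle artifacts beyond the linear decay,
and real α-gliadin sequence composition (repeats are only as repetitive
as chance makes them).  Passing tests therefore demonstrate the logic and
numerics of the pipeline under realistic error rates and family
structure, not performance on real MiSeq chemistry.

## Problem sizes used by the test suite

The end-to-end round trip uses a 30-copy family (10 per subgenome), 30
edits spanning −9..+3 bp across all subgenomes, 3 copies (10%) lost as a
large deletion, and ~50,000 read pairs at 0.2% substitution error — sized
so the full suite runs in about a minute.  Denoising is verified against
an exhaustive independent implementation on 1000 random instances of ≤ 20
uniques; TMM against an independent implementation on 100 random matrices
(and edgeR directly); NJ against additive matrices up to 8 taxa.

## Known limitations

- Merging is strictly ungapped; an indel sequencing error inside the
  overlap fails the pair rather than being resolved.
- Two different copies edited to the same sequence collapse into one
  CRISPR Amp (inherent to sequence-level analysis; the published workflow
  has the same property).
- The greedy denoiser's join rule uses founding abundances in input
  order; it is deterministic but, like UNOISE, not invariant to abundance
  perturbations near the β(d) boundary.
- `pairwise_distances` is O(n²) Biopython alignments; fine for hundreds
  of Amps, not for tens of thousands.
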