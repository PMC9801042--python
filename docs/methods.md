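# Methods

This note documents the models, defaults, and numerical choices behind
`mircurate`, and what the synthetic benchmarks do and do not establish.

## Coordinate and sequence conventions

All intervals are 0-based half-open internally; GFF3 I/O converts to and
from the 1-based inclusive on-disk convention. Stored RNA always uses U
(FASTA/SAM input may use T), and minus-strand loci are stored as the
transcribed strand, so mature offsets, read-stack offsets, and duplex
coordinates are all expressed on one strand regardless of genomic
orientation.

## Compilation

Per-source annotations are parsed from GFF3 (`miRNA_primary_transcript`
and `miRNA` feature types by default, both configurable) with matures
nested by coordinate containment. Coordinate-free precursors are located
by exact/≤k-mismatch search on both strands (default k = 2, substitutions
only). Indel-tolerant placement is deliberately out of scope: the search
is deterministic and dependency-free, and precursors that move between
genome builds by more than a couple of substitutions deserve manual
attention anyway. A precursor with several genome hits becomes sibling
records that share a family letter.

Aggregation merges same-strand loci whose reciprocal overlap is at least
`min_overlap_fraction` (default 0.5), using single linkage; the
representative of a merged cluster is its longest member, sources are
unioned, and matures are deduplicated by (offset, length) after remapping
through genomic coordinates. Records without coordinates pass through as
singletons deduplicated by exact sequence, which also makes aggregation
idempotent. The merge fraction is exposed because no community consensus
exists for what counts as "the same locus" across databases.

Novel loci (present only in the predicted source) are named
`<prefix>-MIR_N<k><letter>` with `k` a running locus index in genomic
order and the letter distinguishing identical-sequence siblings; matures
take the `miR` stem plus a `-5p`/`-3p` arm suffix inferred from which
precursor half the mature midpoint occupies.

## Read processing

Reads use the collapsed representation standard in sRNA work (unique
sequence/placement plus count; adapter trimming and FASTQ collapsing are
upstream concerns). SAM parsing keeps mapped, ungapped alignments only,
recovers counts from the common `_xN` name suffix, and takes sample
identity from per-read RG tags. Multi-mapped reads count fully at each
placement up to a cap of 20 placements; fractional weighting is not
attempted because the criteria and precision statistics are per-locus
ratios that fractional counts would not change materially at typical
miRNA mapping multiplicities.

TPM uses all genome-mapped reads of a sample as the denominator — not
only miRNA-assigned reads — matching the usual definition and making
per-sample TPMs comparable across annotation versions. Expression breadth
is the fraction of samples at or above 1 TPM; "broad" requires strictly
more than half.

De-novo locus discovery is a read-cluster stage: same-strand reads within
200 nt cluster, clusters longer than 300 nt are discarded (plant
precursor length norms), and survivors are excised with 100-nt flanks;
the most abundant read becomes the provisional mature.

## Folding and duplex geometry

The default folder maximizes total pair weight over nested structures
with a Nussinov-style dynamic program: GC −3, AU −2, GU −1, minimum
hairpin loop 3 nt. These toy weights stand behind the MFE/AMFE symbols;
AMFE = energy / length × 100. The traceback is deterministic (pairing is
preferred over leaving a base unpaired on ties; the smallest bifurcation
point wins), so equal-energy structures resolve reproducibly. The folder
is validated against exhaustive structure enumeration on short random
sequences. Thermodynamic parameter sets, pseudoknots, and suboptimal
ensembles are out of scope, but any external folder can be used through
the verbatim dot-bracket input path, which scores supplied structures
under the active weights when no energy is given.

Star inference is fixed to canonical DCL geometry: the star spans the
pair-table partners of the mature, shifted to leave 2-nt 3′ overhangs on
both strands; unpaired anchor positions are skipped inward and the
skipped amount restored as overhang. Duplex mismatches count mature
positions unpaired or paired outside the star, excluding the mature's own
2-nt 3′ overhang — in a perfect stem those two positions necessarily pair
with bases just outside the star, so counting them would misclassify
textbook-perfect duplexes. Asymmetric-bulge nucleotides sum the imbalance
of interior loops between the two duplex strands. A mature whose partners
fall on both sides, or inside itself, straddles the terminal loop and is
rejected.

Processing precision is the fraction of stacked read counts whose 5′ and
3′ ends both fall within ±1 nt (configurable) of an annotated mature or
the inferred star.

## Feature registry

The default registry has 84 sequence features (mono/di/tri-nucleotide
frequencies) plus GC content and lengths; structure features (paired
fraction, MFE, AMFE, stem length, loop size, the four duplex statistics,
and a 20-bin per-position pairing profile); and three expression
summaries (max TPM, mean TPM, breadth). Raw per-sample TPMs as features
are supported in principle but summaries are the default: raw vectors
make the model dataset-shaped and unusable across studies with different
sample counts. The registry is versioned and configurable rather than
hard-coded, and both SVM training and scoring verify that candidate
vectors come from the identical registry. Candidates without a resolvable
duplex receive finite fail-worst sentinels (all-mismatch, zero overhangs)
rather than NaNs.

## Selection

Criteria defaults encode consensus plant rules: mature 20–24 nt,
precursor ≤ 300 nt, ≤ 5 duplex mismatches, ≤ 3 nt asymmetric bulge,
3′ overhangs of 2 ± 1 nt, precision ≥ 0.75, expression in ≥ 2 libraries,
and star evidence or cross-library replication of the canonical mature.
Every threshold is configuration-exposed. Missing read evidence fails the
evidence-dependent rules closed rather than erroring, so database-only
entries can still ride through on the SVM route — and conversely the
criteria route can rescue candidates the SVM finds atypical.

The one-class SVM (RBF kernel) standardizes features with center/scale
learned from the training positives only; zero-variance features are
dropped with a warning and recorded in the model. ν defaults to 0.05
(so ≈95% of the annotated positives score as inliers); γ defaults to
1/(number of kept features), the usual "scale" heuristic given unit
variance after standardization. The decision threshold is the natural
boundary (decision function ≥ 0) and is exposed as a parameter. The
final selection mode defaults to the union of the two routes; the
arithmetic of the published worked example (588 criteria + 704 SVM = 886
selected) is consistent only with a union.

## Curation analytics

isomiR classes are template variants only: add5/sub5 and add3/sub3 are
coordinate shifts of the read ends relative to the annotated mature, and
the amounts reconstruct the read interval exactly (an inverse-mapping
property the tests exercise). Non-templated tailing is out of scope.
Reads are assigned to an arm by which precursor half their 5′ end falls
in, so star-arm products are never misread as extreme mature variants.

Arm switching uses a pairwise dominance rule: an event requires one
sample where the 5p arm exceeds the 3p arm by ≥ 2-fold and another where
the reverse holds, with both arms at ≥ 1 TPM in each implicated sample.
The floor prevents ratio flips driven by zeros. The published analyses
present arm selection visually; this explicit rule is this package's
operationalization, and both thresholds are parameters.

Genomic context takes the highest-precedence feature label covering at
least half the precursor (default precedence TE > lncRNA > intron > exon >
miRNA-overlap, falling back to intergenic); TE subclasses (TIR, Helitron,
LINE, LTR) inherit TE precedence. Reports are static markdown + JSON so
regeneration from identical inputs is byte-deterministic — a property the
export tests assert.

## Polyploid homoeologs

Subgenome labels come from chromosome-name patterns (wheat convention
`1A`…`7D` by default). Homology is defined on mature sequences —
single-linkage clusters under edit distance ≤ 2 (edlib), with group ids
taken from the lexicographically smallest member so the partition is
input-order independent. Grouping on matures rather than precursors is a
design choice: mature sequences are the conserved, functional unit, and
precursor arms diverge much faster. Configurations are per-subgenome copy
counts (`1:1:1` = triad); any group with a duplicated copy or an unplaced
member is "others". The bias test is a plain goodness-of-fit χ² without
continuity correction against equal expectations (subgenome-size-
proportional expectations are available); for three subgenomes the
upper-tail p equals exp(−χ²/2), which the tests verify to 1e-10. Ternary
coordinates normalize (A, B, D) expression to shares; a zero-sum triple
yields a flagged undefined point instead of an error so whole tables can
be mapped.

## Synthetic fixtures

The generator plants perfect hairpins (random stem + loop +
reverse-complement stem) with the mature on the 5′ arm and the star at
the canonical 2-nt-overhang partner. Random stems occasionally admit an
equal-energy alternative fold through internal self-complementarity, so
stem draws are rejected until the folded structure reproduces the planted
duplex — the generator's contract is a perfect hairpin, not merely a
plausible one. Decoys are dinucleotide-shuffled copies (random Eulerian
walk on the dinucleotide multigraph) on separate contigs: composition
preserved, structure destroyed, and no reads by default.

Simulated reads mix, per locus and sample: canonical mature/star reads at
the planted precision; isomiR reads at the configured per-class rates
(1–2 nt end shifts); and a uniform background rejected away from ±2 nt of
canonical ends so that the planted precision is recovered without bias at
the default ±1 tolerance. Arm dominance is 0.8/0.2 by default and flips
between sample halves for a configurable fraction of loci (default 0.2)
to exercise arm-switch detection. Per-locus, per-sample depth is Poisson
around the configured mean, giving realistic expression variance.
Everything derives from one seed; equal configs produce byte-identical
on-disk bundles.

Default study conditions: 50 planted hairpins + 50 decoys, stem 30 nt,
loop 8 nt, mature 21 nt, depth 50 reads/locus/sample, precision 0.95,
4 samples. These sizes keep the full compile→reads→fold→select round trip
and the whole test suite at desk scale while leaving enough reads per
locus for the binomial recovery properties to be sharp.

What passing these benchmarks does **not** show about real data: planted
hairpins are perfect stems, so duplex thresholds are never stressed near
their boundaries; decoys preserve composition but not the hard negatives
real genomes produce (siRNA clusters, tRNA/rRNA fragments, inverted
repeats); read simulation has no sequencing error, adapter contamination,
or non-templated tailing; and the one-class separation of structure
features is easier than on borderline genuine loci. The benchmarks
establish correctness of the statistics and the plumbing, not real-world
sensitivity/specificity.

## Numerical choices and degenerate inputs

Folding requires ≥ min_loop + 2 nt and rejects non-ACGU(T) characters.
TPM requires positive library totals; breadth requires ≥ 1 sample;
precision requires a nonempty stack (an empty stack is an explicit "no
read support" error, while missing evidence inside the criteria engine
fails rules closed instead). One-class fitting requires ≥ 10 training
vectors. χ² requires a positive total; triad fraction requires ≥ 1 group.
Ties in the fold traceback, cluster ids, and report ordering are all
resolved lexicographically so every output is reproducible byte-for-byte.
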