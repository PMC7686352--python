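# Methods

This note records the models and procedures the package implements, the
defaults that matter, and the design choices made where the underlying
method leaves room.

## Coordinates and data model

Internal coordinates are 1-based fully inclusive (GTF native); BED input is
converted at the boundary (`start_internal = start_bed + 1`) and back on
write, so both round-trips are exact bijections. Genes whose transcripts
disagree on chromosome or strand are refused at load rather than silently
dropped — such genes are artefacts of coordinate mapping and a hard error
keeps provenance auditable. Chromosome-name harmonisation (e.g. `chr1` →
`1`) is a read-time map. BED6 entries without block structure become
single-exon transcripts, the simplest structure consistent with the record.
Chicken chromosome size classes default to macro = chr 1–5, micro =
chr 11–33, medium = other named chromosomes, and are configurable.

## Source aggregation

Two gene models overlap when any two of their transcripts are same-strand,
same-chromosome and share at least one nucleotide. The default compares
transcript extents (`level="span"`), equivalent to a bedtools intersect of
transcript features; `level="exon"` requires an exon-pair intersection and
is offered as the more stringent variant. Strand `.` never matches:
unstranded models cannot assert a same-strand conflict. Rejection is
gene-atomic — one overlapping transcript removes the whole candidate gene —
and merging never edits a model: every admitted gene is the identical input
record (sequential admission was chosen over meta-assembly merging
precisely because the latter fuses distinct models into chimeras). The same
rule, applied symmetrically, filters a coordinate-mapped catalogue against
a new assembly's reference annotation.

CAGE support of a source is the fraction of its LNC transcripts whose TSS
lies within a peak extended by the window (± 30 bp default, both endpoints
inclusive: support means |TSS − nearest peak bp| ≤ 30). Peak strand is
ignored by default (the peaks mark TSS positions, not gene models) with a
flag to require strand match. Sources are added in order of decreasing
support fraction; ties break lexicographically by label so runs are
deterministic. Gene-id collisions across sources are a hard error, not an
auto-rename.

## Pair classification

Distances are counted as bases strictly between two spans; bookended or
overlapping spans have distance 0. This differs by ±1 from some interval
toolkits' conventions and is fixed and documented here. Distance bins are
inclusive on the small side: ≤ 1 kb, ≤ 5 kb ("close"), > 5 kb ("distant").

For disjoint spans on opposite strands, the pair is *divergent* when the
two 5′ ends face each other across the gap (equivalently: the left feature
is on `-`), *convergent* when the 3′ ends do. Upstream/downstream is
relative to the PCG TSS. Genic subtypes use span containment (containing:
LNC ⊇ PCG; nested: LNC ⊆ PCG; equal spans count as containing); exonic vs
intronic uses exon–exon intersection only, with no partial exon splitting —
the simplest geometry consistent with the categories. The closest-PCG
search uses a 100 kb window measured from the transcript span edge; ties at
equal gap prefer the candidate upstream of the LNC, then the smaller
(gene_id, transcript_id). One gene-level record is emitted per LNC: the
shared call when all transcripts agree on (type, direction, partner),
otherwise the closest transcript's call (genic beating intergenic at equal
distance) flagged as a conflict. LNCs with no candidate in the window are
reported as unclassified, so record count always equals LNC count.

A useful internal symmetry: reflecting all coordinates and flipping all
strands views the locus from the opposite DNA strand and leaves every
classification field invariant (divergent stays divergent, upstream stays
upstream, since the reference TSS mirrors too). The property tests exercise
this invariance.

Host detection reports any small RNA (miRNA, snoRNA, snRNA) whose span lies
fully within an LNC gene span, regardless of strand — both sense and
antisense hosting occur in real annotations — recording the strand relation
and exonic/intronic location. Many-to-many relations are kept.

## Expression processing

Tissue profiles are arithmetic means of replicate TPM (median available);
mean is the usual convention for TPM tissue summaries. A gene is expressed
in a tissue at TPM ≥ 0.1, a common floor for lowly expressed lncRNA work.
The model-retention filter additionally requires read support: by default
every sample of at least one tissue must carry ≥ 5 expected reads — the
filter exists to remove models supported by one or two reads regardless of
replicate, and the all-samples reading enforces exactly that; any-sample
and tissue-sum readings are selectable flags.

Background-noise loci copy the LNC gene-length multiset and are placed by
rejection sampling, uniform over chromosome positions (chromosome chosen
length-weighted), at least 5 kb from any transcribed region; a length that
cannot be placed raises after a bounded number of tries. A seed is
mandatory in the CLI so locus sets are reproducible.

Tissue clustering uses 1 − Pearson correlation on log10(TPM + 1) profiles
with Ward linkage (Lance–Williams update on the supplied dissimilarities,
the ward.D2-equivalent convention — stated because the two common Ward
variants differ). Zero-variance profiles get correlation 0 with a warning
rather than an error. Dendrograms export as Newick.

Gene densities are counts per Mb per chromosome; size-class aggregates are
total counts over total Mb of the class, and the LNC–PCG density
correlation across chromosomes is Spearman.

## Tissue specificity

τ is computed on raw tissue-mean TPM exactly as printed above; no log
transform or sub-threshold zeroing by default (flags exist for log2(TPM+1)
input and for zeroing entries < 0.1, since published τ variants differ).
All-zero profiles have no defined maximum and are excluded as undefined
rather than assigned τ = 0. Top1/Top2 ties break by tissue-label order and
are flagged. The tissue-specific call is τ ≥ 0.95; the per-tissue counts
assign each specific gene to its Top1 tissue, and the TPM < 1 vs ≥ 1 tier
is split on Top1 expression. The τ ≥ 0.95 threshold does not analytically
imply any particular Top1/Top2 ratio; fold changes are reported but never
enforced.

## Co-expression statistics

Spearman ρ uses average ranks; the two-sided p-value is the t
approximation for n ≥ 10 and a full-permutation enumeration below that.
Constant vectors give undefined ρ and p = 1, and stay in the testing family
as not-significant so denominators remain auditable. BH adjustment is the
standard step-up, one family per pair kind and run (LNC:PCG and PCG:PCG
separately, since they are separate analyses); the |ρ| value corresponding
to the FDR cut depends on the empirical p distribution and is reported per
run, never hard-coded. Enrichment tests are one-sided (greater) Fisher
exact tests — the hypothesis is enrichment — with a two-sided flag; star
codes are * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001. Distance comparisons are
two-sided Mann–Whitney, exact for small tie-free samples. The
miRNA-hosting screen defaults to |ρ| ≥ 0.8 with BH FDR ≤ 0.01 within each
host's family (0.05 selectable).

## Synthetic data

The generators plant every quantity the analyses measure. Overlap-planted
genes share ≥ 1 bp with a designated base gene on the same strand (minimal
overlaps by default, to exercise the boundary of the merge rule);
non-overlapping genes occupy coordinate regions reserved per source, so
merged gene sets are order-invariant exactly when the theory says they
should be. CAGE peaks cover exactly the planted fraction of each source's
TSSs; the planted TSSs of different sources are kept ≥ 250 bp apart so no
peak supports a foreign transcript. Default support fractions are 7.3 %,
5.5 %, 5.3 % and 4.2 % over 1,000 transcripts per source — the reported
per-source support levels, at a transcript count where the rounded counts
are exact. Pair fixtures isolate each planted LNC:PCG pair in a 300 kb
block, beyond the 100 kb search window, so the planted partner is provably
the closest; planted gaps include the 1,000/5,000/5,001 bin boundaries and
the reported divergent and same-strand median distances (3,957 and
6,005 bp) as fixture values.

τ profiles invert the formula: a two-level profile (x, x/r, 0, …, 0) has
τ = 1 − 1/(r(T−1)), so r = 1/((T−1)(1−τ)) hits any target τ ≥ (T−2)/(T−1);
lower targets are rejected as unattainable for this profile family.
Correlated pairs use a Gaussian copula with Pearson parameter
2·sin(πρ_s/6) so the rank correlation targets the requested Spearman ρ
(exact at ±1). The expression panel defaults to 21 tissues × 8 replicates,
matching the structure of a multi-tissue atlas panel; replicate noise is
multiplicative log-normal and **off by default**, so planted values are
recovered exactly in tests; robustness tests set the scale explicitly
(at scale 0.1, high-τ targets are recovered within ±0.02, while flat
profiles drift upward because noise inflates the maximum). Read counts
follow TPM at a fixed depth factor, except planted low-support genes capped
at 2 reads everywhere, which the retention filter must remove.

What the generator does **not** emulate: real chicken genome composition,
exon-number and length distributions of real lncRNA models, mapping
artefacts, compositional TPM coupling across genes, or tissue-correlated
biological replicates. Passing tests therefore demonstrate correctness of
the rules and statistics on data satisfying their stated assumptions, not
performance on real sequencing data.

## Problem sizes

Defaults keep every stage desk-scale: 1,000-gene sources for the
aggregation tests (where the planted fractions are exact under rounding),
≤ 200-gene instances for the quadratic merge oracle, 10,000 random
profiles for the τ loop-vs-vectorised comparison, 100-seed null
simulations of 30–40 pairs for the FDR guarantee, and full enumeration
oracles only where they are cheap (n = 6 permutations, 2×2 tables with
margins ≤ 30).

## Known limitations

- The closest-PCG search is brute force over same-chromosome transcripts;
  fine for catalogue-scale inputs (tens of thousands of genes), but an
  interval-indexed search would be needed for much larger annotations.
- FEELnc-style classification supports one closest partner per LNC; the
  multi-partner/interaction-scoring variants are out of scope.
- Coding-potential prediction, quantification, liftover and
  pathway-enrichment lookups are upstream/downstream of this package and
  deliberately excluded.
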