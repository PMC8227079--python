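# Methods

This note documents the models, rules and numerical choices behind
`mitescape`, a pipeline for genome-wide annotation of miniature
inverted-repeat transposable elements (MITEs) and their interaction with
genes. It follows the analysis design used for the carrot (*Daucus carota*)
DH1 reference genome, generalised so every stage runs and is testable on
synthetic genomes with planted ground truth.

## Copy detection: the 80-80-80 rule with end anchoring

Full-length copies of each family consensus are located by local alignment of
the consensus against both strands of every contig. The engine is a k-mer
seeded Smith–Waterman:

* exact 11-mer matches between consensus and contig are clustered into
  candidate windows (clusters split at gaps larger than the consensus length
  plus 50 bp; each window padded by one consensus length);
* within each window, alignments are extracted Waterman–Eggert style: the
  best local alignment (match +1, mismatch −1, linear gap −2) is reported,
  its subject span masked, and the matrix recomputed until the best score
  falls below `floor(min_len × (2·min_identity/100 − 1))` (48 for the 80/80
  thresholds). Identity is matches over alignment columns, gaps included.

A hit is accepted as a full-length copy when it satisfies the 80-80-80 family
rule — identity ≥ 80 %, alignment ≥ 80 bp, covering ≥ 80 % of the consensus —
**and** is anchored at both consensus ends: the alignment must begin within
the first 10 bases of the consensus and end within the last 10 (offsets are
1-based; offset 1 means the terminal base aligns). Offsets are counted on the
query (consensus) ends; whether the original protocol counted them on query,
subject or both is not stated, so this choice is fixed and documented here.
Truncated or internal fragments are deliberately excluded — the annotation
counts full-length elements only.

When accepted copies of different families overlap by more than 50 % of the
shorter span, the copy with the highest identity × coverage is kept, ties
going to the lexicographically smaller family name. This resolution rule is a
design choice of this implementation.

With 11-mer seeds the scan is exhaustive in practice for the rule's operating
range: at the 80 %-identity floor an 80-bp alignment contains ~4.7 exact
11-mers in expectation, and the unit tests assert exact agreement with an
independently coded full-matrix aligner on ~50-kb windows.

## Structural classification: TSDs, TIRs, superfamilies

For every accepted copy, 50-nt flanks are extracted and the target site
duplication (TSD) is called by comparing the element-adjacent k-mers of the
two flanks for k = 10, 9, 8, 3, 2 (longest first; first exact match wins).
Only when no exact match exists at any length is a single mismatch tolerated
for k ≥ 8, with the call marked inexact — long TSDs drift, while two-base
ones must be exact because they match by chance too easily; probing tolerant
long k-mers before exact short ones would let chance near-matches shadow a
genuine 2–3-bp TSD. Elements whose adjacent hexamer on either side is a (TA)₃ run are
flagged as sitting in a TA microsatellite.

Terminal inverted repeats (TIRs) are called by scanning arm lengths 8–50 and
maximising the ungapped identity between the leading arm and the reverse
complement of the trailing arm (ties to the longer arm). A TIR is recognised
at arm ≥ 10 and identity ≥ 80 %; both thresholds are configurable, since
they stand in for what was originally a manual curation step.

The TSD → superfamily mapping is standard Class II biology:

| TSD                  | superfamily        |
|----------------------|--------------------|
| TA (k = 2)           | Stowaway (Tc1/mariner) |
| TAA / TTA (k = 3)    | Tourist (PIF/Harbinger) |
| any 8-mer            | hAT-like           |
| any 9–10-mer         | Mutator-like       |

Elements in TA stretches whose TIR identity is below 80 % are called MiM
(MITE inserted in microsatellite). The MiM rule runs first: a MiM's
microsatellite flanks always present a TA dinucleotide, so the plain mapping
would mislabel it Stowaway. MiMs are reported within the Mutator-like group
in summary tables, matching their accepted attribution.

Family-level clustering applies the same 80-80-80 relation (≥ 80 % identity
over ≥ 80 % of the shorter consensus and ≥ 80 bp, either strand) and takes
single-linkage connected components. Single linkage is the right closure
here: the rule defines a pairwise relation, not a partition, and merging
observed libraries (522 consensi → 428 families in the carrot work) implies
transitive grouping. The cluster representative is its longest member.

## Autonomous Mutator mining and MiM linkage

Putative autonomous partners of MiMs are mined by six-frame translated search
of Mutator transposase queries against the genome (local alignment under
BLOSUM62, gap open −11 / extend −1, score ≥ 100). Each hit region is
extended by 4 kb on both sides and the two flanks are aligned against each
other in complementary orientation (match +1 / mismatch −1 / linear gap −4).
An arm pair of ≥ 20 bp at ≥ 50 % identity with alignment score ≥ 20 defines
the element boundaries as the outermost arm coordinates; regions without
such a pair are reported as candidates without boundaries. The scoring and
the score floor are deliberate: a bare ≥ 20 bp/≥ 50 % contract is
statistically meaningless in a 4 kb × 4 kb comparison (with generous match
or gap scores, the expected maximum of a purely random flank pair exceeds a
genuine 25-bp arm's score, and chance alignments wander across diagonals
into qualifying "arms"). The stiff gap and the floor restore the
significance cut a default nucleotide blast self-hit applies, at the cost
that weakly conserved arms without match-dense cores go undetected — as
they would in the blast-based protocol too.

MiM consensi are linked to mined elements by aligning both 50-bp termini
against each element (both strands); a link requires ≥ 80 % identity over
≥ 30 bp. Consensi shorter than 50 bp are flagged per record.

## Genomic context and enrichment

Each copy receives exactly one category, evaluated in priority order
5′UTR > 3′UTR > CDS > intron > upstream > downstream > intergenic against
every gene on its contig. UTR/CDS categories require any overlap; intron
requires full containment ("located within"), so boundary-straddling copies
fall through to the next rule. Upstream/downstream are strand-aware windows
with an inclusive edge-to-edge gap ≤ 1000 bp; a copy near several genes takes
the highest-priority category over all of them, ties at equal priority going
to the nearest gene edge. Genes with several isoforms are collapsed to the
union of exons and of annotated UTRs, with intron space the gaps in the exon
union — the analysis categorises per gene, not per isoform.

The group × category table feeds a Pearson chi-squared test of independence:
E = (row total × column total)/grand total, statistic Σ(O−E)²/E with
df = (rows−1)(cols−1), reported with the per-cell contributions and deviation
signs that drive an enrichment balloon plot. The genic fraction is
100 × (total − intergenic)/total, genic meaning gene body plus the 1-kb
flanking windows.

## Co-transcription and the M/g statistic

Reads are matched to MITE copy sequences by local alignment (both strands,
best hit per read and copy); matches longer than 20 bp above 80 % identity
count as evidence. A copy is co-transcribed when at least ten matching reads
accumulate — summed over libraries by default (whether the original filter
was per tissue or pooled is unstated; a per-library mode only needs the
per-library evidence table). Co-transcribed copies join their host or
neighbouring gene through the context category; intergenic copies have no
gene to join.

Expression is normalised as RPK = count/(length/1000) and
normalized RPK = RPK/(library size/10⁶). For each gene × copy × library,
M/g is the MITE segment's normalized RPK over the gene's; the gene
denominator counts all reads on the gene span, MITE segment included (subset
semantics are not stated in the original; this choice is fixed here). A
record is selected when gene normalized RPK > 1 and M/g > 1.9, both strict;
the RPK > 1 filter is applied on the normalized scale (a raw-RPK reading is
available via a flag in the pipeline thresholds). Genes whose defined M/g
values span a range > 1.5 across ≥ 2 libraries are flagged as candidates for
tissue-specific isoform usage. M/g is invariant to library size by
construction; with a zero gene denominator the ratio is undefined and never
selected.

## Cross-species comparison

Between species, families are "related" under a laxer 60/60 criterion: best
local alignment (either strand) at ≥ 60 % identity covering ≥ 60 % of either
family's own length. The either-direction disjunction makes the relation
symmetric; "MITE length" is read as each family's own length, which the
original phrasing leaves ambiguous. Sharing is counted by direct matches
only — no transitive closure across species. The pairwise table carries a
similarity bin (identity × best coverage at 0.25/0.50/0.75 cuts) as a
stand-in for a blast score-ratio colouring; this is an approximation, since
score ratios and identity × coverage order pairs slightly differently.

## The synthetic data generator

`synthdata` emulates the survey's inputs at desk scale with exact ground
truth. Defaults are a 2-Mb genome in two contigs, eight families — two each
from the Stowaway/Tourist/hAT lineages at the mean element lengths observed
in the carrot census (254, 319, 454 bp), one Mutator-like family and one MiM
family — 25 copies per family at 10 % divergence, 120 genes, and twenty
libraries of 2 × 10⁶ reads, mirroring the twenty-tissue expression design.

Insertions are point events on the base coordinate system: each copy is
written as TSD + element + TSD (Stowaway TA; Tourist TAA/TTA; hAT and
Mutator duplicate the 8–10-bp host k-mer at the site, whose host copy serves
as the right-hand TSD; MiMs are wrapped in generated (TA)n runs, n ≥ 5).
Gene features spanning an insertion point widen around it and downstream
coordinates shift, which is exactly how a fixed annotation presents a MITE
that landed in a feature. Insertions are non-nested and keep ≥ 130 bp
spacing so 50-nt flanks stay clean. Divergence applies i.i.d. substitutions
to the element interior; the first and last 3 bp are left intact, modelling
the conserved transposition-competent termini that full-length detection
presumes. Context ground truth is computed by a generator-side geometry
routine kept deliberately separate from `genome_context`, so the two
implementations check each other; an optional category mix steers insertion
sites into UTRs, CDS, introns, flanks or deep intergenic space.

Read counts are Poisson. Gene expression weights are lognormal(0, 1), scaled
so each library's expected gene total is half its nominal size; each genic
copy's expected count is set so the expected normalized-RPK ratio equals its
target M/g (scalar, per-copy, or drawn uniform [0.2, 4) when unspecified —
no noise model or M/g distribution is prescribed by the study, so Poisson
and a flat draw are the simplest defensible choices). The generator does not
simulate read sequences, sequencing error or splice isoforms; tests passing
on this data show the statistics and rules are computed correctly, not that
the pipeline is robust to alignment artefacts of real RNA-seq.

All randomness flows from one `numpy` Generator seeded by the
`SyntheticSpec`, so a fixed spec object yields byte-identical
FASTA/GFF3/TSV outputs.

## Problem sizes and runtime choices

The full-scale census (473-Mb genome, 428 families, 31,025 copies) is not
re-derivable at desk scale — it depends on the original assembly and a
manually curated library. The package therefore verifies two complementary
things: (i) summary arithmetic on the published census table (genic fraction
54 %, mean lengths 254/454 bp, genome fractions 2.19/2.09/0.93 %) through the
same summary code used for synthetic runs, and (ii) full-pipeline behaviour
on 2-Mb synthetic genomes (8 × 25 copies, divergence up to 0.15), where
planted-copy recovery ≥ 95 % within ±5 bp, superfamily classification is
exact on unmutated flanks, and M/g targets are recovered within 10 %. These
sizes keep a complete run in tens of seconds while leaving every rule
exercised at its threshold.

## Known limitations

* Truncated/partial copies and nested insertions are out of scope by design;
  the generator can nest only for stress testing.
* blastn score parity is not attempted anywhere; acceptance is defined by
  identity/length/coverage contracts, not by reproducing a specific tool's
  scores or E-values.
* The chi-squared test is asymptotic; with very sparse categories (e.g. CDS
  counts in small synthetic runs) cells can be near-empty and the pipeline
  reports the table but the p-value should be read with the usual caution.
* The comparative similarity bins approximate a score-ratio colouring, and
  sub-60 %-identity homology is invisible to the 60/60 rule by construction.
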