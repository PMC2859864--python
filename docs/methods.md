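# Methods

`flcdna` re-implements, as a tested library, the computational pipeline of a
full-length cDNA (FLcDNA) resource project: finished cDNA clone sequences
are curated into a non-redundant, full-length-CDS-bearing set (an
"nrFLcDNA" collection), annotated for CDS/UTR structure, mapped onto genome
scaffolds to derive exon/intron gene models, screened for alternative
splicing, and compared against a second cultivar's genome to estimate the
exonic substitution (SNP) rate.  Because the real clone collections and
genome assemblies are large external resources, every stage is exercised on
synthetic data with machine-readable ground truth; this note records the
models, the defaults, and what the synthetic results do and do not show.

## Alignment model and E-values

Pairwise search is exact affine-gap Smith–Waterman (match +1, mismatch −3,
gap open 5, extend 2 per base for nucleotides; BLOSUM62 with 11/1 for
proteins).  Significance uses ungapped Karlin–Altschul statistics:
λ solves Σᵢⱼ pᵢpⱼ e^{λ sᵢⱼ} = 1 (bisection-refined to |residual| < 1e-12)
and K comes from the standard lattice series
K = dλ e^{−2σ} / (H (1 − e^{−λd})), σ = Σ_k k⁻¹ [P(S_k ≥ 0) +
E(e^{λS_k}; S_k < 0)], truncated when terms fall below 1e-12 (they decay
geometrically).  For +1/−3 on uniform background this reproduces the
published ungapped constants (λ = 1.374, K = 0.711), and BLOSUM62 gives
(0.3176, 0.134).  E = K·m·n·e^{−λS} with raw (unadjusted) sequence lengths
and one E-value per best local alignment.  These E-values are mutually
comparable but are not bit-identical to NCBI BLAST (no effective-length or
gapped corrections); every threshold that consumes them is a configuration
knob whose default is the corresponding study criterion (1e-180, 1e-50,
1e-30, 1e-10).

Two identity conventions coexist: `AlignmentHit.identity` is matches over
non-gap columns, while every curation threshold uses `identity_blast`
(matches over all alignment columns, the convention BLAST tabular output
prints).  The distinction matters: under the non-gap convention a pure
indel variant (a splice isoform) would always look 100% identical and
collapse as redundant.

### Batch search and seeding

`search()` aligns a query against every database record when the total DP
work is small (< 5·10⁷ cells), and otherwise prescreens candidates with an
exact k-mer index (k = 12 nucleotide, 4 protein; query k-mers sampled at
stride k/3; near-homopolymer and two-letter k-mers excluded; candidates
need ≥ 4 shared k-mers).  At the pipeline's operating thresholds every
qualifying hit shares long exact k-mer runs, so seeding does not change
decisions; it only removes the quadratic all-versus-all cost that would
otherwise dominate.  Long genome subjects can additionally be clipped to
the seed-covered region plus a margin.  The exactness-versus-oracle test
suites always run the unseeded path.

## Spliced (est2genome-style) alignment

The spliced aligner extends the affine DP with an intron state: a
genome-only jump of length ≥ `min_intron` (default 60 nt) costing a flat
penalty (default 40, +20 for non-GT..AG termini), evaluated in O(1) per
cell with per-row running maxima over admissible donors.  Ties between
equal-scoring splice placements resolve to the leftmost donor.  Both
orientations are tried; on the minus strand coordinates are mapped back to
the forward axis while splice dinucleotides are reported in transcription
sense.  With the intron state priced out the model reduces exactly to the
plain local aligner (a tested invariant), and on short random instances the
optimized kernel equals a transparent O(m·n²) reference DP.

A structural consequence of flat intron penalties: an internal exon shorter
than the penalty (40 nt at +1 match) is absorbed into one merged canonical
intron, and an insertion longer than roughly half its affine gap cost is
modeled as an intron.  The synthetic generator therefore keeps exons ≥ 60
nt, introns ≥ 70 nt and alternative-splice offsets ≤ 28 nt (see below), the
regime in which recovery is provably unambiguous.  est2genome behaves the
same way on real data; there the mislabeled cases surface as "partial
retained introns".

## Synthetic data generator

The generator emulates the study conditions end to end.  Length
distributions are log-normal pinned to the published summary pairs
(mean/median): cDNA inserts arise from 5'-UTR (175/106 nt), CDS (312/292
codons plus stop), 3'-UTR (257/220 nt); exons 274/154 nt and introns
594/264 nt; exon count per gene is 1 + Poisson(3.9) (mean 4.9, median 4).
Hard minimums (exon 60, intron 70, UTR5 12, UTR3 20, CDS 30 codons) are
applied by clamping draws upward, which leaves medians untouched.  GC
content defaults to 40.3% and stop codons are drawn at 40.6/35.6/23.8%
TGA/TAA/TAG.  Genes sit 20 per scaffold with 2 kb spacers, random strand;
all introns are GT..AG; the transcript's exon partition is drawn from the
exon-length distribution and rescaled to the transcript length.

Isoforms: per gene and event class, with the configured probability
(defaults 0.55/0.16/0.20/0.05 for retained intron / alternative donor /
alternative acceptor / exon skip), one alternative isoform is emitted.
Alternative donors/acceptors use GT/AG sites planted 9–28 nt inside the
intron; exon skips remove one internal exon; all transcripts get a 15–40 nt
poly(A) tail.  Three planting guards keep classification truth exact:
junctions are resampled whenever an equal-scoring canonical slide exists;
each structural element hosts at most one event; and a gene is resampled at
build time until at least one internal exon cannot be misread as a
canonical intron (an exon that happens to look GT..AG-flanked within a
small reconciliation cost is genuinely ambiguous to any est2genome-style
method).  Events that remain impossible on a gene (single-exon genes, no
eligible intron) are skipped and logged; the guards keep the per-class skip
rates small and near-uniform, so emitted class proportions track the
configured rates within multinomial sampling error.

Clone libraries: each transcript yields one full-length clone plus
Poisson(redundancy_mean − 1) 5'-truncated copies (exponential mean 60 nt,
clipped to [10, min(150, 15% of length)] and always upstream of every
planted event block of the gene).  Chimeras ligate a 5' fragment of one
gene body to the 3' end of another through a BamHI (GGATCC) or XhoI
(CTCGAG) site; ncRNA and pathogen contaminants copy records from separate
400–900 nt pools that also serve as the filter databases.  Reads for the
trimming/clustering stage add a 25–35 nt vector flank and a degraded 3'
tail, with Phred qualities ~N(38, 4) clipped to [2, 60] and decaying after
position 500 ("noisy" profile) or a two-level 40/10 profile for
exact-trimming tests.  The variant "second cultivar" genome applies
independent substitutions at the configured rate (default 0.061%),
positions recorded; no indels.

Everything derives from one integer seed through spawned NumPy generators,
so identical configurations are byte-identical across platforms.

What the generator does *not* emulate: sequencing errors in finished
sequences (the study's finished clones average Phred 65, one error in
3·10⁶ bases, so they are treated as error-free), heterogeneous expression
levels, genome assembly gaps/repeats, paralogy, and real splice-site or
codon-usage signals beyond the stop-codon mixture.  Passing the synthetic
suites therefore demonstrates correctness of the decision logic and
estimators under the stated criteria — not robustness to paralogs or
assembly artifacts.

### Expected dispositions (truth-side oracle)

For curation tests the expected terminal disposition of every clone is
derived in closed form from planted geometry alone: clones of one gene
differ only by indel blocks, truncations and tail lengths, so their optimal
local alignment is a run of matched segments whose gaps are either bridged
(affine cost) or truncated away; the best run is enumerated exactly,
adjacent blocks merging into one gap run.  The study's redundancy criteria
(E < 1e-180, BLAST identity ≥ 97%, mutual coverage ≥ 80%) are then applied
to these closed-form statistics, components collapsed to their longest
member, and remaining clones labeled by construction class.  This
deliberately reproduces counter-intuitive but correct outcomes: a small
alternative-splice isoform *is* redundant under those criteria, and a
retained-intron isoform of a long transcript can win the collapse and evict
its spliced sibling.  The oracle shares no code with the aligner.

## Curation cascade

Filters run in fixed order — redundancy → ncRNA → pathogen → chimera →
retained intron — and a sequence removed by an earlier stage is never
tested again, so stage counts are order-dependent, and the ledger satisfies
in = removed + kept exactly at every stage.  Decisions:

* redundancy: pairs meeting all three criteria link; connected components
  collapse to the longest member (smallest id on ties); a post-pass
  re-checks that no kept pair still links;
* ncRNA: best hit E ≤ 1e-180;
* pathogen: best hit E < 1e-30, rescued when a host transcript matches at
  least as well (host E ≤ pathogen E — ties rescue, since an exact host
  copy is at least as plausible an origin);
* chimera: ≥ 2 unigene hits (E < 1e-50) with *different* functional
  descriptions (casefolded, punctuation and generic tokens
  putative/predicted/like/family/protein dropped; different iff neither
  token set contains the other) on query regions overlapping < 20% of the
  shorter; confirmed by hits on two distinct scaffolds, else by a
  BamHI/XhoI site between the matched regions (window padded 5 nt because
  alignment ends can absorb part of the site);
* retained intron: within the E < 1e-50 similarity group (survivors plus
  the unigene/TC set, at most 12 companions), each companion takes the
  "est" role against the candidate as "genome"; any canonical GT..AG intron
  ≥ min_intron flags the candidate.  Restricting to canonical introns is
  deliberate: a companion's *skipped exon* also appears as a genomic
  insertion in the candidate, but without spliceosomal termini.

## CDS, UTRs and composition

Poly(A) tails are the longest suffix ≥ 10 nt that starts with A and is
≥ 90% A (the start-with-A condition pins the boundary to the tail).  ORFs
are enumerated exhaustively in the three sense frames — every ATG..stop
pair, plus end-open partials for truncated CDSs.  Selection is
homology-first: up to the 20 longest candidates (≥ 10 aa) are searched
against the protein database at E < 1e-10; the full-length candidate with
the smallest E wins, falling through the E ranking if the best hit is not
full length; an all-tie takes the longest tied candidate; no hits fall back
to the longest *complete* ORF (an open frame with no stop codon almost
always out-lengths the real CDS by a few residues and would shadow it).
Completeness is full_length iff the CDS has both ATG and stop; the stop
codon is counted inside the CDS interval and excluded from the protein, so
a 938 bp mean CDS corresponds to the conventional 313 aa mean polypeptide.
UTRs partition the cDNA exactly: 5'-UTR + CDS + 3'-UTR + poly(A).
Composition tables count A/T/G/C with N and X tallied separately and
excluded from the four-way denominator; stop-codon usage is reported over
full-length CDSs.

## Genome mapping and statistics

A poly(A)-stripped cDNA is assigned to the scaffold sharing most seeds
(k = 14, ≥ 3 shared), spliced-aligned against the seed-covered region
extended by a configurable margin, and accepted as full-length-mapped when
E < 1e-50, exon-column identity ≥ 90%, cDNA coverage ≥ 90% and both cDNA
ends (first/last 20 nt) lie inside exon blocks — the end-anchoring
operationalizes "matched in full length" beyond bare coverage.  The margin
defaults to 12 kb (bounding the longest intron seen in real data); the
synthetic pipeline runs with 2 kb since simulated introns stay below that,
which is a pure compute choice, never a correctness one.  Exons are typed
initial/internal/terminal (single for one-exon models) in transcript sense;
gene length equals Σexons + Σintrons exactly.  Translation start/stop sites
map to exon indices through the cDNA intervals of the exon blocks, giving
the frequency of start/stop codons in internal exons (UTR-intron
occurrence).

Splice events between two co-located models are classified per structural
difference (one pair can yield several events): retained_intron when one
model's exon spans the other's intron with both flanking boundaries shared;
alt_donor/alt_acceptor when an intron pair shares exactly one end (donor =
5' end in transcription sense); exon_skip when an internal exon of one
model overlaps nothing in the other while its flanking exons are shared;
anything else is `other`.

The SNP estimate is exon-restricted: over cDNA–scaffold pairs with exon
identity ≥ 99.5%, the rate is substitution columns / aligned non-gap exon
columns (indel columns excluded from both), reported as a percentage and as
"one difference in N nt".

## Problem sizes and statistical checks

Desk-scale runs use: 200 genes (seed 1) for exact-recovery acceptance
(curation dispositions, CDS/UTR and exon boundaries, event classes — all
must be exact); 400 genes for SNP-rate recovery (≈ 550 kb aligned exon
bases, binomial SE ≈ 5%, checked within 15% relative); 2000 genes for
distribution calibration (median intron within 5% of 264 nt, stop-codon and
event-class mixtures within 99% binomial CIs) — at this scale statistics
come from truth-table gene models, since the point is generator
calibration, not the aligner.  Fisher's exact frequency comparison
(two-sided, per category, no multiplicity correction by default with an
optional Benjamini–Hochberg flag) is delegated to scipy and cross-checked
against a direct hypergeometric tail enumeration.

## Known limitations

* E-values are ungapped-theory approximations; absolute values differ from
  NCBI BLAST, so thresholds tuned on real BLAST output may need adjustment.
* The aligner kernels are exact DPs; without the seed prescreen the
  pipeline is quadratic in collection size and impractical beyond a few
  thousand sequences.
* Event classification assumes models mapped to the same locus; paralogous
  mappings would produce `other`/spurious events.
* The closed-form disposition oracle covers the generator's geometry
  (single-block isoforms, 5' truncations); it is not a general alignment
  predictor.
* Single-linkage clustering with a fixed 100 nt / 95% rule has no
  chimera-awareness at the read stage; chimeric reads can bridge clusters
  (they are caught later by the curation cascade, as in the original
  procedure).
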