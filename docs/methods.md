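# Methods

`bcrep` re-implements, as a tested pipeline, the repertoire analysis used to
ask whether TLR7 signaling (triggered by ssRNA packaged in Qβ virus-like
particles) induces and maintains antibody diversity: clonotyping of
antigen-specific heavy-chain reads, read-normalized diversity, IGHV usage,
somatic-hypermutation (SHM) profiling, cross-repertoire CDR3 sharing and
repertoire-similarity trees.  It runs either on external AIRR/clonotype data
or on its own synthetic cohorts with full ground truth.

## Germline mini-reference

A packaged synthetic murine IGH mini-locus (8 V including IGHV1-7, 4 D, 4 J)
stands in for a full curated reference: it is large enough to express
dominant-gene usage and family-level summaries at desk scale without any
download.  Sequences are random nucleotides with correct anchor structure, not
IMGT alleles; names follow IMGT style (`gene*allele`; family = prefix before
the hyphen-number).  Anchors are the first base of the conserved Cys-104 codon
(V) and Trp/Phe-118 codon (J); the CDR3 convention includes both anchor
codons.  V segments carry the Cys codon 9 nt before their 3' end (so modest
exonuclease trimming never removes it); J anchors sit 9–12 nt from the 5' end.
All coordinates in the package are 0-based, half-open.

## Synthetic cohorts

The generator emulates the study design: 2 cohorts x 2 time points x
`n_samples` mice, 3 IgG subclasses per sample.  Defaults are the package's own
encoding of the design's qualitative contrasts, not measurements:

| parameter | rna_loaded | rna_free | meaning |
|---|---|---|---|
| `n_clones` | 500 | 150 | clonal richness per sample |
| `zipf_exponent` | 1.1 | 1.6 | clone-size power law (higher = more skewed) |
| `shm_rate` | 0.02 | 0.02 | per-base substitution probability (d10) |
| `isotype_proportions` | 0.2/0.4/0.4 | 0.6/0.3/0.1 | IgG1/IgG2b/IgG2c switch weights |

Shared defaults: `v_usage_bias` puts weight 0.6 on IGHV1-7 (uniform over the
rest), `n_public = 5` spiked public CDR3s, `reads_per_sample = 2500`,
`shm_time_factor = 1.5` at d17 (SHM progresses between time points).  The
RNA-loaded cohort is thus richer, flatter and IgG2b/2c-dominant; the RNA-free
cohort is the converse.  Only rank-order recovery of these contrasts is
asserted anywhere — no absolute diversity or mutation level is treated as a
reference value.

Model components, in order:

* **V(D)J rearrangement** — V drawn from `v_usage_bias`, D/J uniform; trimming
  lengths from bounded geometric laws (V ≤ 6, D ≤ 4, J ≤ min(anchor, 8) nt);
  N1/N2 insertions of bounded-geometric length with uniform bases.
  Non-productive junctions (frame shift, lost anchors, stop codons) are
  resampled, with a bounded attempt count so a broken reference fails loudly.
* **Clonal expansion** — deterministic Zipf rank-size allocation summing
  exactly to the library budget (largest-remainder rounding), then shuffled
  onto clones.  Heavy-tailed expansion is the minimal structure that makes
  clonotype counts differ from read counts, which the diversity statistic
  requires.
* **SHM** — uniform, substitution-only, no hotspots or indels; mutations are
  drawn once per clone lineage, so all reads of a clone share them.  Lineages
  whose CDR3 loses productivity are resampled: cells without a functional
  receptor are never sorted as antigen-specific B cells.
* **Class switching** — each clone is IgG1-committed or joins the IgG2b/2c
  pool (probability from `isotype_proportions`); pool clones draw IgG2b/IgG2c
  membership flags in the configured 2b:2c ratio.  IgG2b and IgG2c
  repertoires of a sample therefore sample a common clone set, which is what
  makes them measurably closer to each other than to IgG1.
  `correlated_switching=False` gives the simpler one-isotype-per-clone model.
* **Library sequencing** — one AIRR file per sample x isotype, each receiving
  a near-equal share of `reads_per_sample` (exact conservation per sample).
  This emulates saturating per-subclass PCR followed by equimolar pooling:
  per-library depth reflects pooling, not cellular isotype composition.
  The richness/depth ratio used for diversity is depth-sensitive, so
  comparing libraries at comparable depth is essential; allocating reads
  proportionally to isotype prevalence instead would manufacture diversity
  differences that are artifacts of depth, not of repertoire structure.
* **Public clonotypes** — `n_public` fixed CDR3 amino-acid strings are
  re-embedded by deterministic reverse translation into every sample (V from
  the usage bias, J constrained to match the terminal Trp/Phe), protected
  from SHM within the CDR3 and guaranteed at least one read per library.
  This makes cross-sample sharing exactly recoverable and testable.

One AIRR row is one read (`duplicate_count` = 1), so "read counts" in the
diversity denominator are unambiguous.  Everything is reproducible from the
config seed (per-sample child seeds via `SeedSequence.spawn`); identical
configs produce byte-identical AIRR and truth files.

What the generator does **not** emulate: sequencing error and quality values,
paired-end read structure, indel SHM and lineage-tree-structured
diversification, allelic variation, light chains, primer or chimera
artifacts.  Passing recovery tests therefore shows the pipeline's statistics
are correct and well-calibrated under a clean substitution-only model — not
that the annotator is robust to raw-instrument noise.

## Annotation

A deliberately simple, deterministic stand-in for production V(D)J
annotators: banded affine-gap local alignment (Gotoh) of each read against
every plausible germline V and J.  Scoring defaults: match +2, mismatch -2,
gap open -6 plus -1 per gapped base.  Candidate segments are found by shared
12-mer seeding; the band (half-width 16) is centred on the best-voted
diagonal, and when no seed exists the full exact DP is run instead, so the
banding is purely a speed device.  Segment ties break by higher score, then
longer alignment, then lexicographic name — annotation is a per-read pure
function, independent of input order.

Numerical choices worth knowing:

* Alignments are reduced to their best-scoring **ungapped block** before
  anchor projection and mutation counting.  Junction-edge gap artifacts (a
  spurious 1–2 nt gap bridging into random junction sequence) are thereby
  clipped; a genuine internal indel leaves the anchor outside the block and
  the read fails `anchor_unmapped`, consistent with the substitution-only
  mutation model.
* CDR3 = read substring from the base mapped to the V anchor through the end
  of the codon mapped to the J anchor, both anchor codons included;
  `junction_aa` must start with C, end with W/F and contain no stop to pass.
* `v_mutation_count` counts substitutions within the aligned V span only.
* Failures are reason-coded (`too_short` < 30 nt, `no_v`/`no_j` when the best
  block is shorter than 60/20 nt, `anchor_unmapped`, `unproductive_cdr3`),
  never fatal; filtered reads are tallied, not silently dropped.
* D calls are informational only: the input `d_call` is passed through when
  present, otherwise the longest exact ≥6 nt overlap with the CDR3 interior.
* Isotype is taken from the AIRR `c_call` column, not inferred from
  constant-region sequence (subclass demultiplexing happens upstream, at the
  primer level).

On simulated data at the default SHM load the annotator recovers V calls and
CDR3s essentially exactly (the test suite asserts ≥95% V-call accuracy and
near-zero mutation-count error); the oracle-equivalence tests pin the aligner
to an independent optimal local aligner.

## Clonotypes and per-repertoire statistics

Two clonotype definitions: `cdr3_aa` (CDR3 amino-acid identity) and `vdj_nt`
(full VDJ nucleotide string, V-alignment start through J-alignment end).
Diversity is read literally as unique clonotypes divided by reads — a
richness/sequencing-depth ratio in (0, 1], not an entropy; Shannon and
Simpson indices are available as clearly-non-primary extras.  V usage and
mutation summaries are computed over clonotypes (each clonotype counted once,
with the modal V call of its reads) to avoid expansion-size confounding;
read-weighted variants exist behind a `weight="reads"` flag.  Mutation
averaging collapses reads to clonotypes first (mean of per-clonotype means);
IgG2b+2c pooling is plain concatenation of passing records before
summarizing.

## Cross-repertoire comparison

The sharing universe is the union of unique CDR3 amino-acid sequences over
the repertoires compared; all "shared by ≥ k" percentages are fractions of
this union (a per-repertoire variant is emitted alongside, since external
datasets may have used either convention).  The headline threshold is
occupancy ≥ 2, exposed as a parameter; "top shared" means occupancy strictly
greater than 6 repertoires.  Consensus of shared CDR3s is a per-position
plurality vote (ties to the lexicographically smallest residue) within one
length stratum — sequences are stratified by length and the modal stratum
analyzed, rather than building a gapped MSA.  Pairwise repertoire distance is
1 − Jaccard on CDR3 sets by default, with Bray-Curtis on clonotype
frequencies as the abundance-aware option.  The repertoire tree is UPGMA —
deterministic (ties broken by cluster order), ultrametric, emitted as Newick
with branch lengths — chosen as a display tree; no algorithm is claimed to be
inferential here, and no bootstrap support is computed.

## Pipeline

`run_pipeline` executes simulate (or load) → annotate → profile → compare →
figures, with a sample sheet (`file, sample_id, group, time_point, isotype`)
as the single metadata source.  Row counts are reconciled across stages and
recorded, with SHA-256 checksums of all outputs, in a manifest written last;
a failed stage leaves a `FAILED` marker naming the stage.  External data
enter as read-level AIRR TSVs or clonotype-level MiXCR-style exports
(`cloneCount`/`aaSeqCDR3` columns); both map onto the same internal tables.

## Problem sizes and limitations

Recovery tests run 20 independent studies of ~2 x 10^4 reads each (8 samples
x 2500 reads), a scale at which the rank-order contrasts are decisively
resolved while the whole suite stays desk-scale.  Known limitations: the
annotator is not a full V(D)J caller (no paired-end assembly, no allele
inference, no indel-tolerant mutation counting); the diversity ratio remains
depth-sensitive, so cross-dataset comparisons should be made at comparable
depth; UPGMA trees are summaries of pairwise overlap, not phylogenies; and
the bundled reference is synthetic, so externally produced data must be
analyzed against their own germline reference (`--germline`).
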