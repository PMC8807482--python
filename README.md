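# bcrep

B-cell receptor (BCR) repertoire analysis for heavy-chain IgG sequencing
studies, built around the question of how an adjuvant signal (TLR7 sensing of
ssRNA packaged in virus-like particles) shapes antigen-specific antibody
diversity.  The package provides, as a reusable and tested library:

* **clonotyping** under two definitions — CDR3 amino-acid identity
  (`cdr3_aa`) and full-VDJ nucleotide identity (`vdj_nt`);
* **read-normalized diversity** — unique clonotypes ÷ reads of a repertoire,
  the depth-normalized richness in (0, 1];
* **IGHV usage and somatic-hypermutation profiling** — per-gene clonotype
  usage frequencies, and substitution counts on germline IGHV summarized per
  V family and overall;
* **cross-repertoire sharing** — occupancy spectra ("x% of CDR3s shared by
  ≥ k repertoires"), pairwise Jaccard indexes, 3-isotype Venn partitions, and
  plurality consensus of top-shared CDR3s with per-position conservation;
* **repertoire-similarity trees** — UPGMA on Jaccard (or Bray-Curtis)
  distances, written as Newick;
* a **synthetic AIRR cohort simulator** with complete ground truth (clones,
  V/D/J, planted mutations, spiked public clonotypes), emulating a 2-cohort ×
  2-time-point × 3-subclass immunization study;
* a simplified, deterministic **annotator** (k-mer-seeded banded
  Smith–Waterman against a packaged germline mini-reference, CDR3 extraction
  between the conserved Cys-104 and Trp/Phe-118 anchors, V-region mutation
  counting).

The audience is immunologists and bioinformaticians who want the repertoire
statistics of such a study as composable Python functions operating on AIRR
Rearrangement TSVs, with a simulator that makes every downstream statistic
testable against ground truth.

## Core quantities

For a repertoire r with clonotype counts {c_1 … c_K} over N reads:

* normalized diversity  D(r) = K / N;
* Jaccard index of repertoires A, B on CDR3 sets  J = |A∩B| / |A∪B|;
* sharing spectrum  s(k) = |{x ∈ U : occ(x) ≥ k}| / |U|, U the CDR3 union;
* V usage  u(g) = (clonotypes with modal V gene g) / K;
* mutation load = mean over clonotypes of the per-clonotype mean substitution
  count on the aligned germline IGHV;
* UPGMA tree on d = 1 − J (ultrametric, deterministic tie-breaks).

## Worked example

```bash
python examples/02_annotate_and_profile.py
```

simulates one mouse per cohort and time point (600 reads per sample, shared
between the three IgG subclass libraries), annotates every read and prints
per-repertoire profiles:

```
repertoire                         reads clono divers   mut IGHV1-7
rna_loaded_d10_m1_IgG1               200    65  0.325  5.54    0.52
rna_loaded_d10_m1_IgG2b              200    90  0.450  5.68    0.62
rna_loaded_d10_m1_IgG2c              200    83  0.415  5.57    0.54
...
rna_free_d10_m1_IgG2b                200    33  0.165  5.42    0.67
rna_free_d10_m1_IgG2c                200    21  0.105  5.52    0.76
rna_free_d17_m1_IgG2c                200    16  0.080  9.00    0.62
```

Reading the numbers: the RNA-loaded (TLR7-stimulated-like) IgG2b/2c
repertoires are several-fold more diverse than their RNA-free counterparts
(0.45/0.42 vs 0.17/0.11 clonotypes per read) while IgG1 differs much less;
IGHV1-7 dominates usage everywhere (~0.6, the configured bias); and the mean
V-region mutation count rises from ~5.6 at day 10 to ~8.9 at day 17 as
hypermutation progresses.  `examples/03_sharing_and_tree.py` continues with
sharing: the 5 spiked public CDR3s are exactly the clonotypes found in more
than 6 repertoires, and the UPGMA tree pairs each sample's IgG2b with its
IgG2c repertoire before joining IgG1 — the class-switch correlation the
simulator encodes.

Other entry points: `examples/01_simulate_cohort.py` (ground-truth
simulation), `examples/04_full_pipeline.py` (one-call run with manifest), and
the `bcrep` CLI (`simulate`, `annotate`, `profile`, `compare`, `run`,
`import`) for shell use, e.g.

```bash
bcrep run --out results_run --seed 5
bcrep import --in clones.tsv --dialect mixcr_export_tsv --out imported
```

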