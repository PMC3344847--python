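# polytome

Polysome-profiling translatome analysis for two-colour arrays: from raw
probe intensities to translation-efficiency scores, stress translation
classes, translatome–transcriptome coordination, mRNA sequence-feature
associations, positional RNA-structure profiles, and gene-set enrichment.

## The problem

Polysome profiling separates a cell's mRNA into a polysome pool **P**
(two or more ribosomes; actively translated) and a free+monosome pool
**FM** (at most one ribosome).  Hybridising the two pools against each
other on a two-colour array — Cy3 (green) for P, Cy5 (red) for FM — gives,
per mRNA, a **translation efficiency**

    M = log2(P / FM) = log2(green / red)

and an abundance proxy

    A = ½ · log2(green · red).

Comparing M between control and stressed cells (e.g. ER stress from
thapsigargin, which phosphorylates eIF2α and halts most initiation)
partitions mRNAs into translation classes:

| class | rule (defaults) | biology |
|---|---|---|
| **S** sensitive  | ΔM ≤ −0.8 | translation shut down by the initiation blockade |
| **R** resistant  | M ≥ 0.8 in both conditions | keeps translating through stress (BiP-like) |
| **I** inducible  | control M ≤ 0 and ΔM ≥ +1 | repressed by upstream AUGs, relieved under stress (ATF4-like) |
| **U** unclassified | none of the above | |

Rules are evaluated with precedence **I → R → S**, so an mRNA falling from
M = 3 to M = 1 counts as resistant, not sensitive.

Around this core the package provides: normexp/half background correction
of probe tables; replicate averaging and abundance filtering; midrank
percentile placement of calibration markers; ortholog pairing of two
species' translatomes with abundance-stratified Pearson correlation; the
5′UTR/CDS/3′UTR feature report (lengths, G+C, upstream-AUG counts, Kozak
−3 purine context) with Welch-t / Fisher tests across classes; equilibrium
base-pair probabilities from McCaskill's partition-function recursion
under a per-pair-weight model, profiled positionally around start/stop
codons; and FatiGO/FatiScan-style Fisher and ranked-partition enrichment
over GMT gene-set files.  A synthetic-data generator produces probe
tables, transcript FASTA/CDS annotations and ground truth so the whole
pipeline is testable without any downloads.

## Worked example

Generate a 500-gene synthetic study and run the full pipeline:

```bash
polytome simulate --outdir demo/data --seed 7 --n-genes 500
cat > demo/run.yaml <<'YAML'
control_probes: demo/data/probes_control.tsv
stress_probes: demo/data/probes_stress_3h.tsv
output_dir: demo/out
seed: 7
background_method: half
a_min: 4.5
fasta: demo/data/transcripts.fasta
cds_table: demo/data/cds.tsv
gmt: demo/data/sets.gmt
bpp_window: [1, 25]
bpp_flank: 10
n_partitions: 15
YAML
polytome run --config demo/run.yaml
```

The run prints its filter bookkeeping and class census:

```
"classes": { "I": 47, "R": 21, "S": 220, "U": 210 },
"control_probes": 1500,
"genes_in_both_conditions": 498,
"stress_genes_dropped_by_a_filter": 2
```

Of 500 genes (3 probes each), 498 pass the abundance filter in both
conditions; 220 are called stress-sensitive, 21 resistant, 47 inducible —
94.6% of calls match the generator's ground truth at the default noise
level.  `demo/out/translatome.tsv` holds the per-gene table:

```
gene_id   te_control  te_stress  delta_te  a_control  a_stress  delta_a  class_label
TX00000   -0.072      -0.327     -0.256    7.05       7.17      0.116    U
TX00001    0.850       0.981      0.131    6.47       6.58      0.106    R
```

`coordination.json` reports the translation-vs-abundance Venn — here
`{"translation_only": 247, "abundance_only": 0, "both": 9}`: under acute
stress the remodeling is almost entirely translational.  The
ranked-partition scan (`enrichment_scan.tsv`) recovers the ground-truth
programs from the TE ranking, e.g. `TRUTH_S_PROGRAM` peaks at partition 6
with adjusted p ≈ 6e-16.

Every step is also available as a library call (`polytome.arrayio`,
`.translatome`, `.orthologs`, `.seqfeat`, `.rnastruct`, `.enrichment`,
`.simdata`) and as individual subcommands (`preprocess`, `classify`,
`orthologs`, `features`, `bpp`, `enrich`).

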