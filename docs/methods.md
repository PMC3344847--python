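# Methods

## Translation-efficiency scoring

Each probe carries foreground and local background intensities for the
green (Cy3, polysome) and red (Cy5, free+monosome) channels.  After
background correction, per-probe scores are `M = log2(green/red)` and
`A = ½·log2(green·red)`; replicate probes of the same mRNA are averaged on
the M/A scale (not on raw intensities), and genes are kept when `A`
exceeds the abundance cutoff strictly (`A > a_min`, default 4; the filter
is a literal reading of "A values above x").

Background correction offers three methods:

* `none` — foreground passed through (for data corrected upstream).
* `half` — `max(fg − bg, 0.5)`; the 0.5-unit floor is the conventional
  choice for this method and keeps log-ratios finite.  It is exact when
  the reported background equals the additive contamination.
* `normexp` — the observed `fg − bg` is modelled as Normal(μ, σ²)
  background plus Exponential(α) signal.  Moments identify all three
  parameters (the third central moment of the convolution is 2α³), and
  the corrected value is the conditional mean `E[S | X = x] =
  μ_sx + σ·φ(z)/Φ(z)` with `μ_sx = x − μ − σ²/α`, evaluated through
  `log_ndtr` for numerical stability deep in the left tail.  A degenerate
  moment fit (non-positive skewness or implied variance) falls back to
  `half` with a logged warning.  The estimator is a global per-channel
  fit; no dye-bias or spatial normalisation is applied.

## Translation classes

With control and stress TE per gene, classes are assigned by precedence
**I → R → S → U**: inducible if control M ≤ 0 and ΔM ≥ 1; else resistant
if M ≥ 0.8 in both conditions; else sensitive if ΔM ≤ −0.8; else
unclassified.  The precedence resolves the genuine S/R overlap (an mRNA
dropping 3.0 → 1.0 satisfies both): resistance is defined by maintained
absolute engagement, so R wins.  I and R are structurally disjoint
whenever `i_control_max < r_level`, which the threshold container
enforces.  The class cutoff for "sensitive" (0.8) and the Venn cutoff for
"changed translation" (1.0) are deliberately separate knobs; abundance
change uses |ΔA| ≥ 1 with no additional statistical test layered on top.

Calibration markers are placed on the TE distribution by midrank
percentile, `(rank − ½)/n · 100`, which is permutation-stable and puts a
fully tied distribution at 50.

## Ortholog agreement

Translatomes of two species are joined through a two-column ortholog
table (duplicates dropped, one-to-many mappings expanded — no collapsing
rule is imposed).  Agreement is Pearson r (and R² = r²) within abundance
strata defined by `min(A_a, A_b) ≥ cutoff` — requiring both species to
clear the cutoff is the conservative reading of a cross-species abundance
threshold.  Strata with n < 3 or zero variance report r as undefined.

## Sequence features

Transcripts are split by 0-based half-open CDS coordinates (inclusive of
start and stop codons) into 5′UTR / CDS / 3′UTR; sequences are stored
uppercase with U → T.  Features: region lengths; G+C% over A/C/G/T with
Ns excluded from numerator and denominator (undefined for empty regions);
the number of ATG triplets lying entirely within the 5′UTR (every
position scanned, overlapping occurrences counted — no frame or uORF-stop
requirement, since the quantity of interest is upstream initiation
opportunities); and the −3 context of the initiator (purine = favourable
Kozak R, unknown when the 5′UTR is shorter than 3 nt or the base is N).

The class report first applies the selection filter (A ≥ 5.5, both UTRs
≥ 10 nt by default), then compares each group (Total, High = M ≥ 2,
Low = M ≤ −1.5, R, I) against its complement: two-sided Welch t for
continuous features (medians are displayed for lengths, means for GC%, as
is conventional, although the test compares full distributions), Fisher
exact for proportion rows (uAUG ≥ k, −3 purine frequency) — a t-test on
binary indicators is ill-posed, and this substitution is recorded in the
report metadata.  Groups with n < 2 report undefined statistics.  No
multiple-testing correction is applied within the report table; the
significance flag defaults to p < 0.005.

## Base-pair probabilities

The structure model is deliberately minimal: pseudoknot-free pairings
with one Boltzmann weight per pair type (defaults GC = 3.0, AU = 1.5,
GU = 0.8, reflecting relative stability; configurable), no stacking or
loop terms, and hairpin loops of at least `min_loop = 3` unpaired bases.
A structure's weight is the product of its pair weights; the empty
structure contributes 1, so Z ≥ 1.  This suffices for the analysis the
profile supports — *contrasts* of mean positional pairing probability
between transcript groups — and the profile machinery also accepts
externally computed sparse BPP matrices for parity runs against a full
thermodynamic folder.

The partition function uses the unambiguous decomposition by the status
of the leftmost base (`Z[i,j) = Z[i+1,j) + Σ_m w(i,m)·Z[i+1,m)·Z[m+1,j)`);
pair probabilities come from the matching outside recursion (the grammar
has at most two nonterminals per production, so inside–outside runs in
O(N³) rather than the naive O(N⁴) outside sum).  Correctness is pinned to
an exhaustive structure-enumeration oracle on short sequences
(agreement ≈ 1e-15).  One caveat established numerically: the
reverse-complement symmetry of the BPP matrix holds only for pair
alphabets closed under reverse complementation (Watson–Crick); GU wobble
maps to the non-pairing AC and breaks it.

Positional profiles anchor per-base pairing probabilities (marginal sum
over partners) at the start codon (+1 = A of AUG) or stop codon (+1 =
first stop base); there is no offset 0.  Each transcript is folded over
the window plus a flank (default 50 nt each side, clipped to the
sequence) rather than full length — folding extent is a desk-scale
choice; tests use smaller windows (flank 10–15) where the designed
signal is local.  Transcripts whose window leaves the sequence are
excluded and logged.  Groups are compared per position by two-sided Welch
t; raw p < 0.05 is flagged, and BH-adjusted values are reported alongside.

## Enrichment

Gene sets come from GMT files (unique ids, non-empty member lists
enforced).  Single-selection mode intersects each set with the
background, builds the 2×2 table, and reports two-sided Fisher exact p
(depletion signed by the odds ratio; one-sided mode by flag) with
Benjamini–Hochberg adjustment across sets — BH is the field default where
"adjusted p" is otherwise unspecified.  The ranked-partition scan tests
partitions k = 1..30 (default), selecting the top `⌈k·n/(n_partitions+1)⌉`
of the ranking each time, adjusts across the whole (set, partition)
family, and reports each set's minimal adjusted p with its partition.

## The synthetic-data generator

The generator is the analysis statistic inverted: TE maps to a polysome
fraction by the log-odds link `φ = 2^te/(1+2^te)`, expected channel
intensities are `green ∝ gain_p·abundance·φ` and
`red ∝ gain_fm·abundance·(1−φ)`, replicate probes receive multiplicative
log-normal noise (σ = 0.25 by default) and additive Normal background
(mean 40, sd 8, clipped at 0) whose exact value is also written to the
probe's background columns.  With equal gains and zero noise the pipeline
recovers TE and classes exactly — the sharp end of the recovery tests.

Ground-truth classes are drawn from a configurable mixture (defaults
S = 0.45, R = 0.04, I = 0.08, remainder U, matching a fibroblast-like
census; presets `jurkat_like` and `nih3t3_like` carry the
lymphocyte/fibroblast mixtures and the global P:FM RNA mass ratios of
2:1 / 1.5:1 in control and 1:3 under stress).  Class-conditional TE
distributions are anchored to the biology the classes describe:
sensitive mRNAs start near the population median (control TE ~N(1.2,
0.7)) and lose ≥ 1.2 log2 (mean drop ≈ 2, consistent with a ~90%
translational shutdown); resistant mRNAs sit at 1.2 + Exp(0.8) in both
conditions (BiP-like, clear of the 0.8 level); inducible mRNAs start at
−0.5 − Exp(1.0) (ATF4-like repression, mean −1.5) and gain 1.5 + Exp(0.7);
unclassified mRNAs drift sub-threshold with stress TE capped below the
resistant level.  The margins between truth and threshold are thus
explicit distributional choices, not artifacts; they determine the
attainable classification accuracy at a given noise level (~0.95 balanced
accuracy at σ = 0.25 with 3 probes per gene).

Sequence anatomy is coupled to class in the directions seen on real
arrays: inducible transcripts get ~1.6 expected upstream AUGs versus
~0.25 for highly translated ones, longer CDS (×1.8) and 3′UTRs, and
−4 points of G+C; the −3 purine context appears at frequency 0.86.
Upstream AUGs are planted exactly (background ATGs are destroyed by a
G→C edit that cannot create new ones; planted ATGs are spaced ≥ 3 apart),
and the truth table stores features re-measured from the emitted
sequences, so recovery tests compare against exactly what is in the
FASTA.  CDS regions read as plausible ORFs (ATG start, no premature
stops, one stop codon).

When a global mass ratio is configured, the polysome-channel gain is
rescaled so the summed channel masses obey it — reproducing the
proportional-labeling confound of the real protocol.  This shifts every
measured M by a common offset; recovery tests therefore run with equal
gains and no mass constraint, while the preset runs expose the estimator
bias deliberately.

What the generator does *not* emulate: probe cross-hybridisation, spatial
array artifacts, dye-swap designs, intensity-dependent (loess-type) dye
bias, and biological replicate variance beyond probe-level noise.
Passing recovery tests therefore demonstrates correctness of the
estimator chain under the stated noise model, not robustness to
array-specific systematics.

## Problem sizes and numerical choices

Test and acceptance runs use 2,000-gene studies (3 probes/gene) for
recovery, 200 random sequences of length ≤ 14 against the enumeration
oracle, windows of ~40 positions with 15-nt flanks for structure
profiles (n = 100 per group), 400-gene rankings with 30 partitions for
the scan, and an exhaustive Fisher-vs-hypergeometric sweep over all 2×2
tables with total ≤ 40 plus 2,000 random tables with total ≤ 200 (the
full exhaustive sweep to total 200 — ~7×10⁷ tables — adds no information
at 1e-12 agreement and is omitted as a size choice).  Two-sided Fisher
tie handling uses the conventional (1 + 1e-7) relative tolerance.
Floating-point output is written at %.10g so reruns are byte-identical.

## Known limitations

* The structure model ignores stacking and loop entropies; absolute BPP
  values are not thermodynamic — only group contrasts are meaningful.
* The normexp moment estimator is simple and global; saddle-point or ML
  fits would be more efficient on small arrays.
* The feature report tests group-vs-complement; the choice of baseline
  (e.g. High vs Low instead) changes p-values and is configurable only by
  subsetting the input.
* Time-course designs are handled as independent control-vs-stress
  comparisons per timepoint; no longitudinal model is fitted.
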