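# Methods

## Stage model

All analyses run over an ordered stage series, by default the nine
synchronized meiotic time points V (vegetative), P (pre-meiotic), T0
(pachytene), T1 (end of prophase I), T2 (metaphase I), T3 (anaphase I), T4
(metaphase II), T5 (anaphase II), T6 (meiotic exit). The series is
configurable; every statistic that speaks of "earlier/later", "consecutive
intervals" or "windows" is defined by stage rank in this series.

## Structural-dynamics statistics

Inputs are per-transcript, per-stage DMS reactivity vectors with a missing
mask. DMS methylates accessible A and C; when base identities are present,
statistics default to A/C positions only (`ac_only`, configurable, since
published analyses do not always state the restriction — both modes are
provided).

For a transcript with profiles at stages *i* and *j*:

* **r(i,j)** — Pearson correlation over positions covered in both stages.
  Undefined (excluded, not imputed as 0) when fewer than `min_common`
  positions overlap or either vector is constant: missingness is not
  dissimilarity. `min_common` defaults to 50 co-covered positions, a value
  that stabilizes r at transcript scale; "sufficient coverage" has no
  universal definition and the cutoff is exposed in the config.
* **ΔDMS(i,j)** — per-position reactivity(i) − reactivity(j) for i earlier
  than j, so positive Δ means reactivity loss over time. The transcript
  statistic is the median over defined positions. Intramolecular refolding
  moves reactivity both ways (median ≈ 0); an intermolecular duplex
  suppresses reactivity across the molecule (median ≫ 0). The screen keeps
  transcripts whose maximum median ΔDMS over ordered stage pairs exceeds
  0.15, and reports min-r lists at cutoffs 0.6 and 0.5. All cutoffs are
  strict inequalities.
* **Class label** — stable if min r ≥ 0.8; otherwise unidirectional if the
  ΔDMS screen fires; otherwise bidirectional; insufficient when no stage
  pair is evaluable. This operationalizes a verbal taxonomy; thresholds are
  configurable. Note that a noise-free multiplicative suppression leaves r
  at 1.0, so duplex targets are found by the ΔDMS screen, not by low r —
  the two statistics are deliberately complementary.

## Antisense-ratio dynamics

Strand-specific counts per (gene, stage) are TPM-normalized with sense and
antisense entries of a locus as separate terms in the per-stage million
(rate = count/length; TPM = rate / Σrates × 1e6). The antisense read ratio
is antisense TPM / (sense + antisense TPM); since both strands share the
locus length, this equals the read-count ratio of the locus. The TPM floor
(default 10) is applied to the locus total — the floor's reference quantity
is not fixed by convention, and a sense-only mode is available. Stages
below the floor or without data are missing.

Dynamic genes: max ratio − min ratio > 0.20 (absolute ratio units, i.e.
percentage points — ratios are already fractions) with at most one missing
stage. The activation interval is the consecutive-defined-stage pair with
the largest ratio increase; ties break to the earliest interval for
determinism. A gene is **meiosis-specific** when every defined V/P ratio is
at or below background + margin (0.15 + 0.05) and the interval starts at P
or later. The background term reflects incomplete second-strand digestion
in stranded library preparation (~15% of reads retain the wrong strand);
an optional correction ratio′ = max(0, (ratio − b)/(1 − b)) is provided but
off by default. The "meiosis-specific" rule is an operational
interpretation of a verbal description and is flagged as such.

Trajectory clustering uses centroid linkage on the centered Pearson
distance 1 − r, computed over co-defined stages, with centroids recomputed
as the member mean profile — the semantics of the classic Cluster 3.0
program. This linkage is implemented in the package because scipy's
centroid linkage is Euclidean-only and cannot reproduce correlation-based
centroid recomputation under missing data. Centroid linkage can produce
non-monotone merge heights; heights are reported as computed. Constant rows
are dropped with a warning. Cluster assignments at k clusters replay the
first n − k merges.

## Motif and TSS analysis

PWMs come either from JASPAR text PFMs (parsed with Bio.motifs, a
pseudocount of 1 added to every cell before column normalization) or from
IUPAC consensus strings: each column gives (1 − (4−k)·eps)/k to each of its
k allowed bases and eps (default 0.01) to the rest. The two motifs of
interest are URS1 (`TCGGCGGCTA`, Ume6p, early meiosis) and MSE
(`GNCRCAAAW`, Ndt80p, mid meiosis).

Scanning scores every window with log2(p/background) sums, uniform
background by default (synthetic genomes are uniform; a background vector
is accepted for real genomes). N contributes 0 bits — neutral rather than
−∞ — so masked bases do not veto a window. A hit requires score /
max-attainable-score ≥ `min_score_fraction` (default 0.85 for permissive
scans of short degenerate motifs, 0.95 for strict linking; published scans
do not state their threshold, so it is exposed). Minus-strand windows are
scored on the reverse complement and reported in forward coordinates.

Antisense-promoter regions are the 1 kb past a gene's 3′ end, strand-aware
([end, end+1000) for + genes; [start−1000, start) reverse-complemented for
− genes), truncated with a flag at chromosome edges. Enrichment of
motif-positive regions (≥ 1 hit, either strand) in a foreground set versus
background uses the one-sided hypergeometric upper tail, with a Haldane
(+0.5) correction of the odds ratio at zero cells.

Read 5′ ends (chromStart for +, chromEnd−1 for −) are clustered per strand
by single-linkage within a merge window (default 10 nt), representative =
modal position, ties broken toward the 5′-most position in transcription
direction; clusters need ≥ 3 reads. A motif links to a TSS when the TSS is
on the strand opposite the gene and lies within 100 bp downstream of the
motif's downstream edge in the antisense direction (offset = motif_start −
tss for + genes, tss − motif_end + 1 for − genes). Distances measured from
the motif edge rather than its start are a documented choice (the
convention is not fixed by the source analyses) and the bound is
configurable.

## Pulse and convergent-promoter analysis

Abundance rows are z-scored over defined stages (population sd). The pulse
rule: peak = argmax z within the window (default P..T1), rise = peak −
min(z) at or before the peak, fall = peak − min(z) from after the peak
through one stage past the window end; pulsed iff rise ≥ δ and fall ≥ δ
with δ = 1 z-unit. The rule is monotone in δ and invariant to affine
transforms of the raw track. It operationalizes "rapid rise then equally
rapid fall"; the alternative route — cluster z-scored trajectories, then
label pulse-shaped clusters — is available through the clustering module,
and their agreement on synthetic data is measured by the test suite rather
than assumed. Because z-scoring amplifies a flat track's noise to unit
variance, pulse detection presupposes genes with genuine dynamics (in
practice: genes passing an expression-change filter).

Concurrency: the sharpest consecutive-stage sense-TPM decline is concurrent
with antisense activation when the two intervals share or abut a stage —
adjacent stages in mid-meiosis are minutes apart, within trajectory
alignment resolution.

Convergent promoters: URS1 scanned in the 1-kb sense promoter (upstream)
and MSE in the 1-kb antisense promoter (downstream), both strands, strict
threshold 0.95; convergent iff both are found. Transcription-factor
occupancy data are out of scope; convergence is called from sequence only.

## Synthetic-data generator

The generator's defaults are the study conditions; every cohort carries an
exact-quota truth table (class counts are deterministic, not Bernoulli), and
all outputs are byte-reproducible from (config, seed).

* **Reactivity series** — 500 transcripts × 200 nt × 9 stages. Baselines
  are gamma(shape 2) draws rescaled so the A/C-restricted median is exactly
  0.5 (the A/C restriction matches the default scan mode; exact rescaling
  makes the suppression arithmetic analytic: suppressing with f = 0.6
  forces a median ΔDMS of exactly 0.30). 8% of transcripts are
  intermolecular (all positions × (1−f) inside the T1..T4 window), 10%
  intramolecular (+δ on half the eligible A/C positions, −δ on an
  equal-size half with baseline ≥ δ, so the Δ multiset is symmetric and the
  median exactly 0), the rest stable. Gaussian noise (σ = 0.05) truncated
  at zero; 10% missing at random.
* **Stranded counts** — 1,000 genes × 9 stages. Per-gene depth is lognormal
  (median 1,000 reads/stage, log-sd 0.5 — bulk yeast RNA-seq scale). The
  locus total is negative-binomial (dispersion 0.3, var = μ + 0.3μ²); the
  strand split is a binomial thinning at the antisense fraction, so each
  strand is marginally NB with the same dispersion while the ratio keeps
  binomial precision — overdispersion is biological, shared by both strands
  of a locus. The antisense fraction is 0.15 before activation and 0.45
  from the activation interval's end onward. 30% of genes activate, with
  interval quotas placing 78% of activations in P→T0 and T0→T1; 3% mimic
  early antisense (high at V/P, collapsing at T0); 10% are pulsed (total
  output spikes ×5 at the activation start and collapses to ×0.3 after),
  which couples the sharpest sense decline to antisense activation.
* **Genome loci** — 100 non-overlapping genes on random strands, 1-kb
  regions on both sides. 80% of loci are antisense-active: a URS1 or MSE
  realization is planted on the antisense strand of the downstream region,
  a true antisense TSS at a truncated-geometric offset (mean 40, max
  100 bp) downstream of the motif in the antisense direction, 20 read 5′
  ends jittered around the TSS (sd 5) plus 10% uniformly scattered
  artifact ends (mimicking degradation-derived 5′ ends). 20% of loci are
  convergent (sense-orientation URS1 planted upstream). Backgrounds are
  uniform and *scrubbed*: chance IUPAC-exact occurrences of either motif
  outside planted sites are mutated at a pattern-specific column, so the
  planted sites are the only exact matches for any seed.
* **Pulse tracks** — 200 trajectories: 30% pulsed (+2 z-units at a peak in
  P..T1), the rest rising/declining/rebound archetypes at comparable
  amplitude, noise sd 0.2.

What the generator does not emulate: read-level sequencing (no FASTQ, no
alignment), reactivity normalization chemistry, library-composition effects
on TPM, transcript isoforms and overlapping gene architectures, real
promoter sequence composition (backgrounds are uniform), and degradation
kinetics. Recovery tests therefore certify the statistics and their
implementations under the stated noise models — not performance on real
libraries, where coverage, background composition, and isoform structure
add failure modes the generator excludes by design.

## Numerical choices

* Undefined correlations/medians are excluded from minima/maxima, never
  imputed; ties in activation intervals, TSS representatives and cluster
  merges break deterministically (earliest interval, 5′-most position,
  lowest node pair).
* Reactivity values are written with the shortest round-trip decimal
  representation and parsed with exact float conversion, so write∘read is
  the identity and writers are byte-stable.
* Zero-variance rows are dropped (with warnings) before z-scoring and
  clustering; all-zero stages are an error in TPM normalization.
* Seeds: each generator derives its stream from the single config seed
  (offsets +1, +2, +3 for counts, pulse tracks, loci) so cohorts are
  independent but jointly reproducible.

## Problem sizes

Default cohort sizes (500 transcripts, 1,000 genes, 100 loci, 200 pulse
tracks) were chosen so that every recovery statistic has a denominator
large enough for stable estimates while the full acceptance run completes
in seconds on one CPU; they are the sizes the test suite and
`scripts/acceptance.py` use.
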