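# Methods

## Problem and model

`chromgex` predicts steady-state gene expression from chromatin
accessibility and, optionally, chromatin-conformation loops, and uses the
fitted models to prioritize transcription factors (TFs) acting at promoters
versus distal, loop-linked enhancers.

For a gene *g* with most-5′ TSS and a set 𝒟_g of accessibility peaks linked
to it, three peak summaries are computed with an exponential distance decay
(Ouyang-style):

    pl_g = Σ_d l(d)·e^(−dist(d,g)/d0)      (total peak length)
    pc_g = Σ_d e^(−dist(d,g)/d0)           (decayed peak count)
    ps_g = Σ_d s(d)·e^(−dist(d,g)/d0)      (aggregated peak signal)

where l(d) is peak length, s(d) the accessibility signal, dist(d,g) the
distance from the peak centre to the most-5′ TSS, and d0 = 5000 bp controls
the decay. Peaks reached through a chromatin loop get the undecayed
analogues pl*, pc*, ps* — the loop itself is evidence of spatial proximity,
so a linear-genome decay would be wrong there (and empirically shrinks the
loop features toward zero).

TF–gene scores aggregate per-peak TRAP affinities a_{p,t}:

    a_{g,t}  = Σ_{p∈𝒫_g} a_{p,t}/(|p| − |m_t| + 1)            (promoter)
    a*_{g,t} = Σ_{p∈𝒟_{g,𝒱_g}} a_{p,t}/(|p| − |m_t| + 1)      (loop, never decayed)

with |m_t| the motif (PSEM) length; the denominator is the number of
possible binding offsets. The 3 kb promoter window uses the undecayed form;
a 50 kb window variant applies the decay (`RunConfig.tf_decay`).

## Peak-to-gene linkage

Three paradigms, all on 0-based half-open coordinates:

* **window** — peak ∈ 𝒟_{g,w} iff it overlaps the window of size |w|
  centred on the most-5′ TSS by ≥ 1 bp; symmetric halves, odd sizes round
  the upstream half down; a peak may serve several genes.
* **nearest gene** — each peak goes to the gene with the closest TSS on the
  same chromosome (peak centre → most-5′ TSS; ties broken by the
  lexicographically smaller gene id), partitioning the assignable peaks.
* **loop-augmented** — a loop whose anchor overlaps the promoter search
  window of size *r* (loop window, LW; default 5 kb) contributes its other
  anchor as a distal window *v*; peaks overlapping any *v* form the distal
  set. A peak in both the promoter window and a *v* counts **once, on the
  promoter side** (redundancy rule); identical distal windows are
  deduplicated; anchors are used verbatim (padding configurable, default 0).

An optional chromatin-state filter retains only peaks that overlap, by
≥ 1 bp, a promoter/enhancer ChromHMM segment linked to the same gene under
the same paradigm (distal peaks are intersected with segments overlapping
the same loop windows). Adjacent same-state segments are merged on read.

## TRAP affinities

Affinities use the biophysical occupancy model: a PSEM stores non-negative
mismatch energies ε (consensus base 0); a candidate site with total energy
E contributes z/(1+z) with z = R0·e^(−E), summed over both strands and all
offsets. R0 = exp(0.584·|m| − 5.66) as in the original parameterization;
N bases contribute zero energy. The batch scanner concatenates peak
sequences with sentinel separators and scores each motif in one vectorized
pass. A precomputed peak × TF affinity TSV can replace the engine entirely
(`RunConfig.affinity_table`), keeping the learning layers independent of it.

## Learning

The design matrix is assembled in five ways (promoter peak features only;
promoter + loop peak features, separate or columnwise-combined; promoter
peaks + promoter TF scores; the *extended feature space* with all six peak
columns plus separate promoter and loop columns per TF). Features and
expression are log(v+1)-transformed, centred, and scaled to unit sample
variance; zero-variance columns are dropped with a warning (constancy is
detected exactly, not via a float-noise std).

The elastic net is written with the mixing parameter α on the **ridge**
term,

    β̂ = argmin ‖y − Xβ‖² + λ[α‖β‖² + (1−α)‖β‖₁],

and mapped internally to scikit-learn's `l1_ratio = 1 − α`. Because
coordinate-descent λ paths are undefined at l1_ratio = 0, the pure-ridge
endpoint is represented by l1_ratio = 0.01. Model selection is nested: ten
Monte-Carlo outer splits (80% train / 20% test, independent per split),
with a six-fold inner CV choosing α over a grid (default step 0.01, i.e.
101 points) and λ over an automatic geometric path (default 100 values) by
minimum mean inner MSE; the model is refit on the full training split and
scored by Spearman correlation on the held-out 20%. λ = 0 falls back to an
exact least-squares solve. Everything is deterministic in the seed.

Per-feature significance: an OLS model restricted to the features the
elastic net kept, with a partial F-test (1 numerator df, the squared-t
test) per coefficient; aliased columns are dropped greedily. These p-values
ignore correlation between TF activities and should be read as a secondary
layer of evidence.

## Null models

`shuffle_loops` relocates each loop **jointly** — both anchors shift by the
same offset to a uniformly random valid position (chromosomes weighted by
their number of valid starts) — so anchor lengths and the anchor–anchor
distance of every loop are preserved exactly. This is strictly stronger
than matching the distance distribution, and makes the real-vs-null
contrast purely about *where* loops sit. By default a loop may change
chromosome; the experiment pipeline restricts to the source chromosome so
null loops remain comparable per chromosome. `shuffle_gene_annotation`
relocates gene bodies the same way, preserving length and strand. Shuffled
loops may overlap each other, as nothing in the construction forbids it.

In real-vs-null comparisons a fold whose model keeps no feature produces
constant predictions; its rank correlation is undefined and is scored 0
(no rank association). The comparison itself is a one-sided rank-sum test
of the real fold Spearman values against the pooled null folds.

## TF prioritization

Mean fold coefficients (absent = 0) define the non-zero TF sets per context;
scaling divides by the maximum absolute mean coefficient per sample, so
scaled values lie in [−1, 1] with signs preserved. Set logic over samples
and contexts yields an UpSet-compatible membership matrix and the TFs
recurring in ≥ k samples per context (default k = 2). The
expression-enrichment test draws 1000 random TF sets of the query's size
without replacement and compares the query's expression against the pooled
samples with a two-sided rank-sum test (a per-set resampling variant is
available via `pooled=False`); its empirical size at nominal 5% is inside
[0.03, 0.07] in our calibration runs.

## Synthetic data

`FixtureSpec` defaults define the reference conditions: 4 chromosomes of
2.5 Mb, 2000 protein-coding genes on a jittered grid, ~8000 peaks (1–3 per
promoter, extra peaks inside distal loop anchors, the remainder
background), 1000 loops anchored at a random half of the promoters with
anchor width 5 kb and anchor distances 50–400 kb, 50 PSEMs of length 7–11
from random consensus sequences, and a ChromHMM track covering promoter
peaks (TssA), distal peaks (Enh) and background (Quies). Each TF's
consensus is embedded into a random ~10% of peaks so TF-gene scores vary
independently across TFs rather than all tracking total peak mass.

Expression is a sparse linear combination of the *pipeline-computed*
TF-gene scores (default: three promoter effects and two loop effects,
mixed signs) on the log1p/standardized scale, plus Gaussian noise whose sd
is `noise_sd` × the signal sd (so SNR = 1/noise_sd; default 0.2 → SNR 5),
shifted, clipped at 0 and inverse-transformed with expm1. Because the
planted model lives on exactly the scale the learner uses, recovery is
exact in the noise-free limit.

What the fixture does **not** emulate: mappability and GC structure, peak
caller artefacts, trans effects, TF–TF cooperativity, realistic HiChIP
contact counts, or the heavy-tailed gene-density landscape of a real
genome. Passing tests therefore demonstrate correctness of the method's
arithmetic and its ability to recover planted signal under the stated
conditions — not performance on real chromatin data.

## Problem sizes and numerical choices

The recovery and loop-benefit experiments (acceptance tests and
`scripts/acceptance.py`) run the nested CV with an α-grid step of 0.2–0.25
and a 50-point λ path; with ≈100 features and 2000 genes the selected
models are insensitive to the finer default grid, which remains the package
default (step 0.01, 100 λ values). The loop-benefit fixture uses 600 genes,
10 TFs and 300 loops with loop-only planted effects. Ties in nearest-gene
linkage and in TF rankings break lexicographically; tolerances: preprocessed
column means are 0 within 1e−12, the λ→0 elastic net matches OLS within
1e−6 on full-rank systems, decay closed forms hold to 1e−12.

## Known limitations

* TRAP's λ-scaling is folded into the PSEM energies; imported PSEMs
  calibrated for other conventions may need rescaling.
* The nearest-gene paradigm measures distance to the most-5′ TSS only; the
  TSS-vs-TTS ambiguity of that paradigm is resolved to TSS by design.
* OLS p-values ignore collinearity among TF features; treat them as
  supporting evidence, not as primary inference.
* The gene-annotation shuffle relocates genes independently, so shuffled
  genes can overlap; this mirrors the cited shuffle tool's behaviour.
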