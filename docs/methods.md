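# Methods

`tc2tf` implements a two-stage analysis of a two-genotype stimulation time
course: (1) identification of responsive genes and of the kinetic difference
between wild type (wt) and knockout (ko), and (2) prediction of
transcription factors whose binding sites are over-represented in the
promoters of the genotype-dependent genes. A synthetic-data generator with
ground-truth labels makes every stage testable end to end.

## Expression model and preprocessing

The pipeline works on log2 intensities of a probe × sample matrix with a
factorial design: genotype ∈ {wt, ko} × time ∈ {0, 6, 12, 24, 48} h ×
replicate ∈ {1, 2, 3}, where t = 0 is the unstimulated control.

**Quantile normalization** maps every sample column onto the across-column
mean of order statistics; within-column rank order is preserved and tied
values receive the mean of the tied reference quantiles. After normalization
all columns hold the identical value multiset (exactly, for tie-free
columns), which removes any per-sample additive or monotone distortion. The
operation is idempotent.

**Fold change** is computed per replicate against the t = 0 control of the
same genotype and replicate: FC(g, t, r) = I(g, t, r) − I(g, 0, r). The
replicate-matched reference is what makes per-replicate ranking meaningful.
Probes with an ambiguous or missing gene mapping are dropped; when several
probes map to one gene, the probe with the largest |FC| over the time course
represents the gene in that genotype/replicate (ties broken by probe id).
Collapsing this early diverges from workflows that collapse only before
promoter analysis; it gives a single gene-level fold-change cube for all
later stages.

Background correction is out of scope (the generator produces
background-free intensities); a constant-offset subtraction for linear-scale
input is available in `preprocess.subtract_offset`.

## Rank-score filter, intersection, clustering

Per replicate, each gene's response is summarized on **absolute** log2 fold
change by its time-averaged mean FE_mean and its peak FE_peak. Both are
divided by their across-gene maximum within the replicate and combined as

    s = sqrt(FE_mean_norm² + FE_peak_norm²) ∈ [0, √2].

s is monotone in each component, so any monotone transform of s (for
example, dropping the square root) yields the same ordering; the ordering,
not the value of s, is the contract. Ties on s break by FE_peak descending,
then gene id — needed only for determinism. Ranking uses absolute fold
change so that repressed genes rank alongside induced ones; clustering and
superimposition use **signed** profiles so the two directions separate.

Genes common to the per-replicate top-k lists (default k = 1000) form the
responsive set. The set is clustered by Lloyd k-means (scikit-learn, default
k = 6, 10 restarts, seeded; labels renumbered by cluster size for
reproducibility) on the signed replicate-mean profiles, and the ko profiles
of the same genes are superimposed cluster by cluster as mean ± sd per time
point. Normalization maxima are per replicate; a global-maximum variant
would rescale both components identically within a replicate pair and is not
exposed.

## Moderated interaction testing

A saturated cell-means model is fitted per gene over the (genotype, time)
cells; the residual variance s_g² pools within-cell sums of squares with
d = Σ(n_cell − 1) degrees of freedom. The per-time interaction contrast

    C_t = (I_ko,t − I_ko,0) − (I_wt,t − I_wt,0)

is zero whenever the response to the stimulus is the same in both genotypes,
whatever its magnitude — it isolates the genotype-dependent (maintenance)
component of the response.

Variances are moderated with the standard empirical-Bayes construction,
implemented in-package: with e_g = log s_g², the excess of var(e) over
trigamma(d/2) estimates trigamma(d0/2) (monotone root-finding; d0 = ∞ when
the excess is non-positive), and s0² follows from mean(e) with digamma bias
corrections. The posterior variance s̃_g² = (d0·s0² + d·s_g²)/(d0 + d) gives
a moderated t = C_t/√(s̃_g²·v_c) with v_c = Σ 1/n over the four contrast
cells and d + d0 degrees of freedom (normal reference at d0 = ∞; d0 = 0
reproduces the ordinary t exactly and is kept as a switch). F = t² with one
numerator df is the per-time test; per-time testing matches per-time
reporting, and Benjamini–Hochberg runs within each time point's gene
ensemble by default (`bh_scope="global"` adjusts across all tests instead).
Genes pass at adjusted p < 0.05.

The BH step-up rule is implemented directly (q_(i) = min_{j≥i} p_(j)·m/j,
clipped at 1) and checked in the tests against a brute-force enumeration.

## Promoter scanning

Count matrices (TRANSFAC dialect; fractional counts accepted) are converted
to log2-odds weights against a background base composition b (default
uniform) with a pseudocount β = 1 split by background:

    w(a, j) = log2((n_aj + β·b_a) / ((n_j + β)·b_a)),

which keeps every weight finite. The per-promoter statistic is the maximum
window score over both strands of the 4 kb promoter (a promoter has "at
least one significant site" exactly when its best site is significant at the
per-sequence level). Windows containing N score at a large negative sentinel
and can never win; scanning is case-insensitive. Strand ties within 1e-9 are
broken toward the smaller position, then the + strand (the two strands sum
weights in different orders, so exact float equality cannot detect ties).

Significance is calibrated per promoter by a composition-preserving random
letter shuffle: the null statistic is the best score of a shuffled copy,
repeated n_perm times (default 1000), and

    p = (1 + #{null ≥ observed}) / (n_perm + 1),

so p ≥ 1/(n_perm + 1) and downstream BH never sees p = 0. A promoter is a
hit for a motif at p < 0.1. A dinucleotide (Altschul–Erikson) shuffle is
available for composition-sensitive users. In `build_hit_table` one batch of
shuffles per promoter is scored against all motifs — a valid Monte-Carlo
null (p-values across motifs need not be independent) that divides the
shuffling cost by the number of motifs.

**Discreteness at the consensus ceiling.** The max score is capped at the
exact-consensus score, and a random 4 kb sequence contains a given L-mer
with probability ≈ 2·(4000−L)/4^L — about 0.11 for L = 8, 0.008 for L = 10.
Because ties count toward the null (the ≥ in the estimator), p-values for
short motifs are conservative near the cap: for 8-position motifs the
fraction of background promoters reaching p < 0.1 is ~0.02–0.03 rather than
the nominal 0.10, while for 10-position and longer motifs the statistic is
effectively continuous and the nominal rate is recovered. This conservatism
only reduces false-positive hits; the calibration checks therefore use a
10-position motif.

## TFBS enrichment

The genotype-dependent genes at the late time point (default 24 h) that map
unambiguously to a gene with an available promoter are split into K = 3
sub-clusters by complete-linkage agglomerative clustering on 1 − Pearson
correlation over the 24 h sample columns. For each motif and each gene set
(the full set and each sub-cluster), a one-sided Fisher's exact test — the
hypergeometric upper-tail probability of the observed hit count given the
margins — compares hit frequency in the set against all other
promoter-bearing genes on the array (for a sub-cluster, the background
includes the differential genes outside it). Only enrichment is reported by
default (a two-sided variant exists); BH runs across motifs within each gene
set. With no set gene hit (a = 0) the upper tail covers all outcomes and
p = 1 exactly.

## Synthetic data generator

The generator emulates the statistical structure of the study, with
ground truth for every stage:

* **Kinetic classes.** Each gene is nonresponsive, transient or sustained,
  induced or repressed. All responsive genes share a full-amplitude early
  response (≤ 12 h) **identical in both genotypes** — the
  receptor-independent initiation. Transient genes decay linearly to
  baseline between 12 and 24 h in both genotypes; sustained genes do the
  same in the knockout but retain ≥ 0.8 of the amplitude in the wild type
  (0.9× at 24 h, 0.8× at 48 h). The two-phase shape is piecewise-linear —
  the simplest form with the qualitative signature of an early shared phase
  and a genotype-dependent maintenance phase. By construction the genotypes
  differ only at 24 and 48 h.
* **Defaults** (the emulated study conditions): 2000 genes, 7.5% responsive,
  60% of those sustained, 40% repressed, peak amplitude 2.0 log2 units,
  i.i.d. Gaussian log-scale noise with sd 0.3, baselines N(8, 1.5²), three
  replicates per genotype, knockout decay complete at 24 h. Effect sizes and
  noise are artifact conventions (reported in output headers), chosen so
  that responsive genes are clearly separable yet single-replicate noise is
  non-trivial (per-replicate fold-change noise sd ≈ 0.42).
* **Mapping frictions.** 1% extra probes are flagged ambiguous, 2% of genes
  carry a second attenuated probe, and 5% of genes lack a promoter, so the
  probe-filtering and promoter-availability steps are exercised.
* **Interaction-only dataset.** A separate generator plants a genotype
  difference (δ = 1.5 by default) at exactly one time point with no other
  signal, to probe the per-time specificity of the interaction contrast.
* **Motifs and promoters.** PWM count matrices are drawn with one dominant
  base per position whose probability is solved (by bisection on the entropy)
  to hit a requested per-position information content; non-dominant counts
  are mildly uneven, as in real collections — perfectly symmetric ones would
  collapse window scores onto a lattice (score = number of consensus
  matches) and break the near-continuity that permutation calibration relies
  on. The jitter vanishes at the entropy extremes (0 and 2 bits), which stay
  exact. Promoters are i.i.d. background sequence (uniform by default) with
  1–3 instances per firing rule sampled from the count-proportional
  distribution and written at non-overlapping positions on a random strand;
  planted positions are recorded.

What the generator does **not** emulate: probe-level scanner artifacts, dye
or spatial effects, background signal, correlated noise across genes,
realistic promoter composition (GC skew, repeats, CpG islands) or motif
co-occurrence. Passing recovery tests therefore show that the pipeline's
inference is correct under its own model assumptions, not that the biology
of any particular dataset will be this clean.

## Problem sizes and numerical choices

The test suite and the acceptance script run the recovery analyses at 2000
genes with three replicates; promoter calibration uses 300–500 background
4 kb sequences at 200 shuffles, and the enrichment recovery uses 40 set vs
400 background promoters of 1 kb at 60–100 shuffles over 20 seeds — sizes at
which the Monte-Carlo error of each measured rate is small compared to the
margin of the property being checked. All randomness flows from explicit
seeds (numpy `SeedSequence` spawning); identical configuration gives
byte-identical pipeline outputs, which the determinism test checks
literally. Expression TSVs are parsed with correctly-rounded float
conversion so written matrices round-trip bit-exactly.

Known limitations: the moderated-t hyperparameters use the method of
moments, which can be off for very small ensembles (a 50-gene minimum is
enforced); the max-score cap conservatism for short motifs described above;
complete-linkage ties are broken by scipy's internal merge order (labels are
stabilized by first occurrence, and partitions are input-order invariant);
k-means recovers the planted kinetic classes only up to splits when k
exceeds the number of distinct true profiles.
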