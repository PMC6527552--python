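# Methods

## Data model

A screen is a cells × genes raw count matrix with a per-cell perturbation
label (a gene symbol, or `CTRL` for negative controls pooled across all
non-targeting guides) and an optional condition tag. All matrices are
oriented cells × genes in memory; Matrix Market input, which is usually
genes × cells on disk, is re-oriented by matching dimensions against the
barcode and gene file lengths, and a square matrix with equal barcode and
gene counts is rejected as ambiguous rather than guessed. Cells without a
perturbation assignment are dropped with a logged count.

## Filter chain

The filters run in a fixed order — QC → imputation → zero-expression
perturbations → efficiency filter → minimum cells — because each consumes
the previous stage's output; every filter is pure (input unchanged,
output cells a subset of input cells).

**QC.** A cell is kept when genes detected ≥ `min_genes` (default 500),
total UMI ≥ `min_umi` (default 1000) and the mitochondrial fraction ≤
`max_mito_fraction` (default 0.10). The mitochondrial fraction is the
*count of detected mitochondrial genes over all detected genes* — a
detected-gene fraction, not a UMI fraction. Mitochondrial genes are
recognized by gene-id prefix (`MT-`/`mt-`, configurable).

**Imputation.** A pluggable stage: `none` (default) passes raw counts
through; `shrink` replaces each zero entry by λ (default 0.1) times the
gene's mean over nonzero cells, a deliberately minimal smoother. A matrix
imputed by any external tool can be supplied as the input counts instead;
downstream stages do not assume integer counts after this point.

**Zero-expression perturbations.** A knockout label whose own gene is
zero in every cell of the dataset carries no evidence the perturbation
happened; the label and its cells are removed. Labels with no matching
gene row (e.g. promoter-targeted screens) skip the check with a warning.

**Efficiency (escaper) filter.** Only 70–80% of guide-carrying cells
acquire a functional edit. Per perturbation: DE genes versus controls are
found by two-sample Kolmogorov–Smirnov at raw p < 0.05 (asymptotic
two-sided, no multiplicity correction — the threshold is a sensitivity
knob, not an inference); per perturbed cell the median cosine similarity
of the DE-gene profile to same-label peers, M(P), and to controls, M(C),
are compared and the cell is removed iff M(C) > M(P) (ties retain, the
strict inequality). If the removed share of a perturbation reaches
`drop_fraction` (default 0.90) the whole perturbation goes. Controls are
never filtered here — they define the reference. Zero-norm DE vectors
receive similarity 0 to everything; a single-cell perturbation or an
empty DE set leaves cells untouched with a warning.

A structural caveat, visible in the test suite: when nearly *all* of a
perturbation's cells are escapers, peers and controls are draws from the
same population, so M(P) and M(C) estimate the same quantity and the
per-cell decision approaches a coin flip. The whole-perturbation drop
rule therefore fires reliably only when a (sizeable) edited contingent
makes escapers' peers dissimilar; a perturbation that is essentially all
escapers is instead neutralized downstream by its near-null TPDS.

**Minimum cells.** Perturbations with fewer than `min_cells` (default 30)
remaining cells are dropped; if the *controls* fall below the threshold
the pipeline errors out, since every later statistic is defined against
the control population.

## Gene selection and the token matrix

Genes are scored by the dispersion difference
`DD_i = |ZD_case(i) − ZD_control(i)|`, where the dispersion is
`D_i = ln(σ²_i/μ_i)` (natural log; genes with zero mean or variance are
unusable) and ZD is the z-score of D within equal-frequency
mean-expression bins (default 20 bins, sample SD with n−1; a bin with
zero spread yields z = 0; fewer usable genes than bins collapses to
⌊usable/2⌋ bins). Case is all perturbed cells pooled, control the control
cells, with bins defined independently in each. The top `n_dde_genes`
(default 500) by DD are kept, ties broken by gene id after rounding DD to
10 decimals so the selection is invariant to cell order. Note that a
z-score within an n-gene bin is bounded by ≈ √n, so a single
variance-inflated gene saturates rather than grows without bound.

The topic-model input is `round((X − μ_c)/μ_c · 10)` per selected gene
(μ_c the control mean; genes with zero control mean are excluded),
rounding half away from zero and clipping negatives to 0, because word
counts must be nonnegative. Clipping discards down-regulation; the
clipped fraction is logged. Control cells therefore map near 0 and only
above-control expression generates tokens.

## Topic model

Cells are documents, token counts word frequencies. Latent Dirichlet
allocation with symmetric priors α (default 50/n topics) on θ and β
(default 0.1) on φ is fitted by collapsed Gibbs sampling — written here
as a numba kernel because the sampler's seed discipline is part of the
contract: a fixed seed gives bit-identical θ and φ across runs and
platforms. Tokens are expanded cell-major with genes in *gene-id order*,
a canonical order independent of column layout, so permuting gene columns
permutes φ's columns and leaves θ unchanged. Estimates use the smoothed
counts of the final post-burn-in sweep (default 1000 sweeps, burn-in
500); `average=True` averages counts over all post-burn-in sweeps
instead — smoother but mixing label-switching states on multimodal
posteriors, hence not the default. All-zero cells are excluded from the
chain and assigned the uniform distribution.

**Topic-number selection.** For each candidate n (default 4–6), the scan
fits a model (seed + candidate index) and computes a specificity score
`SS = ln(mean_j σ²_j/μ_j²)` over θ columns (the mean squared coefficient
of variation: topics should spread unevenly over cells) and a purity
score `PS = ln(mean_i σ²_i)` over θ rows (few topics should dominate a
cell). Degenerate inputs floor the log argument at 1e-12. The combination
score is `CS = α·minmax(SS) + (1−α)·minmax(PS)` with α default 0.5,
min–max taken across candidates (all-equal extents give 1); the best
candidate maximizes CS, ties to the smaller n. Variances use ddof=1
throughout, as everywhere in the package.

**Annotation.** Per topic, the top ⌈10%⌉ genes by φ (ties by gene id) are
tested for over-representation against a user-supplied GMT collection by
the hypergeometric tail over the fitted gene universe, with
Benjamini–Hochberg correction across sets within a topic; the top 5 terms
by q are reported. This keeps annotation offline and deterministic; no
ontology structure is used.

## Effect statistics

θ is z-normalized per topic against the control population (control mean
and sample SD; a constant control column falls back to SD 10⁻¹², logged).

`TPD_ij` is the pooled-variance two-sample t statistic between M cells of
perturbation i and *all* control cells on normalized topic j, where M is
the minimal cell count over perturbations; to neutralize sample-size
imbalance the statistic is the median over `n_boot` (default 1000)
bootstrap draws of M cells without replacement (a perturbation with
exactly M cells is degenerate: every draw is the full sample). The
control side is the full control population rather than M cells — the
null baseline construction below makes the same choice, so the two are
comparable. Zero pooled variance with unequal means yields a signed
infinity sentinel. Randomness is organized as substreams keyed by
(master seed, CRC32 of the label, topic index), so results are invariant
to cell and label ordering and independent of iteration order.

`TPD_random,j` repeats the construction with the case side drawn from the
controls themselves — the ranking's null. `TPDA = TPD − TPD_random` (per
topic), `TPDR_ij = |TPD_ij| / Σ_j' |TPD_ij'|` (share over *topics*; the
per-perturbation variant is available via `axis="perturbations"`),
and the topic-specific score is

    CS_ij = ½ · ( norm_j |TPD_ij| + norm_j TPDR_ij )

with min–max extents over topics within perturbation i (degenerate
extents contribute 0; a single topic is an error since the score is then
undefined). Its per-topic significance threshold is the median over 1000
repetitions of the same CS computation applied to a control-only TPD row.
The overall score is `TPDS_i = Σ_j |TPDA_ij|`, reported raw and
normalized by its maximum; perturbation relationships are Pearson
correlations of TPDA rows; and between two conditions the impact ratio is
`PID_i = share₂(i)/share₁(i)` over the common perturbations (shares of
the condition's TPDS total; a zero condition-1 share flags PID infinite).
Significance thresholds gate only the topic-specific scores, not the
overall ranking.

**Robustness.** A random 20% of controls is relabeled as a
pseudo-perturbation and the effect stage rerun (default 10 repetitions),
recording the fraction of true perturbations ranking below the pseudo one
and the Pearson correlation of normalized TPDS against the unrelabeled
run. θ is held fixed across repetitions: the topic model never sees
labels, so relabeling cannot change it given the gene set; only the
label-dependent stages (normalization, TPD) are recomputed. A full refit
would additionally perturb DDE selection through the shrunken control
pool — a second-order effect at a 20% split.

## Off-target screening

Candidate discovery is a plain Hamming scan of the guide (18–23 nt)
against every transcript window on both strands (mismatch budget default
3; minimal distance per gene reported once; optional NGG-PAM filter, off
by default). Sequence similarity alone is weak evidence, so a candidate
is flagged only if the Pearson correlation between target and candidate
expression is significantly *higher* in perturbed cells than in controls
— one-sided Fisher z at α = 0.05. The choice of Pearson + Fisher z is
this package's, documented rather than inherited. CRISPRi screens, whose
silencing is locus-specific, should skip the module.

## Synthetic screens

The generator mirrors the topic model's own generative story so that
recovery is well-posed: topic gene loadings φ_true ~ Dirichlet(0.05)
(sparse programs); control cells draw θ_true ~ Dirichlet(base); a
perturbation adds its effect size to the base concentration of its
assigned topic (perturbations cycle through topics); cell counts are
multinomial in θ_true·φ_true at a Poisson library size, followed by
independent Bernoulli dropout. Escapers keep the perturbed label but draw
from the control law (default fraction 0.25, the field's 20–30% figure).
The target gene of each perturbation is floored at loading 4/G before
normalization — screens target expressed genes — and its counts are
scaled by 0.1 in edited cells, so the zero-expression filter only fires
when the knockdown factor is set to 0.

Defaults: 5 perturbations × 60 cells, 150 controls, 300 genes, 3 topics,
base 0.8 per topic, effect 4.0, library 1000, dropout 0.1. Base 0.8 keeps
the control population diffuse, so the default effect of 4 (mean θ on the
assigned topic 0.75 versus 0.33) is a strong but not separable-by-eye
phenotype, and the graded grid {0, 0.5, 1, 2, 4} used in the ranking
tests spans undetectable to strong. `SimConfig.strong_separation()`
(base 5.0, effect 25.0) is the regime for escaper-filter evaluation: a
concentrated control prior is what makes "wild-type phenotype" a coherent
class — under the diffuse default, ~18% of control draws lie inside the
perturbed phenotype and no similarity filter can separate them, a limit
of the data, not the method. `simulate_two_conditions` shares φ_true
between conditions and multiplies the planted effects by per-perturbation
modulation factors.

What the generator does *not* emulate: overdispersed (negative-binomial)
noise, ambient RNA, doublets, guide-level structure below the gene, or
batch effects. Passing tests therefore demonstrate the statistics recover
planted structure under the model's own assumptions, not performance on
any particular real dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run simulations at 220–600 cells,
150–300 genes, 150–300 Gibbs sweeps and 100–300 bootstrap draws — scales
chosen so the whole suite completes in minutes on one CPU while leaving
wide margins on every property; the library defaults (1000 sweeps, 1000
draws) are for real analyses. Ranking tables break ties by label;
written floats carry 6 significant digits; every output table carries the
tool version and a hash of the fully resolved configuration, and a rerun
with the same configuration and seed is byte-identical.

Known limitations: down-regulation is invisible to the topic model
(clipped at 0 — encoding it as paired "down" pseudo-genes is a possible
extension); TPD saturates in t-statistic fashion for very strong effects,
compressing the top of the ranking; PID inherits the noise of two
independent topic fits; and the escaper filter degrades as the escaper
fraction approaches 1 for the structural reason given above.
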