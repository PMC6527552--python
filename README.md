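# topicscreen

Topic-model analysis and perturbation-effect ranking for single-cell
CRISPR screens (Perturb-seq / CRISP-seq / CROP-seq).

Pooled single-cell CRISPR screens read out the transcriptome of each cell
together with the guide it carries, but turning that into a ranked list of
perturbation effects is confounded by low-quality cells, guides that never
produce a functional edit (20–30% of cells keep a wild-type phenotype),
wildly unequal cell numbers per perturbation, and the sheer
dimensionality of expression space. `topicscreen` addresses each in turn:

1. **Filtering.** Standard QC (genes detected, UMI total, mitochondrial
   fraction) plus screen-specific filters: perturbations whose target gene
   is never expressed are removed; "escaper" cells whose
   differential-expression profile is closer to controls than to their own
   perturbation peers (median cosine similarity, M(C) > M(P)) are removed;
   perturbations with fewer than 30 cells are dropped.
2. **Representation.** Cells become documents of gene tokens: genes are
   ranked by the dispersion difference DD = |ZD_case − ZD_control| (binned
   z-scores of ln(σ²/μ)), expression is normalized against control means
   (round(10·(X − μ_c)/μ_c), clipped at 0) and a latent Dirichlet
   allocation model is fitted by collapsed Gibbs sampling. Each cell gets
   topic proportions θ, each topic a gene distribution φ; the topic count
   is chosen automatically by a specificity/purity combination score.
3. **Ranking.** The effect of perturbation *i* on topic *j* is the TPD: a
   pooled two-sample t statistic between control-normalized topic
   probabilities of perturbed and control cells, bootstrapped at the
   minimal perturbation size M (median over 1000 draws). From it derive
   the control baseline TPD_random, the adjusted TPDA = TPD − TPD_random,
   the per-topic share TPDR, the topic-specific score
   CS = ½·(norm|TPD| + norm TPDR) with an empirical significance
   threshold, the overall score TPDS = Σ_j |TPDA_ij|, Pearson
   correlations between perturbation profiles, and the between-condition
   impact ratio PID.
4. **Off-target checks** for knockout guides: Hamming-window candidate
   search on both strands, confirmed only by a significant *increase* in
   target–candidate expression correlation in perturbed cells (Fisher z).

A fully parameterized synthetic-screen generator with planted topics,
effect sizes and escaper cells makes every stage testable end to end.

## Worked example

```python
import topicscreen as ts

dataset, truth = ts.simulate_screen(ts.SimConfig(seed=11))
cfg = ts.RunConfig(min_genes=0, min_umi=0, n_topics=3, n_iter=300,
                   burn_in=150, n_boot=300, n_threshold_reps=100,
                   n_dde_genes=200, seed=11)
result = ts.run_pipeline(dataset, cfg)
print(result.profile.ranking())
```

prints

```
 rank perturbation       TPDS  TPDS_normalized
    1        G0004 20.316262         1.000000
    2        G0001 18.653202         0.918141
    3        G0005 18.493309         0.910271
    4        G0002 17.175989         0.845431
    5        G0003 15.862042         0.780756
```

TPDS is the summed absolute adjusted topic effect: all five knockouts were
planted with the same effect size, and all five rank far above the control
baseline (a relabeled-control pseudo-perturbation lands near zero). The
`examples/` directory has one short script per capability — filtering,
topic-number selection and annotation, two-condition comparison, and
off-target screening — each printing its result with a line on what the
numbers mean.

A thin CLI wraps the same pipeline (`topicscreen simulate | preprocess |
fit | rank | all | compare | robustness | offtarget`); every run directory
contains the resolved JSON configuration and all intermediate tables, and
reruns with the same seed are byte-identical.

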