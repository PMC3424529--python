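# swarmsvm

Gene selection and two-class tumor classification from expression matrices,
combining three ingredients:

1. **mRMR preselection** — genes are ranked by a greedy first-order
   incremental criterion, maximizing mutual information with the class label
   while subtracting mean redundancy against the genes already chosen:
   `I(T, g) − (1/|S|) Σ_{s∈S} I(g, s)` (scores in bits, genes discretized at
   `μ ± σ` by default). The top k = 50 genes form the working panel.
2. **Particle-swarm weighting and tuning** — a swarm searches k raw gene
   weights `a_i ∈ [0, 1]` together with the SVM soft-margin penalty
   `C ∈ [0.01, 5000]` and RBF width `γ ∈ [0.0001, 32]` (k + 2 decision
   variables; velocity update `v ← w v + c1 r1 (p_best − x) + c2 r2 (g_best − x)`
   with w = 0.9, c1 = c2 = 2, swarm 50, 70 iterations by default), scoring
   each position by the classification accuracy of the machine it encodes.
3. **Weighted RBF SVM with a gene gate** — weights at or below a threshold
   δ are zeroed, `U_δ(a_i) = a_i · 1[a_i > δ]`, the rest renormalized to
   `α` with `Σ α_k = 1`, and the classifier uses the weighted kernel
   `K'(x_i, x_j) = exp(−γ Σ_k α_k (x_ik − x_jk)²)`. Genes with zero weight
   are invisible to the decision function; uniform weights recover the
   standard RBF SVM at width γ/d.

The library targets researchers who want a transparent, fully seeded
re-implementation of this family of wrapper methods, with leave-one-out /
10-fold evaluation, a δ grid search, and the standard ablation variants
(fixed-parameter SVM, mRMR-SVM, hyperparameter-only PSO-SVM) for comparison.
See `docs/methods.md` for assumptions, numerical choices and known
limitations — including why accuracy-only fitness cannot identify a unique
weight vector on separable data.

## Worked example

`examples/rank_genes.py` plants 5 informative genes (class means shifted by
4 within-class SDs) among 55 noise genes and ranks by mRMR:

```text
planted informative genes: ['g13', 'g50', 'g54', 'g57', 'g7']
gene_id  rank  gene_index  relevance_bits  step_score
    g13     1          12        0.453283    0.453283
    g50     2          49        0.453283    0.258206
    g57     3          56        0.350000    0.182771
     g7     4           6        0.400000    0.164242
    g54     5          53        0.381508    0.118276
    g44     6          43        0.168963    0.032344
    ...
5 of 5 planted genes occupy the top-5 ranks
```

`relevance_bits` is `I(label; gene)`; `step_score` is the difference
objective at the step the gene was chosen (relevance minus mean redundancy
against earlier picks — note how g50, a near-duplicate signal of g13, is
penalized relative to its raw relevance).

`examples/train_weighted_svm.py` runs the full pipeline (preselect 20 genes,
swarm-weight them, gate at δ = 0.3) and prints the surviving genes, the
tuned `(C, γ)` and the final training accuracy;
`examples/compare_variants.py` cross-validates the four ablation variants
under shared folds.

The same functionality is scriptable from the shell:

```bash
swarmsvm simulate --n-samples 40 --n-genes 100 --effect-size 2 --seed 1 --out data.csv
swarmsvm rank data.csv --sample-id-column sample_id --k 50 --out ranking.csv
swarmsvm train data.csv --sample-id-column sample_id --delta 0.3 --model-out model.json
swarmsvm ablate data.csv --sample-id-column sample_id --seed 1 --out ablation.csv
```

Real datasets load from delimited text in either orientation
(samples-as-rows with a label column, or the transposed microarray export);
label encodings are always declared explicitly, e.g. `--label-map ALL=1,AML=-1`.

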