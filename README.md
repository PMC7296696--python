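# sscentrality

Source/Sink centrality (SSC) for directed biological pathway graphs, with a
complete statistical validation pipeline against a-priori important gene
sets.

## The problem

Signaling pathways have an upstream-to-downstream organisation: receptors
and ligands sit at the top, effectors and transcription factors at the
bottom. Standard directed centralities are blind to one of these ends. A
directed Katz or PageRank score flows along edge directions, so a node with
no incoming edges (an upstream receptor) gets the minimum possible PageRank,
and a node with no outgoing edges (a downstream effector) gets the minimum
possible Katz score — even though genes at *both* terminal ends are often
exactly the biologically important ones.

SSC fixes this by scoring every node twice:

* **Source centrality** — importance as a *sender* of signal: the model
  evaluated along edge directions.
* **Sink centrality** — importance as a *receiver*: the same model on the
  transposed graph (all edges reversed).
* **SSC** — their elementwise sum, computed with identical parameters.

For a pathway graph G with 0/1 adjacency A, clamped out/in-degree matrices
`D = diag(max(deg⁺,1))` and `D′ = diag(max(deg⁻,1))`, dampening factor α and
constant vector β, the spectral variants are closed-form linear solves:

| model | source | sink |
|---|---|---|
| PageRank | `C = (I − αAD′⁻¹)⁻¹ β` | `C = (I − αAᵀD⁻¹)⁻¹ β` |
| Katz | `C = (I − αA)⁻¹ β` | `C = (I − αAᵀ)⁻¹ β` |
| Laplacian (degree-averaged) | `C = (I − αD⁻¹A)⁻¹ β` | `C = (I − αD′⁻¹Aᵀ)⁻¹ β` |

plus non-parametric degree (in + out) and harmonic closeness
(`C(v) = Σᵤ 1/d(v,u)`, unreachable pairs contributing 0). Katz is refused
unless `α < 1/λ₁` (λ₁ the adjacency spectral radius). Note the PageRank here
is the literal closed form with a constant restart vector β — no dangling-node
redistribution and no sum-to-one normalisation.

The validation pipeline quantifies how well each variant places important
genes (e.g. cancer or essential genes) at high centrality:

1. **Quantile regression** — within-pathway ranks mapped to quantiles
   1..100 (`Q = ⌈100·rank/n⌉`), counts pooled across pathways, and the
   percentage of important genes per quantile `Fᵢ = 100·rᵢ/nᵢ` regressed on
   the quantile index `i` (OLS, `Fᵢ = a₁·i + a₀`).
2. **CDF comparison** — per-pathway z-scores pooled into 100 quantiles and
   compared between important and other genes with a one-sided two-sample
   Kolmogorov–Smirnov test (`D = sup (F_other − F_important)`).
3. **Per-pathway tests** — one-sided Welch t and Wilcoxon rank-sum per
   pathway, Benjamini–Hochberg FDR per (model, variant, test) family.
4. **Sensitivity scan** — the regression repeated for all four PageRank
   variants over α ∈ [0.1, 0.9] (step 0.01), SSC vs undirected compared by
   Fisher's Z-transformation of the fit correlations.

Readers for KGML (KEGG pathway XML) and plain edge-list TSV, GMT /
gene-per-line gene sets, and the standard pathway quality filters
(size, spectral-radius, constant-centrality and minimum-important-gene
rules) are included, together with a synthetic generator of layered
pathway-like DAGs with importance planted at terminal ends, at hubs, or
uniformly — so the entire pipeline runs with no external downloads.

## Worked example

```python
from sscentrality import SyntheticSpec, generate_cohort, CentralityValidation

cohort = generate_cohort(SyntheticSpec(n_pathways=40, seed=7))
results = CentralityValidation.from_cohort(cohort).fit()
print(results.summary())
```

prints (abridged):

```
Source/Sink centrality validation
==================================================
pathways analysed: 32 kept / 40 input
important genes:   328
FDR level:         0.05

Quantile regression (importance fraction ~ quantile)
--------------------------------------------------
centrality                 slope           p   adj r2
pagerank-source           0.2215   4.503e-04    0.115
pagerank-sink             0.0988   1.306e-01    0.014
pagerank-ssc              0.4359   1.598e-13    0.435
katz-source               0.2140   2.236e-03    0.087
katz-sink                 0.1053   1.083e-01    0.017
katz-ssc                  0.3374   2.728e-10    0.340
```

The cohort plants important genes at the first and last pathway layers.
The pure source and sink variants each see only one end, so their slopes
are small; SSC sees both, and its slope (percentage points of important
genes gained per quantile step) and adjusted r² are far larger. The
`results` object also carries the KS table, the per-pathway test table
with FDR flags, and a `sensitivity(alphas)` scan; `results.to_files(dir)`
writes everything as TSV.

The same workflow is available from the shell:

```sh
sscentrality simulate --out cohort/ --n-pathways 40 --seed 7
sscentrality compute  --input cohort/ --out profiles.tsv
sscentrality validate --input cohort/ --gene-sets cohort/important.gmt --out report/
sscentrality sensitivity --input cohort/ --gene-sets cohort/important.gmt --out scan.tsv
```

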