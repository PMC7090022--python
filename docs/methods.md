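# Methods

## The model

The predictor operates on a triple-layer heterogeneous network: three entity
layers (small molecules, miRNAs, diseases) joined by three binary bipartite
association matrices — `B` (small molecule × miRNA), `C` (miRNA × disease),
`SD` (small molecule × disease) — and three intra-layer similarity matrices
`Ss`, `Sm`, `Sd`.  Its working assumption is guilt-by-association: similar
small molecules tend to target similar miRNAs, and entities associated with a
common disease are more likely to share other partners.  All matrices are
indexed by lexicographically sorted entity ids, which makes every result
reproducible bit-for-bit from the same inputs.

### Similarity layers

*Small molecules* fuse four sources by entrywise weighted mean (default
weights all 1): side-effect Jaccard, a chemical-structure similarity matrix
computed externally and consumed as a file, disease-phenotype Jaccard over
the diseases each molecule is associated with, and target-gene Jaccard.
Target-gene Jaccard is our stand-in for gene-set functional similarity: the
latter requires a gene functional network that is out of scope here, and the
pipeline equally accepts a precomputed matrix in its place.  *miRNAs* fuse
disease-phenotype Jaccard (from `C`) and target-gene Jaccard.  Jaccard over
empty unions is defined as 0 (entities sharing no annotation are maximally
dissimilar); self-similarity is always 1, including for unannotated
entities, so every output is a valid similarity matrix (symmetric, in
[0, 1], unit diagonal).

*Diseases* are compared semantically on an ontology DAG.  Each annotated
disease induces a closure (itself plus all ancestors).  Method 1 gives each
closure node a contribution that decays by a factor `delta` per generation
(self = 1; a multi-parent ancestor takes the max over its children's
contributions, i.e. `delta^(shortest ancestor distance)`), and scores a pair
by the shared-node contribution mass over the two semantic values.  Method 2
replaces decay contributions with information content,
`-log(fraction of disease closures containing the node)` (natural log), so
universally shared roots contribute nothing.  The fused disease similarity
averages the two methods when *both* diseases carry DAG annotation and
otherwise falls back to the Gaussian interaction-profile (GIP) kernel over
the disease's miRNA association profile (the corresponding column of `C`).

Two printed-form ambiguities in this construction are resolved by explicit,
flagged defaults:

* **GIP bandwidth.**  The standardized bandwidth is
  `gamma = gamma_prime / mean(‖ID(d)‖²)` (division), so denser association
  profiles get a flatter kernel — the standard construction.  The
  multiplicative variant is available via `gip_bandwidth(..., mode="multiply")`.
  `gamma_prime` defaults to 1, the conventional choice.
* **Method-2 denominator.**  Method 2 normalizes by the summed method-2
  contributions (`DS2`), which makes self-similarity exactly 1; normalizing
  by the method-1 semantic values is available via
  `semantic_similarity_m2(..., denominator="ds1")`.  Under the `DS2` default
  the log base cancels; it is fixed to natural log for the exported
  per-term values.

`delta` defaults to 0.5, the conventional mid-range decay in this family of
DAG measures, and is configurable.

### Credible negative selection

Unobserved pairs are scored by the similarity-weighted support they receive
from the positive set: `ssm(j,k) = Σ_l B(l,k)·Ss(j,l)` (mass from small
molecules known to target miRNA k) plus `smr(j,k) = Σ_i B(j,i)·Sm(i,k)`
(mass from miRNAs known to be targeted by molecule j), and the distance
`d = exp(−(ssm+smr))`.  `d` is strictly decreasing in the support and lies
in (0, 1]; a pair with no support at all has distance exactly 1.  The
weights on `B` entries are binary — a normalized prior would only rescale
all distances monotonically while obscuring the scale of `d`.  The top
`round(proportion × n_positives)` candidates (round half away from zero,
minimum 1, capped at the candidate count) are selected, with a deterministic
tie-break: distance descending, then small-molecule id, then miRNA id.
`proportion = 1.0` (default) selects as many negatives as there are
positives.

### The walk

Both score matrices start from edge-uniform priors: each of the E known
edges carries mass 1/E.  Selected negatives may be stamped into the initial
SM state with a configurable non-positive weight; the default 0 records them
for evaluation only, the least-assumption choice since no magnitude for a
"known negative" prior is principled, and the effect of negative selection
is still fully expressed through the evaluation.  The update runs for
exactly `max(l1, r1, l2, r2)` iterations with no convergence loop — the step
counts are part of the model:

```
t <= l1:  SM_t = ( a*Ss@SM_{t-1} + (1-a)*B  +  SD@MD_{t-1}' ) / 2
t  > l1:  SM_t =   a*SM_{t-1}@Sm + (1-a)*B
t <= l2:  MD_t = ( a*Sm@MD_{t-1} + (1-a)*C  +  SM_{t-1}'@SD ) / 2
t  > l2:  MD_t =   a*MD_{t-1}@Sd + (1-a)*C
```

with `B`, `C` here denoting the 1/E-normalized priors (matching the scale of
the walk state; binary matrices would dominate the blend by a factor of E)
and `SD` the binary small-molecule–disease associations acting as the bridge
between layers.  The MD update always uses the *previous* iteration's SM.
`r1` and `r2` enter only the iteration count; a warning is logged when
`r1 > l1` or `r2 > l2`, where the extra iterations run the late-phase
updates.  Similarity matrices are used raw (no stochastic normalization),
exactly as the updates are written; scores are therefore not probabilities
and only their ranking is interpreted.  Defaults `alpha = 0.4`, `l1 = 4`,
`r1 = l2 = r2 = 1` are the operating point at which this walk family
performs best in repeated cross-validation tuning.

### Evaluation

Folds partition the known positives (leave-one-out, or seeded k-fold with
near-equal parts; k-fold at k = n reproduces LOOCV exactly).  Credible
negatives are selected **once from the full positive set** — they are
non-associations under every fold — and each fold then masks only its test
positives out of `B`, reruns the walk on the training network, and ranks the
held-out positives against all selected negatives.  AUC is the rank
statistic (ties count ½; implemented via scikit-learn and cross-checked in
the tests against a pairwise-concordance oracle).  Recall, precision and
accuracy need a binarization rule for continuous scores: by default the
top-P pairs are predicted positive with P the number of test positives — a
parameter-free rule standard in link prediction (a fixed numeric threshold
is configurable); the rule is recorded in every report.  Reported AUC is the
mean over folds; confusion counts are summed across folds.  The ablation
harness reruns the identical cross-validation with uniformly random
unobserved pairs (same count, seeded) in place of credible negatives and
reports both arm AUCs and their difference; repeats shift the fold seed.

## The synthetic benchmark

The generator plants cluster structure: each entity belongs to one of
`n_clusters` groups; associations appear with probability `p_in` inside
matched groups and `p_out` across them; annotation terms are drawn from
cluster-specific pools plus a small shared pool; the chemical similarity
matrix is high within clusters with Gaussian noise; the ontology is a forest
of per-cluster subtrees of depth `dag_depth` with annotated diseases
attached as leaves, and a fraction (default 10%) of diseases is left
unannotated to exercise the kernel fallback.  One seed drives everything.
Defaults — 100 small molecules × 80 miRNAs × 30 diseases, 4 clusters,
`p_in = 0.3`, `p_out = 0.01` — give roughly 660 positive associations, the
scale of the curated association sets this pipeline targets, while keeping a
full LOOCV run in seconds on one CPU.

Because clusters make guilt-by-association true by construction, high
cross-validated AUC here demonstrates that the pipeline correctly exploits
that signal end-to-end — not that real curated data carries as much signal.
Real association sets have heavy-tailed degree distributions, correlated
annotation sources, and block-free structure that the generator deliberately
does not model; absolute AUCs on real data will differ.

## Numerical and degenerate-input choices

* Similarity files are symmetrized as (M + M')/2 and clipped to [0, 1] with
  logged warnings, never rejected — external tools emit asymmetric scores.
* Duplicate edge-list lines collapse to a single edge (associations are
  binary presence).
* An all-zero interaction-profile table makes the GIP bandwidth undefined
  and is rejected; an association table with no edges cannot be normalized
  into a prior and is rejected.
* A non-finite walk state raises immediately with the iteration index.
* Universe alignment pads missing similarity rows with identity, missing
  association rows with zeros, and reports every added id.

## Known limitations

* Gene-set functional similarity is consumed, not computed; the target-set
  Jaccard stand-in ignores between-gene functional relationships.
* Chemical structure similarity always arrives as a matrix; no fingerprints
  or structure parsing.
* Scores are unnormalized propagation masses; only ranks are meaningful.
* The negative-prior encoding of credible negatives in the walk state
  defaults to inert (0); the evaluation, not the walk, is where negative
  selection earns its effect in the default configuration.
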