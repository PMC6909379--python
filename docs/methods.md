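# Methods

## Model

The data are a bipartite graph of verified disease–lncRNA associations,
stored as a binary adjacency `A` with diseases on rows and lncRNAs on
columns. The working hypothesis is the standard one in this literature:
phenotypically similar diseases tend to involve functionally similar
lncRNAs and vice versa. The model therefore (1) builds disease- and
lncRNA-side similarity matrices, (2) smooths `A` through them, and
(3) ranks candidate pairs by a two-pass resource-allocation diffusion
(probabilistic-spreading style) on the smoothed matrices.

### Semantic similarity (SS)

Each disease is located in the MeSH disease hierarchy by one or more
dot-delimited tree numbers; truncating the last segment of a coordinate
gives its parent. A disease's DAG is its own coordinates plus all their
ancestors. Contributions decay geometrically: the disease's own nodes get
1 and an ancestor gets `Δ` times the maximum contribution of its children
in the DAG, which for coordinate tries equals `Δ^h` with `h` the shortest
hop distance down to a self node. `SS` is the shared contribution mass
normalized by the two diseases' total semantic values. It lies in [0, 1],
is symmetric, and is 1 on the diagonal for annotated diseases.

Design choices that were genuinely open:

- **Node identity is the full coordinate string.** A disease with several
  tree numbers contributes several self nodes, each with contribution 1,
  and shared-node matching is by coordinate. The alternative (merging
  coordinates that map to one MeSH heading) would change SS for
  multi-coordinate diseases; coordinate identity keeps ancestor
  computation exact and needs no heading table.
- **Unannotated diseases have SS ≡ 0 against everyone, including
  themselves.** The ensemble then falls back to the interaction-profile
  kernel, so the unit-diagonal property of the final similarity survives.
- `Δ` accepts the degenerate value 0 (only self nodes keep credit), which
  is useful for testing limits; the default is 0.5, the conventional
  choice for this decay.

### Interaction-profile kernels (KD, KL)

`K_ij = exp(−γ‖IP_i−IP_j‖²)` with `γ = γ′ /` (mean squared profile norm),
`γ′ = 1`. Disease profiles are the **rows** of `A` and lncRNA profiles the
**columns**. (The source description of profiles as "columns" for diseases
is dimensionally impossible for an N_d × N_l adjacency; rows are the only
orientation under which disease–disease distances are defined.) A fully
zero profile matrix leaves the bandwidth undefined and raises an error;
this is why the synthetic generator guarantees non-empty rows and columns.

### Functional similarity (FS) and ensembles

`FS_ij` is the average best-match `SS` between the two lncRNAs'
associated disease sets, normalized by the total set size; it is 0 when
either set is empty (as happens for lncRNAs held out in column-wise
cross-validation). Note `FS_ii < 1` when some of an lncRNA's diseases lack
MeSH annotation — this follows directly from the defining formula, so the
unit diagonal of `FS` (and hence exactly 1 on the `LS` diagonal) is only
guaranteed at full MeSH coverage.

`DS` and `LS` average the semantic/functional channel with the kernel
entrywise where the former is nonzero, else take the kernel alone.

### Diffusion

`DA = DS·A`, `LA = A·LS`. For seed disease `u`, pass one sends each
lncRNA's seed resource (`LA_ui`, resp. `DA_ui`) to diseases in proportion
to that matrix's column; pass two returns each disease's received resource
to lncRNAs in proportion to its row. The channels are blended with α in
pass one and β in pass two (defaults 0.3 and 0.5). Exactly two passes are
performed — no iteration, no restart.

Numerical conventions:

- **Zero normalizers transmit nothing.** When a column or row of `DA`/`LA`
  sums to zero, its term contributes 0 instead of dividing by zero. A node
  with no weighted edges carries no resource; all scores stay finite and
  nonnegative.
- **Seeds come from `DA`/`LA`, not from the raw row `A_u`.** This is what
  lets a disease whose associations are entirely held out (or genuinely
  unknown) still seed the diffusion through semantic similarity.
- Per-seed totals are conserved: pass one delivers exactly
  `α·ΣLA_u + (1−α)·ΣDA_u` and pass two redistributes exactly the pass-one
  total (when no normalizer is zero). These identities are tested.
- Rankings break score ties by average rank (so AUROC is tie-correct) and
  candidate listings use stable label order within ties.

## Evaluation protocol

- **Global LOOCV**: each known pair is removed in turn; every similarity
  matrix is recomputed from the masked adjacency (this recomputation is a
  contract of the protocol, not an option); the fold's positive is the
  held-out pair's score and its negatives are the unknown pairs of the
  same disease row. Scores are pooled across folds into one ROC. Pooling
  (rather than per-disease averaging) was an open choice; per-disease
  AUROCs are also emitted for transparency.
- **Local CV** (rows = new diseases, cols = new lncRNAs): K random folds
  (default 5, seeded), held-out rows/columns zeroed, similarities
  recomputed, positives/negatives taken from the held-out block, pooled.
  Caveat: pooled local AUROC compares absolute scores across seed
  diseases, whose totals equal their own (very different) resource
  budgets. On the synthetic conditions this scale mixing pulls the pooled
  number toward or below 0.5 even when each held-out disease's own
  candidates are ranked well (within-row AUROC ≈ 0.75–0.85 when the
  semantic signal is informative); interpret pooled local CV accordingly.
- **Grid search**: LOOCV AUROC over α, β ∈ {0, 0.1, …, 1}. Fold
  similarities are α/β-independent, so each fold is reduced once to four
  vectors and every grid point is a bilinear combination of them — a pure
  engineering speedup, invisible in results. Ties in the grid argmax go to
  the lexicographically smallest (α, β).
- **AUROC** is computed from the rank-sum statistic (average ranks), which
  equals all-pairs comparison with half credit for ties; both classes must
  be present.
- **Enrichment**: all `N = N_d·N_l` pairs are ranked by score (stable
  order within ties); each bin of `x` consecutive pairs gets
  `(m/size)/(M/N)`. A final partial bin is scored with its true size, so
  the size-weighted mean over bins is exactly 1.

## Synthetic data

The generator plants a block structure: diseases and lncRNAs are assigned
round-robin to `n_blocks` communities; associations appear with
probability `p_within` inside a community and `p_between` across; each
block owns a disjoint synthetic MeSH tree (coordinates in the
`C01.234.567` dialect), so same-block diseases share ancestors and
cross-block semantic similarity is exactly 0. Draws are redrawn (bounded)
until every row and column has an association, because the kernel
bandwidth is undefined on all-zero profile sets. Defaults — 20×20, two
blocks, `p_within = 0.8`, `p_between = 0.02`, DAG depth ≤ 4, 90% MeSH
coverage — define the planted study condition used throughout the tests;
the structureless control uses `p_within = p_between = 0.2` at the same
size and seed policy.

What the generator does **not** emulate: the heavy-tailed degree
distributions of real curated databases (most real lncRNAs have exactly
one known disease), correlated annotation depth (cancer terms sit deep in
MeSH), multi-membership of diseases across branches, and naming noise
beyond case/whitespace. Passing tests on synthetic data therefore
demonstrate correctness of the computations and recoverability of planted
signal, not expected performance on real curated data.

A second generator builds a pair of synthetic "database" tables with
prescribed per-table entity/association counts and a prescribed overlap
(shared diseases, lncRNAs, and pairs), used to exercise the
merge-and-normalize ingestion path at realistic sizes. It is a synthetic
stand-in: only the counts and overlap structure are meaningful.

## Problem sizes and determinism

Cross-validation at the default synthetic size (20×20, ~160 folds, each
rebuilding the full similarity stack) runs in well under a second, and the
full 121-point grid search in about half a second; these sizes were chosen
because they already separate planted from structureless conditions
cleanly. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configurations produce
byte-identical artifacts.

## Known limitations

- The two mixing weights must be tuned per dataset (the grid search is
  provided for this); there is no principled default beyond prior
  practice.
- The semantic channel depends on the MeSH snapshot used to assign tree
  numbers; results on real data shift with thesaurus versions.
- Negative (verified non-)associations are not modelled; all unknown pairs
  are treated as candidates.
- Pooled local cross-validation mixes score scales across seed diseases
  (see above).
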