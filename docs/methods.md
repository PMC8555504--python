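# Methods

## Setting and model

The package reconstructs TF–miRNA–mRNA regulatory structure from
case/control transcriptomics. The underlying biological model is the
canonical cascade: a transcription factor (TF) activates or represses the
transcription of a miRNA, and the mature miRNA represses its target mRNAs.
In injury settings such as renal ischemia–reperfusion, this predicts a sign
pattern over differential-expression directions: for an activation edge the
TF and miRNA move together, and a miRNA's true targets move opposite to the
miRNA. The pipeline treats this sign pattern as a *filter* applied to
externally predicted regulation edges, not as something it learns: the
TF→miRNA catalogue (TransmiR-like, with an action type per edge) and the
miRNA→target table (miRDB-like, with a prediction score per edge) are
consumed as given.

## Differential expression

Each study is an already log2-transformed, normalised features × samples
matrix with a case/control design (≥ 2 samples per group enforced; the
real arrays this emulates had ≥ 8). Per feature the effect is
`log2FC = mean(case) − mean(control)` and the p-value comes from a Welch
two-sample t-test; q-values are Benjamini–Hochberg. The Welch test was
chosen over a moderated (limma-style) statistic deliberately: with the
generator's homoscedastic Gaussian noise, variance moderation adds nothing,
and keeping the test elementary makes the closed-form oracle in the test
suite exact. That is a known divergence from array-analysis practice and is
the main reason absolute DEG counts from real array screens are not a
reproduction target for this stage.

Calling thresholds are |log2FC| ≥ 1 (boundary passes) and FDR < 0.05
(boundary fails). Zero-variance features cannot be tested and are flagged:
p = 1 when the group means agree, p = 0 when they differ.

## Rank aggregation

Consensus DEGs over m studies use the beta order-statistic score: with each
study contributing a ranked list over a shared universe of N features,
position k maps to a normalised rank r = k/N and absent features get
r = 1. For the sorted vector r₍₁₎ ≤ … ≤ r₍ₘ₎,
`b_k = P(Beta(k, m−k+1) ≤ r₍ₖ₎)` and `ρ = min_k b_k`; significance is the
Bonferroni-corrected `min(1, m·ρ)`, thresholded at 0.05. Because b_k is
marginally uniform under the null, the Bonferroni bound makes the corrected
call rate conservative for uniformly random full lists — the calibration
suite verifies this empirically.

Per-direction lists are built by ordering each study's features with the
requested log2FC sign by ascending p-value (`full` mode, the default), or
only the features passing the thresholds (`thresholded` mode). A
consequence worth knowing: in `full` mode a null feature's normalised rank
lives on (0, ~0.5] rather than (0, 1], because the direction split halves
the list while N stays the whole universe. Consistent mid-ranking features
can therefore reach corrected scores below 0.05, and the consensus DEG list
is liberal relative to the planted truth. This does not propagate into the
network stage (spurious DEGs lack prediction-table support) but it is the
reason recovery metrics are defined on triads and loops, not on the DEG
list itself. `thresholded` mode is the specific alternative.

## MCODE modules and hub genes

The module detector is the classical core-clustering procedure: each
vertex is weighted by k × density of the highest k-core of its closed
neighbourhood; seeds are processed by decreasing weight (ties broken
lexicographically for determinism) with seeding restricted to vertices of
degree ≥ 3; expansion admits unused neighbours whose weight is within 20%
of the seed's (vwp = 0.2), breadth-first, each vertex belonging to at most
one module; the haircut iteratively removes members of within-module degree
< 2; and a module survives only if it contains a non-empty 4-core. The
"degree ≥ 3 / 4-core" pair is the most literal reading of the screening
convention this pipeline follows; the classical defaults (2, 2) are plain
parameters. Fluff post-processing is omitted (it is off by default in the
original tool). If the haircut severs a cut vertex the seed's connected
component is kept, preserving the invariant that modules are connected.
Hub genes are the union of module members ordered by module score then
vertex weight.

In the pipeline the PPI graph is first restricted to consensus DEGs,
mirroring the practice of building the PPI network from the DEG list.

## Network assembly and loops

Overlap first: TFs of called DEMs that are themselves called DEGs
(carrying the DEG direction), and predicted targets of called DEMs with
score ≥ 50 that are called DEGs. The 50 floor is the conventional
prediction-score cutoff; the published loop evidence scores (51–88) all
clear it. Sign filtering then drops activation edges with discordant
directions, repression edges with concordant directions, all edges of
unknown action, and miRNA→target edges whose target moves with the miRNA.
Assembly enumerates complete TF→miRNA→target paths and prunes every node on
no path. The sign rule is implemented symmetrically rather than assuming
"all network miRNAs are up-regulated"; the all-up outcome observed in the
motivating screen becomes a checkable consequence of mostly-activating
catalogues, not an assumption.

Feedback loops are searched over the sign-consistent activating TF→miRNA
edges against the *full* target table — no score floor and no direction
filter on the reciprocal miRNA→TF listing — because loops are reported
outside the assembled network and may involve miRNAs pruned from it. A
repression TF→miRNA edge never forms a loop.

## Diagnostics

TF–target Pearson correlations are computed across pooled samples (cases
plus controls); |r| > 0.3 with p < 0.05 (both strict) flags a pair. Pooling
is the default because the screen this emulates correlates across all
samples of the training dataset; a per-group screen would measure a
different (within-condition) quantity. ROC AUC per gene is the tie-adjusted
Mann–Whitney U over case/control labels; genes down-regulated in cases are
reported at inverted orientation (AUC := max(a, 1−a)) with the orientation
recorded, so direction does not mask marker strength; AUC > 0.9 (strict)
flags a good marker, with no confidence intervals (DeLong is out of scope).
The 2^−ΔΔCt utility implements the standard reference-gene-normalised qPCR
fold change.

## Synthetic data: what it emulates and what it does not

The generator plants signed log2 effects (|δ| ≥ 1, default 2) on a common
DEG/DEM set across studies, adds i.i.d. Gaussian noise (sd 0.5) around
per-study Uniform(4, 12) baselines, and writes prediction tables containing
the planted consistent edges, decoys of all three inconsistency classes
(activating TF over a discordant miRNA; repression with concordant signs; a
"target" moving with its miRNA), and random filler edges anchored on
non-differential miRNAs so filler cannot complete a triad. The PPI graph is
an Erdős–Rényi G(·, 0.05) background over the DE genes plus sampled
non-DE genes, with planted cliques (sizes 8, 6, 5) on DE genes.

Default study conditions: 3 mRNA studies and 1 miRNA study, 10
samples/group, 2000 genes (30 of them TF symbols), 150 miRNAs, 40 true
DEGs, 20 true DEMs, 5 triads, 3 loops, 2 decoys per class. These sizes keep
every simulation suite in the seconds-to-minutes range while leaving the
planted structure a small minority of each table, as in real catalogues.

Deliberately not modelled: probe-level artifacts, batch effects,
inter-study platform differences, correlated noise between features,
mean–variance trends, and sequencing counts (no negative-binomial mode —
RNA-seq validation is outside this package's scope). Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
stated noise model, not robustness to real array pathologies; with real
data the DE stage, not the network logic, is where those pathologies would
bite.

## Numerical and design notes

- Symbols are joined case-insensitively; miRNA names drop species prefixes
  ("mmu-miR-155" ≡ "mir-155") because upstream sources mix spellings.
  Duplicate matrix rows collapse to the highest-mean row (a convention —
  probe collapsing in the emulated preprocessing is unspecified).
- ρ is computed with the regularised incomplete beta function
  (`scipy.stats.beta.cdf`), identical to the binomial tail sum but stable
  for large m.
- Determinism: all generator draws flow from one `numpy` Generator seeded
  by the user; MCODE tie-breaks and all set orderings are lexicographic;
  same seed ⇒ byte-identical fixture files.
- Degenerate inputs are typed errors, not warnings: empty universes,
  unsorted rank vectors, scores outside [0, 100], single-class ROC labels,
  missing reference genes.
- SIF output carries node layer/direction in a `.nodes.tsv` sidecar since
  the SIF grammar has no attributes; GraphML round-trips the network
  losslessly (verified by attribute-isomorphism tests). PPI edge-list
  round-trips preserve edges; isolated vertices are not representable in a
  2-column edge list.

## Known limitations

- Consensus DEG calling in `full` mode is liberal (see above); treat the
  DEG list as a ranking, or use `thresholded` mode, when the list itself is
  the product.
- Nearby planted PPI cliques can merge into one module when background
  edges bridge them and their weights are within the vwp band; the hub-gene
  union is unaffected, which is why recovery is asserted on the union.
- Correlation p-values are not multiplicity-corrected, matching the
  emulated screen's usage.
- The curated loop-evidence fixture is a transcription of published
  records, included to exercise the loop detector on real symbols; it is
  not a substitute for running the full screen on real array data, which
  requires preprocessing outside this package's scope.
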