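# Methods

## Model and assumptions

The package operationalises one idea: genes whose products interact —
consecutive enzymes of a biosynthetic pathway, a transporter and its
substrate's synthase — experience correlated selective pressure, so their
gene trees should agree beyond what speciation alone imposes. Coevolution
is therefore measured as topological agreement between per-gene homolog
trees, not as sequence-level covariation. Two assumptions follow:

- the homolog family of each input protein is sampled from a common set of
  species deep enough (≥ 4 shared species per compared subtree pair) for
  tree agreement to be meaningful;
- gene duplications are frequent enough that a duplication-naive tree
  distance would be dominated by paralogy rather than history.

## Duplication handling

Internal nodes are classified by the species-overlap criterion: a node is
a duplication iff at least two of its child clades share a species. This
needs no species tree and errs toward calling duplications when taxon
sampling is dense. Before comparison, each tree is expanded into its
duplication-free resolutions: at every duplication node one child lineage
is kept per resolution, with the rest of the tree untouched. A tree with
`m` independent duplications yields up to `2^m` resolutions (capped at 64
with a warning; the cap only bites in heavily duplicated families where
the distance is ill-determined anyway). An alternative decomposition —
cutting the tree into disjoint pieces at duplication nodes — was rejected:
one duplication deep in a tree severs every ancestor on the path to the
root, shattering a 16-species tree into ~10 uninformative fragments and
turning whole matrix rows into NA.

## Distances

For a resolution pair (p, q) with shared species S, |S| ≥ 4, both
restrictions to S are compared unrooted by the Robinson–Foulds (RF)
distance computed on species-labelled splits, normalised by the maximum —
the number of non-trivial splits in p plus those in q, i.e. `2(|S|−3)` for
two binary trees and the generalised bipartition count when polytomies are
present (two star trees are identical, RF_norm = 0). The strict distance
is the unweighted mean over evaluable resolution pairs; if no pair is
evaluable the entry is NA, never silently 0. The evolutionary distance
uses the same traversal with pair score
`1 − (1 − RF_norm) · |S| / max(|S_p|, |S_q|)`, so perfect agreement on a
small shared core of a much larger family still scores poorly. Both
distances live in [0, 1] and equal each other when species sets coincide.
The combined distance is the element-wise sum (a `mean` option exists);
since the ICQ thresholds the combined matrix relative to its own maximum,
any positive scaling of the combination is immaterial, and the choice is
recorded in output metadata.

## ICQ

`ICQ = 1 − g / (2·d·(d−1))` for `d` genes, `g` = (# off-diagonal strict
entries < 0.7) + (# off-diagonal combined entries ≤ 0.6 × max(combined)).
`g` counts ordered entries — a qualifying unordered pair contributes 2 per
matrix — so the denominator `2·d·(d−1)` is attained exactly at saturation
and ICQ spans [0, 1]; an unordered convention is selectable and recorded
in the result. The strict comparison is "<", the combined one "≤",
deliberately asymmetric: an all-zero combined matrix (identical trees)
qualifies everywhere. NA entries never qualify. The noise threshold 0.708
ships as advisory metadata calibrated on fungal control sets; results
report the verdict (`above_noise`) but never halt on it. The threshold
estimator for new databases fits a Gaussian KDE (Silverman bandwidth) to
each of two ICQ samples and returns the sign change of the density
difference between the two modes, refined by Brent root bracketing;
identical samples yield NA with a diagnostic rather than an arbitrary
crossing.

## Automated cluster definition

Each matrix's rows (one distance profile per gene) are centred —
unscaled, the columns share units — and projected onto the first three
principal components via SVD; component signs are fixed by making each
component's largest-magnitude loading positive, so runs are
bit-reproducible. Three components were kept on the view that further
components reintroduce noise; with fewer than three informative directions
the missing score columns are zero.

The optimal k is chosen by majority over 21 cluster-validity indices
scoring Ward/Euclidean candidate partitions for k in [2, 5]: CH,
silhouette, Davies–Bouldin, Dunn, C-index, Gamma, G+, Tau, point-biserial,
McClain–Rao, Ratkowsky–Lance, Ball–Hall, Hartigan (original H ≤ 10 rule),
Krzanowski–Lai, trace(W), trace(cov W), Scott–Symons, Marriot,
Friedman–Rubin trace, Friedman–Rubin determinant, and SD. Seven more
battery members (CCC, Gap, Duda, pseudo-t², Frey, SDbw, Beale) are not
implemented and are logged as excluded, so the electorate is always
explicit. Each index votes by its published optimum direction
(max/min/largest jump/elbow); difference- and elbow-based rules compare
levels only inside the candidate range, matching the NbClust reference
behaviour, so they vote on its interior. An index whose value is
undefined for the data (zero variance, singular within-group scatter,
empty between set) abstains; with zero total scatter all indices abstain.
Ties in the majority break toward the smaller k (parsimony). An empty
vote set — or any unrecoverable numerical failure during voting — triggers
the backup: k-means with a preset k = 3 (capped at d−1), the three groups
being the biosynthetic / further-essential / gap roles one expects in a
BGC. k-means itself uses k-means++ with 25 restarts and a fixed seed;
`k_max` is capped at d−1 with a warning, and `k_min = 2` because an
optimal-k search below 2 is meaningless for these indices.

The strict- and combined-matrix clusterings are computed and reported
separately (which one the benchmark used is not decidable, and the two
matrices carry different signal); for detection the default aggregation is
the union of the two core-sharing clusters, configurable to intersection
or either single matrix, and flagged in the output.

## Evaluation

Detection is the union of clusters containing a core gene, minus the cores.
Two scoring modes: *essential* (positives = biosynthetic ∪
further-essential) and *biosynthetic* (positives = biosynthetic only;
further-essential genes leave the table entirely). Negatives are gap ∪
extra in both, so the specificity side is mode-invariant. Core genes are
never counted. Zero-denominator ratios are NA. The no-information rate is
implemented as the majority-class share `max(P, N) / (P + N)` — the
convention consistent with the published report this battery mirrors — and
the textbook minority share is also emitted under its own name
(`minority_class_share`).

## Synthetic data: what it emulates, what it does not

The generator emulates the *control sets* used to calibrate the method: a
co-evolved family is a Yule species tree (uniform tip speciation,
exponential branch lengths) copied per gene with exactly `nni_moves`
nearest-neighbour interchanges, log-normal branch jitter (σ = 0.25), and
subtree duplications grafted as their own siblings at rate 0.1 per
internal node; independent genes get uniform random rooted binary
topologies (stepwise uniform edge insertion). Defaults — 16 species, 6
co-evolved + 3 independent genes, 1 NNI move — describe a strong-signal
regime in which recovery should be near-certain, and the test suite
measures exactly that. What the generator does *not* emulate: tree
estimation error from finite alignments, database-dependent taxon
sampling, horizontal transfer, and rate heterogeneity among lineages.
Passing tests therefore show the statistical machinery is correct and the
pipeline recovers planted structure; they do not certify performance on
real proteome databases, which depends on upstream tree quality.

NNI was preferred over SPR as the perturbation because a single parameter
controls RF distance monotonically; branch jitter is log-normal to keep
lengths positive without truncation.

## Numerical choices and degenerate inputs

- Missing Newick branch lengths default to 1.0 with a warning; all
  distances here are topological, so only plots are affected.
- NA distance entries are excluded from g-counting; before PCA they are
  imputed with the column mean of the finite entries, logged — this keeps
  the embedding defined without inventing coevolution signal.
- Matrices are validated symmetric with zero diagonal; NA is serialized as
  "NA" in TSV.
- Degenerate all-equal matrices produce zero-variance embeddings, a full
  abstention, and hence the k = 3 backup; with fewer than 4 genes the
  automated stage refuses and only manual-style outputs make sense.
- All randomness (simulation, k-means restarts) flows from one run seed
  recorded in the manifest; two runs with identical inputs and seed are
  byte-identical.

## Problem sizes used in the shipped analyses

The acceptance script and test suite run the benchmark at 20 seeded
replicates (9-gene clusters, 16 species), the ICQ separation at 40 paired
draws, the optimal-k recovery at 20 three-blob fixtures (30 points each),
and the KDE crossing at 500 draws per sample — sizes chosen so the
sampling error of the reported means is small relative to the effects
measured.

## Known limitations

- The strict/evolutionary distances follow the published description of
  the treeKO approach; the original tool is not redistributed here, and
  its exact pair weighting for heavily duplicated families may differ from
  the unweighted mean over resolutions used here.
- The validity-index electorate is a 21-member subset of the published
  28-index battery; the majority can differ from the full battery's on
  ambiguous data (on clean structure both agree).
- The homology stage orchestrates external binaries (DIAMOND/BLAST, MAFFT,
  FastTree) and is exercised in tests only through mocked adapters; remote
  NCBI search is exposed as a stub and not implemented.
- ICQ noise threshold 0.708 is specific to the fungal control calibration;
  new databases need re-estimation via the KDE-crossing tool.
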