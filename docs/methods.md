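# Methods

## Model and assumptions

The pipeline treats a protein complex as a connected, typically dense
subgraph of a static undirected PPI network whose members (a) share
biological function and (b) are active over the same stretch of time. Both
constraints are applied *before* any graph mining: time-resolved expression
data select active proteins per time point, GO biological-process
annotations group proteins into functional clusters, and only the
intersection of the two groupings is mapped onto the network. The network
itself is unweighted; extra columns in edge-list inputs are parsed and
discarded. Protein identifiers are opaque case-sensitive strings, and joins
between files are exact string matches — any probe-to-protein or alias
mapping must happen upstream.

## Stage-by-stage choices

**Activity (three-sigma model).** The threshold
μ + β·σ·(1 − 1/(1+σ²)) uses the *population* standard deviation (divide by
n) by default; the convention is stated explicitly because it changes
thresholds, and a `sd_mode="sample"` switch is provided. The activity
comparison is inclusive (≥), so a constant profile (σ = 0) is active at
every time point. β accepts any non-negative real; 0–3 is the recommended
grid (at β = 0 the threshold is the row mean, and every non-constant profile
is active at least at its maximum). Proteins present in the network but
missing from the expression matrix are never active: they cannot be
assessed, and the conservative reading keeps active sets inside the measured
proteins. Repeated measurement cycles are averaged per within-cycle time
point *before* thresholding.

**Wang similarity.** Per-term contribution maps are computed by label-
propagation from the target term upward, re-relaxing a parent whenever a
better path-product arrives; this equals the max-over-paths definition (the
test suite checks it against an exhaustive path enumerator on random DAGs).
Default edge weights are 0.8 (is-a) and 0.6 (part-of); other relationship
types are dropped at OBO load. The term-pair similarity uses the
best-match numerator Σ(S_A(t) + S_B(t)) over shared ancestors, which
normalises self-similarity to exactly 1 — the property the downstream
clustering relies on for its unit affinity diagonal. An alternative
numerator Σ SV(t) is available as `s_go_numerator="literal"` for audit; it
is *not* self-normalising. Proteins without biological-process annotation
are excluded from clustering entirely (best-match averaging is undefined on
empty sets); expansion over the full network is the one mechanism that can
still recruit them into a complex.

**Spectral clustering.** Normalised spectral clustering in the
Ng–Jordan–Weiss form: the similarity matrix is used directly as the affinity
(it is already bounded in [0,1], so no kernel is applied), the top-K
eigenvectors of D^(−1/2)·A·D^(−1/2) are row-normalised, and scikit-learn's
KMeans (10 restarts, fixed seed, best inertia) assigns labels. Eigenvector
signs are canonicalised (non-negative column sum) so that permuting the
input rows permutes the result instead of perturbing it. When the affinity
graph has at least K connected components, whole components are packed
greedily into K groups instead of eigendecomposing a degenerate null space;
components are never split in that regime. Empty clusters are permitted
(non-empty count ≤ K). K has no automatic selection; sweeping K (and β)
against a reference set is what the `sweep` command is for. Presets from
tuning on the published yeast benchmarks: Collins K=30 β=0, Krogan K=35 β=0,
WI-PHI K=17 β=1.

**Extraction, expansion, merging.** Connected components of size ≥ 2 of
each APC-induced subgraph become candidates; identical member sets arising
from different (time point, cluster) cells are collapsed with concatenated
provenance before expansion. Expansion re-evaluates the admission threshold
α·|V_c| against the *current* complex each pass, admits all qualifying
neighbours of a pass simultaneously (removing intra-pass order dependence),
and iterates to a fixpoint; it is monotone and terminates within |V| passes.
Merging collapses exact duplicates, then repeatedly replaces the
highest-overlap pair (OS ≥ γ) by its union, breaking ties towards the
smaller union and then the lexicographically smallest member tuple — a
canonical order chosen because the merge result genuinely depends on order
and reproducibility requires fixing one. Size-2 candidates are kept through
expansion and merging (they may grow) and filtered only at output
(`min_size`, default 3).

**Numerical comparisons.** The admission test |E(p,G_c)| ≥ α·|V_c| and the
merge test OS ≥ γ compare an exact rational against a float product; both
use a 1e−9 slack so that exact equalities such as 3 ≥ 0.6·5 are not broken
by binary rounding. Degenerate inputs: an empty prediction set is a valid
outcome (precision 0, logged); an empty reference set or empty network is an
error; K > number of annotated proteins is clamped with a log message inside
`predict` (and an error when calling the clustering directly).

**Evaluation.** Matching is one-to-many in both directions. Duplicate
predicted complexes count once (the precision denominator must not be
inflatable); reference sets are used as distributed, including any size-2
reference complexes — only *predictions* are size-filtered. Size histograms
are reported per exact size plus the 3 / 4 / 5+ binning.

## Synthetic generator

`SyntheticSpec` defaults define the study conditions used by the recovery
tests: 10 planted complexes of 4–8 proteins, within-complex edge probability
0.9, 100 background proteins with background edge probability 0.01 (planted
members participate in background edges too, creating false-positive
attachments that exercise the expansion threshold), 12 time points with a
contiguous 4-point active window per complex, baseline 5.0, pulse height 1.0
over noise SD 0.2 (signal-to-noise 5), annotation coherence 1.0, and a
3-level branching-3 is-a/part-of tree with one distinct signature leaf per
complex. Windows may overlap between complexes, so the
active-set × cluster intersections are nontrivial. Background proteins are
unannotated; incoherent members are annotated to a sibling leaf. Everything
derives from one `numpy` generator seeded by `spec.seed`.

What the generator does *not* emulate: scale-free degree structure of real
PPI networks, multi-term annotation profiles, annotation noise to distant
terms, periodic (metabolic-cycle) expression beyond a single pulse window,
and measurement dropouts. Passing recovery tests therefore demonstrate the
pipeline's internal correctness under its own assumptions, not performance
on real interactome data.

Problem sizes in the test suite (≈165 proteins, 12 time points, 5 seeds for
recovery; 200 random DAGs of ≤ 12 terms for the similarity oracle; 50 random
graphs for structural invariants) were chosen as the smallest instances that
still exercise every code path and the stated study conditions; the whole
suite runs in a few seconds.

## Known limitations

- Spectral partitions are deterministic per seed but not claimed to
  reproduce any other implementation's partitions; the clustering variant and
  initialisation are this package's explicit choices.
- Permutation consistency of clustering holds for well-separated similarity
  structure; with near-degenerate eigenvalues k-means may settle differently
  for permuted inputs.
- No weighting, signing or dynamic rewiring of the network; no
  core-attachment modelling; no information-content similarity variants; no
  automatic K selection.
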