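# Methods

This note records how the package's analyses are defined, the defaults
that matter, and the choices made where the underlying methodology is
genuinely open. It describes what the code computes; every number quoted
in the README's worked example is printed by the code itself.

## Curation

The standardization pass applies, in order: toolkit cleanup; reduction to
the largest covalent component (most heavy atoms, ties broken by higher
molecular weight, then lexicographically smallest canonical SMILES —
ties must be broken deterministically or curation would not be
reproducible); an element whitelist (H, B, C, N, O, F, Si, P, S, Cl, Se,
Br, I) checked *after* fragment reduction so an exotic counterion never
rejects its organic parent; neutralization and reionization; canonical
tautomer; canonical SMILES; duplicate removal on exact canonical-SMILES
equality keeping the first occurrence. Stereochemistry is stripped by
default and preserved on request (`keep_stereo=True`), the intended use
being de novo–designed molecules whose stereocenters are part of the
design; in that mode the tautomer canonicalizer is configured not to
discard sp3/double-bond stereo along tautomeric paths.

Two caveats worth knowing. Canonical SMILES equality is dialect-specific:
equality across toolkits (or toolkit versions) is not guaranteed, so
duplicate collapse is defined relative to this package's writer. And
tautomer canonicalization can change a molecule's Bemis–Murcko scaffold
(e.g. 2-hydroxyazines become their oxo tautomers), which measurably
affects chemotype counts — the curation report records the tautomer-rule
provenance for this reason.

The pass is idempotent: re-curating a curated library reports zero
removals. The count identity `n_output = n_input − n_parse_failed −
n_element_rejected − n_duplicates_removed` holds on every input and is
property-tested.

## Descriptors and scores

The descriptor vector holds MW (g/mol), HBD, HBA, TPSA (Å²), Crippen
logP, rotatable bonds, ESOL, SAscore, QED, and an optional externally
computed logD (pH 7.4) — logD is an input column, never computed here.
ESOL uses Delaney's published regression, log S = 0.16 − 0.63 clogP −
0.0062 MW + 0.066 RB − 0.74 AP with AP the aromatic fraction of heavy
atoms; it approximates the solubility descriptor of commercial engines.
QED is the published weighted-desirability parameterization (threshold
0.67 for "attractive"); SAscore is the published fragment-contribution +
complexity-penalty score on [1, 10], with > 6 conventionally deemed
synthetically infeasible. Both are computed with the toolkit's reference
implementations.

The de novo score is range-based: each of seven descriptors (MW, HBD,
HBA, logP, ESOL, SAscore, TPSA) contributes 1 if inside its closed
target interval, else 0; the score is the arithmetic mean, multiplied by
`(1 − penalty_value)` if any penalty SMARTS matches. Membership is a
hard 0/1 gate rather than a ramp — the desirability shape used by
commercial scoring engines is not public, and a hard gate is the only
parameter-free choice. The penalty defaults to a hard veto
(`penalty_value = 1`), targeting nucleoside-like substructures
(ribofuranose attached to an aromatic nitrogen) because the motivating
use case seeks non-nucleoside chemistry. The shipped interval file is a
worked default; `build_score_rules(actives, n_sd=1)` derives intervals
as mean ± 1 SD over any reference active set, which is how such ranges
are constructed in practice.

Ligand efficiency is docking score divided by heavy-atom count; the
package only post-processes docking tables (id, program, score,
heavy_atoms) and never runs docking.

## Fragmentation and selection

RECAP cleavage is implemented at bond level: eleven motifs (amide, ester,
amine, ether, olefin, quaternary N, aromatic N–aliphatic C, lactam
N–aliphatic C, aromatic C–aromatic C, sulfonamide; urea is covered by the
amide pattern) expressed as two-atom SMARTS over acyclic bonds, all
matched bonds cut simultaneously. This "cut-all-bonds" formulation was
chosen over reaction-based decomposition because it guarantees two
properties the pipeline relies on: the fragments partition the parent's
heavy atoms (k cuts → exactly k + 1 fragments), and every fragment
occurrence is retained, including repeated ones. Attachment points are
kept as dummy atoms and re-reported as `growing_sites` (their indices in
the fragment's canonical atom order); fragment MW is computed with the
attachment points hydrogen-capped. A molecule with no cleavable bond
yields no fragments — it is not its own fragment. Both C–O bonds of a
dialkyl ether match the ether motif, so the ether oxygen can end up as a
two-site fragment; this is a consequence of bond-level cutting and is
deliberate. Water, ammonia and HCl are never used as building blocks.

MaxMin selection is the classic greedy: the first pick is `seed mod pool
size` (the common implementation choice; similarity-based initialization
is another, but a seed-indexed start makes the trace a pure function of
(pool order, seed)); each subsequent pick maximizes its minimum Tanimoto
distance to the picks so far, ties to the lowest pool index. Requesting
more than the pool returns the whole pool with a warning on the trace
rather than an error, matching how the pipeline degrades when a filter
leaves fewer fragments than the target (the classic greedy 2-approximation
of the optimal min-distance subset is verified exhaustively on small
pools in the tests).

Pipelines: training sets keep MW > 300 (strict) then MaxMin to 285 with
MACCS keys; fragment libraries keep MW < 300 (strict, rule of three),
MaxMin to 400, keep logD ≤ 3 (closed), MaxMin to 177. The strict/closed
bounds are pinned by tests exactly as stated.

## Diversity statistics

Fingerprints: MACCS keys reported as exactly the 166 defined bits (the
toolkit's unused bit 0 is dropped), and radius-2 circular fingerprints
folded to 1024 (chemical-space work) or 2048 bits (modeling). Tanimoto
on two all-zero vectors is defined as 1 — two featureless molecules are
indistinguishable, and this keeps the similarity matrix total.

Pairwise statistics stream one row at a time (the M×M matrix is never
materialized); the median is over the M(M−1)/2 off-diagonal values, and
the CDF is compressed to distinct similarity values.

Chemotypes are Bemis–Murcko scaffolds; ring-free molecules pool into a
single ACYCLIC chemotype that by default participates in N, the CSR
curve and the entropy (an acyclic-rich library *is* scaffold-poor), with
`include_acyclic=False` available since published tables differ on this
convention; the acyclic fraction is always reported separately. The CSR
curve ranks chemotypes by descending count (ties lexicographic), plots
(i/N, cumᵢ/M) with the origin prepended, and linear interpolation /
trapezoid AUC — the originating methodology leaves the interpolation
unstated. F50 is the smallest i/N with cumᵢ/M ≥ 0.5. SSE_n renormalizes
the top-n counts among themselves and scales by log n (log N when
N < n); an even spread returns exactly 1.0 (the equal-counts case is
returned analytically rather than through floating-point entropy). Note
two degeneracies of the convention: N = 1 gives the same diagonal CSR
curve (AUC 0.5) as all-unique, and merging two chemotypes does not
always increase AUC (e.g. counts [5,1,1] → [6,1] lowers it slightly), so
AUC should be read alongside N/M and SSE rather than alone.

Property-space diversity is the median pairwise Euclidean distance over
six z-scored properties (MW, HBD, HBA, TPSA, nRotB, logP); when several
datasets are compared (CDPlots), the scaling is fitted on their union so
colors are comparable. Min-max scaling is available. Near-constant
columns are given unit scale so they contribute zero instead of
amplifying floating-point noise. Median (not mean) is used as the
summary statistic for robustness; published tables do not state their
choice.

A CDPlot point per dataset carries x = median MACCS/Tanimoto similarity,
y = scaffold AUC, color = property distance, size = M. Embeddings use
PCA (deterministic, full SVD, explained variance reported) or t-SNE
(seeded; perplexity defaults to min(30, (n−1)/3)) over z-scored
properties, MACCS or ECFP4 bits.

## Activity models

Labeling: IC50 values are converted to µM (nM/µM/mM accepted; unknown
units are an error listing the rows). A record is ACTIVE when its
relation bounds the value at or below 10 µM (=, <, ≤), INACTIVE when it
pins the value above (= above threshold, or >/≥ at or above threshold),
and AMBIGUOUS otherwise (e.g. "< 100 µM", "> 1 µM", or an unrecognized
relation symbol). Ambiguous records are removed; structures reported
with conflicting pinned labels are removed entirely as contradictory;
concordant duplicate structures collapse to one record keeping the
median value. Duplicate detection operates on canonical structures, so
tables should be curated first.

The model grid crosses five algorithms (k-NN with Jaccard metric, random
forest, gradient boosted trees, RBF-kernel SVM, a single-hidden-layer
feed-forward network) with three fingerprints (MACCS 166, Morgan
radius-2 2048, RDK 2048). Selection uses leave-one-out cross-validation:
all n held-out predictions form one confusion matrix and BA =
(TPR + TNR)/2 picks the winner; ties go to the setting declared earlier
in the grid. The shipped grids are deliberately tiny (neighbors 1/3/5;
100 trees; 50 boosting stages; C 1/10; one 32-unit hidden layer) —
defaults chosen once for adequate accuracy at LOO cost on a single CPU:
the boosted trees use depth-2 stumps with per-split feature subsampling
(√p of 2048 bits), and the network stops at tol 1e-3, both of which cut
LOO cost by one to two orders of magnitude with no measurable BA change
on the synthetic recovery datasets. All stochastic learners are seeded.

Distance to model (DM) is the mean Jaccard distance of a query's Morgan
fingerprint to all training compounds. Evaluation records are stably
sorted by DM and split into four equal-sized quartiles (ties keep input
order, so 180 records always yield 45 per quartile); per-quartile
precision and recall for the active class quantify how performance
degrades with distance. A quartile with no predicted actives reports NaN
precision, never a divide-by-zero. Deployment bins come from the
LOO-evaluation distances of the full training set — the training-set DM
analysis is the calibrated one, a small external test set's quartiles
being too few-sample to trust — and any query farther than the largest
evaluation distance is flagged BEYOND (unknown confidence) rather than
forced into Q4.

## Synthetic data

The generators exist so every stage can be tested against exact ground
truth. Libraries are built by decorating ring scaffolds (a fixed pool of
16 common ring systems) with acyclic single-bonded substituents at ring
carbons; such decorations provably preserve the Bemis–Murcko chemotype,
and the generator asserts this for every emitted molecule instead of
trusting the table. Planted chemotype frequencies are therefore
recovered *exactly* by the scaffold profile (note the curation caveat
above: re-curating generated molecules can shift tautomers).

Activity tables draw actives from azine/indole-type scaffolds and
inactives from a disjoint aliphatic/thiophene pool; the separability
knob s mixes the pools (s = 1 disjoint, s = 0 both classes from the
union, making labels independent of structure). Class draw order is a
seeded permutation — decoration streams yield progressively more
substituted molecules, so drawing one class first would leak complexity
into the label even at s = 0. IC50s are lognormal (medians 1 µM and
100 µM, σ = 0.8 log-units, resampled onto the correct side of the 10 µM
threshold so planted labels are exact); units mix nM and µM to exercise
conversion. An exact round(fraction·n) of rows get non-pinning
qualifiers; contradictory pairs are fresh structures appearing twice on
opposite sides of the threshold, so each pair removes exactly two rows.
Docking tables draw scores from Normal(−7, 1.5) kcal/mol.

What the generators do *not* emulate: realistic medicinal-chemistry
property distributions, activity cliffs, assay noise in between the two
lognormal modes, scaffold hopping within a class, or class imbalance
beyond the requested counts. Passing tests therefore demonstrate that
the statistics and the workflow are computed correctly, not that any
particular model will perform comparably on real screening data.

## Problem sizes and determinism

Test and demonstration runs use desk-scale inputs chosen to exercise the
contracts: libraries of 10–100 molecules for diversity oracles (the
streaming similarity path is checked against a dense recomputation at
M = 100), pools of 8 for exhaustive MaxMin checks, and n = 200 activity
records (160 after the stratified split) for model recovery — large
enough that LOO balanced accuracy separates signal (≈1.0 at s = 1) from
chance (≈0.5 at s = 0), small enough for single-CPU leave-one-out. Every
stochastic step (generators, splits, learners, t-SNE, MaxMin first pick)
takes an explicit seed, and all outputs are pure functions of their
inputs plus that seed.

## Known limitations

- Chance-level model selection: the best-of-15 BA on structure-free
  labels is a maximum over correlated null statistics and can exceed a
  single-model ±2σ band; judging "no signal" from the grid maximum alone
  over-rejects (see the per-model chance-level property in the tests).
- RECAP here is a bond-cutting formulation; reaction-based RECAP
  implementations differ on urea (carbonyl deletion) and on duplicate
  leaf handling, so fragment sets agree only where a single cut applies.
- Cross-toolkit canonical-SMILES equality, and hence duplicate collapse
  and scaffold-overlap counts, is not guaranteed.
- logD is consumed, never computed; docking scores are consumed, never
  computed.
- The commercial descriptor engine's exact values (consensus logP, its
  ESOL variant) are approximated by open equivalents; range-based scores
  built from different engines' descriptors are not interchangeable.
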