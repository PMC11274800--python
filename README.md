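# libprof

Profiling and critical comparison of de novo–designed chemical libraries.

Computational de novo design programs can generate thousands of candidate
molecules focused on a target (here motivated by inhibitors of DNMT1, the
maintenance DNA methyltransferase). Before any of those molecules are
synthesized or screened, the library itself has to be judged: is it
drug-like, synthetically accessible, structurally diverse, and does it
plausibly contain actives? `libprof` implements that judgement as a
reusable pipeline for computational and medicinal chemists:

- **Curation** — standardize structures, keep the largest component,
  restrict to organic elements, neutralize/reionize, canonical tautomer,
  deduplicate; deterministic and idempotent.
- **Profiling** — MW, HBD, HBA, TPSA, logP, nRotB, ESOL (Delaney), QED,
  SAscore; a range-based de novo score (arithmetic mean of in-interval
  indicators over seven descriptors, with a substructure penalty for
  nucleoside-like scaffolds); ligand efficiency LE = docking score /
  heavy atoms.
- **Fragments** — RECAP retrosynthetic fragmentation with growing-site
  annotation; rule-of-three size gate (MW < 300); logD ≤ 3 gate; greedy
  MaxMin diversity selection on MACCS-keys Tanimoto distance (fragment
  libraries of 400 → 177, training sets of 285 with MW > 300).
- **Diversity** — median pairwise Tanimoto similarity (MACCS keys,
  ECFP4); Bemis–Murcko chemotype statistics: N/M, cyclic-system-retrieval
  (CSR) curves with AUC and F50, scaled Shannon entropy SSE<sub>n</sub> of
  the n most frequent chemotypes; property-space median Euclidean
  distance; consensus diversity plots (CDPlots); PCA / t-SNE chemical-space
  embeddings.
- **Activity models** — qualifier-aware IC50 labeling (active iff
  unequivocally ≤ 10 µM), stratified 80/20 split, a 5-algorithm ×
  3-fingerprint model grid selected by leave-one-out cross-validated
  balanced accuracy, and distance-to-model (DM) confidence: the mean
  Jaccard distance of a query to the training compounds, binned into the
  quartiles Q1–Q4 of the evaluation distances, with farther queries
  flagged BEYOND (unknown confidence).
- **Synthetic data** — seeded generators of libraries with planted
  chemotype-frequency distributions and of IC50 tables with ambiguous
  qualifiers, contradictory duplicates and a tunable class-separability
  knob, each with exact ground truth, so the entire pipeline is testable
  offline.

## Key quantities

For a dataset of M molecules with N Bemis–Murcko chemotypes ranked by
frequency, the CSR curve plots the cumulative fraction of molecules
recovered against the fraction of chemotypes; its trapezoid AUC is 0.5
for an all-singleton library and approaches 1 as a few chemotypes
dominate. F50 is the smallest chemotype fraction recovering half the
molecules. The scaled Shannon entropy of the top-n chemotype counts
c₁…cₙ (renormalized, pᵢ = cᵢ/Σc) is

    SSE_n = −Σ pᵢ log pᵢ / log n

which is exactly 1 for an even spread and 0 when one chemotype holds
everything. Balanced accuracy is BA = (sensitivity + specificity)/2, and
the distance to model of a query q with fingerprint F(q) is
DM(q) = mean over training compounds t of (1 − Tanimoto(F(q), F(t))).

## Worked example

Generate a synthetic library with a planted chemotype distribution
(12 + 6 + 4 + 2 molecules over four scaffolds, plus 2 acyclic compounds)
and profile its diversity:

```
$ libprof synth library --out lib.smi --truth truth.csv \
      --frequencies 12,6,4,2 --n-acyclic 2 --seed 42
26 molecules -> lib.smi; truth -> truth.csv
$ libprof diversity lib.smi --codes DEMO --out div.csv
wrote 1 datasets -> div.csv
```

or in Python:

```python
import libprof as lp

records = lp.read_library("lib.smi", "SMILES")
records, report = lp.curate(records)
mols = [r.canonical_smiles for r in lp.curated(records)]
profile = lp.scaffold_profile(mols)
print(f"M={profile.M} N={profile.N} N/M={profile.nm_ratio:.3f} "
      f"AUC={profile.auc:.3f} F50={profile.f50:.3f} SSE10={profile.sse_n:.3f}")
stats = lp.pairwise_similarity_stats(mols, "MACCS166")
print(f"median MACCS/Tanimoto similarity: {stats.median:.3f}")
```

prints

```
M=26 N=6 N/M=0.231 AUC=0.718 F50=0.333 SSE10=0.817
median MACCS/Tanimoto similarity: 0.200
```

Six chemotypes cover the 26 molecules: the four planted scaffolds, the
pooled ACYCLIC class, and one extra created by curation itself — the
canonical-tautomer step rewrites a hydroxypyrimidine analog as its
pyrimidinone tautomer, whose Bemis–Murcko scaffold differs (a concrete
reminder that tautomer standardization affects scaffold counts). An AUC
of 0.718 and F50 of 0.333 say a third of the chemotypes already recover
half the library, i.e. moderately concentrated; SSE10 of 0.817 reflects
the planted unevenness; the low median similarity (0.20) shows the
decorated analogs are still structurally varied at the whole-molecule
level.

Other entry points: `libprof profile`, `libprof score`, `libprof
fragments`, `libprof trainingset`, `libprof embed`, `libprof train`,
`libprof synth activity`, `libprof synth docking` — see `libprof --help`.

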