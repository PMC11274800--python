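"""Global diversity and scaffold analysis of compound datasets.

A dataset's diversity is summarized from three complementary views:

* whole-structure fingerprints (MACCS keys, circular ECFP4) compared with
  the Tanimoto coefficient — the median off-diagonal pairwise similarity;
* Bemis-Murcko chemotypes — scaffold counts, the cyclic-system-retrieval
  (CSR) curve with its AUC and F50, and the scaled Shannon entropy of the
  most populated chemotypes;
* physicochemical properties — the median pairwise Euclidean distance of
  six scaled properties.

Consensus diversity plots place one point per dataset combining all three
views plus dataset size.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, MACCSkeys, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

ACYCLIC = "ACYCLIC"


class FingerprintKind(str, enum.Enum):
    MACCS166 = "MACCS166"
    ECFP4_1024 = "ECFP4_1024"
    ECFP4_2048 = "ECFP4_2048"


def _as_mol(mol: Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    parsed = Chem.MolFromSmiles(mol)
    if parsed is None:
        raise ValueError(f"unparseable structure: {mol!r}")
    return parsed


_MORGAN = {
    1024: rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024),
    2048: rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048),
}


def fingerprint(
    mol: Chem.Mol | str,
    kind: FingerprintKind | str = FingerprintKind.MACCS166,
    nbits: Optional[int] = None,
) -> np.ndarray:
    """Binary fingerprint as a numpy bool array.

    MACCS is fixed at the 166 defined keys (the toolkit's unused bit 0 is
    dropped); ECFP4 is a radius-2 circular fingerprint folded to 1024 or
    2048 bits.
    """
    kind = FingerprintKind(kind)
    m = _as_mol(mol)
    if kind is FingerprintKind.MACCS166:
        bv = MACCSkeys.GenMACCSKeys(m)
        arr = np.zeros(bv.GetNumBits(), dtype=bool)
        for b in bv.GetOnBits():
            arr[b] = True
        return arr[1:]  # bit 0 is unused padding
    size = nbits or (1024 if kind is FingerprintKind.ECFP4_1024 else 2048)
    if size not in _MORGAN:
        raise ValueError(f"unsupported ECFP4 width {size}")
    bv = _MORGAN[size].GetFingerprint(m)
    arr = np.zeros(size, dtype=bool)
    for b in bv.GetOnBits():
        arr[b] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; two all-zero vectors are defined as identical."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass
class SimilarityStats:
    fingerprint: FingerprintKind
    n: int
    median: float
    mean: float
    #: (similarity value, cumulative fraction of pairs), non-decreasing
    cdf: list[tuple[float, float]] = field(default_factory=list)


def fingerprint_matrix(
    mols: Sequence[Chem.Mol | str], kind: FingerprintKind | str
) -> np.ndarray:
    return np.stack([fingerprint(m, kind) for m in mols])


def pairwise_similarity_stats(
    mols: Sequence[Chem.Mol | str],
    fingerprint_kind: FingerprintKind | str = FingerprintKind.MACCS166,
) -> SimilarityStats:
    """Statistics over the M(M-1)/2 off-diagonal Tanimoto similarities.

    Similarities are produced one row at a time against the remaining
    molecules, so the full M x M matrix is never materialized.
    """
    kind = FingerprintKind(fingerprint_kind)
    if len(mols) < 2:
        raise ValueError("need at least 2 molecules for pairwise statistics")
    fps = fingerprint_matrix(mols, kind)
    pop = fps.sum(axis=1)
    values = []
    for i in range(len(mols) - 1):
        rest = fps[i + 1:]
        inter = np.logical_and(fps[i], rest).sum(axis=1)
        union = pop[i] + pop[i + 1:] - inter
        sims = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
        values.append(sims)
    vals = np.sort(np.concatenate(values))
    frac = np.arange(1, len(vals) + 1) / len(vals)
    # compress the CDF to the last point of each distinct similarity value
    keep = np.r_[np.diff(vals) > 0, True]
    cdf = list(zip(vals[keep].tolist(), frac[keep].tolist()))
    return SimilarityStats(
        fingerprint=kind,
        n=len(mols),
        median=float(np.median(vals)),
        mean=float(vals.mean()),
        cdf=cdf,
    )


def bm_scaffold(mol: Chem.Mol | str) -> str:
    """Bemis-Murcko chemotype: ring systems plus linkers, side chains
    removed.  Ring-free molecules pool into the ACYCLIC chemotype."""
    m = _as_mol(mol)
    if rdMolDescriptors.CalcNumRings(m) == 0:
        return ACYCLIC
    scaffold = MurckoScaffold.GetScaffoldForMol(m)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ACYCLIC
    return Chem.MolToSmiles(scaffold)


@dataclass
class ScaffoldProfile:
    counts: dict[str, int]
    M: int                      # molecules
    N: int                      # chemotypes
    nm_ratio: float             # N/M
    csr: list[tuple[float, float]]
    auc: float
    f50: float
    sse_n: float
    sse_top_n: int
    acyclic_fraction: float


def _sorted_counts(counts: Counter) -> list[tuple[str, int]]:
    # descending count, ties by lexicographic chemotype SMILES
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def scaled_shannon_entropy(counts: Sequence[int], top_n: int = 10) -> float:
    """Shannon entropy of the ``top_n`` largest counts, renormalized among
    themselves and scaled by log(n'); n' = min(top_n, len(counts)).

    1.0 means the molecules are spread evenly over the n' chemotypes
    (maximum diversity); 0.0 means a single chemotype holds them all.
    """
    top = sorted(counts, reverse=True)[: min(top_n, len(counts))]
    n = len(top)
    if n <= 1:
        return 0.0
    if len(set(top)) == 1:
        return 1.0  # even spread: entropy is log n exactly
    p = np.asarray(top, dtype=float)
    p = p / p.sum()
    p = p[p > 0]
    h = -(p * np.log(p)).sum()
    return float(h / np.log(n))


def profile_from_counts(
    counts: Counter | dict[str, int], sse_top_n: int = 10
) -> ScaffoldProfile:
    """Chemotype statistics from a chemotype -> count table.

    The CSR curve plots the cumulative fraction of molecules recovered
    against the fraction of chemotypes, chemotypes ranked by descending
    frequency, with the origin prepended; AUC is the trapezoid area and F50
    the smallest chemotype fraction recovering half the molecules.
    """
    counts = Counter(counts)
    if not counts:
        raise ValueError("empty chemotype table")
    ordered = _sorted_counts(counts)
    M = sum(c for _, c in ordered)
    N = len(ordered)
    cum = np.cumsum([c for _, c in ordered]) / M
    x = np.arange(1, N + 1) / N
    csr = [(0.0, 0.0)] + list(zip(x.tolist(), cum.tolist()))
    auc = float(np.trapezoid([p[1] for p in csr], [p[0] for p in csr]))
    f50 = float(x[int(np.argmax(cum >= 0.5))])
    sse = scaled_shannon_entropy([c for _, c in ordered], sse_top_n)
    return ScaffoldProfile(
        counts=dict(ordered),
        M=M,
        N=N,
        nm_ratio=N / M,
        csr=csr,
        auc=auc,
        f50=f50,
        sse_n=sse,
        sse_top_n=min(sse_top_n, N),
        acyclic_fraction=counts.get(ACYCLIC, 0) / M,
    )


def scaffold_profile(
    mols: Sequence[Chem.Mol | str],
    sse_top_n: int = 10,
    include_acyclic: bool = True,
) -> ScaffoldProfile:
    """Chemotype statistics of a dataset.

    With ``include_acyclic`` (default) the pooled ACYCLIC chemotype takes
    part in N, the CSR curve and the entropy, so acyclic-rich sets register
    as scaffold-poor; the acyclic fraction is always reported relative to
    the full dataset either way.
    """
    if not mols:
        raise ValueError("empty dataset")
    counts = Counter(bm_scaffold(m) for m in mols)
    total = sum(counts.values())
    acyclic_fraction = counts.get(ACYCLIC, 0) / total
    if not include_acyclic:
        counts.pop(ACYCLIC, None)
        if not counts:
            raise ValueError("dataset has no cyclic molecules")
    profile = profile_from_counts(counts, sse_top_n)
    profile.acyclic_fraction = acyclic_fraction
    return profile


def scaffold_overlap(
    profile_a: ScaffoldProfile, profile_b: ScaffoldProfile
) -> tuple[set[str], set[str], set[str]]:
    """(shared, unique_a, unique_b) chemotype sets; ACYCLIC excluded."""
    a = set(profile_a.counts) - {ACYCLIC}
    b = set(profile_b.counts) - {ACYCLIC}
    return a & b, a - b, b - a


class Scaling(str, enum.Enum):
    ZSCORE = "ZSCORE"
    MINMAX = "MINMAX"


#: property columns used for property-space diversity and embeddings
PROPERTY_NAMES = ("mw", "hbd", "hba", "tpsa", "nrotb", "logp")


def property_matrix(mols: Sequence[Chem.Mol | str]) -> np.ndarray:
    """MW, HBD, HBA, TPSA, nRotB, logP for each molecule (n x 6)."""
    rows = []
    for m in mols:
        m = _as_mol(m)
        rows.append([
            Descriptors.MolWt(m),
            Lipinski.NumHDonors(m),
            Lipinski.NumHAcceptors(m),
            rdMolDescriptors.CalcTPSA(m),
            Lipinski.NumRotatableBonds(m),
            Crippen.MolLogP(m),
        ])
    return np.asarray(rows, dtype=float)


def _scale(x: np.ndarray, reference: np.ndarray, scaling: Scaling) -> np.ndarray:
    if scaling is Scaling.ZSCORE:
        center = reference.mean(axis=0)
        scale = reference.std(axis=0)
    else:
        center = reference.min(axis=0)
        scale = reference.max(axis=0) - reference.min(axis=0)
    # (near-)constant columns contribute 0 rather than amplifying float noise
    tol = 1e-9 * np.maximum(1.0, np.abs(center))
    scale = np.where(scale <= tol, 1.0, scale)
    return (x - center) / scale


def property_distance(
    mols: Sequence[Chem.Mol | str],
    scaling: Scaling | str = Scaling.ZSCORE,
    reference: Optional[np.ndarray] = None,
) -> float:
    """Median pairwise Euclidean distance of the six scaled properties.

    ``reference`` supplies the property matrix used to fit the scaling
    (e.g. the union of all datasets under comparison); defaults to the
    dataset itself.
    """
    from scipy.spatial.distance import pdist

    if len(mols) < 2:
        raise ValueError("need at least 2 molecules")
    scaling = Scaling(scaling)
    x = property_matrix(mols)
    ref = reference if reference is not None else x
    return float(np.median(pdist(_scale(x, ref, scaling))))


@dataclass
class CDPlotPoint:
    dataset_code: str
    x: float            # median MACCS/Tanimoto similarity
    y: float            # scaffold CSR AUC
    color_value: float  # property-space median distance
    size_value: int     # dataset size M


def cdplot_data(
    datasets: Sequence[tuple[str, Sequence[Chem.Mol | str]]],
    sse_top_n: int = 10,
    scaling: Scaling | str = Scaling.ZSCORE,
    plot_path: Optional[str] = None,
) -> list[CDPlotPoint]:
    """One consensus-diversity point per dataset; optionally renders the
    scatter plot to ``plot_path``.  Property scaling is fitted on the union
    of all datasets so colors are comparable."""
    pooled = np.vstack([property_matrix(mols) for _, mols in datasets])
    points = []
    for code, mols in datasets:
        stats = pairwise_similarity_stats(mols, FingerprintKind.MACCS166)
        profile = scaffold_profile(mols, sse_top_n=sse_top_n)
        points.append(
            CDPlotPoint(
                dataset_code=code,
                x=stats.median,
                y=profile.auc,
                color_value=property_distance(mols, scaling, reference=pooled),
                size_value=len(mols),
            )
        )
    if plot_path:
        _render_cdplot(points, plot_path)
    return points


def _render_cdplot(points: Sequence[CDPlotPoint], path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    sizes = np.array([p.size_value for p in points], dtype=float)
    sizes = 60 + 400 * sizes / sizes.max()
    sc = ax.scatter(
        [p.x for p in points], [p.y for p in points],
        s=sizes, c=[p.color_value for p in points],
        cmap="RdYlGn_r", edgecolor="k",
    )
    for p in points:
        ax.annotate(p.dataset_code, (p.x, p.y), textcoords="offset points",
                    xytext=(6, 6), fontsize=8)
    ax.set_xlabel("median MACCS/Tanimoto similarity")
    ax.set_ylabel("scaffold CSR AUC")
    fig.colorbar(sc, label="median property distance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


class Representation(str, enum.Enum):
    PROPERTIES6 = "PROPERTIES6"
    MACCS166 = "MACCS166"
    ECFP4_1024 = "ECFP4_1024"


class EmbedMethod(str, enum.Enum):
    PCA = "PCA"
    TSNE = "TSNE"


def embed_chemspace(
    datasets: Sequence[tuple[str, Sequence[tuple[str, Chem.Mol | str]]]],
    representation: Representation | str = Representation.PROPERTIES6,
    method: EmbedMethod | str = EmbedMethod.PCA,
    params: Optional[dict] = None,
    seed: int = 0,
):
    """2D chemical-space embedding of one or more datasets.

    ``datasets`` is a list of (code, [(id, mol), ...]).  Returns a pandas
    DataFrame with columns id, dataset_code, dim1, dim2; for PCA the frame's
    ``attrs['explained_variance_ratio']`` carries the component variances.
    """
    import pandas as pd

    representation = Representation(representation)
    method = EmbedMethod(method)
    params = dict(params or {})
    ids, codes, mols = [], [], []
    for code, items in datasets:
        for mid, m in items:
            ids.append(mid)
            codes.append(code)
            mols.append(m)
    if len(mols) < 3:
        raise ValueError("need at least 3 molecules to embed")
    if representation is Representation.PROPERTIES6:
        x = property_matrix(mols)
        std = x.std(axis=0)
        if np.all(std == 0):
            raise ValueError("zero-variance input: nothing to embed")
        x = _scale(x, x, Scaling.ZSCORE)
    else:
        kind = (FingerprintKind.MACCS166
                if representation is Representation.MACCS166
                else FingerprintKind.ECFP4_1024)
        x = fingerprint_matrix(mols, kind).astype(float)

    info: dict = {}
    if method is EmbedMethod.PCA:
        from sklearn.decomposition import PCA

        if np.all(x.std(axis=0) == 0):
            raise ValueError("zero-variance input: PCA undefined")
        pca = PCA(n_components=2, svd_solver="full")
        coords = pca.fit_transform(x)
        info["explained_variance_ratio"] = pca.explained_variance_ratio_.tolist()
    else:
        from sklearn.manifold import TSNE

        perplexity = params.pop("perplexity", min(30.0, max(2.0, (len(mols) - 1) / 3)))
        tsne = TSNE(
            n_components=2, random_state=seed, perplexity=perplexity,
            init="pca", **params,
        )
        coords = tsne.fit_transform(x)
    df = pd.DataFrame(
        {"id": ids, "dataset_code": codes,
         "dim1": coords[:, 0], "dim2": coords[:, 1]}
    )
    df.attrs.update(info)
    return df
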