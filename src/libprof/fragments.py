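"""Fragment generation and diversity-driven subset selection.

RECAP-style retrosynthetic fragmentation cuts molecules at bonds a chemist
could plausibly form (amide, ester, amine, urea, ether, olefin, quaternary
nitrogen, aromatic N-aliphatic C, lactam N-aliphatic C, biaryl and
sulfonamide motifs).  All matched acyclic bonds are cut at once, so the
fragments partition the parent's heavy atoms and each carries attachment
markers recording where it can grow.

Subset selection uses the greedy MaxMin algorithm on fingerprint Tanimoto
distances; combined pipelines build fragment libraries (RO3 size filter ->
MaxMin -> logD gate -> MaxMin) and diverse training sets (MW > 300 ->
MaxMin).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

from .diversity import FingerprintKind, fingerprint_matrix
from .io_curation import MoleculeRecord

# Two-atom bond SMARTS for the RECAP cleavage motifs.  Only acyclic single
# bonds are cut (plus the acyclic olefin double bond); ring bonds are never
# broken.  The urea motif is covered by the amide pattern (each N-C(=O)
# bond is cleavable).
RECAP_BOND_SMARTS: list[tuple[str, str]] = [
    ("amide", "[C;!R;$(C=O)]-!@[N;+0;!$([N]=*)]"),
    ("ester", "[C;!R;$(C=O)]-!@[O;+0;D2]"),
    ("amine", "[N;+0;!R;D2,D3;!$(N=*);!$(N[C,S]=[O,S,N])]-!@[C;!$(C=[O,N,S])]"),
    ("ether", "[C]-!@[O;+0;D2;!R;!$(OC=O)]"),
    ("olefin", "[C;!R]=!@[C;!R]"),
    ("quaternary_n", "[N;+1;D4]-!@[C]"),
    ("aromatic_n_aliphatic_c", "[n;+0]-!@[C;!$(C=[O,N,S])]"),
    ("lactam_n_aliphatic_c", "[N;+0;R;$(N[C;R]=O)]-!@[C;!$(C=[O,N,S])]"),
    ("aromatic_c_aromatic_c", "[c]-!@[c]"),
    ("sulfonamide", "[N;+0;!$(N=*)]-!@[S;$(S(=O)=O)]"),
]

_RECAP_PATTERNS = [
    (name, Chem.MolFromSmarts(smarts)) for name, smarts in RECAP_BOND_SMARTS
]

#: tiny byproduct fragments never used as building blocks
EXCLUDED_FRAGMENTS = frozenset({"O", "N", "Cl"})  # H2O, NH3, HCl


@dataclass
class FragmentRecord:
    """One RECAP fragment with attachment bookkeeping.

    ``smiles`` keeps the attachment markers as dummy atoms; ``growing_sites``
    are the indices of those markers in the fragment's canonical atom order.
    ``mw`` is computed with the markers capped by hydrogens.
    """

    smiles: str
    parent_id: str
    mw: float
    logd: Optional[float] = None
    growing_sites: list[int] = field(default_factory=list)

    def heavy_atoms(self) -> int:
        mol = Chem.MolFromSmiles(self.smiles)
        return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1
                   and a.GetAtomicNum() != 0)


def _capped(mol: Chem.Mol) -> Chem.Mol:
    """Fragment with attachment markers replaced by hydrogens."""
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        if atom.GetAtomicNum() == 0:
            atom.SetAtomicNum(1)
            atom.SetIsotope(0)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.RemoveHs(out)


def capped_smiles(fragment_smiles: str) -> str:
    """Canonical SMILES of the fragment with growing sites hydrogen-capped."""
    mol = Chem.MolFromSmiles(fragment_smiles)
    return Chem.MolToSmiles(_capped(mol))


def recap_cleavable_bonds(mol: Chem.Mol) -> list[int]:
    """Indices of bonds matched by any RECAP cleavage motif."""
    bonds: set[int] = set()
    for _, patt in _RECAP_PATTERNS:
        for match in mol.GetSubstructMatches(patt):
            bond = mol.GetBondBetweenAtoms(match[0], match[1])
            if bond is not None:
                bonds.add(bond.GetIdx())
    return sorted(bonds)


def recap_fragment(
    mol: Chem.Mol | str, parent_id: str = ""
) -> list[FragmentRecord]:
    """Leaf fragments of the full RECAP decomposition.

    All cleavable bonds are cut simultaneously; a molecule with no
    cleavable bond yields an empty list (it is not its own fragment).
    Cutting k bonds yields exactly k+1 fragments whose heavy atoms
    partition the parent's.
    """
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"unparseable structure: {mol!r}")
        mol = parsed
    bonds = recap_cleavable_bonds(mol)
    if not bonds:
        return []
    fragmented = Chem.FragmentOnBonds(
        mol, bonds, addDummies=True, dummyLabels=[(0, 0)] * len(bonds)
    )
    pieces = Chem.GetMolFrags(fragmented, asMols=True, sanitizeFrags=True)
    records = []
    for piece in pieces:
        smiles = Chem.MolToSmiles(piece)
        canonical = Chem.MolFromSmiles(smiles)
        sites = [
            a.GetIdx() for a in canonical.GetAtoms() if a.GetAtomicNum() == 0
        ]
        records.append(
            FragmentRecord(
                smiles=smiles,
                parent_id=parent_id,
                mw=float(Descriptors.MolWt(_capped(canonical))),
                growing_sites=sites,
            )
        )
    return records


def ro3_mw_filter(
    frags: Sequence[FragmentRecord], max_mw: float = 300.0
) -> list[FragmentRecord]:
    """Rule-of-three size gate: keep fragments with MW strictly below
    ``max_mw``; the trivial byproducts water, ammonia and HCl are always
    dropped."""
    kept = []
    for f in frags:
        if capped_smiles(f.smiles) in EXCLUDED_FRAGMENTS:
            continue
        if f.mw < max_mw:
            kept.append(f)
    return kept


def logd_filter(
    frags: Sequence[FragmentRecord],
    logd_table: Mapping[str, float],
    max_logd: float = 3.0,
) -> list[FragmentRecord]:
    """Keep fragments with logD <= ``max_logd`` (closed bound).

    ``logd_table`` maps fragment SMILES to externally computed logD at
    pH 7.4; a fragment may instead carry its own ``logd``.  Missing entries
    raise with the full list of offenders.
    """
    missing = []
    kept = []
    for f in frags:
        logd = f.logd if f.logd is not None else logd_table.get(f.smiles)
        if logd is None:
            missing.append(f.smiles)
            continue
        if logd <= max_logd:
            kept.append(
                FragmentRecord(f.smiles, f.parent_id, f.mw, float(logd),
                               list(f.growing_sites))
            )
    if missing:
        raise KeyError(f"missing logD for fragments: {missing}")
    return kept


@dataclass
class SelectionTrace:
    """Bookkeeping of a MaxMin pick: ordered ids, indices and settings."""

    picked_ids: list[str]
    picked_indices: list[int]
    seed: int
    fingerprint: FingerprintKind
    k: int
    warning: Optional[str] = None


def _pool_items(pool) -> tuple[list[str], list[str]]:
    """(ids, smiles) from records, fragments, (id, smiles) pairs or SMILES."""
    ids, smiles = [], []
    for i, item in enumerate(pool):
        if isinstance(item, MoleculeRecord):
            ids.append(item.id)
            smiles.append(item.canonical_smiles or item.source_smiles)
        elif isinstance(item, FragmentRecord):
            ids.append(item.smiles)
            smiles.append(capped_smiles(item.smiles))
        elif isinstance(item, tuple):
            ids.append(str(item[0]))
            smiles.append(item[1])
        else:
            ids.append(str(i))
            smiles.append(str(item))
    return ids, smiles


def maxmin_select(
    pool,
    k: int,
    fingerprint: FingerprintKind | str = FingerprintKind.MACCS166,
    seed: int = 0,
) -> SelectionTrace:
    """Greedy MaxMin diverse-subset selection on Tanimoto distance.

    The first pick is the item at index ``seed mod pool size``; each later
    pick maximizes its minimum distance (1 - Tanimoto) to the picks so far,
    ties broken by lowest pool index.  Deterministic given (pool order,
    seed).  ``k`` larger than the pool returns the whole pool with a
    warning recorded on the trace.
    """
    kind = FingerprintKind(fingerprint)
    ids, smiles = _pool_items(pool)
    n = len(ids)
    if n == 0:
        raise ValueError("empty pool")
    if k < 1:
        raise ValueError("k must be >= 1")
    warning = None
    if k >= n:
        if k > n:
            warning = f"requested {k} items from a pool of {n}; returning all"
        return SelectionTrace(list(ids), list(range(n)), seed, kind, k, warning)

    fps = fingerprint_matrix(smiles, kind)
    pop = fps.sum(axis=1)

    def dist_to(i: int) -> np.ndarray:
        inter = np.logical_and(fps[i], fps).sum(axis=1)
        union = pop[i] + pop - inter
        sim = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
        return 1.0 - sim

    first = seed % n
    picked = [first]
    min_dist = dist_to(first)
    while len(picked) < k:
        min_dist[picked] = -1.0  # never repick
        nxt = int(np.argmax(min_dist))  # argmax takes the lowest tied index
        picked.append(nxt)
        min_dist = np.minimum(min_dist, dist_to(nxt))
    return SelectionTrace(
        [ids[i] for i in picked], picked, seed, kind, k, warning
    )


def prepare_training_set(
    library: Sequence[MoleculeRecord],
    target_size: int = 285,
    seed: int = 0,
) -> SelectionTrace:
    """Diverse training set: drop fragment-like molecules (MW <= 300), then
    MaxMin-select ``target_size`` with MACCS keys."""
    survivors = []
    for rec in library:
        mol = rec.mol()
        if mol is not None and Descriptors.MolWt(mol) > 300.0:
            survivors.append(rec)
    if not survivors:
        return SelectionTrace([], [], seed, FingerprintKind.MACCS166,
                              target_size, warning="no molecules with MW > 300")
    return maxmin_select(survivors, target_size, FingerprintKind.MACCS166, seed)


def prepare_fragment_library(
    frags: Sequence[FragmentRecord],
    logd_table: Mapping[str, float],
    intermediate_k: int = 400,
    final_k: int = 177,
    seed: int = 0,
    max_mw: float = 300.0,
    max_logd: float = 3.0,
) -> tuple[SelectionTrace, dict[str, int]]:
    """Fragment-library pipeline: RO3 size gate -> MaxMin(400, MACCS) ->
    logD <= 3 gate -> MaxMin(177, MACCS).  Returns the final trace plus the
    per-stage survivor counts."""
    counts = {"input": len(frags)}
    stage1 = ro3_mw_filter(frags, max_mw)
    counts["ro3"] = len(stage1)
    trace1 = maxmin_select(stage1, intermediate_k, FingerprintKind.MACCS166, seed)
    stage2 = [stage1[i] for i in trace1.picked_indices]
    counts["maxmin_intermediate"] = len(stage2)
    stage3 = logd_filter(stage2, logd_table, max_logd)
    counts["logd"] = len(stage3)
    trace = maxmin_select(stage3, final_k, FingerprintKind.MACCS166, seed)
    counts["final"] = len(trace.picked_ids)
    return trace, counts
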