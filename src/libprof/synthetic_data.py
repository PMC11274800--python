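"""Seeded generators of synthetic libraries and activity tables.

These emulate the statistical structure the analysis stages assume —
libraries with a controlled chemotype-frequency distribution, IC50 tables
with qualifier strings, removable ambiguous rows and contradictory
duplicates, and docking-score tables — so the whole pipeline is testable
without downloading anything.  Every generator is a pure function of its
spec (seed included) and returns a ground-truth table alongside the data.

Molecules are built by decorating ring scaffolds with acyclic substituents
at ring-carbon positions.  Acyclic single-bonded substituents are removed
by Bemis-Murcko pruning, so each decorated molecule provably keeps its
scaffold's chemotype; the generator asserts this for every emitted
molecule rather than trusting the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from rdkit import Chem

from .diversity import bm_scaffold
from .io_curation import MoleculeRecord, Status

#: Ring scaffolds verified to survive decoration with the substituent pool.
DEFAULT_SCAFFOLD_POOL = [
    "c1ccccc1",            # benzene
    "c1ccncc1",            # pyridine
    "c1cncnc1",            # pyrimidine
    "c1ccsc1",             # thiophene
    "c1ccoc1",             # furan
    "C1CCCCC1",            # cyclohexane
    "C1CCNCC1",            # piperidine
    "C1CCOC1",             # tetrahydrofuran
    "c1ccc2ccccc2c1",      # naphthalene
    "c1ccc2ncccc2c1",      # quinoline
    "c1ccc2[nH]ccc2c1",    # indole
    "c1ccc(-c2ccccc2)cc1", # biphenyl
    "C1CCCCCC1",           # cycloheptane
    "C1CCCC1",             # cyclopentane
    "c1cnccn1",            # pyrazine
    "c1cc[nH]c1",          # pyrrole
]

#: Acyclic substituents attached by a single bond (atom 0 is the anchor).
DEFAULT_SUBSTITUENT_POOL = [
    "C", "CC", "CCC", "CC(C)C", "O", "OC", "OCC", "N", "NC", "F", "Cl",
    "Br", "C#N", "C(F)(F)F", "CO", "CCO", "CCN", "C(C)C",
]

#: Acyclic molecules for the chain component of a library.
_ACYCLIC_HEADS = ["C", "CC", "CCC", "CCCC", "CCCCC", "CCCCCC"]
_ACYCLIC_TAILS = ["O", "N", "CO", "CN", "C(C)O", "OC", "C(=O)O", "C#N"]


@dataclass
class SyntheticLibrarySpec:
    scaffold_pool: list[str] = field(
        default_factory=lambda: list(DEFAULT_SCAFFOLD_POOL))
    frequency: list[int] = field(default_factory=lambda: [5, 3, 2])
    substituent_pool: list[str] = field(
        default_factory=lambda: list(DEFAULT_SUBSTITUENT_POOL))
    n_acyclic: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.frequency) > len(self.scaffold_pool):
            raise ValueError("more frequencies than scaffolds")
        if any(f < 1 for f in self.frequency):
            raise ValueError("frequencies must be positive")


def _attach(scaffold: Chem.Mol, site: int, substituent: str) -> Optional[str]:
    """Canonical SMILES of the scaffold with ``substituent`` single-bonded
    at ring atom ``site``, or None if the chemistry does not work out."""
    sub = Chem.MolFromSmiles(substituent)
    if sub is None:
        return None
    combined = Chem.RWMol(Chem.CombineMols(scaffold, sub))
    combined.AddBond(site, scaffold.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        mol = combined.GetMol()
        Chem.SanitizeMol(mol)
    except Exception:
        return None
    return Chem.MolToSmiles(mol)


def _decorations(scaffold_smiles: str, substituents: list[str],
                 rng: np.random.Generator) -> Iterator[str]:
    """Deterministic stream of distinct decorated molecules sharing the
    scaffold's chemotype, starting with the bare scaffold."""
    scaffold = Chem.MolFromSmiles(scaffold_smiles)
    target = Chem.MolToSmiles(scaffold)
    sites = [
        a.GetIdx() for a in scaffold.GetAtoms()
        if a.GetAtomicNum() == 6 and a.GetTotalNumHs() > 0
    ]
    seen = {target}
    yield target
    combos = [(s, sub) for s in sites for sub in substituents]
    order = rng.permutation(len(combos))
    singles: list[tuple[int, str]] = []
    for idx in order:
        site, sub = combos[idx]
        smi = _attach(scaffold, site, sub)
        if smi is None or smi in seen:
            continue
        if bm_scaffold(smi) != target:
            raise AssertionError(
                f"decoration {sub!r} at {site} broke chemotype {target!r}")
        seen.add(smi)
        singles.append((site, sub))
        yield smi
    # double substitutions extend the supply when single ones run out
    for i, (s1, x1) in enumerate(singles):
        for s2, x2 in singles[i:]:
            if s1 == s2:
                continue
            once = _attach(scaffold, s1, x1)
            mol = Chem.MolFromSmiles(once)
            site2 = s2  # scaffold indices are preserved by _attach
            smi = _attach(mol, site2, x2)
            if smi is None or smi in seen:
                continue
            if bm_scaffold(smi) != target:
                raise AssertionError(
                    f"double decoration broke chemotype {target!r}")
            seen.add(smi)
            yield smi


def _acyclic_molecules() -> Iterator[str]:
    for head in _ACYCLIC_HEADS:
        for tail in _ACYCLIC_TAILS:
            smi = Chem.CanonSmiles(head + tail)
            yield smi


def gen_scaffold_library(
    spec: SyntheticLibrarySpec,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Library with a planted chemotype-frequency distribution.

    For scaffold i, ``spec.frequency[i]`` distinct molecules sharing its
    Bemis-Murcko chemotype are emitted, plus ``n_acyclic`` ring-free
    molecules.  Deterministic per seed.  Returns curated records and a
    ground-truth id -> chemotype table.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[MoleculeRecord] = []
    truth_rows = []
    counter = 0

    def emit(smiles: str, chemotype: str) -> None:
        nonlocal counter
        counter += 1
        mid = f"SYN{counter:05d}"
        records.append(MoleculeRecord(
            id=mid, source_smiles=smiles, canonical_smiles=smiles,
            status=Status.CURATED,
        ))
        truth_rows.append({"id": mid, "chemotype": chemotype})

    for scaffold_smiles, freq in zip(spec.scaffold_pool, spec.frequency):
        target = Chem.CanonSmiles(scaffold_smiles)
        stream = _decorations(scaffold_smiles, spec.substituent_pool, rng)
        for _ in range(freq):
            try:
                emit(next(stream), target)
            except StopIteration:
                raise ValueError(
                    f"substituent pool exhausted for scaffold {scaffold_smiles!r}"
                ) from None
    acyclic = _acyclic_molecules()
    for _ in range(spec.n_acyclic):
        emit(next(acyclic), "ACYCLIC")
    truth = pd.DataFrame(truth_rows, columns=["id", "chemotype"])
    return records, truth


#: scaffold pools for the two activity classes (disjoint chemotypes)
ACTIVE_SCAFFOLDS = ["c1ccc2ncccc2c1", "c1cncnc1", "c1ccc2[nH]ccc2c1",
                    "c1ccncc1"]
INACTIVE_SCAFFOLDS = ["C1CCCCC1", "C1CCNCC1", "c1ccsc1", "C1CCOC1"]


@dataclass
class SyntheticActivitySpec:
    n_active: int = 100
    n_inactive: int = 100
    separability: float = 1.0
    ambiguous_fraction: float = 0.0
    contradictory_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must be in [0, 1]")
        if not 0.0 <= self.ambiguous_fraction <= 1.0:
            raise ValueError("ambiguous_fraction must be in [0, 1]")
        if min(self.n_active, self.n_inactive, self.contradictory_pairs) < 0:
            raise ValueError("counts must be >= 0")


def _sample_ic50_um(rng: np.random.Generator, active: bool) -> float:
    """Lognormal IC50 (uM): median 1 for actives, 100 for inactives,
    sigma 0.8 log-units, resampled onto the correct side of 10 uM."""
    median = 1.0 if active else 100.0
    for _ in range(1000):
        v = float(np.exp(np.log(median) + 0.8 * rng.standard_normal()))
        if (v <= 10.0) == active and v != 10.0:
            return v
    return median  # pragma: no cover - rejection virtually never exhausts


def gen_activity_dataset(
    spec: SyntheticActivitySpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ChEMBL-style activity table with planted class structure.

    Actives decorate one scaffold pool and inactives a disjoint one; the
    separability knob mixes the pools (1 = disjoint, 0 = both classes drawn
    from the union, labels independent of structure).  An exact
    ``round(ambiguous_fraction * n)`` of the base rows get non-pinning
    qualifiers; ``contradictory_pairs`` extra structures appear twice with
    values on opposite sides of the threshold.  Returns the table and a
    ground-truth row classification.
    """
    rng = np.random.default_rng(spec.seed)
    streams: dict[str, Iterator[str]] = {}
    used: set[str] = set()

    def draw(scaffold: str) -> str:
        if scaffold not in streams:
            streams[scaffold] = _decorations(
                scaffold, DEFAULT_SUBSTITUENT_POOL, rng)
        for smi in streams[scaffold]:
            if smi not in used:
                used.add(smi)
                return smi
        raise ValueError(f"decoration stream exhausted for {scaffold!r}")

    def pick_scaffold(active: bool) -> str:
        own = ACTIVE_SCAFFOLDS if active else INACTIVE_SCAFFOLDS
        if rng.random() < spec.separability:
            pool = own
        else:
            pool = ACTIVE_SCAFFOLDS + INACTIVE_SCAFFOLDS
        return pool[rng.integers(len(pool))]

    rows, truth_rows = [], []
    n_base = spec.n_active + spec.n_inactive
    # interleave class draws: decoration streams yield progressively more
    # substituted molecules, so drawing one class first would correlate
    # molecular complexity with the label even at separability 0
    flags = [bool(f) for f in rng.permutation(
        [True] * spec.n_active + [False] * spec.n_inactive)]
    n_ambiguous = round(spec.ambiguous_fraction * n_base)
    ambiguous_idx = set(
        rng.choice(n_base, size=n_ambiguous, replace=False).tolist())

    for i, active in enumerate(flags):
        smi = draw(pick_scaffold(active))
        mid = f"ACT{i + 1:05d}"
        if i in ambiguous_idx:
            # lower/upper bounds that do not pin the class
            relation, value = (">", 1.0) if active else ("<", 100.0)
            expected = "AMBIGUOUS"
        else:
            relation = "="
            value = _sample_ic50_um(rng, active)
            expected = "ACTIVE" if active else "INACTIVE"
        unit = "nM" if rng.random() < 0.5 else "uM"
        reported = value * 1000.0 if unit == "nM" else value
        rows.append({
            "id": mid, "smiles": smi, "standard_value": reported,
            "standard_units": unit, "standard_relation": relation,
        })
        truth_rows.append({
            "id": mid, "smiles": smi, "expected_label": expected,
            "survives": expected in ("ACTIVE", "INACTIVE"),
        })

    for j in range(spec.contradictory_pairs):
        pool = ACTIVE_SCAFFOLDS + INACTIVE_SCAFFOLDS
        smi = draw(pool[rng.integers(len(pool))])
        for k, value in enumerate((1.0, 100.0)):
            mid = f"CON{j + 1:04d}_{k + 1}"
            rows.append({
                "id": mid, "smiles": smi, "standard_value": value,
                "standard_units": "uM", "standard_relation": "=",
            })
            truth_rows.append({
                "id": mid, "smiles": smi, "expected_label": "CONTRADICTORY",
                "survives": False,
            })

    order = rng.permutation(len(rows))
    table = pd.DataFrame([rows[i] for i in order])
    truth = pd.DataFrame([truth_rows[i] for i in order])
    return table, truth


def gen_docking_table(n: int, seed: int = 0) -> pd.DataFrame:
    """Docking scores ~ Normal(-7, 1.5) kcal/mol with heavy-atom counts."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    programs = np.where(rng.random(n) < 0.5, "VINA", "LEDOCK")
    return pd.DataFrame({
        "id": [f"DOCK{i + 1:05d}" for i in range(n)],
        "program": programs,
        "score": rng.normal(-7.0, 1.5, size=n),
        "heavy_atoms": rng.integers(15, 41, size=n),
    })
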