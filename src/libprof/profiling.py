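"""Molecular descriptors, drug-likeness and the range-based de novo score.

Descriptors follow the usual small-molecule profile: MW, hydrogen-bond donors
and acceptors, TPSA, Crippen logP, rotatable bonds, ESOL aqueous solubility
(Delaney's regression), SAscore synthetic accessibility and QED
drug-likeness.  The de novo score rewards molecules whose descriptors fall
inside target intervals derived from known actives (mean +/- SD), with a
multiplicative penalty for nucleoside-like substructures.
"""

from __future__ import annotations

import enum
import functools
import os
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, RDConfig, rdMolDescriptors

__all__ = [
    "DescriptorVector",
    "ScoreRules",
    "DockingRecord",
    "descriptor_vector",
    "qed",
    "sascore",
    "esol",
    "denovo_score",
    "build_score_rules",
    "default_score_rules",
    "ligand_efficiency",
    "read_docking_table",
]

#: QED at or above this is conventionally called "attractive".
QED_ATTRACTIVE_THRESHOLD = 0.67
#: SAscore above this is conventionally called synthetically infeasible.
SASCORE_FEASIBLE_MAX = 6.0

#: The seven descriptors entering the de novo score.
SCORED_DESCRIPTORS = ("mw", "hbd", "hba", "logp", "esol", "sascore", "tpsa")


def _as_mol(mol: Chem.Mol | str) -> Chem.Mol:
    if isinstance(mol, Chem.Mol):
        return mol
    parsed = Chem.MolFromSmiles(mol)
    if parsed is None:
        raise ValueError(f"unparseable structure: {mol!r}")
    return parsed


@dataclass
class DescriptorVector:
    """Physicochemical profile of one molecule."""

    mw: float          # g/mol
    hbd: int
    hba: int
    tpsa: float        # A^2
    logp: float
    nrotb: int
    esol: float        # log10(mol/L)
    sascore: float     # [1, 10]
    qed: float         # [0, 1]
    logd: Optional[float] = None  # externally supplied, pH 7.4

    def as_dict(self) -> dict:
        return {
            "mw": self.mw, "hbd": self.hbd, "hba": self.hba,
            "tpsa": self.tpsa, "logp": self.logp, "nrotb": self.nrotb,
            "esol": self.esol, "sascore": self.sascore, "qed": self.qed,
            "logd": self.logd,
        }


@functools.lru_cache(maxsize=1)
def _sascorer():
    """The contributed SAscore implementation shipped with RDKit."""
    sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
    if not os.path.exists(os.path.join(sa_dir, "sascorer.py")):
        raise RuntimeError(
            "SAscore fragment-contribution data not found in the RDKit "
            f"installation ({sa_dir})"
        )
    if sa_dir not in sys.path:
        sys.path.append(sa_dir)
    import sascorer  # type: ignore

    return sascorer


def sascore(mol: Chem.Mol | str) -> float:
    """Synthetic accessibility score in [1, 10] (1 = easy, 10 = hard)."""
    return float(_sascorer().calculateScore(_as_mol(mol)))


def sa_infeasible(mol: Chem.Mol | str) -> bool:
    return sascore(mol) > SASCORE_FEASIBLE_MAX


def qed(mol: Chem.Mol | str) -> float:
    """Quantitative estimate of drug-likeness (weighted geometric mean of
    desirability-transformed properties), in [0, 1]."""
    return float(QED.qed(_as_mol(mol)))


def qed_attractive(mol: Chem.Mol | str) -> bool:
    return qed(mol) >= QED_ATTRACTIVE_THRESHOLD


def esol(mol: Chem.Mol | str) -> float:
    """Estimated aqueous solubility, log10(mol/L), via Delaney's regression:

        logS = 0.16 - 0.63 clogP - 0.0062 MW + 0.066 RB - 0.74 AP

    where AP is the fraction of heavy atoms that are aromatic.
    """
    m = _as_mol(mol)
    heavy = m.GetNumHeavyAtoms()
    aromatic = sum(1 for a in m.GetAtoms() if a.GetIsAromatic())
    ap = aromatic / heavy if heavy else 0.0
    return (
        0.16
        - 0.63 * Crippen.MolLogP(m)
        - 0.0062 * Descriptors.MolWt(m)
        + 0.066 * Lipinski.NumRotatableBonds(m)
        - 0.74 * ap
    )


def descriptor_vector(
    mol: Chem.Mol | str, logd: Optional[float] = None
) -> DescriptorVector:
    m = _as_mol(mol)
    return DescriptorVector(
        mw=float(Descriptors.MolWt(m)),
        hbd=int(Lipinski.NumHDonors(m)),
        hba=int(Lipinski.NumHAcceptors(m)),
        tpsa=float(rdMolDescriptors.CalcTPSA(m)),
        logp=float(Crippen.MolLogP(m)),
        nrotb=int(Lipinski.NumRotatableBonds(m)),
        esol=float(esol(m)),
        sascore=sascore(m),
        qed=qed(m),
        logd=logd,
    )


@dataclass
class ScoreRules:
    """Interval rules plus substructure penalty for the de novo score.

    ``ranges`` maps descriptor names (fields of :class:`DescriptorVector`)
    to closed [low, high] intervals; membership is scored 0/1 and the score
    is the arithmetic mean of the indicators.  If any penalty SMARTS
    matches, the score is multiplied by ``(1 - penalty_value)``; the default
    penalty of 1.0 is a hard veto.
    """

    ranges: dict[str, tuple[float, float]]
    penalty_patterns: list[str] = field(default_factory=list)
    penalty_value: float = 1.0

    def __post_init__(self) -> None:
        valid = set(DescriptorVector.__dataclass_fields__)
        for name, (low, high) in self.ranges.items():
            if name not in valid:
                raise ValueError(f"score rule references unknown descriptor {name!r}")
            if low > high:
                raise ValueError(f"invalid interval for {name}: ({low}, {high})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoreRules":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            ranges={k: (float(v[0]), float(v[1])) for k, v in data["ranges"].items()},
            penalty_patterns=list(data.get("penalty_patterns", [])),
            penalty_value=float(data.get("penalty_value", 1.0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "ranges": {k: [float(v[0]), float(v[1])] for k, v in self.ranges.items()},
            "penalty_patterns": list(self.penalty_patterns),
            "penalty_value": float(self.penalty_value),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_score_rules() -> ScoreRules:
    """Rules shipped with the package (see data/score_rules.yaml)."""
    return ScoreRules.from_yaml(Path(__file__).parent / "data" / "score_rules.yaml")


def build_score_rules(
    actives: Sequence[Chem.Mol | str],
    n_sd: float = 1.0,
    penalty_patterns: Optional[Sequence[str]] = None,
    penalty_value: float = 1.0,
) -> ScoreRules:
    """Derive interval rules as mean +/- ``n_sd`` SD of the seven scored
    descriptors over a set of active compounds."""
    vecs = [descriptor_vector(m) for m in actives]
    ranges = {}
    for name in SCORED_DESCRIPTORS:
        vals = np.array([getattr(v, name) for v in vecs], dtype=float)
        mu, sd = float(vals.mean()), float(vals.std())
        ranges[name] = (mu - n_sd * sd, mu + n_sd * sd)
    patterns = list(penalty_patterns) if penalty_patterns is not None else list(
        default_score_rules().penalty_patterns
    )
    return ScoreRules(ranges=ranges, penalty_patterns=patterns,
                      penalty_value=penalty_value)


def denovo_score(mol: Chem.Mol | str, rules: ScoreRules) -> float:
    """Range-based score in [0, 1]: arithmetic mean of in-interval
    indicators over the rules' descriptors, times the substructure penalty."""
    m = _as_mol(mol)
    vec = descriptor_vector(m)
    hits = []
    for name, (low, high) in rules.ranges.items():
        value = getattr(vec, name)
        if value is None:
            raise ValueError(f"descriptor {name!r} unavailable for scoring")
        hits.append(1.0 if low <= value <= high else 0.0)
    score = float(np.mean(hits)) if hits else 0.0
    for smarts in rules.penalty_patterns:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"invalid penalty SMARTS {smarts!r}")
        if m.HasSubstructMatch(patt):
            score *= 1.0 - rules.penalty_value
            break
    return score


class DockingProgram(str, enum.Enum):
    VINA = "VINA"
    LEDOCK = "LEDOCK"
    OTHER = "OTHER"


@dataclass
class DockingRecord:
    id: str
    program: DockingProgram
    score: float        # kcal/mol, more negative = better
    heavy_atoms: int
    le: float = 0.0     # kcal/mol per heavy atom

    def __post_init__(self) -> None:
        self.le = ligand_efficiency(self.score, self.heavy_atoms)


def ligand_efficiency(score: float, heavy_atoms: int) -> float:
    """Docking score divided by the number of heavy atoms."""
    if heavy_atoms < 1:
        raise ValueError(f"heavy_atoms must be >= 1, got {heavy_atoms}")
    return score / heavy_atoms


def read_docking_table(path: str | Path) -> list[DockingRecord]:
    """CSV with columns id, program, score, heavy_atoms."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"id", "program", "score", "heavy_atoms"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"docking table missing columns: {sorted(missing)}")
    return [
        DockingRecord(
            id=str(row.id),
            program=DockingProgram(str(row.program).upper())
            if str(row.program).upper() in DockingProgram.__members__
            else DockingProgram.OTHER,
            score=float(row.score),
            heavy_atoms=int(row.heavy_atoms),
        )
        for row in df.itertuples()
    ]


def profile_table(mols: Mapping[str, Chem.Mol | str] | Sequence[tuple[str, str]],
                  logd: Optional[Mapping[str, float]] = None):
    """DataFrame of descriptor vectors keyed by compound id."""
    import pandas as pd

    items = mols.items() if isinstance(mols, Mapping) else mols
    rows = []
    for mid, m in items:
        vec = descriptor_vector(m, logd.get(mid) if logd else None)
        rows.append({"id": mid, **vec.as_dict()})
    return pd.DataFrame(rows)
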