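"""Activity labeling, model grid with LOO-CV, and distance-to-model confidence.

The workflow turns a ChEMBL-style IC50 export into a binary classification
dataset (actives: unequivocal IC50 <= 10 uM), trains an algorithm x
fingerprint grid selected by leave-one-out balanced accuracy, and estimates
per-prediction confidence from the mean Jaccard distance of a query to the
training compounds (distance to model, DM), binned into the quartiles of
the training-evaluation distances.  Queries farther than anything seen in
evaluation are flagged BEYOND, i.e. unknown confidence.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .diversity import FingerprintKind, fingerprint_matrix

ACTIVE = "ACTIVE"
INACTIVE = "INACTIVE"
AMBIGUOUS = "AMBIGUOUS"
CONTRADICTORY = "CONTRADICTORY"


class Qualifier(str, enum.Enum):
    EQ = "EQ"
    LT = "LT"
    LE = "LE"
    GT = "GT"
    GE = "GE"


_RELATION_MAP = {
    "=": Qualifier.EQ, "==": Qualifier.EQ, "~": Qualifier.EQ,
    "<": Qualifier.LT, "<=": Qualifier.LE,
    ">": Qualifier.GT, ">=": Qualifier.GE,
    "EQ": Qualifier.EQ, "LT": Qualifier.LT, "LE": Qualifier.LE,
    "GT": Qualifier.GT, "GE": Qualifier.GE,
}

_UNIT_TO_UM = {"nM": 1e-3, "uM": 1.0, "µM": 1.0, "μM": 1.0, "mM": 1e3}


def _label_one(qualifier: Qualifier, value_um: float, threshold: float) -> str:
    """Pin the class only when the relation forces one side of the
    threshold: bounded-above values <= threshold are active; values (or
    lower bounds) at/above the threshold are inactive; anything else is
    ambiguous."""
    if qualifier in (Qualifier.EQ, Qualifier.LT, Qualifier.LE):
        if value_um <= threshold:
            return ACTIVE
        return INACTIVE if qualifier is Qualifier.EQ else AMBIGUOUS
    # GT / GE
    return INACTIVE if value_um >= threshold else AMBIGUOUS


@dataclass
class LabelResult:
    #: every input row annotated with its label
    records: pd.DataFrame
    #: the surviving training table (one row per structure)
    dataset: pd.DataFrame
    summary: dict


def label_activity(
    table: pd.DataFrame,
    threshold_um: float = 10.0,
    id_column: str = "id",
    smiles_column: str = "smiles",
    value_column: str = "standard_value",
    unit_column: str = "standard_units",
    relation_column: str = "standard_relation",
) -> LabelResult:
    """Qualifier-aware activity labeling of an IC50 table.

    Rows whose relation/value pair does not pin the class are AMBIGUOUS and
    removed; structures reported with conflicting pinned labels are
    CONTRADICTORY and removed entirely; concordant duplicate structures
    collapse to one row carrying the median value.  Unknown units raise,
    listing the offending rows; unknown relation symbols are treated as
    non-pinning.
    """
    df = table.copy().reset_index(drop=True)
    bad_units = [
        (i, u) for i, u in enumerate(df[unit_column])
        if str(u) not in _UNIT_TO_UM
    ]
    if bad_units:
        raise ValueError(f"unknown IC50 units (row, unit): {bad_units}")
    value_um = [
        float(v) * _UNIT_TO_UM[str(u)]
        for v, u in zip(df[value_column], df[unit_column])
    ]
    labels = []
    for rel, v in zip(df[relation_column], value_um):
        q = _RELATION_MAP.get(str(rel).strip())
        labels.append(AMBIGUOUS if q is None else _label_one(q, v, threshold_um))
    df["value_um"] = value_um
    df["label"] = labels

    pinned = df[df["label"].isin([ACTIVE, INACTIVE])]
    contradictory_structures = {
        smi for smi, grp in pinned.groupby(smiles_column)
        if grp["label"].nunique() > 1
    }
    df.loc[df[smiles_column].isin(contradictory_structures), "label"] = CONTRADICTORY

    kept = df[df["label"].isin([ACTIVE, INACTIVE])]
    rows = []
    n_collapsed = 0
    for smi, grp in kept.groupby(smiles_column, sort=False):
        n_collapsed += len(grp) - 1
        rows.append({
            id_column: grp[id_column].iloc[0],
            smiles_column: smi,
            "value_um": float(grp["value_um"].median()),
            "label": grp["label"].iloc[0],
        })
    dataset = pd.DataFrame(rows, columns=[id_column, smiles_column, "value_um", "label"])
    summary = {
        "n_input": len(df),
        "n_ambiguous": int((df["label"] == AMBIGUOUS).sum()),
        "n_contradictory_rows": int((df["label"] == CONTRADICTORY).sum()),
        "n_duplicates_collapsed": n_collapsed,
        "n_dataset": len(dataset),
        "n_active": int((dataset["label"] == ACTIVE).sum()),
        "n_inactive": int((dataset["label"] == INACTIVE).sum()),
    }
    return LabelResult(records=df, dataset=dataset, summary=summary)


def stratified_split(
    dataset: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    label_column: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified random train/test split, deterministic given seed."""
    from sklearn.model_selection import train_test_split

    counts = dataset[label_column].value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present to split")
    if counts.min() < 2:
        raise ValueError(f"a class has fewer than 2 members: {counts.to_dict()}")
    train, test = train_test_split(
        dataset,
        train_size=train_fraction,
        stratify=dataset[label_column],
        random_state=seed,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)


class Algorithm(str, enum.Enum):
    KNN = "KNN"
    RF = "RF"
    GBT = "GBT"
    SVM = "SVM"
    FFNN = "FFNN"


class ModelFingerprint(str, enum.Enum):
    MACCS166 = "MACCS166"
    MORGAN2_2048 = "MORGAN2_2048"
    RDK_2048 = "RDK_2048"


@dataclass
class ModelSpec:
    algorithm: Algorithm
    fingerprint: ModelFingerprint
    hyperparameters: dict = field(default_factory=dict)


@dataclass
class ModelEval:
    ba: float
    precision: dict[str, float]
    recall: dict[str, float]
    n_train: int
    y_true: list[str] = field(default_factory=list)
    y_pred: list[str] = field(default_factory=list)


def model_fingerprints(
    smiles: Sequence[str], kind: ModelFingerprint | str
) -> np.ndarray:
    """Feature matrix of binary fingerprints for the model grid."""
    kind = ModelFingerprint(kind)
    if kind is ModelFingerprint.MACCS166:
        return fingerprint_matrix(list(smiles), FingerprintKind.MACCS166)
    if kind is ModelFingerprint.MORGAN2_2048:
        return fingerprint_matrix(list(smiles), FingerprintKind.ECFP4_2048)
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable structure: {smi!r}")
        bv = Chem.RDKFingerprint(mol, fpSize=2048)
        arr = np.zeros(2048, dtype=bool)
        for b in bv.GetOnBits():
            arr[b] = True
        rows.append(arr)
    return np.stack(rows)


def build_estimator(spec: ModelSpec, seed: int = 0):
    """sklearn estimator for a model spec (stochastic learners seeded)."""
    algo = Algorithm(spec.algorithm)
    hp = dict(spec.hyperparameters)
    if algo is Algorithm.KNN:
        from sklearn.neighbors import KNeighborsClassifier

        return KNeighborsClassifier(
            n_neighbors=hp.pop("n_neighbors", 3), metric="jaccard",
            algorithm="brute", **hp,
        )
    if algo is Algorithm.RF:
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(
            n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp
        )
    if algo is Algorithm.GBT:
        from sklearn.ensemble import GradientBoostingClassifier

        # shallow stumps with feature subsampling: orders of magnitude
        # cheaper under LOO on 2048-bit inputs, no accuracy cost at this n
        return GradientBoostingClassifier(
            n_estimators=hp.pop("n_estimators", 50),
            max_depth=hp.pop("max_depth", 2),
            max_features=hp.pop("max_features", "sqrt"),
            random_state=seed, **hp,
        )
    if algo is Algorithm.SVM:
        from sklearn.svm import SVC

        return SVC(C=hp.pop("C", 1.0), kernel=hp.pop("kernel", "rbf"), **hp)
    from sklearn.neural_network import MLPClassifier

    hidden = hp.pop("hidden_layer_sizes", [32])
    return MLPClassifier(
        hidden_layer_sizes=tuple(hidden), max_iter=hp.pop("max_iter", 200),
        tol=hp.pop("tol", 1e-3), n_iter_no_change=hp.pop("n_iter_no_change", 5),
        random_state=seed, **hp,
    )


def _evaluate(y_true: np.ndarray, y_pred: np.ndarray, n_train: int) -> ModelEval:
    from sklearn.metrics import balanced_accuracy_score, precision_score, recall_score

    classes = [ACTIVE, INACTIVE]
    ba = balanced_accuracy_score(y_true, y_pred)
    precision = {
        c: float(precision_score(y_true, y_pred, pos_label=c, zero_division=np.nan))
        for c in classes
    }
    recall = {
        c: float(recall_score(y_true, y_pred, pos_label=c, zero_division=np.nan))
        for c in classes
    }
    return ModelEval(
        ba=float(ba), precision=precision, recall=recall, n_train=n_train,
        y_true=list(y_true), y_pred=list(y_pred),
    )


def loocv_balanced_accuracy(
    spec: ModelSpec,
    smiles: Sequence[str],
    labels: Sequence[str],
    seed: int = 0,
    X: Optional[np.ndarray] = None,
) -> ModelEval:
    """Leave-one-out predictions aggregated into a single confusion matrix;
    BA = (sensitivity + specificity) / 2."""
    from sklearn.model_selection import LeaveOneOut, cross_val_predict

    y = np.asarray(labels)
    if len(y) < 10:
        raise ValueError("need at least 10 training records")
    if len(set(y)) < 2:
        raise ValueError("training set must contain both classes")
    if X is None:
        X = model_fingerprints(smiles, spec.fingerprint)
    est = build_estimator(spec, seed)
    y_pred = cross_val_predict(est, X, y, cv=LeaveOneOut(), n_jobs=1)
    return _evaluate(y, y_pred, n_train=len(y))


def default_grids() -> dict:
    path = Path(__file__).parent / "data" / "model_grids.yaml"
    return yaml.safe_load(path.read_text())


def _expand_grid(grid: dict) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, combo))
            for combo in itertools.product(*(grid[k] for k in keys))]


def grid_search(
    smiles: Sequence[str],
    labels: Sequence[str],
    grids: Optional[dict] = None,
    algorithms: Optional[Sequence[Algorithm | str]] = None,
    fingerprints: Optional[Sequence[ModelFingerprint | str]] = None,
    seed: int = 0,
) -> list[tuple[ModelSpec, ModelEval]]:
    """Evaluate every algorithm x fingerprint combination by LOO-CV BA.

    Within each combination the best hyperparameter setting wins; ties go
    to the setting declared earlier in the grid.  Returns the leaderboard
    sorted by descending BA (combination order breaks exact ties).
    """
    grids = grids if grids is not None else default_grids()
    algorithms = [Algorithm(a) for a in (algorithms or list(Algorithm))]
    fingerprints = [ModelFingerprint(f) for f in
                    (fingerprints or list(ModelFingerprint))]
    board: list[tuple[ModelSpec, ModelEval]] = []
    for fp in fingerprints:
        X = model_fingerprints(smiles, fp)
        for algo in algorithms:
            grid = grids.get(algo.value, {})
            best: Optional[tuple[ModelSpec, ModelEval]] = None
            for hp in _expand_grid(grid) or [{}]:
                spec = ModelSpec(algo, fp, hp)
                ev = loocv_balanced_accuracy(spec, smiles, labels, seed, X=X)
                if best is None or ev.ba > best[1].ba:
                    best = (spec, ev)
            board.append(best)
    board.sort(key=lambda t: -t[1].ba)
    return board


def dm_distance(query_fp: np.ndarray, train_fps: np.ndarray) -> float:
    """Mean Jaccard distance (1 - Tanimoto) of a query to the training
    compounds; the distance-to-model confidence measure."""
    if len(train_fps) == 0:
        raise ValueError("empty training set")
    q = np.asarray(query_fp, dtype=bool)
    t = np.asarray(train_fps, dtype=bool)
    inter = np.logical_and(q, t).sum(axis=1)
    union = q.sum() + t.sum(axis=1) - inter
    sims = np.where(union == 0, 1.0, inter / np.maximum(union, 1))
    return float(np.mean(1.0 - sims))


def dm_distances(query_fps: np.ndarray, train_fps: np.ndarray) -> np.ndarray:
    return np.array([dm_distance(q, train_fps) for q in query_fps])


@dataclass
class DMBins:
    """Quartile cut points of evaluation DM values plus the largest
    evaluation distance (queries beyond it have unknown confidence)."""

    boundaries: tuple[float, float, float]
    dm_max: float

    def bin(self, dm: float) -> str:
        if dm > self.dm_max:
            return "BEYOND"
        for name, bound in zip(("Q1", "Q2", "Q3"), self.boundaries):
            if dm <= bound:
                return name
        return "Q4"


@dataclass
class DMQuartileReport:
    bins: DMBins
    #: per-quartile dicts with n_active, n_inactive, precision, recall
    rows: dict[str, dict]
    beyond_count: int = 0


def dm_quartile_report(
    eval_records: Sequence[tuple[str, str, float]],
    bins: Optional[DMBins] = None,
) -> DMQuartileReport:
    """Per-quartile precision/recall of the ACTIVE class.

    ``eval_records`` are (true label, predicted label, dm) triples.  With
    no ``bins`` supplied the quartiles are the records' own DM quartiles:
    records are stably sorted by DM and split into four equal-sized groups
    (ties keep input order), so 180 records yield 45 per quartile.
    """
    records = list(eval_records)
    beyond = 0
    if bins is None:
        if len(records) < 4:
            raise ValueError("need at least 4 records to form quartiles")
        dm = np.array([r[2] for r in records])
        order = np.argsort(dm, kind="stable")
        groups = np.array_split(order, 4)
        boundaries = tuple(float(dm[g].max()) for g in groups[:3])
        bins = DMBins(boundaries=boundaries, dm_max=float(dm.max()))
        assignment = {}
        for name, g in zip(("Q1", "Q2", "Q3", "Q4"), groups):
            for i in g:
                assignment[int(i)] = name
        binned = [(records[i][0], records[i][1], assignment[i])
                  for i in range(len(records))]
    else:
        binned = []
        for true, pred, dm_val in records:
            b = bins.bin(dm_val)
            if b == "BEYOND":
                beyond += 1
                continue
            binned.append((true, pred, b))

    rows = {}
    for q in ("Q1", "Q2", "Q3", "Q4"):
        members = [(t, p) for t, p, b in binned if b == q]
        tp = sum(1 for t, p in members if t == ACTIVE and p == ACTIVE)
        fp = sum(1 for t, p in members if t == INACTIVE and p == ACTIVE)
        fn = sum(1 for t, p in members if t == ACTIVE and p == INACTIVE)
        rows[q] = {
            "n_active": sum(1 for t, _ in members if t == ACTIVE),
            "n_inactive": sum(1 for t, _ in members if t == INACTIVE),
            "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
            "recall": tp / (tp + fn) if (tp + fn) else float("nan"),
        }
    return DMQuartileReport(bins=bins, rows=rows, beyond_count=beyond)


def predict_with_confidence(
    model,
    fingerprint: ModelFingerprint | str,
    queries: Sequence[tuple[str, str]],
    train_smiles: Sequence[str],
    bins: DMBins,
) -> pd.DataFrame:
    """Predict labels for (id, smiles) queries with DM confidence bins.

    ``model`` must already be fitted on the full labeled dataset.  DM is
    computed with Morgan fingerprints against the training compounds;
    queries whose DM exceeds the largest evaluation distance are BEYOND.
    """
    ids = [q[0] for q in queries]
    smiles = [q[1] for q in queries]
    X = model_fingerprints(smiles, fingerprint)
    preds = model.predict(X)
    train_morgan = model_fingerprints(train_smiles, ModelFingerprint.MORGAN2_2048)
    query_morgan = model_fingerprints(smiles, ModelFingerprint.MORGAN2_2048)
    dms = dm_distances(query_morgan, train_morgan)
    return pd.DataFrame({
        "id": ids,
        "label": preds,
        "dm": dms,
        "confidence_bin": [bins.bin(d) for d in dms],
    })
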