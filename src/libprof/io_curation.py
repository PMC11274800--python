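"""Reading, writing and standardization of chemical libraries.

The curation protocol mirrors common practice for assembling screening
libraries: structures are cleaned up, reduced to their largest covalent
component, restricted to a whitelist of organic elements, neutralized,
reionized, collapsed to a canonical tautomer and deduplicated on canonical
SMILES.  The whole pass is deterministic and idempotent, so re-curating a
curated library is a no-op.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

#: Elements accepted in curated libraries (organic subset plus B, Si, Se).
ALLOWED_ELEMENTS = frozenset(
    {1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53}
)


class Status(str, enum.Enum):
    RAW = "RAW"
    CURATED = "CURATED"
    REJECTED = "REJECTED"


class RejectionReason(str, enum.Enum):
    PARSE_ERROR = "PARSE_ERROR"
    DISALLOWED_ELEMENT = "DISALLOWED_ELEMENT"
    DUPLICATE = "DUPLICATE"


class LibraryFormat(str, enum.Enum):
    SMILES = "SMILES"
    SDF = "SDF"
    CSV = "CSV"


@dataclass
class MoleculeRecord:
    """One compound tracked through curation."""

    id: str
    source_smiles: str
    canonical_smiles: str = ""
    status: Status = Status.RAW
    rejection_reason: Optional[RejectionReason] = None

    def mol(self) -> Optional[Chem.Mol]:
        """RDKit molecule from the canonical structure (curated records)."""
        if not self.canonical_smiles:
            return None
        return Chem.MolFromSmiles(self.canonical_smiles)


@dataclass
class CurationReport:
    n_input: int = 0
    n_parse_failed: int = 0
    n_multicomponent_reduced: int = 0
    n_element_rejected: int = 0
    n_duplicates_removed: int = 0
    n_output: int = 0
    #: free-form metadata (tautomer rule provenance etc.)
    metadata: dict = field(default_factory=dict)

    def check(self) -> None:
        expected = (
            self.n_input
            - self.n_parse_failed
            - self.n_element_rejected
            - self.n_duplicates_removed
        )
        if self.n_output != expected:
            raise AssertionError(
                f"curation count identity violated: {self.n_output} != {expected}"
            )


def _ordinal_id(index: int, width: int) -> str:
    return str(index).zfill(width)


def read_library(
    path: str | Path,
    format: LibraryFormat | str,
    smiles_column: Optional[str] = None,
    id_column: Optional[str] = None,
) -> list[MoleculeRecord]:
    """Read a library file into RAW records.

    Unparseable individual entries are returned as REJECTED/PARSE_ERROR
    records rather than silently dropped; an unreadable file raises.
    """
    fmt = LibraryFormat(format.upper() if isinstance(format, str) else format)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    entries: list[tuple[Optional[str], str]] = []  # (id or None, smiles)
    if fmt is LibraryFormat.SMILES:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            smiles = parts[0]
            mid = parts[1] if len(parts) > 1 else None
            entries.append((mid, smiles))
    elif fmt is LibraryFormat.CSV:
        smiles_column = smiles_column or "smiles"
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            fields = reader.fieldnames or []
            if smiles_column not in fields:
                raise ValueError(
                    f"CSV {path} has no column {smiles_column!r} (found {fields})"
                )
            idcol = id_column if id_column in fields else (
                "id" if "id" in fields else None
            )
            for row in reader:
                entries.append((row[idcol] if idcol else None, row[smiles_column]))
    elif fmt is LibraryFormat.SDF:
        records: list[MoleculeRecord] = []
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        width = max(4, len(str(len(supplier))))
        for i, mol in enumerate(supplier):
            if mol is None:
                records.append(
                    MoleculeRecord(
                        id=_ordinal_id(i + 1, width),
                        source_smiles="",
                        status=Status.REJECTED,
                        rejection_reason=RejectionReason.PARSE_ERROR,
                    )
                )
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            records.append(
                MoleculeRecord(
                    id=name or _ordinal_id(i + 1, width),
                    source_smiles=Chem.MolToSmiles(mol),
                )
            )
        return records
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown format {format!r}")

    width = max(4, len(str(len(entries))))
    records = []
    for i, (mid, smiles) in enumerate(entries):
        rec = MoleculeRecord(id=mid or _ordinal_id(i + 1, width), source_smiles=smiles)
        if Chem.MolFromSmiles(smiles) is None:
            rec.status = Status.REJECTED
            rec.rejection_reason = RejectionReason.PARSE_ERROR
        records.append(rec)
    return records


# Standardizer singletons; TautomerEnumerator construction is not free.
_UNCHARGER = rdMolStandardize.Uncharger()
_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator()
# stereo-preserving variant for de novo compounds (tautomer canonicalization
# would otherwise drop sp3/double-bond stereo along tautomeric paths)
_STEREO_PARAMS = rdMolStandardize.CleanupParameters()
_STEREO_PARAMS.tautomerRemoveSp3Stereo = False
_STEREO_PARAMS.tautomerRemoveBondStereo = False
_STEREO_TAUTOMERIZER = rdMolStandardize.TautomerEnumerator(_STEREO_PARAMS)


def _largest_fragment(mol: Chem.Mol) -> tuple[Chem.Mol, bool]:
    """Largest covalent component: most heavy atoms, then higher MW, then
    lexicographically smallest canonical SMILES (deterministic tie-break)."""
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol, False
    keyed = [
        (-f.GetNumHeavyAtoms(), -Descriptors.MolWt(f), Chem.MolToSmiles(f), f)
        for f in frags
    ]
    keyed.sort(key=lambda t: t[:3])
    return keyed[0][3], True


def _standardize_one(smiles: str, keep_stereo: bool) -> tuple[Optional[str], bool, bool]:
    """Returns (canonical smiles or None, multicomponent_reduced, element_ok)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None, False, True
    try:
        mol = rdMolStandardize.Cleanup(mol)
        mol, reduced = _largest_fragment(mol)
        Chem.SanitizeMol(mol)
        if any(a.GetAtomicNum() not in ALLOWED_ELEMENTS for a in mol.GetAtoms()):
            return None, reduced, False
        mol = _UNCHARGER.uncharge(mol)
        mol = rdMolStandardize.Reionize(mol)
        if keep_stereo:
            mol = _STEREO_TAUTOMERIZER.Canonicalize(mol)
        else:
            Chem.RemoveStereochemistry(mol)
            mol = _TAUTOMERIZER.Canonicalize(mol)
    except Exception:
        return None, False, True
    return Chem.MolToSmiles(mol), reduced, True


def curate(
    records: Sequence[MoleculeRecord], keep_stereo: bool = False
) -> tuple[list[MoleculeRecord], CurationReport]:
    """Apply the standardization protocol; deterministic and idempotent.

    Element filtering runs after largest-fragment reduction, so an exotic
    counterion never rejects its organic parent.  Duplicates are collapsed on
    exact canonical-SMILES equality, keeping the first occurrence in input
    order.
    """
    report = CurationReport(n_input=len(records))
    report.metadata["tautomer_rules"] = "rdkit rdMolStandardize defaults"
    report.metadata["keep_stereo"] = keep_stereo
    seen: dict[str, str] = {}
    out: list[MoleculeRecord] = []
    for rec in records:
        canonical, reduced, element_ok = _standardize_one(
            rec.source_smiles, keep_stereo
        )
        if reduced:
            report.n_multicomponent_reduced += 1
        if not element_ok:
            out.append(
                MoleculeRecord(
                    rec.id,
                    rec.source_smiles,
                    status=Status.REJECTED,
                    rejection_reason=RejectionReason.DISALLOWED_ELEMENT,
                )
            )
            report.n_element_rejected += 1
            continue
        if canonical is None:
            out.append(
                MoleculeRecord(
                    rec.id,
                    rec.source_smiles,
                    status=Status.REJECTED,
                    rejection_reason=RejectionReason.PARSE_ERROR,
                )
            )
            report.n_parse_failed += 1
            continue
        if canonical in seen:
            out.append(
                MoleculeRecord(
                    rec.id,
                    rec.source_smiles,
                    canonical_smiles=canonical,
                    status=Status.REJECTED,
                    rejection_reason=RejectionReason.DUPLICATE,
                )
            )
            report.n_duplicates_removed += 1
            continue
        seen[canonical] = rec.id
        out.append(
            MoleculeRecord(
                rec.id, rec.source_smiles, canonical_smiles=canonical,
                status=Status.CURATED,
            )
        )
    report.n_output = sum(1 for r in out if r.status is Status.CURATED)
    report.check()
    return out, report


def curated(records: Iterable[MoleculeRecord]) -> list[MoleculeRecord]:
    """The CURATED subset, in order."""
    return [r for r in records if r.status is Status.CURATED]


def write_library(
    records: Sequence[MoleculeRecord],
    path: str | Path,
    format: LibraryFormat | str,
) -> Path:
    """Write CURATED records; round-trips through :func:`read_library`."""
    fmt = LibraryFormat(format.upper() if isinstance(format, str) else format)
    path = Path(path)
    recs = curated(records)
    if fmt is LibraryFormat.SMILES:
        path.write_text(
            "".join(f"{r.canonical_smiles}\t{r.id}\n" for r in recs)
        )
    elif fmt is LibraryFormat.CSV:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "smiles"])
            for r in recs:
                writer.writerow([r.id, r.canonical_smiles])
    elif fmt is LibraryFormat.SDF:
        writer = Chem.SDWriter(str(path))
        for r in recs:
            mol = Chem.MolFromSmiles(r.canonical_smiles)
            mol.SetProp("_Name", r.id)
            writer.write(mol)
        writer.close()
    return path
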