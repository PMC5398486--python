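"""Compound ingestion and activity labeling.

Molecules enter the screening pipeline as SMILES lists, InChI lists, SDF
files or CSV tables; each becomes a :class:`CompoundRecord`.  High-throughput
screens report a percent inhibition per compound, which
:func:`label_by_inhibition` turns into the binary active/inactive labels the
QSAR classifier trains on (active = inhibition strictly above the threshold,
50% by convention).
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.rdBase import BlockLogs

from ._text import clean_inchi, normalize_dashes, parse_number

__all__ = [
    "CompoundRecord",
    "ActivityLabeling",
    "CompoundParseError",
    "read_compounds",
    "label_by_inhibition",
]


class CompoundParseError(ValueError):
    """A structure could not be parsed; carries the entry index."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


@dataclass
class CompoundRecord:
    """One molecule: identifier, structure notation and optional activity.

    ``structure`` holds the notation as given (SMILES or InChI text); ``mol``
    the parsed RDKit molecule.  ``inhibition`` is a percent (may be negative
    for compounds that enhance the readout); ``label`` is ``"active"`` /
    ``"inactive"`` once assigned.
    """

    id: str
    structure: str
    mol: object = field(default=None, repr=False)
    inhibition: float | None = None
    label: str | None = None


@dataclass
class ActivityLabeling:
    """Result of thresholding percent inhibition into binary labels."""

    threshold: float
    n_active: int
    n_inactive: int


def _parse_structure(text: str, index: int):
    """Parse a SMILES or InChI string to an RDKit Mol, raising on failure."""
    with BlockLogs():
        if text.lstrip().lower().startswith("inchi") or text.lstrip().startswith("1S/"):
            mol = Chem.MolFromInchi(clean_inchi(text))
        else:
            mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise CompoundParseError(f"unparseable structure at entry {index}: {text!r}", index)
    return mol


def _read_lines(text: str, kind: str) -> list[CompoundRecord]:
    records = []
    n = 0
    for i, raw in enumerate(text.splitlines()):
        line = raw.strip()
        if not line:
            continue
        n += 1
        if kind == "smiles":
            parts = line.split(None, 1)
            struct, cid = parts[0], (parts[1].strip() if len(parts) > 1 else str(n))
        else:  # one InChI per line; InChI strings contain no spaces once cleaned
            struct, cid = line, str(n)
        mol = _parse_structure(struct, i)
        records.append(CompoundRecord(id=cid, structure=struct, mol=mol))
    return records


def _read_sdf(source: str) -> list[CompoundRecord]:
    supplier = Chem.SDMolSupplier(source, sanitize=True)
    records = []
    for i, mol in enumerate(supplier):
        if mol is None:
            raise CompoundParseError(f"unparseable SDF entry {i}", i)
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else str(i + 1)
        records.append(CompoundRecord(id=cid, structure=Chem.MolToSmiles(mol), mol=mol))
    return records


def _read_csv(text: str) -> list[CompoundRecord]:
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None:
        raise ValueError("CSV input has no header row")
    cols = {c.lower(): c for c in reader.fieldnames}
    struct_col = next((cols[k] for k in ("smiles", "inchi", "structure") if k in cols), None)
    if struct_col is None:
        raise ValueError("CSV needs a 'smiles', 'inchi' or 'structure' column")
    id_col = cols.get("id", reader.fieldnames[0])
    inh_col = next((cols[k] for k in ("inhibition", "inhibition_pct") if k in cols), None)
    records = []
    for i, row in enumerate(reader):
        struct = normalize_dashes(row[struct_col]).strip()
        mol = _parse_structure(struct, i)
        inh = parse_number(row[inh_col]) if inh_col and row[inh_col] not in (None, "") else None
        records.append(CompoundRecord(id=str(row[id_col]).strip(), structure=struct,
                                      mol=mol, inhibition=inh))
    return records


def read_compounds(source: str, format: str) -> list[CompoundRecord]:
    """Read compounds from a file path or literal text.

    Parameters
    ----------
    source : str
        File path, or the text itself for the line-oriented dialects.
    format : {'smiles', 'inchi', 'sdf', 'csv'}
        ``smiles``: one SMILES per line, optional whitespace-separated id.
        ``inchi``: one InChI per line (en-dash tolerant).
        ``sdf``: a V2000 SD file path; ids from the molecule title line.
        ``csv``: header row required; structure column named smiles/inchi.
        Missing ids fall back to the 1-based entry number.

    Raises
    ------
    CompoundParseError
        For an unparseable entry (carries the entry index).
    ValueError
        For an empty input or unknown format.
    """
    if format not in ("smiles", "inchi", "sdf", "csv"):
        raise ValueError(f"unknown format {format!r}")
    if format == "sdf":
        records = _read_sdf(source)
    else:
        text = source
        if os.path.exists(source):
            with open(source, encoding="utf-8") as fh:
                text = fh.read()
        if not text.strip():
            raise ValueError("empty compound input")
        records = _read_lines(text, format) if format in ("smiles", "inchi") else _read_csv(text)
    if not records:
        raise ValueError("empty compound input")
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate compound id {r.id!r}")
        seen.add(r.id)
    return records


def label_by_inhibition(records: list[CompoundRecord], threshold: float = 50.0) -> ActivityLabeling:
    """Assign active/inactive labels by percent inhibition, in place.

    A compound is active iff its inhibition is *strictly* greater than
    ``threshold`` (a value exactly at the threshold is inactive).
    """
    n_active = n_inactive = 0
    for r in records:
        if r.inhibition is None:
            raise ValueError(f"compound {r.id!r} has no inhibition value")
    for r in records:
        if r.inhibition > threshold:
            r.label = "active"
            n_active += 1
        else:
            r.label = "inactive"
            n_inactive += 1
    return ActivityLabeling(threshold=float(threshold), n_active=n_active, n_inactive=n_inactive)
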