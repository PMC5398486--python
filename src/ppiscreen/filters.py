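"""Virtual-screening filters: Tanimoto similarity and PAINS, plus the report.

After the consensus model and the applicability domain have judged a
candidate, two cheminformatics filters annotate it:

- 2D Tanimoto similarity of a hashed path fingerprint (2048 bits, path
  depth 7 by default) against a reference inhibitor, to show whether a
  plain similarity search would have found the same hits;
- a PAINS substructure screen (union of the A/B/C pattern families) to
  flag likely assay-interference compounds.

:func:`build_screen_report` assembles the per-candidate screening table
(id, prediction, reliability, similarity, PAINS flag).
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .compounds import CompoundRecord, _parse_structure

__all__ = [
    "FingerprintScheme",
    "PainsResult",
    "ScreenReportRow",
    "fingerprint",
    "tanimoto",
    "load_pains_catalog",
    "pains_screen",
    "build_screen_report",
    "load_reference_candidates",
]


@dataclass(frozen=True)
class FingerprintScheme:
    """Hashed path (RDKit topological) fingerprint parameters."""

    family: str = "path"
    n_bits: int = 2048
    max_path: int = 7


@dataclass
class BitFingerprint:
    bits: object  # rdkit ExplicitBitVect
    scheme: FingerprintScheme

    def __len__(self) -> int:
        return self.bits.GetNumBits()


@dataclass
class PainsResult:
    flagged: bool
    matched_patterns: list[str] = field(default_factory=list)


@dataclass
class ScreenReportRow:
    """One line of the screening report (one candidate compound)."""

    id: str
    prediction: str          # Active / Inactive
    reliability: str         # Reliable / Unreliable
    tanimoto: float
    pains: str               # Yes / No
    pains_patterns: str = ""


def fingerprint(c: CompoundRecord | str, scheme: FingerprintScheme = FingerprintScheme()
                ) -> BitFingerprint:
    """Hashed path fingerprint of a compound (deterministic per scheme)."""
    if isinstance(c, CompoundRecord):
        mol = c.mol if c.mol is not None else _parse_structure(c.structure, 0)
    else:
        mol = _parse_structure(c, 0)
    bits = Chem.RDKFingerprint(mol, maxPath=scheme.max_path, fpSize=scheme.n_bits)
    return BitFingerprint(bits=bits, scheme=scheme)


def tanimoto(a: BitFingerprint, b: BitFingerprint) -> float:
    """Tanimoto similarity c / (a + b - c) on bit vectors.

    Two all-zero fingerprints are defined as identical (similarity 1).
    """
    if a.scheme != b.scheme:
        raise ValueError("fingerprint schemes differ")
    on_a = a.bits.GetNumOnBits()
    on_b = b.bits.GetNumOnBits()
    if on_a == 0 and on_b == 0:
        return 1.0
    common = len(set(a.bits.GetOnBits()) & set(b.bits.GetOnBits()))
    return common / (on_a + on_b - common)


def load_pains_catalog() -> FilterCatalog:
    """The standard PAINS catalog, union of the A, B and C families."""
    params = FilterCatalogParams()
    params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS)
    return FilterCatalog(params)


def pains_screen(c: CompoundRecord, catalog: FilterCatalog | None = None) -> PainsResult:
    """Screen a compound against PAINS patterns; returns all matched names."""
    if catalog is None:
        catalog = load_pains_catalog()
    mol = c.mol if c.mol is not None else _parse_structure(c.structure, 0)
    matches = [m.GetDescription() for m in catalog.GetMatches(mol)]
    return PainsResult(flagged=bool(matches), matched_patterns=matches)


def build_screen_report(predictions: dict[str, str], reliability: dict[str, str],
                        reference: CompoundRecord, candidates: list[CompoundRecord],
                        scheme: FingerprintScheme = FingerprintScheme(),
                        catalog: FilterCatalog | None = None) -> list[ScreenReportRow]:
    """Assemble the screening report, one row per candidate.

    ``predictions`` and ``reliability`` are keyed by compound id; a missing
    key raises with the offending id.  Similarity is computed against
    ``reference``.
    """
    if catalog is None:
        catalog = load_pains_catalog()
    ref_fp = fingerprint(reference, scheme)
    rows = []
    for c in candidates:
        for table, what in ((predictions, "prediction"), (reliability, "reliability")):
            if c.id not in table:
                raise KeyError(f"no {what} for compound id {c.id!r}")
        pains = pains_screen(c, catalog)
        rows.append(ScreenReportRow(
            id=c.id,
            prediction=predictions[c.id],
            reliability=reliability[c.id],
            tanimoto=tanimoto(fingerprint(c, scheme), ref_fp),
            pains="Yes" if pains.flagged else "No",
            pains_patterns=";".join(pains.matched_patterns),
        ))
    return rows


def write_screen_report(rows: list[ScreenReportRow], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "prediction", "reliability", "tanimoto", "pains", "pains_patterns"])
        for r in rows:
            w.writerow([r.id, r.prediction, r.reliability, f"{r.tanimoto:.4f}",
                        r.pains, r.pains_patterns])


def load_reference_candidates() -> list[dict]:
    """The packaged 30-candidate screening table (plus the SPD304 reference).

    These are the docking-prioritized candidates of the TNF/RANKL screening
    study this package implements, with their published consensus
    prediction, reliability, Tanimoto-to-SPD304 and PAINS annotations.
    InChI strings are stored as printed (including typographic dashes) and
    cleaned on ingestion.
    """
    path = importlib.resources.files("ppiscreen.data") / "screening_candidates.tsv"
    with path.open(encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))
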