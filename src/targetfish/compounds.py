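"""Compound library handling: loading, standardization, stereo expansion, fingerprints.

The library of query molecules (the "chemical space") enters as a SMILES CSV
or an SDF. Every structure is standardized to a canonical parent form (salt
stripping, charge neutralization, canonical SMILES), molecules with
unspecified stereocenters are expanded to all concrete stereoisomers, and
each record is described by two bit-vector fingerprints: a circular
substructure fingerprint of radius 2 (ECFP4-class) and a linear-path
fingerprint of maximum path length 7 (FP2-class).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors, rdFingerprintGenerator
from rdkit.Chem.EnumerateStereoisomers import (
    EnumerateStereoisomers,
    StereoEnumerationOptions,
)
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")

Source = Literal["natural", "semisynthetic", "synthetic", "unknown"]


@dataclass(frozen=True)
class CompoundRecord:
    """One member of the compound library.

    ``parent_id`` points at the pre-expansion entry (itself when the record
    was never expanded), so downstream stages can roll activity of a concrete
    stereoisomer up to the compound it came from.
    """

    compound_id: str
    smiles_input: str
    smiles_canonical: str
    name: str = ""
    parent_id: str = ""
    n_unspecified_centers: int = 0
    source: Source = "unknown"

    def __post_init__(self) -> None:
        if not self.parent_id:
            object.__setattr__(self, "parent_id", self.compound_id)


@dataclass(frozen=True)
class FingerprintConfig:
    """Fingerprint parameters, configured once per library."""

    circular_radius: int = 2
    circular_bits: int = 2048
    path_max_length: int = 7
    path_bits: int = 2048


@dataclass(frozen=True)
class FingerprintSet:
    """Circular (ECFP4-class) and path (FP2-class) bit vectors of one molecule."""

    circular_fp: np.ndarray
    path_fp: np.ndarray


class LibraryError(ValueError):
    """Fatal problem with a compound library file."""


@dataclass
class RejectReport:
    """Input entries that failed to parse or standardize, with reasons."""

    entries: list[tuple[str, str]] = field(default_factory=list)  # (row/id, reason)

    def add(self, row: str, reason: str) -> None:
        self.entries.append((row, reason))

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["row", "reason"])
            w.writerows(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def _canonical(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(mol)


def _count_unspecified_centers(mol: Chem.Mol) -> int:
    """Unspecified tetrahedral centers plus unspecified stereogenic double bonds."""
    si = Chem.FindPotentialStereo(mol)
    return sum(1 for el in si if str(el.specified) == "Unspecified")


_uncharger = rdMolStandardize.Uncharger()


def standardize(record: CompoundRecord) -> CompoundRecord:
    """Standardize one record: keep the largest fragment, neutralize charges,
    canonicalize, and count unspecified stereocenters.

    Largest-fragment rule: most heavy atoms; ties broken by molecular weight,
    then lexicographically by canonical SMILES (deterministic).
    """
    mol = Chem.MolFromSmiles(record.smiles_input)
    if mol is None:
        raise LibraryError(f"unparseable SMILES for {record.compound_id!r}: {record.smiles_input!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=True)
    if not frags:
        raise LibraryError(f"no fragments after parsing {record.compound_id!r}")
    best = max(
        frags,
        key=lambda m: (m.GetNumHeavyAtoms(), Descriptors.MolWt(m), _canonical(m)),
    )
    if best.GetNumAtoms() == 0:
        raise LibraryError(f"zero atoms after salt stripping for {record.compound_id!r}")
    neutral = _uncharger.uncharge(best)
    can = _canonical(neutral)
    # canonicalization must be idempotent; re-parse to assert validity
    mol2 = Chem.MolFromSmiles(can)
    if mol2 is None:  # pragma: no cover - RDKit canonical SMILES always reparse
        raise LibraryError(f"canonical SMILES failed to reparse for {record.compound_id!r}")
    return replace(
        record,
        smiles_canonical=Chem.MolToSmiles(mol2),
        n_unspecified_centers=_count_unspecified_centers(mol2),
    )


def enumerate_stereoisomers(record: CompoundRecord, max_centers: int = 6) -> list[CompoundRecord]:
    """Expand a standardized record into all concrete stereoisomers.

    A record with k unspecified centers (tetrahedral or double-bond) yields up
    to 2^k fully specified records whose ``parent_id`` is the input's
    compound_id; degenerate assignments (meso forms) are deduplicated by
    canonical SMILES. Records with k = 0 are returned unchanged, and records
    with k > ``max_centers`` are passed through unexpanded rather than
    exploding combinatorially.
    """
    k = record.n_unspecified_centers
    if k == 0:
        return [record]
    if k > max_centers:
        return [record]
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    opts = StereoEnumerationOptions(onlyUnassigned=True, unique=True)
    out: list[CompoundRecord] = []
    seen: set[str] = set()
    for i, iso in enumerate(EnumerateStereoisomers(mol, options=opts)):
        can = _canonical(iso)
        if can in seen:
            continue
        seen.add(can)
        out.append(
            CompoundRecord(
                compound_id=f"{record.compound_id}_s{len(out) + 1}",
                smiles_input=record.smiles_input,
                smiles_canonical=can,
                name=record.name,
                parent_id=record.compound_id,
                n_unspecified_centers=0,
                source=record.source,
            )
        )
    return out


def expand_library(records: Iterable[CompoundRecord], max_centers: int = 6) -> list[CompoundRecord]:
    """Stereo-expand every record of a standardized library."""
    out: list[CompoundRecord] = []
    for rec in records:
        out.extend(enumerate_stereoisomers(rec, max_centers=max_centers))
    return out


def load_library(
    path: str | Path,
    format: Literal["smiles-csv", "sdf"] = "smiles-csv",
) -> tuple[list[CompoundRecord], RejectReport]:
    """Load and standardize a compound library from a SMILES CSV or an SDF.

    CSV columns: ``compound_id,smiles[,name,source]``. Unparseable entries go
    to the rejects report instead of being silently dropped; a file with zero
    parseable records, or duplicate compound_ids, is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"library file not found: {path}")
    rejects = RejectReport()
    records: list[CompoundRecord] = []
    if format == "smiles-csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise LibraryError(f"CSV {path} lacks a 'smiles' column")
            for i, row in enumerate(reader, start=2):
                rec = CompoundRecord(
                    compound_id=str(row.get("compound_id") or f"row{i}"),
                    smiles_input=row["smiles"],
                    smiles_canonical="",
                    name=row.get("name", "") or "",
                    source=(row.get("source") or "unknown"),  # type: ignore[arg-type]
                )
                try:
                    records.append(standardize(rec))
                except LibraryError as exc:
                    rejects.add(f"row {i}", str(exc))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier, start=1):
            if mol is None:
                rejects.add(f"record {i}", "unparseable SDF record")
                continue
            cid = mol.GetProp("compound_id") if mol.HasProp("compound_id") else f"sdf{i}"
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            rec = CompoundRecord(
                compound_id=cid,
                smiles_input=Chem.MolToSmiles(mol),
                smiles_canonical="",
                name=name,
            )
            try:
                records.append(standardize(rec))
            except LibraryError as exc:
                rejects.add(f"record {i}", str(exc))
    else:  # pragma: no cover - guarded by Literal type
        raise LibraryError(f"unknown format {format!r}")
    if not records:
        raise LibraryError(f"no parseable records in {path}")
    ids = [r.compound_id for r in records]
    dupes = sorted({c for c in ids if ids.count(c) > 1})
    if dupes:
        raise LibraryError(f"duplicate compound_id values: {', '.join(dupes)}")
    return records, rejects


def write_library(records: Iterable[CompoundRecord], path: str | Path) -> None:
    """Write records back to the CSV dialect read by :func:`load_library`."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "smiles", "name", "source"])
        for r in records:
            w.writerow([r.compound_id, r.smiles_canonical, r.name, r.source])


def write_sdf(records: Iterable[CompoundRecord], path: str | Path) -> None:
    with Chem.SDWriter(str(path)) as writer:
        for r in records:
            mol = Chem.MolFromSmiles(r.smiles_canonical)
            mol.SetProp("compound_id", r.compound_id)
            mol.SetProp("_Name", r.name or r.compound_id)
            writer.write(mol)


def _bitvect_to_array(bv) -> np.ndarray:
    arr = np.zeros(bv.GetNumBits(), dtype=np.uint8)
    for b in bv.GetOnBits():
        arr[b] = 1
    return arr


def fingerprint(record: CompoundRecord, config: FingerprintConfig = FingerprintConfig()) -> FingerprintSet:
    """Compute the circular and path fingerprints of a standardized record.

    Pure function of the canonical structure: the same canonical SMILES always
    yields bit-identical vectors.
    """
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None:
        raise LibraryError(f"record {record.compound_id!r} has no valid canonical SMILES; standardize first")
    morgan = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.circular_radius, fpSize=config.circular_bits
    )
    rdk = rdFingerprintGenerator.GetRDKitFPGenerator(
        maxPath=config.path_max_length, fpSize=config.path_bits
    )
    return FingerprintSet(
        circular_fp=_bitvect_to_array(morgan.GetFingerprint(mol)),
        path_fp=_bitvect_to_array(rdk.GetFingerprint(mol)),
    )


def fingerprint_matrix(
    records: Iterable[CompoundRecord],
    config: FingerprintConfig = FingerprintConfig(),
    kind: Literal["circular", "path"] = "circular",
) -> np.ndarray:
    """Stack fingerprints of many records into an (n, bits) uint8 matrix."""
    fps = [fingerprint(r, config) for r in records]
    key = "circular_fp" if kind == "circular" else "path_fp"
    if not fps:
        bits = config.circular_bits if kind == "circular" else config.path_bits
        return np.zeros((0, bits), dtype=np.uint8)
    return np.stack([getattr(f, key) for f in fps]).astype(np.uint8)
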