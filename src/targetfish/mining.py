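"""Known-bioactivity mining: build the "known biological space".

Each library compound is resolved to a database compound identifier (CID),
its *active*-flagged assay records (AIDs) are collected, assays that do not
map to exactly one protein are dropped (the single-protein rule removes
cell-based and panel assays), gene names are annotated with protein entry
names and human pathway memberships, and surviving records are aggregated to
compound-target interactions whose integer weight counts the supporting
assay records. The result exports as a SIF network plus edge attributes.

Two backends implement the lookup contract: a local fixture backend reading
four CSV tables (used by all tests), and a live REST client over the public
PubChem/UniProt-style endpoints (integration use only; rate-limited with
retries).
"""

from __future__ import annotations

import csv
import json
import time
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

from rdkit import Chem


@dataclass
class InteractionRecord:
    """One mined compound-target interaction with its supporting evidence."""

    compound_id: str
    target_id: str
    weight: int
    assay_ids: list[str] = field(default_factory=list)
    protein_entry: str | None = None
    pathways: list[str] = field(default_factory=list)


@dataclass
class KnownSpace:
    """All mined interactions of a library, plus unresolved compounds."""

    records: list[InteractionRecord] = field(default_factory=list)
    resolution_failures: list[str] = field(default_factory=list)

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.compound_id, r.target_id) for r in self.records}

    @property
    def total_weight(self) -> int:
        return sum(r.weight for r in self.records)


class MiningBackend(Protocol):
    """Lookup contract for the bioactivity databases."""

    def resolve_compound(self, smiles: str) -> str | None: ...

    def active_assays(self, compound_id: str) -> list[tuple[str, list[str]]]:
        """(assay_id, gene_names) pairs for assays flagged active."""
        ...

    def protein_entry(self, gene: str) -> str | None: ...

    def pathways(self, protein_entry: str) -> list[str]: ...


class FixtureBackend:
    """Backend over four local CSV tables (memoized by construction).

    Tables:
      structures.csv : ``smiles_canonical,cid``
      assays.csv     : ``cid,aid,activity_flag,gene_names`` (semicolon-joined genes)
      proteins.csv   : ``gene,protein_entry``
      pathways.csv   : ``protein_entry,pathway``
    """

    def __init__(self, directory: str | Path):
        d = Path(directory)
        self._cid: dict[str, str] = {}
        with open(d / "structures.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                self._cid[row["smiles_canonical"]] = row["cid"]
        self._assays: dict[str, list[tuple[str, str, list[str]]]] = {}
        with open(d / "assays.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                genes = [g for g in row["gene_names"].split(";") if g]
                self._assays.setdefault(row["cid"], []).append(
                    (row["aid"], row["activity_flag"], genes)
                )
        self._protein: dict[str, str] = {}
        with open(d / "proteins.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                self._protein[row["gene"]] = row["protein_entry"]
        self._pathways: dict[str, list[str]] = {}
        with open(d / "pathways.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                self._pathways.setdefault(row["protein_entry"], []).append(row["pathway"])

    def resolve_compound(self, smiles: str) -> str | None:
        return self._cid.get(smiles)

    def active_assays(self, compound_id: str) -> list[tuple[str, list[str]]]:
        return [
            (aid, genes)
            for aid, flag, genes in self._assays.get(compound_id, [])
            if flag.lower() == "active"
        ]

    def protein_entry(self, gene: str) -> str | None:
        return self._protein.get(gene)

    def pathways(self, protein_entry: str) -> list[str]:
        return list(self._pathways.get(protein_entry, []))


class RestBackend:
    """Live REST client (integration use only; tests use FixtureBackend).

    Polite by construction: at most ``rate`` requests per second, and each
    request is retried up to ``retries`` times with exponential backoff.
    Responses are memoized for the session so repeated queries are pure.
    """

    def __init__(
        self,
        base_url: str = "https://pubchem.ncbi.nlm.nih.gov/rest/pug",
        rate: float = 5.0,
        retries: int = 3,
    ):
        self.base_url = base_url.rstrip("/")
        self.min_interval = 1.0 / rate
        self.retries = retries
        self._last_request = 0.0
        self._cache: dict[str, object] = {}

    def _get(self, url: str):
        if url in self._cache:
            return self._cache[url]
        delay = 1.0
        for attempt in range(self.retries):
            wait = self.min_interval - (time.monotonic() - self._last_request)
            if wait > 0:
                time.sleep(wait)
            try:
                self._last_request = time.monotonic()
                with urllib.request.urlopen(url, timeout=30) as resp:
                    data = json.loads(resp.read().decode())
                self._cache[url] = data
                return data
            except Exception:
                if attempt == self.retries - 1:
                    raise
                time.sleep(delay)
                delay *= 2
        raise RuntimeError("unreachable")  # pragma: no cover

    def resolve_compound(self, smiles: str) -> str | None:
        q = urllib.parse.quote(smiles, safe="")
        try:
            data = self._get(f"{self.base_url}/compound/smiles/{q}/cids/JSON")
        except Exception:
            return None
        cids = data.get("IdentifierList", {}).get("CID", [])
        return str(cids[0]) if cids else None

    def active_assays(self, compound_id: str) -> list[tuple[str, list[str]]]:
        try:
            data = self._get(
                f"{self.base_url}/compound/cid/{compound_id}/assaysummary/JSON"
            )
        except Exception:
            return []
        out: dict[str, set[str]] = {}
        rows = data.get("Table", {}).get("Row", [])
        cols = data.get("Table", {}).get("Columns", {}).get("Column", [])
        idx = {name: i for i, name in enumerate(cols)}
        for row in rows:
            cell = row.get("Cell", [])
            if idx and cell:
                outcome = cell[idx.get("Activity Outcome", -1)]
                if str(outcome).lower() != "active":
                    continue
                aid = str(cell[idx.get("AID", 0)])
                gene = str(cell[idx.get("Target GeneID", idx.get("GeneID", 0))])
                if gene:
                    out.setdefault(aid, set()).add(gene)
        return [(aid, sorted(genes)) for aid, genes in sorted(out.items())]

    def protein_entry(self, gene: str) -> str | None:  # pragma: no cover - network
        try:
            data = self._get(
                "https://rest.uniprot.org/uniprotkb/search?query="
                + urllib.parse.quote(f"gene:{gene} AND organism_id:9606")
                + "&fields=id&format=json&size=1"
            )
            results = data.get("results", [])
            return results[0]["uniProtkbId"] if results else None
        except Exception:
            return None

    def pathways(self, protein_entry: str) -> list[str]:  # pragma: no cover - network
        return []


class MiningError(RuntimeError):
    """Total mining failure (e.g., no compound resolved at all)."""


def resolve_compound(smiles: str, backend: MiningBackend) -> str | None:
    """Resolve a canonical SMILES to a database compound identifier.

    The SMILES is re-canonicalized before lookup so that different spellings
    of one molecule hit the same table row. Failures are reported, not fatal.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is not None:
        smiles = Chem.MolToSmiles(mol)
    return backend.resolve_compound(smiles)


def fetch_active_interactions(
    compound_id: str, backend: MiningBackend
) -> list[tuple[str, str]]:
    """(assay_id, gene) pairs for active assays mapping to exactly one protein."""
    out = []
    for aid, genes in backend.active_assays(compound_id):
        if len(genes) == 1:
            out.append((aid, genes[0]))
    return out


def annotate(records: list[InteractionRecord], backend: MiningBackend) -> list[InteractionRecord]:
    """Fill protein entries and human pathway lists; missing mappings stay absent."""
    for rec in records:
        entry = backend.protein_entry(rec.target_id)
        if entry is not None:
            rec.protein_entry = entry
            rec.pathways = backend.pathways(entry)
    return records


def build_known_space(
    library,
    backend: MiningBackend,
    roll_up_parents: bool = True,
) -> KnownSpace:
    """Mine the known biological space of a standardized compound library.

    Aggregates (compound, target) interactions with weight = number of
    distinct supporting active single-protein assay records. Activity found
    for a stereo-expanded record is also attributed to its parent compound
    (``roll_up_parents``), since subtraction from the predicted space happens
    at the compound level.
    """
    space = KnownSpace()
    agg: dict[tuple[str, str], set[str]] = {}
    resolved_any = False
    for rec in library:
        cid = resolve_compound(rec.smiles_canonical, backend)
        if cid is None:
            space.resolution_failures.append(rec.compound_id)
            continue
        resolved_any = True
        owners = {rec.compound_id}
        if roll_up_parents and rec.parent_id and rec.parent_id != rec.compound_id:
            owners.add(rec.parent_id)
        for aid, gene in fetch_active_interactions(cid, backend):
            for owner in owners:
                agg.setdefault((owner, gene.upper()), set()).add(aid)
    if not resolved_any:
        raise MiningError("no compound in the library could be resolved")
    for (compound_id, target_id), aids in sorted(agg.items()):
        space.records.append(
            InteractionRecord(
                compound_id=compound_id,
                target_id=target_id,
                weight=len(aids),
                assay_ids=sorted(aids),
            )
        )
    annotate(space.records, backend)
    return space


def export_sif(space: KnownSpace, path: str | Path, relation: str = "binds") -> None:
    """Write the known space as a SIF network plus an edge-attribute CSV.

    The SIF file has one tab-separated ``compound relation target`` line per
    interaction; the companion ``<path>.attrs.csv`` carries the weights.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for rec in space.records:
            fh.write(f"{rec.compound_id}\t{relation}\t{rec.target_id}\n")
    with open(path.with_suffix(path.suffix + ".attrs.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "target_id", "weight"])
        for rec in space.records:
            w.writerow([rec.compound_id, rec.target_id, rec.weight])


def import_sif(path: str | Path, relation: str = "binds") -> KnownSpace:
    """Re-read an exported SIF + attribute pair back into a KnownSpace."""
    path = Path(path)
    weights: dict[tuple[str, str], int] = {}
    with open(path.with_suffix(path.suffix + ".attrs.csv"), newline="") as fh:
        for row in csv.DictReader(fh):
            weights[(row["compound_id"], row["target_id"])] = int(row["weight"])
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cid, rel, tid = line.split("\t")
            records.append(
                InteractionRecord(
                    compound_id=cid, target_id=tid, weight=weights.get((cid, tid), 1)
                )
            )
    return KnownSpace(records=records)


def write_known_space_csv(space: KnownSpace, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "target_id", "weight"])
        for rec in space.records:
            w.writerow([rec.compound_id, rec.target_id, rec.weight])


def read_known_space_csv(path: str | Path) -> KnownSpace:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                InteractionRecord(
                    compound_id=row["compound_id"],
                    target_id=row["target_id"],
                    weight=int(row["weight"]),
                )
            )
    return KnownSpace(records=records)
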