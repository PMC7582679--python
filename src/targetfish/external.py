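"""Ingestion of external prediction matrices.

Prediction channels the pipeline does not compute itself - an in-house
pharmacophore-database screen, or saved downloads from web servers - enter
as CSV matrices, either wide (compounds x targets grid, blank = no
prediction) or long (``compound_id,target_id,score`` rows). Each matrix
carries its score semantics (lower_better for E-values, higher_better for
probabilities and pharmacophore fit scores, or already boolean), and exactly
one matrix per consensus run is the *anchor*: the channel whose positive hit
is mandatory for a pair to be eligible.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

FitSemantics = Literal["lower_better", "higher_better", "boolean"]


@dataclass
class PredictionMatrix:
    """Sparse (compound_id, target_id) -> score assertions from one method."""

    method_name: str
    entries: dict[tuple[str, str], float]
    fit_semantics: FitSemantics
    is_anchor: bool = False
    # semantics of the retained scores after binarization, for rank-based
    # evaluation (enrichment); equals fit_semantics until binarize() is called
    rank_semantics: FitSemantics = ""  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.rank_semantics:
            self.rank_semantics = self.fit_semantics

    @property
    def n_entries(self) -> int:
        return len(self.entries)


@dataclass
class TargetAliasTable:
    """Free-text target labels -> canonical gene-symbol-like target ids.

    Matching is case-insensitive; canonical ids are stored uppercase.
    Labels not present in the table map to their own uppercased form only if
    ``strict`` is disabled at harmonization time - by default an unmapped
    label is a hard error.
    """

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {k.upper(): v.upper() for k, v in self.mapping.items()}

    def resolve(self, label: str) -> str | None:
        return self.mapping.get(label.upper())

    @classmethod
    def from_csv(cls, path: str | Path) -> "TargetAliasTable":
        mapping = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                mapping[row["label"]] = row["target_id"]
        return cls(mapping=mapping)

    @classmethod
    def identity(cls, labels) -> "TargetAliasTable":
        return cls(mapping={l: l for l in labels})


class MatrixError(ValueError):
    """Fatal problem with an external prediction matrix."""


def _is_blank(s: str) -> bool:
    s = s.strip().lower()
    if s in ("", "nan", "na", "none"):
        return True
    try:
        return math.isnan(float(s))
    except ValueError:
        return False


def read_matrix(
    path: str | Path,
    layout: Literal["wide", "long"],
    method_name: str,
    fit_semantics: FitSemantics,
    is_anchor: bool = False,
) -> PredictionMatrix:
    """Read a prediction matrix CSV in wide or long layout.

    Blank or "nan" cells mean *no prediction* and create no entry. Duplicate
    (compound, target) rows with conflicting scores are fatal; duplicates
    with equal scores are deduplicated.
    """
    path = Path(path)
    entries: dict[tuple[str, str], float] = {}

    def put(cid: str, tid: str, score: float) -> None:
        key = (cid, tid)
        if key in entries and entries[key] != score:
            raise MatrixError(
                f"{path}: conflicting duplicate scores for {key}: {entries[key]} vs {score}"
            )
        entries[key] = score

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise MatrixError(f"{path}: empty matrix file")
        if layout == "long":
            idx = {name: i for i, name in enumerate(header)}
            for col in ("compound_id", "target_id", "score"):
                if col not in idx:
                    raise MatrixError(f"{path}: long layout requires column {col!r}")
            for row in reader:
                if _is_blank(row[idx["score"]]):
                    continue
                put(row[idx["compound_id"]], row[idx["target_id"]], float(row[idx["score"]]))
        else:
            targets = header[1:]
            for row in reader:
                cid = row[0]
                for tid, cell in zip(targets, row[1:]):
                    if _is_blank(cell):
                        continue
                    put(cid, tid, float(cell))
    return PredictionMatrix(
        method_name=method_name,
        entries=entries,
        fit_semantics=fit_semantics,
        is_anchor=is_anchor,
    )


def binarize(matrix: PredictionMatrix, cutoff: float) -> PredictionMatrix:
    """Keep entries meeting the cutoff and mark the matrix boolean.

    lower_better keeps score <= cutoff; higher_better keeps score >= cutoff.
    Retained entries keep their numeric scores (with the original semantics
    recorded in ``rank_semantics``) so that rank-based evaluation can still
    order them. Idempotent; never creates entries.
    """
    if matrix.fit_semantics == "boolean":
        return matrix
    if matrix.fit_semantics == "lower_better":
        kept = {k: v for k, v in matrix.entries.items() if v <= cutoff}
    else:
        kept = {k: v for k, v in matrix.entries.items() if v >= cutoff}
    return PredictionMatrix(
        method_name=matrix.method_name,
        entries=kept,
        fit_semantics="boolean",
        is_anchor=matrix.is_anchor,
        rank_semantics=matrix.fit_semantics,
    )


def harmonize_targets(
    matrices: list[PredictionMatrix],
    aliases: TargetAliasTable,
) -> list[PredictionMatrix]:
    """Map every target label to its canonical id across all matrices.

    Entries of one method that collapse onto the same canonical target merge
    by best score (min for lower_better, max otherwise). Any label absent
    from the alias table is a hard error listing all offenders.
    """
    unmapped: set[str] = set()
    for m in matrices:
        for _, tid in m.entries:
            if aliases.resolve(tid) is None:
                unmapped.add(tid)
    if unmapped:
        raise MatrixError(f"unmapped target labels: {', '.join(sorted(unmapped))}")
    out = []
    for m in matrices:
        better = min if m.rank_semantics == "lower_better" else max
        merged: dict[tuple[str, str], float] = {}
        for (cid, tid), score in m.entries.items():
            key = (cid, aliases.resolve(tid))
            merged[key] = score if key not in merged else better(merged[key], score)
        out.append(replace(m, entries=merged))
    return out


def write_matrix_long(matrix: PredictionMatrix, path: str | Path) -> None:
    """Write a matrix in long CSV layout (deterministic row order)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "target_id", "score"])
        for (cid, tid), score in sorted(matrix.entries.items()):
            w.writerow([cid, tid, f"{score:.10g}"])
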