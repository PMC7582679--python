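"""Consensus scoring, target ranking/selection, enrichment, and activity calls.

The boolean prediction matrices of all channels are merged into one
"predicted biological space": each (compound, target) pair asserted by at
least one method becomes a record whose consensus score CS counts the
asserting methods, the anchor channel included - a pair predicted by the
anchor plus two servers has CS = 3. A pair is *eligible* only when the
anchor method itself asserts it and CS reaches the configured minimum.
Known interactions mined from assay databases are subtracted; what remains
is the "unknown biological space" from which targets are selected by four
criteria: (I) high-CS hits on the assay panel compounds, (II) high frequency
across the whole library, (III) biological consistency (shared pathways with
other predicted or known targets) and novelty, (IV) availability of a
suitable assay.

Assay results are classified with the activity rule: a mean inhibition is
active iff it is >= 30% (in particular positive) and its relative standard
deviation 100*sd/|mean| is <= 20%; negative means and noisy replicates are
ambiguous and therefore inactive.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from targetfish.external import PredictionMatrix
from targetfish.mining import KnownSpace

ACTIVITY_MEAN_CUTOFF = 30.0  # percent inhibition
ACTIVITY_RELATIVE_SD_CUTOFF = 20.0  # percent of the mean


@dataclass
class ConsensusRecord:
    """One (compound, target) pair with its per-method support."""

    compound_id: str
    target_id: str
    methods_predicting: frozenset[str]
    anchor_hit: bool
    eligible: bool

    @property
    def cs(self) -> int:
        return len(self.methods_predicting)


@dataclass
class TargetRanking:
    """Frequency rank of one target at one CS level."""

    target_id: str
    cs_level: int
    frequency: int
    rank: int


@dataclass
class AssayCall:
    """Activity call for one assayed (compound, target) pair."""

    compound_id: str
    target_id: str
    mean_inhibition_pct: float
    sd_pct: float
    call: str  # "active" | "inactive"


class ConsensusError(ValueError):
    """Fatal configuration problem in the consensus stage."""


def assemble_predicted_space(
    matrices: Sequence[PredictionMatrix],
    min_cs: int = 2,
) -> list[ConsensusRecord]:
    """Merge binarized, harmonized matrices into consensus records.

    Exactly one matrix must be the anchor. Every pair asserted by >= 1 method
    yields a record; ``eligible`` requires an anchor hit and cs >= min_cs.
    """
    anchors = [m for m in matrices if m.is_anchor]
    if len(anchors) != 1:
        raise ConsensusError(f"exactly one anchor matrix required, got {len(anchors)}")
    non_bool = [m.method_name for m in matrices if m.fit_semantics != "boolean"]
    if non_bool:
        raise ConsensusError(f"matrices not binarized: {', '.join(non_bool)}")
    anchor_name = anchors[0].method_name
    methods_by_pair: dict[tuple[str, str], set[str]] = {}
    for m in matrices:
        for pair in m.entries:
            methods_by_pair.setdefault(pair, set()).add(m.method_name)
    records = []
    for (cid, tid), methods in sorted(methods_by_pair.items()):
        anchor_hit = anchor_name in methods
        records.append(
            ConsensusRecord(
                compound_id=cid,
                target_id=tid,
                methods_predicting=frozenset(methods),
                anchor_hit=anchor_hit,
                eligible=anchor_hit and len(methods) >= min_cs,
            )
        )
    return records


def subtract_known(
    records: Sequence[ConsensusRecord],
    known: KnownSpace,
    parent_of: Mapping[str, str] | None = None,
) -> list[ConsensusRecord]:
    """Remove predictions already present in the known space (idempotent).

    A record is removed when its own (compound, target) pair - or its parent
    compound's pair, when a ``parent_of`` mapping is supplied - is known.
    """
    known_pairs = known.pairs()

    def is_known(rec: ConsensusRecord) -> bool:
        if (rec.compound_id, rec.target_id) in known_pairs:
            return True
        if parent_of:
            parent = parent_of.get(rec.compound_id)
            if parent and (parent, rec.target_id) in known_pairs:
                return True
        return False

    return [r for r in records if not is_known(r)]


def criterion_panel_hits(
    records: Sequence[ConsensusRecord],
    panel: Sequence[str],
    min_cs: int = 2,
) -> dict[str, list[tuple[str, int]]]:
    """Criterion I: per-target eligible hits among the assay panel compounds.

    Only records of panel compounds that carry an anchor hit and cs >= min_cs
    count. Returns target_id -> [(compound_id, cs), ...] sorted by compound.
    """
    if not panel:
        raise ConsensusError("empty panel")
    panel_set = set(panel)
    out: dict[str, list[tuple[str, int]]] = {}
    for rec in records:
        if rec.compound_id in panel_set and rec.anchor_hit and rec.cs >= min_cs:
            out.setdefault(rec.target_id, []).append((rec.compound_id, rec.cs))
    return {t: sorted(v) for t, v in sorted(out.items())}


def criterion_ranking(
    records: Sequence[ConsensusRecord],
    cs_levels: Iterable[int] = (2, 3),
) -> list[TargetRanking]:
    """Criterion II: rank targets by how many library compounds reach each CS level.

    A compound counts for a target at level k when it has an eligible record
    with cs >= k. Ties share the lower rank number (competition ranking) and
    are listed lexicographically.
    """
    out: list[TargetRanking] = []
    for level in cs_levels:
        freq: dict[str, set[str]] = {}
        for rec in records:
            if rec.eligible and rec.cs >= level:
                freq.setdefault(rec.target_id, set()).add(rec.compound_id)
        ranked = sorted(freq.items(), key=lambda kv: (-len(kv[1]), kv[0]))
        rank = 0
        prev_freq = None
        for pos, (tid, compounds) in enumerate(ranked, start=1):
            n = len(compounds)
            if n != prev_freq:
                rank = pos
                prev_freq = n
            out.append(TargetRanking(target_id=tid, cs_level=level, frequency=n, rank=rank))
    return out


def criterion_consistency(
    records: Sequence[ConsensusRecord],
    known: KnownSpace,
    pathway_annotations: Mapping[str, Sequence[str]],
    panel: Sequence[str] | None = None,
) -> dict[str, dict]:
    """Criterion III: per-target pathway consistency evidence and novelty.

    For every predicted target: ``novelty`` is True when no panel compound
    (or, without a panel, no compound at all) has a known interaction with
    it, and ``related_targets`` lists the other predicted or known targets
    sharing at least one pathway name.
    """
    predicted_targets = sorted({r.target_id for r in records})
    known_targets = sorted({r.target_id for r in known.records})
    candidates = set(predicted_targets) | set(known_targets)
    panel_set = set(panel) if panel is not None else None
    known_by_target: dict[str, set[str]] = {}
    for rec in known.records:
        known_by_target.setdefault(rec.target_id, set()).add(rec.compound_id)
    out = {}
    for tid in predicted_targets:
        my_paths = set(pathway_annotations.get(tid, ()))
        related = sorted(
            other
            for other in candidates
            if other != tid and my_paths & set(pathway_annotations.get(other, ()))
        )
        known_compounds = known_by_target.get(tid, set())
        if panel_set is not None:
            known_compounds = known_compounds & panel_set
        out[tid] = {"novelty": not known_compounds, "related_targets": related}
    return out


def build_selection_report(
    records: Sequence[ConsensusRecord],
    known: KnownSpace,
    pathway_annotations: Mapping[str, Sequence[str]],
    assay_available: Mapping[str, bool],
    panel: Sequence[str],
    min_cs: int = 2,
    cs_levels: Iterable[int] = (2, 3),
) -> dict[str, dict]:
    """Assemble the per-target criteria I-IV report with the final selection flag.

    ``selected`` is True only when an assay is available (criterion IV) and
    the target is novel (part of criterion III); the remaining criteria are
    reported as evidence for human judgment, not thresholded automatically.
    """
    hits = criterion_panel_hits(records, panel, min_cs=min_cs)
    rankings = criterion_ranking(records, cs_levels=cs_levels)
    consistency = criterion_consistency(records, known, pathway_annotations, panel=panel)
    ranks_by_target: dict[str, dict[int, tuple[int, int]]] = {}
    for tr in rankings:
        ranks_by_target.setdefault(tr.target_id, {})[tr.cs_level] = (tr.rank, tr.frequency)
    report = {}
    for tid in sorted({r.target_id for r in records}):
        cons = consistency.get(tid, {"novelty": True, "related_targets": []})
        available = bool(assay_available.get(tid, False))
        report[tid] = {
            "criterion_I_hits": hits.get(tid, []),
            "criterion_II_ranks": {
                str(level): {"rank": rk, "frequency": fr}
                for level, (rk, fr) in sorted(ranks_by_target.get(tid, {}).items())
            },
            "criterion_III": cons,
            "criterion_IV_assay_available": available,
            "selected": available and cons["novelty"],
        }
    return report


def write_selection_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def _method_goodness(matrix: PredictionMatrix) -> dict[tuple[str, str], float]:
    """Within-method goodness in (0, 1]: best entry 1.0, worst near 0."""
    reverse = matrix.rank_semantics != "lower_better"
    ordered = sorted(matrix.entries.items(), key=lambda kv: (kv[1] if not reverse else -kv[1], kv[0]))
    n = len(ordered)
    return {pair: 1.0 - i / n for i, (pair, _) in enumerate(ordered)}


def _ef(ranked_pairs: list[tuple[str, str]], known_pairs: set, universe: int, top_k: int) -> float:
    top = set(ranked_pairs[:top_k])
    recoverable = len(known_pairs)
    if recoverable == 0:
        return 0.0
    frac = len(top & known_pairs) / recoverable
    expected = top_k / universe
    return frac / expected


def enrichment(
    matrices: Sequence[PredictionMatrix],
    known: KnownSpace,
    top_k: int,
) -> dict[str, float]:
    """Known-interaction recovery test: enrichment factor per method and consensus.

    Known subtraction is *not* applied here - the point is whether each
    ranking recovers the known pairs. The prediction universe is every pair
    asserted by at least one method; EF = (fraction of recoverable known
    pairs in the top_k of a ranking) / (top_k / universe size), i.e. the
    fold improvement over a uniformly random ranking. The consensus ranking
    orders pairs by (cs, best per-method rank goodness) descending.
    """
    if not known.records:
        raise ConsensusError("known space is empty; enrichment undefined")
    universe_pairs = set()
    for m in matrices:
        universe_pairs.update(m.entries)
    universe = len(universe_pairs)
    if universe == 0:
        raise ConsensusError("no predictions loaded")
    known_pairs = known.pairs() & universe_pairs
    if not known_pairs:
        raise ConsensusError("no known pair lies in the prediction universe")

    out: dict[str, float] = {}
    for m in matrices:
        goodness = _method_goodness(m)
        ranked = sorted(m.entries, key=lambda p: (-goodness[p], p))
        out[m.method_name] = _ef(ranked, known_pairs, universe, top_k)

    support: dict[tuple[str, str], int] = {}
    best: dict[tuple[str, str], float] = {}
    for m in matrices:
        goodness = _method_goodness(m)
        for pair in m.entries:
            support[pair] = support.get(pair, 0) + 1
            best[pair] = max(best.get(pair, 0.0), goodness[pair])
    ranked = sorted(universe_pairs, key=lambda p: (-support[p], -best[p], p))
    out["consensus"] = _ef(ranked, known_pairs, universe, top_k)
    return out


def classify_assay_results(
    table: Sequence[tuple[str, str, float, float]],
) -> list[AssayCall]:
    """Apply the activity rule to (compound, target, mean, sd) percent rows.

    active iff mean >= 30, mean > 0, and 100*sd/|mean| <= 20; anything else
    (weak, negative, or noisy) is inactive. A negative sd is fatal.
    """
    calls = []
    for cid, tid, mean, sd in table:
        if sd < 0:
            raise ConsensusError(f"negative standard deviation for ({cid}, {tid})")
        active = (
            mean >= ACTIVITY_MEAN_CUTOFF
            and mean > 0
            and 100.0 * sd / abs(mean) <= ACTIVITY_RELATIVE_SD_CUTOFF
        )
        calls.append(
            AssayCall(
                compound_id=cid,
                target_id=tid,
                mean_inhibition_pct=mean,
                sd_pct=sd,
                call="active" if active else "inactive",
            )
        )
    return calls


def confirmed_target_count(calls: Sequence[AssayCall]) -> int:
    """Number of distinct targets with at least one active call."""
    return len({c.target_id for c in calls if c.call == "active"})


def read_assay_table(path: str | Path) -> list[tuple[str, str, float, float]]:
    """Read an assay CSV ``compound_id,target_id,mean,sd``."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            rows.append(
                (row["compound_id"], row["target_id"], float(row["mean"]), float(row["sd"]))
            )
    return rows


def write_assay_calls(calls: Sequence[AssayCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "target_id", "mean", "sd", "call"])
        for c in calls:
            w.writerow([c.compound_id, c.target_id, c.mean_inhibition_pct, c.sd_pct, c.call])


def write_consensus_csv(records: Sequence[ConsensusRecord], path: str | Path) -> None:
    """Write consensus records: ``compound_id,target_id,cs,anchor_hit,methods,eligible``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "target_id", "cs", "anchor_hit", "methods", "eligible"])
        for r in records:
            w.writerow(
                [
                    r.compound_id,
                    r.target_id,
                    r.cs,
                    int(r.anchor_hit),
                    ";".join(sorted(r.methods_predicting)),
                    int(r.eligible),
                ]
            )


def write_ranking_csv(rankings: Sequence[TargetRanking], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["cs_level", "rank", "target_id", "frequency"])
        for tr in sorted(rankings, key=lambda t: (t.cs_level, t.rank, t.target_id)):
            w.writerow([tr.cs_level, tr.rank, tr.target_id, tr.frequency])
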