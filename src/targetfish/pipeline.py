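"""Stage orchestration: composable pipeline stages with manifests.

Stages (in workflow order): ``simulate`` (emit the synthetic fixture),
``fingerprint`` (standardize + fingerprint the library), ``calibrate`` (fit
the random-ensemble background), ``predict`` (similarity-ensemble channel),
``mine`` (known biological space), ``consensus`` (assemble, subtract, score,
rank), ``report`` (criteria I-IV selection report) and ``classify-assays``
(activity calls on an assay result table).

Every stage writes its primary outputs atomically (temp file + rename) into
the run directory and records a manifest JSON listing inputs, outputs, the
seed and content hashes, so identical configurations reproduce identical
bytes. A stage whose inputs are missing fails with an error naming the stage
that produces them.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import os
import tempfile
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from targetfish import compounds, consensus, external, mining, sea
from targetfish.simulate import FixtureSpec, generate_fixture


class StageInputError(FileNotFoundError):
    """A required stage input is missing; message names the producing stage."""


class ConfigError(ValueError):
    """The run configuration violates its schema."""


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    outdir: str = "run"
    seed: int = 42
    # inputs (populated by `simulate` for fixture-backed runs)
    library: str = ""
    reference_sets: str = ""
    decoy_pool: str = ""
    backend_mode: str = "fixture"  # fixture | live
    backend_dir: str = ""
    methods_file: str = ""  # JSON describing external matrices
    alias_table: str = ""  # optional label -> canonical id CSV
    assay_table: str = ""  # compound_id,target_id,mean,sd CSV
    assay_availability: str = ""  # target_id,available CSV; blank = all available
    panel: list[str] = field(default_factory=list)  # assay panel compound ids
    # parameters
    fingerprint_bits: int = 2048
    tanimoto_threshold: float = 0.57
    background_sizes: list[list[int]] = field(
        default_factory=lambda: [[1, 2], [2, 2], [2, 4], [4, 4], [4, 8], [8, 8], [8, 12]]
    )
    background_samples: int = 100
    sea_e_cutoff: float = 1e-5
    min_cs: int = 2
    cs_levels: list[int] = field(default_factory=lambda: [2, 3])
    enrichment_top_k: int = 0  # 0 = twice the number of known pairs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = sorted(set(data) - valid)
        if bad:
            raise ConfigError(f"unknown config fields: {', '.join(bad)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@contextmanager
def atomic_write(path: str | Path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename into place."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode, newline="" if "b" not in mode else None) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(outdir: Path, stage: str, inputs: list[Path], outputs: list[Path], seed: int) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs},
    }
    with atomic_write(outdir / f"manifest_{stage.replace('-', '_')}.json") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _require(path: str | Path, producer: str) -> Path:
    p = Path(path) if path else Path("")
    if not path or not p.exists():
        raise StageInputError(
            f"missing input {path!r}: run the `{producer}` stage first (it produces this file)"
        )
    return p


def _fingerprinter(config: RunConfig):
    cfg = compounds.FingerprintConfig(
        circular_bits=config.fingerprint_bits, path_bits=config.fingerprint_bits
    )

    def fp(smiles: str) -> np.ndarray:
        rec = compounds.standardize(
            compounds.CompoundRecord(compound_id="q", smiles_input=smiles, smiles_canonical="")
        )
        return compounds.fingerprint(rec, cfg).circular_fp

    return fp


# ----------------------------------------------------------------- stages


def stage_simulate(config: RunConfig, spec: FixtureSpec | None = None) -> dict[str, Path]:
    """Emit the synthetic fixture and point the config at its artifacts."""
    outdir = Path(config.outdir)
    fixture_dir = outdir / "fixture"
    spec = spec if spec is not None else FixtureSpec(seed=config.seed)
    paths = generate_fixture(spec, fixture_dir)
    config.library = str(paths["library"])
    config.reference_sets = str(paths["reference_sets"])
    config.decoy_pool = str(paths["decoy_pool"])
    config.backend_dir = str(fixture_dir / "backend")
    config.methods_file = str(paths["methods"])
    _write_manifest(outdir, "simulate", [], sorted(paths.values()), spec.seed)
    return paths


def _load_library(config: RunConfig) -> list[compounds.CompoundRecord]:
    path = _require(config.library, "simulate")
    records, _ = compounds.load_library(path, format="smiles-csv")
    return records


def stage_fingerprint(config: RunConfig) -> Path:
    """Standardize and fingerprint the library; cache fingerprints as hex."""
    outdir = Path(config.outdir)
    records = _load_library(config)
    cfg = compounds.FingerprintConfig(
        circular_bits=config.fingerprint_bits, path_bits=config.fingerprint_bits
    )
    out = outdir / "fingerprints.csv"
    with atomic_write(out) as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "circular_hex", "path_hex"])
        for rec in records:
            fps = compounds.fingerprint(rec, cfg)
            w.writerow(
                [
                    rec.compound_id,
                    np.packbits(fps.circular_fp).tobytes().hex(),
                    np.packbits(fps.path_fp).tobytes().hex(),
                ]
            )
    _write_manifest(outdir, "fingerprint", [Path(config.library)], [out], config.seed)
    return out


def read_fingerprints(path: str | Path, n_bits: int) -> dict[str, np.ndarray]:
    """Read the circular fingerprints cached by the fingerprint stage."""
    out = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            bits = np.unpackbits(np.frombuffer(bytes.fromhex(row["circular_hex"]), dtype=np.uint8))
            out[row["compound_id"]] = bits[:n_bits].astype(np.uint8)
    return out


def stage_calibrate(config: RunConfig) -> Path:
    """Fit the similarity-ensemble background from the decoy pool."""
    outdir = Path(config.outdir)
    pool_path = _require(config.decoy_pool, "simulate")
    fp = _fingerprinter(config)
    with open(pool_path, newline="") as fh:
        pool = np.stack([fp(row["smiles"]) for row in csv.DictReader(fh)])
    bg = sea.fit_background(
        pool,
        [tuple(s) for s in config.background_sizes],
        threshold=config.tanimoto_threshold,
        n_samples=config.background_samples,
        seed=config.seed,
    )
    out = outdir / "background.json"
    bg.to_json(out)
    _write_manifest(outdir, "calibrate", [pool_path], [out], config.seed)
    return out


def stage_predict(config: RunConfig) -> Path:
    """Run the similarity-ensemble channel for every library compound."""
    outdir = Path(config.outdir)
    fp_cache = _require(outdir / "fingerprints.csv", "fingerprint")
    bg_path = _require(outdir / "background.json", "calibrate")
    refs_path = _require(config.reference_sets, "simulate")
    bg = sea.BackgroundModel.from_json(bg_path)
    fps = read_fingerprints(fp_cache, config.fingerprint_bits)
    references = sea.read_reference_sets(refs_path, _fingerprinter(config))
    pred_path = outdir / "sea_predictions.csv"
    matrix_path = outdir / "matrix_sea.csv"
    all_scores = []
    for cid in sorted(fps):
        all_scores.extend(
            sea.predict_targets(fps[cid], references, bg, e_cutoff=config.sea_e_cutoff, query_id=cid)
        )
    with atomic_write(pred_path) as fh:
        w = csv.writer(fh)
        w.writerow(["query_id", "target_id", "raw", "z", "e_value", "max_tc", "predicted"])
        for s in all_scores:
            w.writerow(
                [
                    s.compound_or_set_id,
                    s.target_id,
                    f"{s.raw_score:.6g}",
                    f"{s.z_score:.6g}",
                    f"{s.e_value:.6g}",
                    f"{s.max_tc:.6g}",
                    int(s.predicted),
                ]
            )
    with atomic_write(matrix_path) as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "target_id", "score"])
        for s in all_scores:
            if s.predicted:
                w.writerow([s.compound_or_set_id, s.target_id, f"{s.e_value:.6g}"])
    _write_manifest(
        outdir, "predict", [fp_cache, bg_path, Path(refs_path)], [pred_path, matrix_path], config.seed
    )
    return matrix_path


def stage_mine(config: RunConfig) -> Path:
    """Mine the known biological space through the configured backend."""
    outdir = Path(config.outdir)
    records = _load_library(config)
    if config.backend_mode == "fixture":
        backend_dir = _require(config.backend_dir, "simulate")
        backend = mining.FixtureBackend(backend_dir)
        backend_inputs = [backend_dir / "structures.csv"]
    elif config.backend_mode == "live":
        backend = mining.RestBackend()
        backend_inputs = []
    else:
        raise ConfigError(f"backend_mode must be fixture or live, got {config.backend_mode!r}")
    space = mining.build_known_space(records, backend)
    known_path = outdir / "known_space.csv"
    with atomic_write(known_path) as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "target_id", "weight"])
        for rec in space.records:
            w.writerow([rec.compound_id, rec.target_id, rec.weight])
    sif_path = outdir / "known_space.sif"
    mining.export_sif(space, sif_path)
    pathways_path = outdir / "target_pathways.json"
    with atomic_write(pathways_path) as fh:
        json.dump(
            {r.target_id: sorted(r.pathways) for r in space.records if r.pathways},
            fh,
            indent=2,
            sort_keys=True,
        )
    _write_manifest(
        outdir,
        "mine",
        [Path(config.library), *backend_inputs],
        [known_path, sif_path, pathways_path],
        config.seed,
    )
    return known_path


def _load_matrices(config: RunConfig) -> list[external.PredictionMatrix]:
    """Load external matrices (methods JSON) plus the computed SEA channel."""
    methods_file = _require(config.methods_file, "simulate")
    base = Path(methods_file).parent
    matrices = []
    with open(methods_file) as fh:
        methods = json.load(fh)
    for name, meta in sorted(methods.items()):
        m = external.read_matrix(
            base / meta["path"],
            layout="long",
            method_name=name,
            fit_semantics=meta["fit_semantics"],
            is_anchor=meta["is_anchor"],
        )
        matrices.append(external.binarize(m, meta["cutoff"]))
    sea_matrix_path = Path(config.outdir) / "matrix_sea.csv"
    if sea_matrix_path.exists():
        m = external.read_matrix(
            sea_matrix_path, layout="long", method_name="SEA", fit_semantics="lower_better"
        )
        # entries were already filtered at the SEA E-value cutoff
        matrices.append(external.binarize(m, float("inf")))
    if config.alias_table:
        aliases = external.TargetAliasTable.from_csv(config.alias_table)
    else:
        labels = {tid for m in matrices for _, tid in m.entries}
        aliases = external.TargetAliasTable.identity(labels)
    return external.harmonize_targets(matrices, aliases)


def stage_consensus(config: RunConfig) -> Path:
    """Assemble the predicted space, subtract the known space, score and rank."""
    outdir = Path(config.outdir)
    known_path = _require(outdir / "known_space.csv", "mine")
    matrices = _load_matrices(config)
    known = mining.read_known_space_csv(known_path)
    library = _load_library(config)
    parent_of = {r.compound_id: r.parent_id for r in library}
    records = consensus.assemble_predicted_space(matrices, min_cs=config.min_cs)
    records = consensus.subtract_known(records, known, parent_of=parent_of)
    cons_path = outdir / "consensus.csv"
    with atomic_write(cons_path) as fh:
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
    rank_path = outdir / "ranking.csv"
    rankings = consensus.criterion_ranking(records, cs_levels=config.cs_levels)
    with atomic_write(rank_path) as fh:
        w = csv.writer(fh)
        w.writerow(["cs_level", "rank", "target_id", "frequency"])
        for tr in sorted(rankings, key=lambda t: (t.cs_level, t.rank, t.target_id)):
            w.writerow([tr.cs_level, tr.rank, tr.target_id, tr.frequency])
    # default slice: twice the known set, so the whole top consensus stratum
    # is covered and the estimate is not dominated by tie-break noise
    top_k = config.enrichment_top_k or 2 * len(known.pairs())
    try:
        ef = consensus.enrichment(matrices, known, top_k=top_k)
    except consensus.ConsensusError:
        ef = {}
    ef_path = outdir / "enrichment.json"
    with atomic_write(ef_path) as fh:
        json.dump({"top_k": top_k, "enrichment_factors": ef}, fh, indent=2, sort_keys=True)
    _write_manifest(
        outdir,
        "consensus",
        [known_path, Path(config.methods_file)],
        [cons_path, rank_path, ef_path],
        config.seed,
    )
    return cons_path


def read_consensus_csv(path: str | Path) -> list[consensus.ConsensusRecord]:
    records = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            records.append(
                consensus.ConsensusRecord(
                    compound_id=row["compound_id"],
                    target_id=row["target_id"],
                    methods_predicting=frozenset(row["methods"].split(";")),
                    anchor_hit=bool(int(row["anchor_hit"])),
                    eligible=bool(int(row["eligible"])),
                )
            )
    return records


def stage_report(config: RunConfig) -> Path:
    """Write the criteria I-IV selection report for every predicted target."""
    outdir = Path(config.outdir)
    cons_path = _require(outdir / "consensus.csv", "consensus")
    known_path = _require(outdir / "known_space.csv", "mine")
    records = read_consensus_csv(cons_path)
    known = mining.read_known_space_csv(known_path)
    pathways_path = outdir / "target_pathways.json"
    annotations = {}
    if pathways_path.exists():
        with open(pathways_path) as fh:
            annotations = json.load(fh)
    if config.assay_availability:
        availability = {}
        with open(config.assay_availability, newline="") as fh:
            for row in csv.DictReader(fh):
                availability[row["target_id"]] = row["available"].strip().lower() in ("1", "true", "yes")
    else:
        availability = {t: True for t in {r.target_id for r in records}}
    panel = config.panel or sorted({r.compound_id for r in records})
    report = consensus.build_selection_report(
        records,
        known,
        annotations,
        availability,
        panel,
        min_cs=config.min_cs,
        cs_levels=config.cs_levels,
    )
    out = outdir / "selection_report.json"
    with atomic_write(out) as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_manifest(outdir, "report", [cons_path, known_path], [out], config.seed)
    return out


def stage_classify_assays(config: RunConfig) -> Path:
    """Classify an assay result table into active/inactive calls."""
    outdir = Path(config.outdir)
    table_path = _require(config.assay_table, "(user-provided assay_table)")
    table = consensus.read_assay_table(table_path)
    calls = consensus.classify_assay_results(table)
    out = outdir / "assay_calls.csv"
    with atomic_write(out) as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "target_id", "mean", "sd", "call"])
        for c in calls:
            w.writerow([c.compound_id, c.target_id, c.mean_inhibition_pct, c.sd_pct, c.call])
    summary = outdir / "assay_summary.json"
    with atomic_write(summary) as fh:
        json.dump(
            {
                "n_rows": len(calls),
                "n_active_calls": sum(c.call == "active" for c in calls),
                "confirmed_targets": sorted({c.target_id for c in calls if c.call == "active"}),
                "confirmed_target_count": consensus.confirmed_target_count(calls),
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    _write_manifest(outdir, "classify-assays", [table_path], [out, summary], config.seed)
    return summary


STAGES = {
    "simulate": stage_simulate,
    "fingerprint": stage_fingerprint,
    "calibrate": stage_calibrate,
    "predict": stage_predict,
    "mine": stage_mine,
    "consensus": stage_consensus,
    "report": stage_report,
    "classify-assays": stage_classify_assays,
}

FULL_CHAIN = ["simulate", "fingerprint", "calibrate", "predict", "mine", "consensus", "report"]


def run_stage(stage: str, config: RunConfig):
    """Run one named stage; see :data:`STAGES` for the catalogue."""
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; choose from {', '.join(STAGES)}")
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    result = STAGES[stage](config)
    config.to_yaml(Path(config.outdir) / "effective_config.yaml")
    return result


def run_full_chain(config: RunConfig, spec: FixtureSpec | None = None) -> Path:
    """Run the whole fixture-backed pipeline; returns the consensus CSV path."""
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    stage_simulate(config, spec=spec)
    for stage in FULL_CHAIN[1:]:
        STAGES[stage](config)
    config.to_yaml(Path(config.outdir) / "effective_config.yaml")
    return Path(config.outdir) / "consensus.csv"
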