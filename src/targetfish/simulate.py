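"""Seeded synthetic fixtures with known ground truth.

The generator emulates the study design the pipeline is built for: a
compound class sharing one scaffold (a 1,3-diarylpropan-1-one /
dihydrochalcone-like core decorated with OH, OMe and a pyranose-like
O-glycoside, mirroring the substitution pattern of natural members of the
class), reference target ligand sets (planted targets get scaffold-sharing
ligands so library compounds genuinely resemble them; decoy targets get
ligands from unrelated scaffold families), a sparse known-interaction table
exposing a chosen fraction of the planted truths as active assay records,
and fallible prediction-method matrices (truths emitted with high
probability, decoys at a configurable noise rate, one matrix marked as the
anchor channel).

Every generator is a pure function of the FixtureSpec: the same spec gives
byte-identical output files.
"""

from __future__ import annotations

import json
import csv
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem

from targetfish.compounds import CompoundRecord, standardize

DHC_TEMPLATE = "O=C(CCc1ccc({r1})c({r2})c1)c1c(O)cc({r3})cc1{r4}"
DHC_SCAFFOLD = "O=C(CCc1ccccc1)c1ccccc1"
DHC_SUBSTITUENTS = ["[H]", "O", "OC", "OC9OC(CO)C(O)C(O)C9O"]

# Unrelated scaffold families for decoy targets and the background decoy pool.
DECOY_FAMILIES: list[tuple[str, str]] = [
    ("indole", "c1ccc2[nH]c({a})cc2c1{b}"),
    ("naphthalene", "c1ccc2cc({a})c({b})cc2c1"),
    ("biphenyl", "c1ccc(-c2ccc({a})c({b})c2)cc1"),
    ("quinoline", "c1ccc2nc({a})cc({b})c2c1"),
    ("coumarin", "O=c1cc({a})c2cc({b})ccc2o1"),
    ("piperidine", "C1CCN(C(=O)C({a})({b})C)CC1"),
    ("pyrimidine", "c1cc({a})nc({b})n1"),
    ("benzimidazole", "c1ccc2[nH]c({a})nc2c1{b}"),
    ("thiophene", "c1cc({a})c({b})s1"),
    ("furanone", "O=C1OC({a})C({b})C1"),
    ("cyclohexane", "C1CC({a})CC({b})C1"),
    ("pyrazole", "c1c({a})n[nH]c1{b}"),
    ("morpholine", "C1COC(C({a})({b})N)CO1"),
    ("benzoate", "COC(=O)c1ccc({a})c({b})c1"),
    ("sulfonamide", "NS(=O)(=O)c1ccc({a})c({b})c1"),
]
DECOY_SUBSTITUENTS = ["[H]", "O", "OC", "C", "CC", "N", "Cl", "F", "CO", "C(C)C"]


@dataclass(frozen=True)
class FixtureSpec:
    """All knobs of the synthetic study, fixing the conditions of every test."""

    seed: int = 42
    n_compounds: int = 60
    scaffold: str = DHC_SCAFFOLD
    n_targets: int = 50
    n_planted_targets: int = 5
    n_confuser_targets: int = 10
    ligands_per_target: int = 8
    intra_set_similarity: str = "high"  # high | medium | low
    known_fraction: float = 0.3
    noise_rate: float = 0.15
    miss_rate: float = 0.15
    decoy_pool_size: int = 300

    def __post_init__(self) -> None:
        if self.n_planted_targets > self.n_targets:
            raise ValueError("n_planted_targets must be <= n_targets")
        if self.n_planted_targets + self.n_confuser_targets > self.n_targets:
            raise ValueError("planted + confuser targets must be <= n_targets")


def _canon(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else None


def _decorate(template: str, slots: list[str], choices: list[str], rng: np.random.Generator) -> str | None:
    values = {slot: choices[rng.integers(len(choices))] for slot in slots}
    return _canon(template.format(**values))


def _template_slots(template: str) -> list[str]:
    import re

    return re.findall(r"\{(\w+)\}", template)


def _draw_distinct(
    template: str,
    choices: list[str],
    n: int,
    rng: np.random.Generator,
    exclude: set[str] = frozenset(),
    max_tries_factor: int = 200,
) -> list[str]:
    slots = _template_slots(template)
    out: list[str] = []
    seen: set[str] = set(exclude)
    for _ in range(n * max_tries_factor):
        smi = _decorate(template, slots, choices, rng)
        if smi is None or smi in seen:
            continue
        seen.add(smi)
        out.append(smi)
        if len(out) == n:
            return out
    raise RuntimeError(
        f"substituent grammar exhausted: produced only {len(out)} of {n} distinct molecules"
    )


def generate_library(spec: FixtureSpec) -> list[CompoundRecord]:
    """n_compounds distinct standardized molecules sharing the class scaffold."""
    rng = np.random.default_rng(spec.seed)
    if spec.n_compounds == 1:
        smiles = [_canon(DHC_TEMPLATE.format(r1="[H]", r2="[H]", r3="[H]", r4="[H]"))]
    else:
        smiles = _draw_distinct(DHC_TEMPLATE, DHC_SUBSTITUENTS, spec.n_compounds, rng)
    records = []
    for i, smi in enumerate(smiles, start=1):
        rec = CompoundRecord(
            compound_id=f"C{i:03d}",
            smiles_input=smi,
            smiles_canonical="",
            name=f"synthetic class member {i}",
            source="synthetic",
        )
        records.append(standardize(rec))
    return records


def planted_target_ids(spec: FixtureSpec) -> list[str]:
    return [f"PLT{i}" for i in range(1, spec.n_planted_targets + 1)]


def confuser_target_ids(spec: FixtureSpec) -> list[str]:
    """Targets whose ligands share the class scaffold but that are NOT true targets.

    They emulate the characteristic failure mode of 2D ligand-based methods:
    chemical resemblance without actual activity, producing confident false
    positives that only a consensus across independent channels filters out.
    """
    return [f"CNF{i:02d}" for i in range(1, spec.n_confuser_targets + 1)]


def decoy_target_ids(spec: FixtureSpec) -> list[str]:
    n = spec.n_targets - spec.n_planted_targets - spec.n_confuser_targets
    return [f"DCY{i:02d}" for i in range(1, n + 1)]


def generate_reference_sets(
    spec: FixtureSpec, library: list[CompoundRecord]
) -> tuple[dict[str, list[str]], list[tuple[str, str]]]:
    """Reference ligand sets per target, plus the planted-truth pair list.

    Planted targets receive ligand sets drawn from the library's scaffold
    grammar (share of scaffold-sharing ligands set by intra_set_similarity:
    high = all, medium = half, low = none); decoy targets draw from unrelated
    scaffold families. Truth = every (library compound, planted target) pair.
    """
    rng = np.random.default_rng(spec.seed + 1)
    library_smiles = {r.smiles_canonical for r in library}
    scaffold_share = {"high": 1.0, "medium": 0.5, "low": 0.0}[spec.intra_set_similarity]
    n_scaffold = int(round(scaffold_share * spec.ligands_per_target))
    sets: dict[str, list[str]] = {}
    used: set[str] = set(library_smiles)
    for tid in planted_target_ids(spec):
        ligands = _draw_distinct(DHC_TEMPLATE, DHC_SUBSTITUENTS, n_scaffold, rng, exclude=used)
        used.update(ligands)
        n_rest = spec.ligands_per_target - n_scaffold
        if n_rest:
            fam = DECOY_FAMILIES[int(rng.integers(len(DECOY_FAMILIES)))]
            rest = _draw_distinct(fam[1], DECOY_SUBSTITUENTS, n_rest, rng, exclude=used)
            used.update(rest)
            ligands = ligands + rest
        sets[tid] = ligands
    # Confuser targets share ligand chemotypes with the library itself: half
    # their ligands ARE library molecules, the rest fresh scaffold decorations.
    # Similarity-only methods therefore assert them with full confidence even
    # though they are not true targets.
    lib_smiles = [r.smiles_canonical for r in library]
    for tid in confuser_target_ids(spec):
        n_from_lib = spec.ligands_per_target // 2
        picks = rng.choice(len(lib_smiles), size=min(n_from_lib, len(lib_smiles)), replace=False)
        ligands = [lib_smiles[i] for i in sorted(picks)]
        fresh = _draw_distinct(
            DHC_TEMPLATE, DHC_SUBSTITUENTS, spec.ligands_per_target - len(ligands), rng, exclude=used
        )
        used.update(fresh)
        sets[tid] = ligands + fresh
    for i, tid in enumerate(decoy_target_ids(spec)):
        fam = DECOY_FAMILIES[i % len(DECOY_FAMILIES)]
        ligands = _draw_distinct(fam[1], DECOY_SUBSTITUENTS, spec.ligands_per_target, rng, exclude=used)
        used.update(ligands)
        sets[tid] = ligands
    truth = [(rec.compound_id, tid) for rec in library for tid in planted_target_ids(spec)]
    return sets, truth


def generate_decoy_pool(spec: FixtureSpec) -> list[str]:
    """Background decoy molecules, clustered into scaffold families.

    Real screening databases are clustered by chemical series rather than
    uniformly diverse; sampling the background from scaffold families keeps
    above-threshold Tanimoto pairs occurring at realistic rates.
    """
    rng = np.random.default_rng(spec.seed + 2)
    per_family = int(np.ceil(spec.decoy_pool_size / len(DECOY_FAMILIES)))
    pool: list[str] = []
    seen: set[str] = set()
    for _, template in DECOY_FAMILIES:
        mols = _draw_distinct(template, DECOY_SUBSTITUENTS, per_family, rng, exclude=seen)
        seen.update(mols)
        pool.extend(mols)
    return pool[: spec.decoy_pool_size]


def generate_backend_tables(
    spec: FixtureSpec,
    library: list[CompoundRecord],
    truth: list[tuple[str, str]],
) -> tuple[dict[str, list[list[str]]], list[tuple[str, str]]]:
    """The four fixture-backend tables, plus the exposed-truth pair list.

    A seeded known_fraction subset of the truth pairs appears as 1-4 active
    single-protein assay records each (giving the interaction weights).
    Distractor records exercise the mining filters: assays annotated with two
    genes (must be dropped by the single-protein rule) and inactive-flagged
    records (must be ignored).
    """
    rng = np.random.default_rng(spec.seed + 3)
    n_exposed = int(round(spec.known_fraction * len(truth)))
    order = rng.permutation(len(truth))
    exposed = [truth[i] for i in sorted(order[:n_exposed])]
    cid_of = {rec.compound_id: f"CID{i + 1:05d}" for i, rec in enumerate(library)}

    structures = [[rec.smiles_canonical, cid_of[rec.compound_id]] for rec in library]
    assays: list[list[str]] = []
    aid_counter = 1
    for compound_id, target_id in exposed:
        n_records = int(rng.integers(1, 5))  # 1..4 supporting records
        for _ in range(n_records):
            assays.append([cid_of[compound_id], f"AID{aid_counter:06d}", "active", target_id])
            aid_counter += 1
    # distractors: multi-gene assays (single-protein rule) and inactive flags
    compounds = [rec.compound_id for rec in library]
    all_targets = planted_target_ids(spec) + confuser_target_ids(spec) + decoy_target_ids(spec)
    for _ in range(max(5, len(exposed) // 4)):
        cid = cid_of[compounds[int(rng.integers(len(compounds)))]]
        t1, t2 = rng.choice(len(all_targets), size=2, replace=False)
        assays.append(
            [cid, f"AID{aid_counter:06d}", "active", f"{all_targets[t1]};{all_targets[t2]}"]
        )
        aid_counter += 1
        cid = cid_of[compounds[int(rng.integers(len(compounds)))]]
        tgt = all_targets[int(rng.integers(len(all_targets)))]
        assays.append([cid, f"AID{aid_counter:06d}", "inactive", tgt])
        aid_counter += 1

    proteins = [[tid, f"{tid}_HUMAN"] for tid in all_targets]
    # planted targets share pathways pairwise so criterion III finds evidence
    pathways = []
    planted = planted_target_ids(spec)
    for i, tid in enumerate(planted):
        pathways.append([f"{tid}_HUMAN", f"PW_CLASS_{i % 2}"])
        pathways.append([f"{tid}_HUMAN", f"PW_{tid}"])
    for tid in confuser_target_ids(spec) + decoy_target_ids(spec):
        pathways.append([f"{tid}_HUMAN", f"PW_{tid}"])

    tables = {
        "structures": [["smiles_canonical", "cid"]] + structures,
        "assays": [["cid", "aid", "activity_flag", "gene_names"]] + assays,
        "proteins": [["gene", "protein_entry"]] + proteins,
        "pathways": [["protein_entry", "pathway"]] + pathways,
    }
    return tables, exposed


def generate_method_noise(
    spec: FixtureSpec,
    library: list[CompoundRecord],
    truth: list[tuple[str, str]],
) -> dict[str, dict]:
    """Simulated external prediction matrices (one marked anchor).

    Each method emits a truth pair with probability 1 - miss_rate and a
    decoy pair with probability noise_rate, with independent noise per
    method (fixed seed offsets). Truth entries draw somewhat better scores
    than decoy entries, with overlap, so single-method rankings are fallible
    while the consensus concentrates on the truths.
    """
    methods = {
        "PHDB": {"fit_semantics": "higher_better", "is_anchor": True, "cutoff": 0.0},
        "SRV1": {"fit_semantics": "lower_better", "is_anchor": False, "cutoff": 1e-3},
        "SRV2": {"fit_semantics": "higher_better", "is_anchor": False, "cutoff": 0.5},
    }
    truth_set = set(truth)
    compounds = [rec.compound_id for rec in library]
    decoys = confuser_target_ids(spec) + decoy_target_ids(spec)
    out: dict[str, dict] = {}
    for k, (name, meta) in enumerate(methods.items()):
        rng = np.random.default_rng(spec.seed + 1000 * (k + 1) + 17)
        entries: dict[tuple[str, str], float] = {}

        def score(is_truth: bool, rng=rng, name=name) -> float:
            # identical truth/decoy overlap structure for every simulated
            # method; only the score semantics differ (E-value-like for SRV1).
            # Decoy scores reach nearly the top of the truth range: a wrongly
            # asserted pair looks almost as confident as a right one, which is
            # what makes the single channels fallible and the consensus useful.
            lo, hi = (0.55, 1.0) if is_truth else (0.5, 0.98)
            g = lo + (hi - lo) * rng.random()
            if name == "SRV1":  # E-value-like, lower better
                return 10 ** (-8.0 * g)
            return g

        for cid, tid in sorted(truth_set):
            if rng.random() >= spec.miss_rate:
                entries[(cid, tid)] = round(score(True), 6)
        for cid in compounds:
            for tid in decoys:
                if rng.random() < spec.noise_rate:
                    entries[(cid, tid)] = round(score(False), 6)
        out[name] = {**meta, "entries": entries}
    return out


def _write_csv(path: Path, rows: list[list[str]]) -> None:
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(rows)


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Emit the full fixture directory; returns the path of every artifact."""
    outdir = Path(outdir)
    (outdir / "backend").mkdir(parents=True, exist_ok=True)
    library = generate_library(spec)
    sets, truth = generate_reference_sets(spec, library)
    tables, exposed = generate_backend_tables(spec, library, truth)
    matrices = generate_method_noise(spec, library, truth)
    pool = generate_decoy_pool(spec)

    paths: dict[str, Path] = {}
    paths["library"] = outdir / "library.csv"
    _write_csv(
        paths["library"],
        [["compound_id", "smiles", "name", "source"]]
        + [[r.compound_id, r.smiles_canonical, r.name, r.source] for r in library],
    )
    paths["reference_sets"] = outdir / "reference_sets.csv"
    _write_csv(
        paths["reference_sets"],
        [["target_id", "smiles"]] + [[tid, smi] for tid in sorted(sets) for smi in sets[tid]],
    )
    paths["truth"] = outdir / "truth.csv"
    _write_csv(paths["truth"], [["compound_id", "target_id"]] + [list(p) for p in truth])
    paths["exposed"] = outdir / "exposed_truth.csv"
    _write_csv(paths["exposed"], [["compound_id", "target_id"]] + [list(p) for p in exposed])
    for name, rows in tables.items():
        paths[name] = outdir / "backend" / f"{name}.csv"
        _write_csv(paths[name], rows)
    for name, meta in matrices.items():
        paths[f"matrix_{name}"] = outdir / f"matrix_{name.lower()}.csv"
        rows = [["compound_id", "target_id", "score"]] + [
            [cid, tid, f"{s:.6g}"] for (cid, tid), s in sorted(meta["entries"].items())
        ]
        _write_csv(paths[f"matrix_{name}"], rows)
    paths["decoy_pool"] = outdir / "decoy_pool.csv"
    _write_csv(
        paths["decoy_pool"],
        [["compound_id", "smiles"]] + [[f"D{i + 1:04d}", smi] for i, smi in enumerate(pool)],
    )
    paths["spec"] = outdir / "fixture_spec.json"
    with open(paths["spec"], "w") as fh:
        json.dump(asdict(spec), fh, indent=2, sort_keys=True)
    paths["methods"] = outdir / "methods.json"
    with open(paths["methods"], "w") as fh:
        json.dump(
            {
                name: {
                    "fit_semantics": meta["fit_semantics"],
                    "is_anchor": meta["is_anchor"],
                    "cutoff": meta["cutoff"],
                    "path": f"matrix_{name.lower()}.csv",
                }
                for name, meta in matrices.items()
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths
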