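"""Similarity-ensemble target prediction (SEA-style).

A protein target is represented by the set of its known ligands. A query
compound (or set of compounds) scores against a target by summing all
pairwise Tanimoto similarities that reach a threshold (default 0.57, the
canonical operating point of the method on circular fingerprints). Because
that raw score grows with the sizes of the two sets, it is standardized
against a background fitted on random ligand ensembles: the mean raw score
is modelled as linear in the set-size product n*m and its standard deviation
as a power law a*(n*m)^b. The resulting z-score is converted to a BLAST-like
E-value through the upper tail of a standard Gumbel extreme-value law,

    p(z) = 1 - exp(-exp(-(z*pi/sqrt(6) + gamma))),    E = n_comparisons * p(z),

with gamma the Euler-Mascheroni constant. Low E-values mean the observed
ensemble similarity is unlikely to be coincidence.

The SuperPred-style channel is this same engine run with its own reference
ligand sets and cutoff; no separate scorer exists.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

EULER_GAMMA = float(np.euler_gamma)

DEFAULT_TANIMOTO_THRESHOLD = 0.57


@dataclass
class TargetLigandSet:
    """A protein target described by the fingerprints of its known ligands."""

    target_id: str
    ligand_fps: np.ndarray  # (n_ligands, n_bits) uint8
    display_name: str = ""

    def __post_init__(self) -> None:
        self.ligand_fps = np.atleast_2d(np.asarray(self.ligand_fps, dtype=np.uint8))
        if self.ligand_fps.shape[0] < 1:
            raise ValueError(f"target {self.target_id!r} has no ligands")

    @property
    def n_ligands(self) -> int:
        return int(self.ligand_fps.shape[0])

    @property
    def n_bits(self) -> int:
        return int(self.ligand_fps.shape[1])


@dataclass
class BackgroundModel:
    """Random-ensemble calibration of raw scores.

    ``mean_coeffs = (b0, b1)`` gives mean(nm) = b0 + b1*nm;
    ``sd_coeffs = (a, b)`` gives sd(nm) = a * nm**b, positive everywhere.
    """

    tanimoto_threshold: float
    mean_coeffs: tuple[float, float]
    sd_coeffs: tuple[float, float]
    n_random_samples: int
    seed: int
    fitted_product_range: tuple[int, int] = (1, 1)

    def mean(self, nm: float) -> float:
        b0, b1 = self.mean_coeffs
        return b0 + b1 * nm

    def sd(self, nm: float) -> float:
        a, b = self.sd_coeffs
        return a * nm**b

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "tanimoto_threshold": self.tanimoto_threshold,
                    "mean_coeffs": list(self.mean_coeffs),
                    "sd_coeffs": list(self.sd_coeffs),
                    "n_random_samples": self.n_random_samples,
                    "seed": self.seed,
                    "fitted_product_range": list(self.fitted_product_range),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "BackgroundModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            tanimoto_threshold=d["tanimoto_threshold"],
            mean_coeffs=tuple(d["mean_coeffs"]),
            sd_coeffs=tuple(d["sd_coeffs"]),
            n_random_samples=d["n_random_samples"],
            seed=d["seed"],
            fitted_product_range=tuple(d["fitted_product_range"]),
        )


@dataclass
class PredictionScore:
    """One query-against-target ensemble comparison."""

    compound_or_set_id: str
    target_id: str
    raw_score: float
    z_score: float
    e_value: float
    max_tc: float
    predicted: bool = False


class BackgroundFitError(RuntimeError):
    """The random-ensemble background could not be fitted (degenerate data)."""


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a AND b| / |a OR b| of two equal-length bit vectors.

    Defined as 0 when both vectors are all-zero.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(a & b) / union)


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """All-pairs Tanimoto between the rows of two (n, bits) uint8 matrices."""
    A = np.atleast_2d(np.asarray(A, dtype=np.uint8))
    B = np.atleast_2d(np.asarray(B, dtype=np.uint8))
    if A.shape[1] != B.shape[1]:
        raise ValueError(f"fingerprint length mismatch: {A.shape[1]} vs {B.shape[1]}")
    inter = A.astype(np.int32) @ B.astype(np.int32).T
    pa = A.sum(axis=1, dtype=np.int32)[:, None]
    pb = B.sum(axis=1, dtype=np.int32)[None, :]
    union = pa + pb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return tc


def raw_score(
    query_fps: np.ndarray,
    target: TargetLigandSet,
    threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
) -> tuple[float, float]:
    """Sum of all pairwise Tanimoto values >= threshold, plus the maximum pair.

    Returns ``(raw, max_tc)``. Either set being empty is fatal.
    """
    query_fps = np.atleast_2d(np.asarray(query_fps, dtype=np.uint8))
    if query_fps.shape[0] == 0:
        raise ValueError("empty query set")
    tc = tanimoto_matrix(query_fps, target.ligand_fps)
    max_tc = float(tc.max()) if tc.size else 0.0
    # sequential row-major accumulation: bit-identical to a plain double loop
    raw = 0.0
    for v in tc.ravel():
        if v >= threshold:
            raw += float(v)
    return raw, max_tc


def _sample_raw_scores(
    rng: np.random.Generator,
    decoy_fps: np.ndarray,
    n: int,
    m: int,
    threshold: float,
    n_samples: int,
) -> np.ndarray:
    """Raw scores of ``n_samples`` disjoint random (n, m) set pairs from the pool."""
    n_pool = decoy_fps.shape[0]
    if n + m > n_pool:
        raise BackgroundFitError(
            f"decoy pool of {n_pool} too small for disjoint sets of sizes {n}+{m}"
        )
    out = np.empty(n_samples)
    for i in range(n_samples):
        idx = rng.choice(n_pool, size=n + m, replace=False)
        tc = tanimoto_matrix(decoy_fps[idx[:n]], decoy_fps[idx[n:]])
        out[i] = tc[tc >= threshold].sum()
    return out


def fit_background(
    decoy_fps: np.ndarray,
    set_sizes: list[tuple[int, int]],
    threshold: float = DEFAULT_TANIMOTO_THRESHOLD,
    n_samples: int = 100,
    seed: int = 0,
) -> BackgroundModel:
    """Fit the random-ensemble background from a decoy fingerprint pool.

    For each requested (n, m) size pair, ``n_samples`` disjoint random set
    pairs are drawn and raw-scored; the per-size empirical means are fitted
    linearly in the product n*m, and the per-size standard deviations as a
    power law a*(n*m)^b on a log-log scale. Size cells whose empirical sd is
    zero (no above-threshold pair ever sampled) carry no scale information
    and are excluded from the sd fit. Deterministic under a fixed seed.
    """
    if n_samples < 50:
        raise ValueError("n_samples must be >= 50 per size pair")
    decoy_fps = np.atleast_2d(np.asarray(decoy_fps, dtype=np.uint8))
    rng = np.random.default_rng(seed)
    products, means, sds = [], [], []
    for n, m in set_sizes:
        raws = _sample_raw_scores(rng, decoy_fps, n, m, threshold, n_samples)
        products.append(n * m)
        means.append(raws.mean())
        sds.append(raws.std(ddof=1))
    products = np.asarray(products, dtype=float)
    means = np.asarray(means)
    sds = np.asarray(sds)

    mean_coeffs = tuple(np.polyfit(products, means, deg=1)[::-1])  # (b0, b1)

    pos = sds > 0
    if pos.sum() < 2:
        raise BackgroundFitError(
            "background degenerate: fewer than two size cells with positive raw-score sd "
            f"(threshold={threshold}, sizes={set_sizes})"
        )
    slope, intercept = np.polyfit(np.log(products[pos]), np.log(sds[pos]), deg=1)
    sd_coeffs = (float(np.exp(intercept)), float(slope))

    model = BackgroundModel(
        tanimoto_threshold=threshold,
        mean_coeffs=(float(mean_coeffs[0]), float(mean_coeffs[1])),
        sd_coeffs=sd_coeffs,
        n_random_samples=n_samples,
        seed=seed,
        fitted_product_range=(int(products.min()), int(products.max())),
    )
    lo, hi = model.fitted_product_range
    grid = np.linspace(lo, hi, 50)
    if not np.all([model.sd(x) > 0 for x in grid]):
        raise BackgroundFitError(
            f"degenerate background fit: non-positive sd prediction in range {lo}..{hi}; "
            f"sd_coeffs={sd_coeffs}"
        )
    return model


def sample_background_z(
    decoy_fps: np.ndarray,
    set_sizes: list[tuple[int, int]],
    bg: BackgroundModel,
    n_draws: int,
    seed: int,
) -> np.ndarray:
    """z-scores of fresh random ensemble pairs (calibration self-check).

    Draws ``n_draws`` disjoint random set pairs, cycling through the given
    sizes, scores them at the background's threshold, and standardizes with
    the background. For a well-calibrated background the sample mean is near
    0 and the sample sd near 1.
    """
    decoy_fps = np.atleast_2d(np.asarray(decoy_fps, dtype=np.uint8))
    rng = np.random.default_rng(seed)
    zs = np.empty(n_draws)
    for i in range(n_draws):
        n, m = set_sizes[i % len(set_sizes)]
        raw = _sample_raw_scores(rng, decoy_fps, n, m, bg.tanimoto_threshold, 1)[0]
        zs[i] = z_score(raw, n, m, bg)
    return zs


def z_score(raw: float, n: int, m: int, bg: BackgroundModel) -> float:
    """Standardize a raw score against the background at set-size product n*m."""
    nm = n * m
    return float((raw - bg.mean(nm)) / bg.sd(nm))


def gumbel_tail(z: float) -> float:
    """Upper-tail probability of the standard-Gumbel-matched extreme-value law."""
    x = z * np.pi / np.sqrt(6.0) + EULER_GAMMA
    return float(-np.expm1(-np.exp(-x)))


def e_value(z: float, n_comparisons: int) -> float:
    """BLAST-style expectation value: comparisons times the Gumbel tail at z."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    e = n_comparisons * gumbel_tail(z)
    return float(min(max(e, 0.0), n_comparisons))


def predict_targets(
    query_fps: np.ndarray,
    references: list[TargetLigandSet],
    bg: BackgroundModel,
    e_cutoff: float = 1e-5,
    query_id: str = "query",
) -> list[PredictionScore]:
    """Score a query ligand set against every reference target set.

    Returns one :class:`PredictionScore` per reference, sorted by ascending
    E-value (ties: descending max_tc, then target_id). ``predicted`` is True
    where e_value <= e_cutoff.
    """
    query_fps = np.atleast_2d(np.asarray(query_fps, dtype=np.uint8))
    n_comp = len(references)
    if n_comp == 0:
        raise ValueError("no reference target sets")
    for ref in references:
        if ref.n_bits != query_fps.shape[1]:
            raise ValueError(
                f"fingerprint length mismatch for target {ref.target_id!r}: "
                f"{ref.n_bits} vs query {query_fps.shape[1]}"
            )
    out = []
    nq = query_fps.shape[0]
    for ref in references:
        raw, max_tc = raw_score(query_fps, ref, bg.tanimoto_threshold)
        z = z_score(raw, nq, ref.n_ligands, bg)
        e = e_value(z, n_comp)
        out.append(
            PredictionScore(
                compound_or_set_id=query_id,
                target_id=ref.target_id,
                raw_score=raw,
                z_score=z,
                e_value=e,
                max_tc=max_tc,
                predicted=e <= e_cutoff,
            )
        )
    out.sort(key=lambda s: (s.e_value, -s.max_tc, s.target_id))
    return out


def read_reference_sets(
    path: str | Path,
    fingerprinter,
) -> list[TargetLigandSet]:
    """Read reference ligand sets from a CSV of ``target_id,smiles`` rows.

    ``fingerprinter`` maps a SMILES string to a 1D uint8 bit vector; the
    compounds module supplies one via standardize + fingerprint.
    """
    by_target: dict[str, list[np.ndarray]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "target_id" not in reader.fieldnames:
            raise ValueError(f"reference set CSV {path} lacks a 'target_id' column")
        for row in reader:
            by_target.setdefault(row["target_id"], []).append(fingerprinter(row["smiles"]))
    return [
        TargetLigandSet(target_id=t, ligand_fps=np.stack(fps))
        for t, fps in sorted(by_target.items())
    ]


def write_predictions(scores: list[PredictionScore], path: str | Path) -> None:
    """Write prediction scores as CSV ``query_id,target_id,raw,z,e_value,max_tc,predicted``."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["query_id", "target_id", "raw", "z", "e_value", "max_tc", "predicted"])
        for s in scores:
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
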