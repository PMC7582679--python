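"""Hybrid 2D/3D target prediction: path-fingerprint Tanimoto fused with
electroshape similarity through a logistic classifier.

The 3D channel uses an electroshape-style descriptor: atoms of a single
energy-minimized conformer are lifted to 4D by appending their scaled
Gasteiger partial charge as a fourth coordinate, five reference points are
chosen deterministically (centroid; atom farthest from the centroid; atom
farthest from that atom; centroid displaced by +/- charge_scale along the
charge axis), and for each reference point the first three moments of the
atom-distance distribution are recorded (mean, standard deviation, cube root
of the third central moment, sign preserved) - 15 numbers in total, invariant
under rigid rotation and translation of the conformer. Two conformers are
compared by the Manhattan distance between their vectors, mapped to a bounded
similarity s3D = 1 / (1 + mean absolute difference).

Per target, the query's best 2D and best 3D similarity to the target's
ligands enter a logistic model P = sigmoid(b0 + b1*s2D + b2*s3D); the shipped
default model is trained on synthetic same-scaffold/random pairs because no
public training corpus exists for this channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from targetfish.compounds import CompoundRecord
from targetfish.sea import tanimoto_matrix

DEFAULT_CHARGE_SCALE = 25.0


@dataclass(frozen=True)
class ElectroShapeVector:
    """15 distance-distribution moments (3 per reference point, 5 points)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (15,):
            raise ValueError(f"electroshape vector must have 15 entries, got {v.shape}")
        object.__setattr__(self, "values", v)


@dataclass
class HybridModel:
    """Logistic fusion coefficients on (intercept, s2D, s3D)."""

    beta0: float
    beta1: float
    beta2: float
    train_seed: int = 0
    decision_threshold: float = 0.5
    charge_scale: float = DEFAULT_CHARGE_SCALE

    def probability(self, s2d: float, s3d: float) -> float:
        x = self.beta0 + self.beta1 * s2d + self.beta2 * s3d
        return float(1.0 / (1.0 + np.exp(-x)))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "beta0": self.beta0,
                    "beta1": self.beta1,
                    "beta2": self.beta2,
                    "train_seed": self.train_seed,
                    "decision_threshold": self.decision_threshold,
                    "charge_scale": self.charge_scale,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "HybridModel":
        with open(path) as fh:
            return cls(**json.load(fh))


class EmbeddingError(RuntimeError):
    """3D conformer generation failed for a molecule."""


def embed_conformer(record: CompoundRecord, seed: int = 0) -> Chem.Mol:
    """Generate one energy-minimized conformer with Gasteiger charges.

    Deterministic under a fixed seed. Raises :class:`EmbeddingError` when
    embedding fails; callers exclude such records from the 3D channel only.
    """
    mol = Chem.MolFromSmiles(record.smiles_canonical)
    if mol is None or mol.GetNumHeavyAtoms() < 1:
        raise EmbeddingError(f"no valid structure for {record.compound_id!r}")
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise EmbeddingError(f"conformer embedding failed for {record.compound_id!r}")
    try:
        AllChem.MMFFOptimizeMolecule(mol, maxIters=500)
    except Exception:
        AllChem.UFFOptimizeMolecule(mol, maxIters=500)
    AllChem.ComputeGasteigerCharges(mol)
    return mol


def _conformer_points(mol: Chem.Mol, charge_scale: float) -> np.ndarray:
    """Heavy-atom 4D coordinates (x, y, z, charge_scale*q), centered on the 3D centroid."""
    conf = mol.GetConformer()
    pts = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() == 1:
            continue
        p = conf.GetAtomPosition(atom.GetIdx())
        q = float(atom.GetDoubleProp("_GasteigerCharge"))
        if not np.isfinite(q):
            q = 0.0
        pts.append([p.x, p.y, p.z, charge_scale * q])
    arr = np.asarray(pts, dtype=float)
    arr[:, :3] -= arr[:, :3].mean(axis=0)
    return arr


def _moments(dists: np.ndarray) -> tuple[float, float, float]:
    mu = float(dists.mean())
    sd = float(dists.std())
    third = float(((dists - mu) ** 3).mean())
    skew = float(np.cbrt(third))
    return mu, sd, skew


def electroshape(mol: Chem.Mol, charge_scale: float = DEFAULT_CHARGE_SCALE) -> ElectroShapeVector:
    """Compute the 15-component electroshape descriptor of an embedded conformer."""
    pts = _conformer_points(mol, charge_scale)
    centroid = pts.mean(axis=0)
    d_to_c = np.linalg.norm(pts - centroid, axis=1)
    far1 = pts[int(np.argmax(d_to_c))]
    far2 = pts[int(np.argmax(np.linalg.norm(pts - far1, axis=1)))]
    charge_axis = np.array([0.0, 0.0, 0.0, 1.0])
    refs = [
        centroid,
        far1,
        far2,
        centroid + charge_scale * charge_axis,
        centroid - charge_scale * charge_axis,
    ]
    values = []
    for ref in refs:
        values.extend(_moments(np.linalg.norm(pts - ref, axis=1)))
    return ElectroShapeVector(values=np.asarray(values))


def similarity_3d(a: ElectroShapeVector, b: ElectroShapeVector) -> float:
    """Bounded electroshape similarity 1 / (1 + mean |a_i - b_i|) in (0, 1]."""
    mad = float(np.abs(a.values - b.values).mean())
    return 1.0 / (1.0 + mad)


def _irls_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 100, tol: float = 1e-10
) -> np.ndarray:
    """Newton/IRLS maximum-likelihood logistic fit with optional L2 penalty."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        grad = X.T @ (y - p) - ridge * beta
        H = (X.T * W) @ X + ridge * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            raise _SeparationError
        beta_new = beta + step
        if not np.all(np.isfinite(beta_new)) or np.abs(beta_new).max() > 1e3:
            raise _SeparationError
        if np.abs(step).max() < tol:
            return beta_new
        beta = beta_new
    return beta


class _SeparationError(RuntimeError):
    pass


def train_hybrid(
    labeled_pairs: Sequence[tuple[float, float, int]],
    seed: int = 0,
    decision_threshold: float = 0.5,
    charge_scale: float = DEFAULT_CHARGE_SCALE,
) -> HybridModel:
    """Fit the logistic fusion model from (s2D, s3D, label) training pairs.

    Maximum-likelihood fit by iterative reweighting; on complete separation
    the fit falls back to a ridge penalty of 1e-4. Deterministic under fixed
    seed and input order.
    """
    pairs = np.asarray(labeled_pairs, dtype=float)
    if pairs.shape[0] < 20:
        raise ValueError("need at least 20 labeled pairs")
    y = pairs[:, 2]
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = np.column_stack([np.ones(len(pairs)), pairs[:, 0], pairs[:, 1]])
    try:
        beta = _irls_logistic(X, y, ridge=0.0)
    except _SeparationError:
        beta = _irls_logistic(X, y, ridge=1e-4)
    return HybridModel(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        beta2=float(beta[2]),
        train_seed=seed,
        decision_threshold=decision_threshold,
        charge_scale=charge_scale,
    )


@dataclass
class TargetDescriptors3D:
    """Electroshape vectors of one target's reference ligands."""

    target_id: str
    vectors: list[ElectroShapeVector]


def predict_hybrid(
    query_path_fp: np.ndarray,
    query_shape: ElectroShapeVector | None,
    reference_path_fps: dict[str, np.ndarray],
    reference_shapes: dict[str, list[ElectroShapeVector]],
    model: HybridModel,
    fallback_model: HybridModel | None = None,
) -> list[tuple[str, float, bool]]:
    """Score one query against every reference target.

    Per target: s2D = max path-fingerprint Tanimoto to the target's ligands,
    s3D = max electroshape similarity; probability = logistic(b0 + b1*s2D +
    b2*s3D). A query without a 3D descriptor is scored by the 2D-only
    fallback model (default: same coefficients with s3D = 0).

    Returns (target_id, probability, predicted) sorted by descending
    probability, ties by target_id.
    """
    out = []
    q2d = np.atleast_2d(np.asarray(query_path_fp, dtype=np.uint8))
    for target_id in sorted(reference_path_fps):
        fps = reference_path_fps[target_id]
        s2d = float(tanimoto_matrix(q2d, fps).max())
        if query_shape is not None and reference_shapes.get(target_id):
            s3d = max(similarity_3d(query_shape, v) for v in reference_shapes[target_id])
            p = model.probability(s2d, s3d)
        else:
            m = fallback_model if fallback_model is not None else model
            p = m.probability(s2d, 0.0)
        out.append((target_id, p, p >= model.decision_threshold))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out
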