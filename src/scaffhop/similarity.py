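"""Fingerprint and charge-aware 3D shape similarity.

Two complementary views of molecular similarity are used by the pipeline:

* **ECFP4/Tanimoto** — a 2048-bit folded circular fingerprint of radius 2,
  compared with the Tanimoto coefficient ``|A∩B| / |A∪B|``.  This is the
  retrieval metric (scaffold vs. library scaffold) and the whole-molecule
  novelty filter (candidate vs. parent).

* **ElectroShape** — a 4D extension of ultrafast shape recognition (USR):
  every atom becomes a point ``(x, y, z, μ·q)`` where ``q`` is its partial
  charge and ``μ = 25 Å/e`` maps charge onto the length scale.  Five
  reference points are constructed (the 4D centroid, the two successive
  farthest atom points, and two chirality-sensitive points obtained by a
  cross-product offset with the maximal/minimal charge in the fourth
  coordinate); the descriptor is, for each reference point, the mean,
  standard deviation and cube-rooted third central moment of its distances
  to all atom points — 15 numbers in total.  Descriptors are compared with
  the inverse translated mean Manhattan distance
  ``S = 1 / (1 + (1/15)·Σ|d1−d2|)``.

Conformers are generated by distance-geometry embedding (ETKDG) with an
explicit seed and relaxed with MMFF94 (UFF fallback); Gasteiger charges are
computed on the hydrogen-complete molecule so that they sum to the net
formal charge.  Hydrogens are included as shape/charge points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import AllChem, rdFingerprintGenerator

from scaffhop.chem_io import MoleculeRecord

logger = logging.getLogger(__name__)

ELECTROSHAPE_MU = 25.0  # Å per elementary charge
N_MOMENTS = 15
MAX_HEAVY_ATOMS = 300
_CHARGE_CLIP = 1.0  # guard against unparameterized Gasteiger atoms

_FP_GEN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


class EmbeddingError(RuntimeError):
    """Raised when 3D embedding fails for a molecule after all retries."""


class DegenerateGeometryError(RuntimeError):
    """Raised when the reference-point construction degenerates
    (collinear farthest-point vectors with zero cross product)."""


@dataclass(frozen=True)
class FingerprintECFP4:
    bits: DataStructs.ExplicitBitVect = field(repr=False)
    n_on: int

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(self.bits.GetOnBits())

    def __len__(self) -> int:
        return self.bits.GetNumBits()


@dataclass(frozen=True)
class ConformerWithCharges:
    coords: np.ndarray  # (n_atoms, 3) in Å
    charges: np.ndarray  # (n_atoms,) in elementary charges
    embed_seed: int


@dataclass(frozen=True)
class ElectroShapeDescriptor:
    moments: np.ndarray  # shape (15,)
    mu: float = ELECTROSHAPE_MU

    def __post_init__(self):
        if self.moments.shape != (N_MOMENTS,):
            raise ValueError(f"descriptor must have {N_MOMENTS} components")


def ecfp4(mol_or_record) -> FingerprintECFP4:
    """2048-bit ECFP4 (Morgan radius-2) fingerprint."""
    mol = mol_or_record.require_ok() if isinstance(mol_or_record, MoleculeRecord) else mol_or_record
    bv = _FP_GEN.GetFingerprint(mol)
    return FingerprintECFP4(bits=bv, n_on=bv.GetNumOnBits())


def tanimoto(a: FingerprintECFP4, b: FingerprintECFP4) -> float:
    """Tanimoto coefficient of two equal-length fingerprints.

    Two all-zero fingerprints are defined as identical (similarity 1.0).
    """
    if len(a) != len(b):
        raise ValueError(f"fingerprint length mismatch: {len(a)} vs {len(b)}")
    if a.n_on == 0 and b.n_on == 0:
        return 1.0
    return DataStructs.TanimotoSimilarity(a.bits, b.bits)


def embed_conformer(mol_or_record, seed: int = 42, max_retries: int = 3) -> ConformerWithCharges:
    """One seeded ETKDG conformer with MMFF/UFF relaxation and Gasteiger charges.

    Deterministic for a fixed seed.  On embedding failure the seed is
    incremented and embedding retried up to ``max_retries`` times before an
    :class:`EmbeddingError` is raised.
    """
    mol = mol_or_record.require_ok() if isinstance(mol_or_record, MoleculeRecord) else mol_or_record
    if mol.GetNumHeavyAtoms() > MAX_HEAVY_ATOMS:
        raise EmbeddingError(
            f"molecule too large to embed ({mol.GetNumHeavyAtoms()} heavy atoms)"
        )
    molh = Chem.AddHs(Chem.Mol(mol))
    last = None
    for attempt in range(max_retries):
        params = AllChem.ETKDGv3()
        params.randomSeed = int(seed) + attempt
        params.useRandomCoords = attempt > 0
        conf_id = AllChem.EmbedMolecule(molh, params)
        if conf_id >= 0:
            break
        last = f"embedding attempt {attempt + 1} failed"
    else:
        raise EmbeddingError(f"could not embed {Chem.MolToSmiles(mol)}: {last}")

    try:
        if AllChem.MMFFHasAllMoleculeParams(molh):
            AllChem.MMFFOptimizeMolecule(molh, maxIters=500)
        else:
            AllChem.UFFOptimizeMolecule(molh, maxIters=500)
    except Exception:  # a failed relaxation still leaves usable coordinates
        logger.debug("force-field relaxation failed for %s", Chem.MolToSmiles(mol))

    AllChem.ComputeGasteigerCharges(molh)
    charges = np.array([a.GetDoubleProp("_GasteigerCharge") for a in molh.GetAtoms()])
    charges = np.nan_to_num(charges, nan=0.0, posinf=0.0, neginf=0.0)
    charges = np.clip(charges, -_CHARGE_CLIP, _CHARGE_CLIP)
    coords = molh.GetConformer().GetPositions().astype(float)
    return ConformerWithCharges(coords=coords, charges=charges, embed_seed=int(seed))


def _moments(dists: np.ndarray) -> tuple[float, float, float]:
    m = float(dists.mean())
    s = float(dists.std())
    third = float(np.mean((dists - m) ** 3))
    return m, s, float(np.cbrt(third))


def electroshape(conf: ConformerWithCharges, mu: float = ELECTROSHAPE_MU) -> ElectroShapeDescriptor:
    """15-component ElectroShape descriptor of a charged conformer.

    Requires at least 3 atoms (the chirality offset needs a non-degenerate
    triangle of reference points); raises :class:`DegenerateGeometryError`
    when the two farthest-point vectors are spatially collinear, in which
    case the caller should retry with a re-embedded conformer.
    """
    n = conf.coords.shape[0]
    if n < 3:
        raise ValueError("ElectroShape needs at least 3 atoms")
    pts = np.column_stack([conf.coords, mu * conf.charges])  # (n, 4)

    c1 = pts.mean(axis=0)
    d1 = np.linalg.norm(pts - c1, axis=1)
    c2 = pts[int(np.argmax(d1))]
    d2 = np.linalg.norm(pts - c2, axis=1)
    c3 = pts[int(np.argmax(d2))]

    a = c2 - c1
    b = c3 - c1
    cross = np.cross(a[:3], b[:3])
    norm_cross = float(np.linalg.norm(cross))
    if norm_cross < 1e-12:
        raise DegenerateGeometryError("collinear reference vectors (zero cross product)")
    offset = cross * (float(np.linalg.norm(a)) / (2.0 * norm_cross))
    spatial = c1[:3] + offset
    c4 = np.append(spatial, mu * float(conf.charges.max()))
    c5 = np.append(spatial, mu * float(conf.charges.min()))

    comps: list[float] = []
    for ref in (c1, c2, c3, c4, c5):
        comps.extend(_moments(np.linalg.norm(pts - ref, axis=1)))
    return ElectroShapeDescriptor(moments=np.array(comps), mu=mu)


def electroshape_similarity(d1: ElectroShapeDescriptor, d2: ElectroShapeDescriptor) -> float:
    """Inverse translated mean Manhattan distance between two descriptors:
    ``1 / (1 + mean |d1 - d2|)`` — 1.0 iff identical, symmetric, in (0, 1]."""
    if d1.moments.shape != d2.moments.shape:
        raise ValueError("descriptor component-count mismatch")
    if d1.mu != d2.mu:
        raise ValueError(f"descriptor charge scaling mismatch: {d1.mu} vs {d2.mu}")
    return 1.0 / (1.0 + float(np.abs(d1.moments - d2.moments).mean()))
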