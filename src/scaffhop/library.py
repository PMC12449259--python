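"""The deduplicated scaffold library and its Tanimoto retrieval index.

A library is a set of unique canonical scaffold SMILES (lone benzene is
never stored) together with a parallel list of ECFP4 fingerprints.
Retrieval is an exact linear scan — correctness first; a scan over a few
million fingerprints is still tractable offline — returning the ``top_k``
most similar entries above a similarity floor, with the query itself
excluded by canonical-SMILES identity (folded fingerprints can collide, so
fingerprint equality is not used for self-exclusion).
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from rdkit import Chem, DataStructs

from scaffhop.chem_io import MoleculeRecord, parse_smiles
from scaffhop.decompose import (
    BENZENE_SMILES,
    ScaffoldRecord,
    enumerate_hiers_scaffolds,
    find_ring_systems,
)
from scaffhop.similarity import FingerprintECFP4, ecfp4, tanimoto

logger = logging.getLogger(__name__)


@dataclass
class ScaffoldLibrary:
    entries: list[ScaffoldRecord]
    index: list[FingerprintECFP4] = field(repr=False)
    source_tag: str = ""

    def __len__(self) -> int:
        return len(self.entries)

    def smiles_set(self) -> set[str]:
        return {e.canonical_smiles for e in self.entries}

    def checksum(self) -> str:
        """Order-independent identity of the entry set (sha256, hex)."""
        payload = "\n".join(sorted(e.canonical_smiles for e in self.entries))
        return hashlib.sha256(payload.encode()).hexdigest()


def _record_for_scaffold_smiles(smiles: str) -> ScaffoldRecord | None:
    rec = parse_smiles(smiles)
    if not rec.ok:
        return None
    mol = Chem.Mol(rec.mol)
    Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol)
    n_sys = len(find_ring_systems(rec.mol))
    if n_sys == 0:
        return None
    return ScaffoldRecord(
        canonical_smiles=canonical,
        kind="basis" if n_sys == 1 else "super",
        n_ring_systems=n_sys,
    )


def _assemble(records: Iterable[ScaffoldRecord], source_tag: str) -> ScaffoldLibrary:
    benzene = Chem.CanonSmiles(BENZENE_SMILES)
    unique: dict[str, ScaffoldRecord] = {}
    for r in records:
        if r.canonical_smiles == benzene:
            continue
        unique.setdefault(r.canonical_smiles, r)
    entries = [unique[s] for s in sorted(unique)]
    index = [ecfp4(parse_smiles(e.canonical_smiles)) for e in entries]
    return ScaffoldLibrary(entries=entries, index=index, source_tag=source_tag)


def build_library(
    molecules: Iterable[MoleculeRecord], source_tag: str = "in-memory"
) -> ScaffoldLibrary:
    """Decompose every valid molecule and pool the deduplicated scaffolds.

    Invalid records are skipped (with a logged count); zero valid molecules
    is fatal.  The result is independent of input order.
    """
    scaffolds: list[ScaffoldRecord] = []
    n_ok = n_bad = 0
    for rec in molecules:
        if not rec.ok:
            n_bad += 1
            continue
        n_ok += 1
        scaffolds.extend(enumerate_hiers_scaffolds(rec))
    if n_bad:
        logger.warning("skipped %d invalid molecules while building library", n_bad)
    if n_ok == 0:
        raise ValueError("no valid molecules to build a scaffold library from")
    lib = _assemble(scaffolds, source_tag)
    logger.info("built scaffold library: %d molecules -> %d scaffolds", n_ok, len(lib))
    return lib


def save_library(lib: ScaffoldLibrary, path: str | os.PathLike) -> Path:
    """Write the library as one canonical SMILES per line (UTF-8, LF)."""
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w", encoding="utf-8", newline="\n") as fh:
        for e in lib.entries:
            fh.write(e.canonical_smiles + "\n")
    return p


def load_library(path: str | os.PathLike, source_tag: str | None = None) -> ScaffoldLibrary:
    """Load a scaffold file (one SMILES per line), normalizing as it goes.

    Lines are re-canonicalized and re-deduplicated, so user files with
    duplicate or non-canonical spellings collapse to one entry each;
    unparseable lines are skipped with a logged warning.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"scaffold library file not found: {p}")
    records: list[ScaffoldRecord] = []
    for lineno, line in enumerate(p.read_text(encoding="utf-8").splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rec = _record_for_scaffold_smiles(line.split()[0])
        if rec is None:
            logger.warning("%s:%d: skipping unparseable or acyclic scaffold %r", p, lineno, line)
            continue
        records.append(rec)
    return _assemble(records, source_tag if source_tag is not None else p.name)


def query_similar(
    lib: ScaffoldLibrary,
    query: ScaffoldRecord,
    top_k: int = 1000,
    min_sim: float = 0.0,
) -> list[tuple[ScaffoldRecord, float]]:
    """Top-k library scaffolds by ECFP4/Tanimoto similarity to the query.

    The query itself (identical canonical SMILES) is excluded; results are
    sorted by similarity descending with ties broken by canonical SMILES
    ascending, and truncated to ``top_k``.
    """
    if not lib.entries:
        raise ValueError("cannot query an empty scaffold library")
    if top_k <= 0:
        return []
    qfp = ecfp4(parse_smiles(query.canonical_smiles))
    sims = DataStructs.BulkTanimotoSimilarity(qfp.bits, [fp.bits for fp in lib.index])
    hits = [
        (entry, float(sim))
        for entry, sim in zip(lib.entries, sims)
        if sim >= min_sim and entry.canonical_smiles != query.canonical_smiles
    ]
    hits.sort(key=lambda t: (-t[1], t[0].canonical_smiles))
    return hits[:top_k]
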