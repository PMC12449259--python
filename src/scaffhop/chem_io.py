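"""SMILES parsing, validation and tabular output.

All chemistry errors are encoded in :class:`MoleculeRecord` rather than
raised, so that batch inputs never abort half-way.  The error taxonomy
distinguishes the failure modes users actually hit: malformed SMILES syntax,
multi-component (salt/complex) inputs, element symbols that do not exist,
and valence violations.  When several apply the most upstream one wins:
``syntax_error > multi_component > invalid_atom > valence_violation``
(a string that does not tokenize cannot meaningfully be component-counted).
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdmolops
from rdkit.Chem.rdchem import AtomKekulizeException, AtomValenceException, KekulizeException

if TYPE_CHECKING:  # pragma: no cover
    from scaffhop.engine import CandidateMolecule

logger = logging.getLogger(__name__)

ERROR_CLASSES = ("none", "multi_component", "invalid_atom", "valence_violation", "syntax_error")

#: columns of the candidate tables, in output order
CANDIDATE_COLUMNS = (
    "candidate_smiles",
    "replaced_scaffold",
    "replacement_scaffold",
    "tanimoto",
    "electroshape",
    "mol_weight",
    "clogp",
    "hbd",
    "hba",
    "lipinski_pass",
)

MERGED_TABLE_NAME = "candidates.tsv"


@dataclass(frozen=True)
class MoleculeRecord:
    """A validated, canonicalized molecule (or a classified parse failure)."""

    input_smiles: str
    canonical_smiles: str = ""
    n_heavy_atoms: int = 0
    n_rings: int = 0
    status: str = "error"
    error_class: str = "none"
    mol: Chem.Mol | None = field(default=None, repr=False, compare=False)

    @property
    def ok(self) -> bool:
        return self.status == "ok"

    def require_ok(self) -> Chem.Mol:
        if not self.ok or self.mol is None:
            raise ValueError(
                f"molecule {self.input_smiles!r} is not valid (error_class={self.error_class})"
            )
        return self.mol


def _error(text: str, error_class: str) -> MoleculeRecord:
    return MoleculeRecord(input_smiles=text, status="error", error_class=error_class)


_BRACKET_ATOM = re.compile(r"\[([0-9]*)([A-Za-z][a-z]?)")


def _element_symbols() -> frozenset[str]:
    pt = Chem.GetPeriodicTable()
    return frozenset(pt.GetElementSymbol(z) for z in range(1, 119))


_ELEMENTS = _element_symbols()


def _classify_parse_failure(text: str) -> str:
    """Decide between syntax_error and invalid_atom for a string RDKit rejects."""
    if text.count("(") != text.count(")") or text.count("[") != text.count("]"):
        return "syntax_error"
    # unmatched ring-closure digits (outside brackets); %nn closures counted too
    stripped = re.sub(r"\[[^]]*\]", "A", text)
    closures = re.findall(r"%\d\d|\d", stripped)
    from collections import Counter

    if any(v % 2 for v in Counter(closures).values()):
        return "syntax_error"
    for _, sym in _BRACKET_ATOM.findall(text):
        if sym in ("H", "D", "T") or sym in _ELEMENTS:
            continue
        if sym[0].islower() and sym.capitalize() in _ELEMENTS:
            continue  # aromatic spelling
        return "invalid_atom"
    # bare (unbracketed) tokens outside the organic subset, e.g. "CCXyC"
    organic = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I", "b", "c", "n", "o", "p", "s"}
    i = 0
    while i < len(stripped):
        ch = stripped[i]
        if ch.isalpha():
            two = stripped[i : i + 2]
            if two in ("Cl", "Br"):
                i += 2
                continue
            if ch not in organic and ch != "A":
                return "invalid_atom"
        i += 1
    return "syntax_error"


def parse_smiles(text: str, strip_salts: bool = False) -> MoleculeRecord:
    """Parse a SMILES string into a :class:`MoleculeRecord`.

    Never raises on bad chemistry; only an empty/whitespace input is a
    programming error.  With ``strip_salts=True`` a multi-component input is
    reduced to its largest fragment (by heavy-atom count) instead of being
    rejected.
    """
    raw = text.strip()
    if not raw:
        raise ValueError("empty SMILES input")

    mol = Chem.MolFromSmiles(raw, sanitize=False)
    if mol is None:
        return _error(raw, _classify_parse_failure(raw))

    frags = rdmolops.GetMolFrags(mol)
    if len(frags) > 1:
        if not strip_salts:
            return _error(raw, "multi_component")
        keep = max(range(len(frags)), key=lambda i: (len(frags[i]), -i))
        pieces = rdmolops.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
        mol = pieces[keep]

    if any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        return _error(raw, "invalid_atom")

    try:
        Chem.SanitizeMol(mol)
    except (AtomValenceException,):
        return _error(raw, "valence_violation")
    except (KekulizeException, AtomKekulizeException):
        return _error(raw, "syntax_error")
    except Exception:
        return _error(raw, "valence_violation")

    if mol.GetNumHeavyAtoms() == 0:
        return _error(raw, "invalid_atom")

    canonical = Chem.MolToSmiles(mol)
    return MoleculeRecord(
        input_smiles=raw,
        canonical_smiles=canonical,
        n_heavy_atoms=mol.GetNumHeavyAtoms(),
        n_rings=mol.GetRingInfo().NumRings(),
        status="ok",
        error_class="none",
        mol=mol,
    )


def read_smiles_file(path: str | os.PathLike, strip_salts: bool = False) -> list[MoleculeRecord]:
    """Read a SMILES file (one molecule per line, ``#`` comments ignored).

    The first whitespace-separated token of each line is the SMILES; any
    remainder (a name) is ignored.  Per-line failures are recorded, never
    raised, so the batch always completes.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"SMILES file not found: {p}")
    records: list[MoleculeRecord] = []
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        records.append(parse_smiles(line.split()[0], strip_salts=strip_salts))
    return records


def candidates_to_frame(candidates: Sequence["CandidateMolecule"]) -> pd.DataFrame:
    """Render candidates as a table with fixed column order and precision.

    Similarities are rounded to 4 decimals, physicochemical properties to 2.
    """
    rows = []
    for c in candidates:
        rows.append(
            {
                "candidate_smiles": c.smiles,
                "replaced_scaffold": c.replaced_scaffold,
                "replacement_scaffold": c.replacement_scaffold,
                "tanimoto": round(c.tanimoto_to_parent, 4),
                "electroshape": round(c.electroshape_to_parent, 4),
                "mol_weight": round(c.mol_weight, 2),
                "clogp": round(c.clogp, 2),
                "hbd": c.hbd,
                "hba": c.hba,
                "lipinski_pass": c.lipinski_pass,
            }
        )
    return pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS))


def _rank_key(c: "CandidateMolecule"):
    return (-c.electroshape_to_parent, -c.tanimoto_to_parent, c.smiles)


def write_candidates(
    candidates: Sequence["CandidateMolecule"],
    out_dir: str | os.PathLike,
    query_scaffolds: Iterable[str] | None = None,
) -> dict[str, Path]:
    """Write one TSV per replaced scaffold plus a merged, globally ranked table.

    Rows are ordered by the pipeline ranking (ElectroShape similarity
    descending, then Tanimoto descending, then canonical SMILES).  The merged
    table is deduplicated by candidate SMILES, keeping the best-ranked
    instance.  ``query_scaffolds``, when given, forces a (possibly
    header-only) table for every query scaffold even if none of its
    candidates survived.  Returns a mapping from table label to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not os.access(out, os.W_OK):
        raise PermissionError(f"output directory not writable: {out}")

    paths: dict[str, Path] = {}
    scaffolds = sorted({c.replaced_scaffold for c in candidates} | set(query_scaffolds or ()))
    for i, scaf in enumerate(scaffolds, start=1):
        sub = sorted((c for c in candidates if c.replaced_scaffold == scaf), key=_rank_key)
        path = out / f"scaffold_{i:03d}.tsv"
        candidates_to_frame(sub).to_csv(path, sep="\t", index=False)
        paths[scaf] = path

    best: dict[str, "CandidateMolecule"] = {}
    for c in sorted(candidates, key=_rank_key):
        best.setdefault(c.smiles, c)
    merged = sorted(best.values(), key=_rank_key)
    merged_path = out / MERGED_TABLE_NAME
    candidates_to_frame(merged).to_csv(merged_path, sep="\t", index=False)
    paths["merged"] = merged_path
    logger.info("wrote %d per-scaffold tables and %d merged rows", len(scaffolds), len(merged))
    return paths


def read_candidate_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a TSV produced by :func:`write_candidates`."""
    return pd.read_csv(path, sep="\t")
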