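"""Scaffold replacement (grafting), filtering, scoring and ranking.

The central operation: given a parent molecule and one of its scaffolds,
sever the bonds leaving the scaffold (the *exit vectors*, each carrying its
substituent fragment and bond order), and re-attach those substituents onto
a replacement scaffold drawn from the library.  Attachment sites are
enumerated injectively over replacement atoms with enough free valence, in
canonical-rank order, capped at ``max_assignments`` per (match, replacement)
pair; chemically unsound assignments are discarded at sanitization.

Candidates are then filtered (whole-molecule Tanimoto to the parent >= the
run threshold; optional preserved-core substructure; optional rule-of-five),
scored with ElectroShape similarity to the parent, ranked lexicographically
by (ElectroShape desc, Tanimoto desc, SMILES asc) and capped per query
scaffold before a global deduplication.

Stereochemistry at severed bonds is dropped (grafting invalidates local
chirality perception); candidates are compared and reported as
constitutional canonical SMILES.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski
from rdkit.Chem.rdchem import RWMol

from scaffhop.chem_io import MoleculeRecord, parse_smiles
from scaffhop.decompose import ScaffoldRecord, enumerate_hiers_scaffolds
from scaffhop.library import ScaffoldLibrary, query_similar
from scaffhop.similarity import (
    DegenerateGeometryError,
    EmbeddingError,
    ecfp4,
    electroshape,
    electroshape_similarity,
    embed_conformer,
    tanimoto,
)

logger = logging.getLogger(__name__)

_BOND_TYPE = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE, 3.0: Chem.BondType.TRIPLE}


@dataclass(frozen=True)
class ExitVector:
    """A severed bond from a scaffold atom to a substituent fragment."""

    scaffold_atom: int  # atom index in the parent molecule
    substituent_atom: int  # parent index of the substituent-side atom
    bond_order: float
    fragment: Chem.Mol = field(repr=False, compare=False)  # attachment atom map-numbered


@dataclass(frozen=True)
class ScaffoldMatch:
    atom_indices: tuple[int, ...]
    exit_vectors: tuple[ExitVector, ...]


@dataclass(frozen=True)
class AttachmentMap:
    """An injective assignment of exit vectors onto replacement-scaffold atoms."""

    exit_vectors: tuple[ExitVector, ...]
    assignment: tuple[int, ...]  # replacement atom index per exit vector


@dataclass
class CandidateMolecule:
    smiles: str
    replaced_scaffold: str
    replacement_scaffold: str
    tanimoto_to_parent: float = 0.0
    electroshape_to_parent: float = 0.0
    mol_weight: float = 0.0
    clogp: float = 0.0
    hbd: int = 0
    hba: int = 0
    lipinski_pass: bool = False
    contains_core: bool = False


@dataclass
class HoppingParams:
    """Run parameters for the hopping pipeline.

    ``n_per_fragment`` caps output per query scaffold; ``tanimoto_threshold``
    is the whole-molecule similarity floor against the parent;
    ``n_fragment_candidates`` is the library retrieval depth per scaffold.
    """

    n_per_fragment: int = 10
    tanimoto_threshold: float = 0.5
    n_fragment_candidates: int = 1000
    lipinski_filter: bool = False
    core_smiles: str | None = None
    seed: int = 42
    max_assignments: int = 100

    def __post_init__(self):
        if not (0.0 <= self.tanimoto_threshold <= 1.0):
            raise ValueError("tanimoto_threshold must lie in [0, 1]")
        if self.n_per_fragment <= 0 or self.n_fragment_candidates <= 0:
            raise ValueError("candidate counts must be positive")


def _canonical(mol: Chem.Mol) -> str:
    m = Chem.Mol(mol)
    Chem.RemoveStereochemistry(m)
    return Chem.MolToSmiles(m)


def locate_scaffold(parent_record: MoleculeRecord, scaffold: ScaffoldRecord) -> list[ScaffoldMatch]:
    """All symmetry-distinct substructure matches of a scaffold in its parent,
    each with the exit vectors carrying the severed substituent fragments."""
    parent = parent_record.require_ok()
    query = Chem.MolFromSmiles(scaffold.canonical_smiles)
    matches = parent.GetSubstructMatches(query, uniquify=True)
    if not matches:
        raise RuntimeError(
            f"scaffold {scaffold.canonical_smiles} does not match parent "
            f"{parent_record.canonical_smiles}: inconsistent decomposition"
        )
    out: list[ScaffoldMatch] = []
    for match in matches:
        mset = set(match)
        raw_exits: list[tuple[int, int, float]] = []
        for i in sorted(mset):
            for b in parent.GetAtomWithIdx(i).GetBonds():
                j = b.GetOtherAtomIdx(i)
                if j not in mset:
                    raw_exits.append((i, j, b.GetBondTypeAsDouble()))
        frags = _sever_fragments(parent, mset, raw_exits)
        if frags is None:
            logger.debug("skipping match with multiply-attached substituent")
            continue
        evs = tuple(
            ExitVector(scaffold_atom=i, substituent_atom=j, bond_order=o, fragment=frags[k])
            for k, (i, j, o) in enumerate(raw_exits)
        )
        out.append(ScaffoldMatch(atom_indices=tuple(match), exit_vectors=evs))
    return out


def _sever_fragments(
    parent: Chem.Mol, mset: set[int], exits: list[tuple[int, int, float]]
) -> dict[int, Chem.Mol] | None:
    """Cut the scaffold atoms out of the parent and return, per exit-vector
    index, the substituent fragment with its attachment atom map-numbered
    ``k+1``.  Returns None when a fragment touches the scaffold more than
    once (an unsupported, necessarily cyclic arrangement)."""
    rw = RWMol(Chem.Mol(parent))
    Chem.Kekulize(rw, clearAromaticFlags=True)
    for k, (_i, j, _o) in enumerate(exits):
        rw.GetAtomWithIdx(j).SetAtomMapNum(k + 1)
    for i in sorted(mset, reverse=True):
        rw.RemoveAtom(i)
    pieces = Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=False)
    frags: dict[int, Chem.Mol] = {}
    for piece in pieces:
        tags = [a.GetAtomMapNum() for a in piece.GetAtoms() if a.GetAtomMapNum()]
        if len(tags) != 1:
            return None
        frags[tags[0] - 1] = piece
    if len(frags) != len(exits):
        return None
    return frags


def graft(
    parent_record: MoleculeRecord,
    match: ScaffoldMatch,
    replacement: ScaffoldRecord,
    max_assignments: int = 100,
    replaced_smiles: str | None = None,
) -> list[CandidateMolecule]:
    """Replace the matched scaffold with ``replacement``, re-attaching every
    substituent.  Returns unscored candidates, deduplicated by canonical
    SMILES and sorted; empty when the replacement cannot host all exit
    vectors."""
    repl_parsed = parse_smiles(replacement.canonical_smiles)
    if not repl_parsed.ok:
        return []
    repl = Chem.Mol(repl_parsed.mol)
    repl_k = Chem.Mol(repl)
    Chem.Kekulize(repl_k, clearAromaticFlags=True)

    n_exits = len(match.exit_vectors)
    if n_exits == 0:
        smi = Chem.CanonSmiles(replacement.canonical_smiles)
        return [
            CandidateMolecule(
                smiles=smi,
                replaced_scaffold=replaced_smiles or "",
                replacement_scaffold=replacement.canonical_smiles,
            )
        ]

    ranks = list(Chem.CanonicalRankAtoms(repl, breakTies=False))
    atom_order = sorted(range(repl.GetNumAtoms()), key=lambda i: (ranks[i], i))

    products: set[str] = set()
    n_explored = 0
    for assignment in itertools.permutations(atom_order, n_exits):
        if n_explored >= max_assignments:
            break
        if not all(
            repl_k.GetAtomWithIdx(a).GetTotalNumHs() >= ev.bond_order
            for a, ev in zip(assignment, match.exit_vectors)
        ):
            continue
        n_explored += 1
        product = _assemble_product(repl_k, match.exit_vectors, assignment)
        if product is not None:
            products.add(product)
    logger.debug(
        "graft %s -> %s: %d assignments explored, %d distinct products",
        replaced_smiles,
        replacement.canonical_smiles,
        n_explored,
        len(products),
    )
    return [
        CandidateMolecule(
            smiles=s,
            replaced_scaffold=replaced_smiles or "",
            replacement_scaffold=replacement.canonical_smiles,
        )
        for s in sorted(products)
    ]


def _assemble_product(
    repl_k: Chem.Mol, exits: tuple[ExitVector, ...], assignment: tuple[int, ...]
) -> str | None:
    rw = RWMol(repl_k)
    attach_for: dict[int, int] = {}
    for k, ev in enumerate(exits):
        base = rw.GetNumAtoms()
        rw.InsertMol(ev.fragment)
        for idx in range(base, rw.GetNumAtoms()):
            if rw.GetAtomWithIdx(idx).GetAtomMapNum() == k + 1:
                attach_for[k] = idx
    for k, (repl_atom, ev) in enumerate(zip(assignment, exits)):
        rw.AddBond(repl_atom, attach_for[k], _BOND_TYPE[ev.bond_order])
    product = rw.GetMol()
    for a in product.GetAtoms():
        a.SetAtomMapNum(0)
    try:
        Chem.SanitizeMol(product)
    except Exception:
        return None
    return _canonical(product)


def lipinski_pass(mol_or_record) -> bool:
    """Classic rule of five: MW <= 500 Da, cLogP <= 5, HBD <= 5, HBA <= 10
    (boundaries inclusive)."""
    mol = mol_or_record.require_ok() if isinstance(mol_or_record, MoleculeRecord) else mol_or_record
    return (
        Descriptors.MolWt(mol) <= 500.0
        and Crippen.MolLogP(mol) <= 5.0
        and Lipinski.NumHDonors(mol) <= 5
        and Lipinski.NumHAcceptors(mol) <= 10
    )


def _score_properties(c: CandidateMolecule, mol: Chem.Mol) -> None:
    c.mol_weight = Descriptors.MolWt(mol)
    c.clogp = Crippen.MolLogP(mol)
    c.hbd = Lipinski.NumHDonors(mol)
    c.hba = Lipinski.NumHAcceptors(mol)
    c.lipinski_pass = (
        c.mol_weight <= 500.0 and c.clogp <= 5.0 and c.hbd <= 5 and c.hba <= 10
    )


def _rank_key(c: CandidateMolecule):
    return (-c.electroshape_to_parent, -c.tanimoto_to_parent, c.smiles)


class RunCounters(dict):
    """Per-stage event counts exposed for logging and the run manifest."""

    def bump(self, key: str, by: int = 1) -> None:
        self[key] = self.get(key, 0) + by


def run_hopping(
    parent_record: MoleculeRecord,
    lib: ScaffoldLibrary,
    params: HoppingParams | None = None,
    counters: RunCounters | None = None,
) -> list[CandidateMolecule]:
    """The full scaffold-hopping pipeline for one parent molecule.

    For every scaffold of the parent: retrieve similar library scaffolds,
    graft each into the parent, filter by whole-molecule Tanimoto threshold
    (and core/rule-of-five constraints when requested), score survivors with
    ElectroShape similarity to the parent, rank, cap per scaffold, then
    deduplicate globally keeping the best-ranked instance.  The parent
    itself is never emitted.
    """
    params = params or HoppingParams()
    counters = counters if counters is not None else RunCounters()
    parent = parent_record.require_ok()
    if parent.GetRingInfo().NumRings() == 0:
        raise ValueError(
            f"parent molecule {parent_record.canonical_smiles} is acyclic: "
            "scaffold hopping needs at least one ring"
        )
    if not lib.entries:
        raise ValueError("scaffold library is empty")

    core = None
    if params.core_smiles:
        core = Chem.MolFromSmiles(params.core_smiles)
        if core is None:
            raise ValueError(f"core_smiles does not parse: {params.core_smiles!r}")

    parent_canonical = _canonical(parent)
    parent_fp = ecfp4(parent)
    parent_desc = electroshape(embed_conformer(parent_record, seed=params.seed))

    scaffolds = sorted(
        enumerate_hiers_scaffolds(parent_record), key=lambda s: s.canonical_smiles
    )
    counters.bump("scaffolds_found", len(scaffolds))

    kept: list[CandidateMolecule] = []
    for scaffold in scaffolds:
        hits = query_similar(lib, scaffold, top_k=params.n_fragment_candidates)
        counters.bump("library_hits", len(hits))
        pooled: dict[str, CandidateMolecule] = {}
        for scaff_match in locate_scaffold(parent_record, scaffold):
            for repl, _sim in hits:
                for cand in graft(
                    parent_record,
                    scaff_match,
                    repl,
                    max_assignments=params.max_assignments,
                    replaced_smiles=scaffold.canonical_smiles,
                ):
                    counters.bump("grafts_generated")
                    pooled.setdefault(cand.smiles, cand)

        survivors: list[CandidateMolecule] = []
        for smi in sorted(pooled):
            cand = pooled[smi]
            if smi == parent_canonical:
                counters.bump("parent_identical_removed")
                continue
            rec = parse_smiles(smi)
            if not rec.ok:
                counters.bump("sanitization_failures")
                continue
            cand.tanimoto_to_parent = tanimoto(parent_fp, ecfp4(rec))
            if cand.tanimoto_to_parent < params.tanimoto_threshold:
                counters.bump("threshold_rejections")
                continue
            if core is not None:
                cand.contains_core = rec.mol.HasSubstructMatch(core)
                if not cand.contains_core:
                    counters.bump("core_rejections")
                    continue
            _score_properties(cand, rec.mol)
            if params.lipinski_filter and not cand.lipinski_pass:
                counters.bump("lipinski_rejections")
                continue
            try:
                desc = electroshape(embed_conformer(rec, seed=params.seed))
            except (EmbeddingError, DegenerateGeometryError) as exc:
                counters.bump("conformer_failures")
                logger.warning("skipping %s: %s", smi, exc)
                continue
            cand.electroshape_to_parent = electroshape_similarity(parent_desc, desc)
            survivors.append(cand)

        survivors.sort(key=_rank_key)
        kept.extend(survivors[: params.n_per_fragment])

    best: dict[str, CandidateMolecule] = {}
    for cand in sorted(kept, key=_rank_key):
        best.setdefault(cand.smiles, cand)
    result = sorted(best.values(), key=_rank_key)
    counters.bump("candidates_emitted", len(result))
    return result
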