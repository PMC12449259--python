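"""Hierarchical (HierS-style) scaffold decomposition.

A molecule is partitioned into *ring systems* (rings fused, bridged or
spiro-joined into one connected ring subgraph, augmented with exocyclic
atoms multiply bonded to ring atoms), *linkers* (acyclic paths connecting
two ring systems, keeping atoms multiply bonded to linker atoms) and *side
chains* (everything else).  The root scaffold drops all side chains; the
enumeration then recursively deletes one ring system at a time — pruning the
dangling linker back towards the surviving rings — and collects every
distinct intermediate down to the single-ring-system *basis* scaffolds.

Two conventions matter throughout:

* scaffold identity is constitutional — stereochemistry is stripped before
  canonicalization;
* a lone benzene ring is never reported as a basis scaffold (it is ubiquitous
  and carries no scaffold-hopping signal), while larger scaffolds containing
  benzene rings (biphenyl, stilbene, ...) are kept.

Multiply-bonded atoms are preserved *within their own structural
component*: a ring system keeps its exocyclic double-bond partners and a
retained linker keeps its carbonyl-style appendages, but when a ring-system
deletion leaves a linker dangling the whole linker goes, multiply-bonded
atoms included (the dangling carbonyl of a benzophenone fragment or an azo
``N=N`` stub is not a scaffold).  Concretely, every child scaffold is
re-derived by applying the side-chain-stripping operation to each
ring-containing fragment, which makes the recursion agree exactly with a
direct enumeration of connected ring-system subsets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem
from rdkit.Chem.rdchem import RWMol

from scaffhop.chem_io import MoleculeRecord, parse_smiles

logger = logging.getLogger(__name__)

BENZENE_SMILES = "c1ccccc1"


@dataclass(frozen=True)
class RingSystem:
    """One connected ring subgraph plus its protected exocyclic atoms."""

    atom_indices: frozenset[int]
    includes_exocyclic: frozenset[int]

    @property
    def all_atoms(self) -> frozenset[int]:
        return self.atom_indices | self.includes_exocyclic


@dataclass(frozen=True)
class ScaffoldRecord:
    canonical_smiles: str
    kind: str  # "basis" | "super"
    n_ring_systems: int

    def __post_init__(self):
        if self.kind == "basis" and self.n_ring_systems != 1:
            raise ValueError("basis scaffold must have exactly one ring system")


@dataclass
class ScaffoldSet:
    parent: MoleculeRecord
    scaffolds: list[ScaffoldRecord] = field(default_factory=list)

    def smiles_set(self) -> set[str]:
        return {s.canonical_smiles for s in self.scaffolds}

    def __len__(self) -> int:
        return len(self.scaffolds)

    def __iter__(self):
        return iter(self.scaffolds)


def _as_mol(mol_or_record) -> Chem.Mol:
    if isinstance(mol_or_record, MoleculeRecord):
        return mol_or_record.require_ok()
    return mol_or_record


def _canonical_scaffold_smiles(mol: Chem.Mol) -> str:
    m = Chem.Mol(mol)
    Chem.RemoveStereochemistry(m)
    return Chem.MolToSmiles(m)


def _kekulized_rw(mol: Chem.Mol) -> RWMol:
    m = Chem.Mol(mol)
    Chem.Kekulize(m, clearAromaticFlags=True)
    return RWMol(m)


def find_ring_systems(mol_or_record) -> list[RingSystem]:
    """Connected components of the ring-bond subgraph, with exocyclic atoms.

    Fused, bridged and spiro rings merge into one system (spiro rings share
    an atom, hence one component).  A non-ring atom joined to a ring atom by
    a bond of order > 1 (e.g. a quinone or indanone oxygen) belongs to the
    system.  Acyclic molecules yield an empty list.
    """
    mol = _as_mol(mol_or_record)
    g = nx.Graph()
    g.add_nodes_from(a.GetIdx() for a in mol.GetAtoms() if a.IsInRing())
    for b in mol.GetBonds():
        if b.IsInRing():
            g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    systems = []
    for comp in nx.connected_components(g):
        exo = set()
        for i in comp:
            for b in mol.GetAtomWithIdx(i).GetBonds():
                j = b.GetOtherAtomIdx(i)
                if (
                    j not in comp
                    and not mol.GetAtomWithIdx(j).IsInRing()
                    and b.GetBondTypeAsDouble() > 1.0
                ):
                    exo.add(j)
        systems.append(RingSystem(frozenset(comp), frozenset(exo)))
    systems.sort(key=lambda rs: min(rs.atom_indices))
    return systems


def _superscaffold_atoms(mol: Chem.Mol) -> set[int] | None:
    """Atom indices retained in the side-chain-free root scaffold."""
    systems = find_ring_systems(mol)
    if not systems:
        return None
    keep: set[int] = set()
    for rs in systems:
        keep |= rs.all_atoms

    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    for b in mol.GetBonds():
        g.add_edge(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
    system_of = {i: k for k, rs in enumerate(systems) for i in rs.atom_indices}

    # linker atoms: on the acyclic tree-path between two different ring systems
    nonkeep = set(range(mol.GetNumAtoms())) - keep
    linker: set[int] = set()
    for comp in nx.connected_components(g.subgraph(nonkeep)):
        attachments: dict[int, set[int]] = {}
        for i in comp:
            for j in g.neighbors(i):
                if j in system_of:
                    attachments.setdefault(system_of[j], set()).add(j)
        if len(attachments) < 2:
            continue  # side chain: touches at most one ring system
        sub = g.subgraph(comp | {a for s in attachments.values() for a in s})
        anchors = [a for s in attachments.values() for a in s]
        for a1, a2 in itertools.combinations(anchors, 2):
            if system_of[a1] == system_of[a2]:
                continue
            try:
                path = nx.shortest_path(sub, a1, a2)
            except nx.NetworkXNoPath:
                continue
            linker |= set(path) & comp
    keep |= linker

    # atoms multiply bonded to kept linker atoms are part of the linker pi system
    changed = True
    while changed:
        changed = False
        for b in mol.GetBonds():
            if b.GetBondTypeAsDouble() <= 1.0:
                continue
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if (i in keep) != (j in keep):
                outside = j if i in keep else i
                inside = i if i in keep else j
                if inside not in system_of and outside not in keep:
                    keep.add(outside)
                    changed = True
    return keep


def _extract(mol: Chem.Mol, keep: set[int]) -> Chem.Mol:
    rw = _kekulized_rw(mol)
    for i in sorted(set(range(mol.GetNumAtoms())) - keep, reverse=True):
        rw.RemoveAtom(i)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def murcko_superscaffold(mol_or_record) -> ScaffoldRecord | None:
    """Remove all side chains, retaining ring systems, linkers and protected
    exocyclic atoms.  Returns ``None`` for acyclic molecules."""
    mol = _as_mol(mol_or_record)
    keep = _superscaffold_atoms(mol)
    if keep is None:
        return None
    scaffold = _extract(mol, keep)
    n_sys = len(find_ring_systems(scaffold))
    return ScaffoldRecord(
        canonical_smiles=_canonical_scaffold_smiles(scaffold),
        kind="basis" if n_sys == 1 else "super",
        n_ring_systems=n_sys,
    )


def _children_after_removal(mol: Chem.Mol, rs_index: int) -> list[Chem.Mol]:
    """Delete ring system `rs_index` (with its exocyclic atoms) and return
    the ring-containing fragments, each stripped back to its own
    side-chain-free scaffold (dangling linkers — multiply-bonded atoms
    included — are side chains of the fragment and disappear)."""
    systems = find_ring_systems(mol)
    gone = set(systems[rs_index].all_atoms)
    rw = _kekulized_rw(mol)
    for i in sorted(gone, reverse=True):
        rw.RemoveAtom(i)
    interim = rw.GetMol()
    if interim.GetNumAtoms() == 0:
        return []
    children = []
    for frag in Chem.GetMolFrags(interim, asMols=True, sanitizeFrags=True):
        if frag.GetRingInfo().NumRings() == 0:
            continue
        keep = _superscaffold_atoms(frag)
        if keep is None:  # unreachable given the ring check; defensive
            continue
        children.append(_extract(frag, keep))
    return children


def enumerate_hiers_scaffolds(mol_or_record) -> ScaffoldSet:
    """Enumerate all scaffolds of a molecule by recursive ring-system removal.

    Starting from the side-chain-free root scaffold, each ring system is
    deleted in turn; when a deletion disconnects the remainder, every
    ring-containing fragment is recursed independently.  The result is the
    deduplicated set of every scaffold encountered, with single-ring-system
    scaffolds equal to benzene excluded.
    """
    if isinstance(mol_or_record, MoleculeRecord):
        record = mol_or_record
    else:
        record = parse_smiles(Chem.MolToSmiles(mol_or_record))
    mol = record.require_ok()

    result = ScaffoldSet(parent=record)
    keep = _superscaffold_atoms(mol)
    if keep is None:
        logger.warning("acyclic molecule %s has no scaffolds", record.canonical_smiles)
        return result

    benzene = Chem.CanonSmiles(BENZENE_SMILES)
    seen: dict[str, int] = {}
    stack = [_extract(mol, keep)]
    while stack:
        cur = stack.pop()
        smi = _canonical_scaffold_smiles(cur)
        if smi in seen:
            continue
        n_sys = len(find_ring_systems(cur))
        seen[smi] = n_sys
        for k in range(n_sys):
            stack.extend(_children_after_removal(cur, k))

    for smi in sorted(seen):
        n_sys = seen[smi]
        if n_sys == 1 and smi == benzene:
            continue
        result.scaffolds.append(
            ScaffoldRecord(
                canonical_smiles=smi,
                kind="basis" if n_sys == 1 else "super",
                n_ring_systems=n_sys,
            )
        )
    return result
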