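"""Independent brute-force oracles used by the test suite and the
acceptance script.

Everything here is deliberately written against RDKit primitives and plain
Python (union-find, explicit loops) rather than through the package's own
code paths, so that agreement between the two is meaningful.
"""

from __future__ import annotations

import itertools
import math
import random

from rdkit import Chem
from rdkit.Chem.rdchem import RWMol

BENZENE = Chem.CanonSmiles("c1ccccc1")


# ---------------------------------------------------------------------------
# scaffold-set oracle: enumerate all connected ring-system subsets
# ---------------------------------------------------------------------------

def oracle_ring_systems(mol: Chem.Mol) -> list[set[int]]:
    """Ring systems by union-find over SSSR rings that share atoms."""
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    merged = True
    while merged:
        merged = False
        for i, j in itertools.combinations(range(len(rings)), 2):
            if rings[i] and rings[j] and rings[i] & rings[j]:
                rings[i] |= rings[j]
                rings[j] = set()
                merged = True
    return sorted((r for r in rings if r), key=min)


def _exocyclic(mol: Chem.Mol, system: set[int]) -> set[int]:
    exo = set()
    for i in system:
        for b in mol.GetAtomWithIdx(i).GetBonds():
            j = b.GetOtherAtomIdx(i)
            if j not in system and not mol.GetAtomWithIdx(j).IsInRing():
                if b.GetBondTypeAsDouble() > 1.0:
                    exo.add(j)
    return exo


def _render_subset(mol: Chem.Mol, systems: list[set[int]], chosen: tuple[int, ...]) -> str | None:
    """Canonical SMILES of the chosen ring systems plus their internal
    linkers, or None when the selection is not a single connected scaffold."""
    keep: set[int] = set()
    for k in chosen:
        keep |= systems[k] | _exocyclic(mol, systems[k])
    absent: set[int] = set()
    for k in range(len(systems)):
        if k not in chosen:
            absent |= systems[k] | _exocyclic(mol, systems[k])

    # linker atoms: acyclic paths between anchors of two chosen systems that
    # avoid every absent ring system
    n = mol.GetNumAtoms()
    adj = {i: set() for i in range(n)}
    for b in mol.GetBonds():
        adj[b.GetBeginAtomIdx()].add(b.GetEndAtomIdx())
        adj[b.GetEndAtomIdx()].add(b.GetBeginAtomIdx())

    def bfs_path(src: int, dst: int) -> list[int] | None:
        # through acyclic atoms only (endpoints are ring atoms)
        prev = {src: None}
        queue = [src]
        while queue:
            cur = queue.pop(0)
            for nxt in sorted(adj[cur]):
                if nxt in prev or nxt in absent:
                    continue
                if nxt != dst and mol.GetAtomWithIdx(nxt).IsInRing():
                    continue
                prev[nxt] = cur
                if nxt == dst:
                    path = [dst]
                    while path[-1] is not None:
                        path.append(prev[path[-1]])
                    return path[:-1]
                queue.append(nxt)
        return None

    linker: set[int] = set()
    for ka, kb in itertools.combinations(chosen, 2):
        for a in sorted(systems[ka]):
            for bnd in sorted(systems[kb]):
                path = bfs_path(a, bnd)
                if path is not None:
                    linker |= {p for p in path if not mol.GetAtomWithIdx(p).IsInRing()}
    keep |= linker

    # multiply-bonded appendages of linker atoms, to closure
    grown = True
    while grown:
        grown = False
        for b in mol.GetBonds():
            if b.GetBondTypeAsDouble() <= 1.0:
                continue
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            for inside, outside in ((i, j), (j, i)):
                if (
                    inside in keep
                    and not mol.GetAtomWithIdx(inside).IsInRing()
                    and outside not in keep
                    and outside not in absent
                    and not mol.GetAtomWithIdx(outside).IsInRing()
                ):
                    keep.add(outside)
                    grown = True

    work = Chem.Mol(mol)
    Chem.Kekulize(work, clearAromaticFlags=True)
    rw = RWMol(work)
    for i in sorted(set(range(n)) - keep, reverse=True):
        rw.RemoveAtom(i)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if len(Chem.GetMolFrags(out)) != 1:
        return None
    if len(oracle_ring_systems(out)) != len(chosen):
        return None
    Chem.RemoveStereochemistry(out)
    return Chem.MolToSmiles(out)


def oracle_scaffold_set(mol: Chem.Mol) -> set[str]:
    """All scaffolds by brute-force enumeration of non-empty connected
    ring-system subsets, lone-benzene basis scaffolds excluded."""
    systems = oracle_ring_systems(mol)
    out: set[str] = set()
    for size in range(1, len(systems) + 1):
        for chosen in itertools.combinations(range(len(systems)), size):
            smi = _render_subset(mol, systems, chosen)
            if smi is None:
                continue
            if size == 1 and smi == BENZENE:
                continue
            out.add(smi)
    return out


# ---------------------------------------------------------------------------
# random ring-molecule generator (for oracle-equivalence sweeps)
# ---------------------------------------------------------------------------

_RING_PIECES = (
    "c1ccccc1",
    "c1ccncc1",
    "c1cncnc1",
    "c1ccsc1",
    "c1ccoc1",
    "c1cc[nH]c1",
    "C1CCNCC1",
    "C1CCOCC1",
    "C1CCCCC1",
    "c1ccc2ccccc2c1",
    "c1ccc2[nH]ccc2c1",
    "C1CCC2(CC1)CCCC2",
)

_LINK_PIECES = ("", "C", "CC", "CCC", "O", "N", "C(=O)", "C(=O)N", "CO", "C=C", "N=N", "S")

_SIDE_PIECES = ("C", "CC", "O", "N", "C(=O)O", "C#N", "F", "OC")


def random_ring_molecule(rng: random.Random, max_systems: int = 4) -> Chem.Mol:
    """A random chain of 1-4 ring systems joined by random linkers, with an
    optional terminal side chain.  Always parses."""
    while True:
        k = rng.randint(1, max_systems)
        parts = [rng.choice(_RING_PIECES)]
        for _ in range(k - 1):
            parts.append(rng.choice(_LINK_PIECES))
            parts.append(rng.choice(_RING_PIECES))
        if rng.random() < 0.4:
            parts.append(rng.choice(_SIDE_PIECES))
        mol = Chem.MolFromSmiles("".join(parts))
        if mol is not None:
            return mol


# ---------------------------------------------------------------------------
# fingerprint similarity oracle
# ---------------------------------------------------------------------------

def tanimoto_sets(a: set[int], b: set[int]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# independent ElectroShape computation (plain loops, math module)
# ---------------------------------------------------------------------------

def oracle_electroshape(coords, charges, mu: float = 25.0) -> list[float]:
    pts = [(x, y, z, mu * q) for (x, y, z), q in zip(coords, charges)]
    n = len(pts)

    def dist(p, q):
        return math.sqrt(sum((pi - qi) ** 2 for pi, qi in zip(p, q)))

    c1 = tuple(sum(p[d] for p in pts) / n for d in range(4))
    c2 = max(pts, key=lambda p: dist(p, c1))
    c3 = max(pts, key=lambda p: dist(p, c2))
    a = tuple(c2[d] - c1[d] for d in range(4))
    b = tuple(c3[d] - c1[d] for d in range(4))
    cx = (
        a[1] * b[2] - a[2] * b[1],
        a[2] * b[0] - a[0] * b[2],
        a[0] * b[1] - a[1] * b[0],
    )
    norm_cx = math.sqrt(sum(c * c for c in cx))
    norm_a = math.sqrt(sum(x * x for x in a))
    scale = norm_a / (2.0 * norm_cx)
    spatial = tuple(c1[d] + scale * cx[d] for d in range(3))
    c4 = spatial + (mu * max(charges),)
    c5 = spatial + (mu * min(charges),)

    out = []
    for ref in (c1, c2, c3, c4, c5):
        ds = [dist(p, ref) for p in pts]
        mean = sum(ds) / n
        var = sum((d - mean) ** 2 for d in ds) / n
        third = sum((d - mean) ** 3 for d in ds) / n
        out.extend([mean, math.sqrt(var), math.copysign(abs(third) ** (1 / 3), third)])
    return out
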