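# Methods

## Scaffold model

A *ring system* is a connected component of the ring-bond subgraph: fused,
bridged and spiro rings collapse into one system (spiro rings share an atom,
hence one component). Ring perception uses the toolkit's smallest set of
smallest rings. A ring system additionally owns every acyclic atom joined to
one of its ring atoms by a bond of order > 1 (quinone and indanone oxygens,
exocyclic methylenes), so oxidation state is part of scaffold identity.

*Linkers* are the acyclic atoms lying on a path between two ring systems,
plus the closure of atoms multiply bonded to linker atoms (a benzophenone
linker keeps its carbonyl oxygen). Everything else is *side chain* and is
removed when forming the root (Murcko-style) scaffold. Multiply-bonded atoms
are preserved *within their own structural component* only: when a
ring-system deletion leaves a linker dangling, the whole linker disappears,
its double-bonded appendages included — a dangling `C=O` or `N=N` stub is
not a scaffold, and every scaffold terminates in rings on all branches.
Concretely, each child scaffold is re-derived by applying the side-chain
stripping operation to each ring-containing fragment left after deleting a
ring system. This choice makes the recursion provably equivalent to direct
enumeration of connected ring-system subsets, which is what the test suite
asserts against a brute-force oracle.

Scaffold identity is constitutional: stereochemistry is stripped before
canonicalization (replacement scaffolds come from heterogeneous parents, and
grafting invalidates local chirality perception anyway). Scaffolds carry no
explicit attachment markers; open valences are implicit hydrogens.

The enumeration excludes a lone benzene ring as a basis scaffold (it is
ubiquitous and has no discriminating value for hopping) but keeps
superscaffolds that contain benzene rings, e.g. biphenyl. Removal of a ring
system that disconnects the remainder recurses into each ring-containing
fragment independently; this is required for the recursion to terminate in
basis scaffolds on branched architectures.

## Library

The scaffold library is the deduplicated union of the enumeration applied to
any molecule collection; the file format is one canonical SMILES per line.
Loading re-canonicalizes and re-deduplicates, so user files with duplicate
or non-canonical spellings normalize transparently. Both basis scaffolds and
superscaffolds are stored: superscaffold replacements permit more aggressive
hops while remaining synthetically meaningful fragments of real molecules.
Retrieval is an exact linear Tanimoto scan over 2048-bit ECFP4 fingerprints
(radius 2) — no approximate nearest-neighbour index; correctness and
determinism outweigh speed at the library sizes involved, and a linear scan
over millions of fingerprints remains tractable offline. The query scaffold
itself is excluded from retrieval by canonical-SMILES identity rather than
fingerprint equality, because folded fingerprints can collide.

## Grafting

For each symmetry-distinct substructure match of a query scaffold in the
parent, the bonds leaving the scaffold are severed; each carries its
substituent fragment and bond order. Substituents are re-attached by
enumerating injective assignments onto replacement-scaffold atoms with
sufficient free valence (total hydrogen count ≥ incoming bond order), in
canonical-rank order, capped at `max_assignments = 100` per
(match, replacement) pair to bound combinatorial blowup; duplicate products
collapse by canonical SMILES, and assignments that fail sanitization are
dropped and counted. A substituent fragment attached to the scaffold at more
than one atom (only possible through a macrocycle, which ring perception
normally absorbs) is unsupported and the match is skipped. Surgery is
performed on kekulized structures and aromaticity is re-perceived on the
product, so swaps between aromatic and saturated scaffolds are legal.

## Scoring

Two similarity measures are deliberately kept separate rather than combined
into one score:

* **Tanimoto (ECFP4, 2048 bits)** is applied to the *whole generated
  molecule* against the whole input — the `-t` threshold (default 0.5)
  controls how conservative the run is; scaffold-level Tanimoto is used only
  for library retrieval. Two all-zero fingerprints are defined as identical
  (similarity 1).
* **ElectroShape** rescoring: each atom (hydrogens included, so charges sum
  to the net formal charge) becomes a 4D point (x, y, z, μ·q) with Gasteiger
  partial charge q clipped to [−1, 1] against unparameterized atoms and
  μ = 25 Å per elementary charge, the constant published with the method,
  stored in the descriptor so mismatched comparisons fail loudly. Reference
  points: c1 the 4D centroid, c2 the atom point farthest from c1, c3 the atom
  point farthest from c2; with a = c2−c1, b = c3−c1 and their spatial parts
  a₃, b₃, the offset c = (|a| / (2|a₃×b₃|))·(a₃×b₃) from the spatial centroid
  defines c4 and c5, whose fourth coordinates are μ·max(q) and μ·min(q) —
  the cross product makes the descriptor chirality-sensitive. For each
  reference point the mean, population standard deviation and cube-rooted
  third central moment (sign preserved) of its distances to all atom points
  give 15 components, compared as S = 1 / (1 + mean |Δ|), so S = 1/2
  corresponds to a mean per-component deviation of 1.

Conformers come from seeded ETKDG distance-geometry embedding with MMFF94
relaxation (UFF when MMFF parameters are missing): one conformer per
molecule — an ensemble would triple-to-tenfold the cost while the ranking
only needs candidates to be *comparable*, and a fixed seed keeps the whole
stack reproducible end to end. Embedding failures retry with incremented
seeds (3 attempts, random-coordinate fallback) before the candidate is
skipped and counted. Spatially collinear reference vectors (zero cross
product) raise a degenerate-geometry error; such conformers are re-embedded
or skipped. Molecules above 300 heavy atoms are refused by the embedder as a
guard.

Ranking is lexicographic: ElectroShape similarity descending, then Tanimoto
descending, then canonical SMILES ascending. ElectroShape dominates because
it is the pharmacophore-preservation signal; the ordering is a package
choice, and both scores are reported per candidate so users can re-rank. The
per-scaffold cap `-n` is applied before global deduplication (best-ranked
instance kept), and candidates identical to the parent are removed.

## Input validation

Chemistry errors never raise: each input maps to exactly one failure class
with precedence `syntax_error > multi_component > invalid_atom >
valence_violation` (a string that does not tokenize cannot be
component-counted). Multi-component inputs (components separated by `.`) are
rejected rather than silently stripped; `--strip_salts` opts into keeping
the largest fragment. Kekulization failures are reported as syntax errors;
wildcard atoms and zero-heavy-atom inputs as invalid atoms.

## Fixture library and validation panel

The bundled fixture generator samples (seeded, deterministic) from a curated
list of 48 drug-like ring-containing molecules plus enumerated
heterocycle–linker–heterocycle combinations, then builds the library through
the ordinary decomposition path. It emulates the *structure* of a real
scaffold library — mixed basis/super scaffolds, heteroaromatics, saturated
rings, carbonyl-bearing linkers — at a few-hundred-entry scale. It does not
emulate the size, the scaffold frequency distribution, or the synthetic
pedigree of a library derived from a large bioactivity database, so passing
tests demonstrate correctness of the machinery, not the chemical quality of
hops from a production library; users with such collections should build
their own file with `scaffhop-build-library` and pass
`--replace_scaffold_files`.

The ten-compound validation panel in `scaffhop.datasets` (five small
molecules, two macrocyclic/peptidomimetic drugs, three peptides up to
tirzepatide at 4813 Da) exercises parsing and property computation across
the molecular-weight range the tool accepts; each transcribed structure was
verified against the drug's published molecular formula.

## Numerical and interface choices

* Similarities are written with 4 decimals, physicochemical properties
  with 2.
* Rule-of-five boundaries are inclusive (MW ≤ 500, cLogP ≤ 5, HBD ≤ 5,
  HBA ≤ 10; all four required).
* Ties everywhere break by canonical SMILES, making output tables
  byte-identical across reruns with the same seed.
* Default retrieval depth is 1000 scaffolds per query scaffold; the demo and
  test runs use 25–50 against fixture libraries of a few dozen entries,
  sizes chosen so the full pipeline (including per-candidate conformer
  embedding) completes in seconds.
* The CLI takes one input molecule per run; batch decomposition is available
  through `scaffhop-build-library`, and the run manifest materializes every
  default so an experiment can be reproduced from it alone.

## Known limitations

* Single-conformer ElectroShape scoring is noisy for highly flexible
  molecules; ranking stability across seeds is not guaranteed for
  near-degenerate scores.
* Gasteiger charges are crude for unusual chemotypes (hypervalent sulfur,
  organometallics); charges are clipped rather than recomputed with a better
  model.
* Stereocenters adjacent to severed bonds lose their assignment; candidates
  are reported as constitutional isomers.
* One scaffold is swapped per candidate; simultaneous multi-scaffold
  replacement is out of scope.
* No docking, binding-affinity prediction, synthetic-accessibility or QED
  scoring is performed; the output table carries the raw similarity and
  rule-of-five columns only.
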