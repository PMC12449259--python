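# scaffhop

Scaffold hopping for medicinal chemistry: given an active molecule, generate
novel analogues by swapping its core ring frameworks for similar scaffolds
drawn from a deduplicated scaffold library, keeping only candidates that stay
close to the input both in fingerprint space and in charge-aware 3D shape.

Scaffold hopping is how medicinal chemists escape intellectual-property
constraints, poor physicochemical properties or metabolic liabilities while
trying to preserve biological activity: the decorations (the pharmacophore
periphery) stay, the core changes. `scaffhop` automates the loop for a single
input molecule and is aimed at hit expansion and lead optimization work.

## Method

1. **Hierarchical scaffold decomposition.** The input molecule is partitioned
   into *ring systems* (fused/bridged/spiro rings merged into one unit,
   augmented with exocyclic atoms joined by bonds of order > 1), *linkers*
   (acyclic paths connecting ring systems, keeping their multiply-bonded
   appendages) and *side chains* (removed). Starting from the side-chain-free
   root scaffold, ring systems are deleted recursively one at a time,
   collecting every distinct intermediate down to single-ring-system *basis*
   scaffolds. Lone benzene rings are excluded as scaffolds — they are
   ubiquitous and carry no hopping signal.
2. **Library retrieval.** Each query scaffold is compared against a scaffold
   library (one canonical SMILES per line; built from any molecule collection
   with `scaffhop-build-library`) using 2048-bit ECFP4 fingerprints and the
   Tanimoto coefficient T(A,B) = |A∩B| / |A∪B|; the top-k most similar
   scaffolds are retrieved (default k = 1000).
3. **Grafting.** The query scaffold's *exit vectors* — bonds from scaffold
   atoms to substituents — are severed and the substituents re-attached onto
   the replacement scaffold, enumerating symmetry-distinct attachment sites
   with sufficient free valence.
4. **Filtering and ranking.** Candidates must reach a whole-molecule ECFP4
   Tanimoto similarity to the input of at least `-t` (default 0.5), may be
   required to preserve a core substructure (`--core_smiles`) and to pass
   Lipinski's rule of five (`--lipinski`). Survivors are scored with
   **ElectroShape**, a 4D ultrafast-shape-recognition descriptor in which each
   atom is a point (x, y, z, μ·q) with partial charge q and μ = 25 Å/e; 15
   distance-distribution moments from 5 reference points are compared as
   S = 1 / (1 + mean|Δ|). Output is ranked by ElectroShape similarity, then
   Tanimoto, then SMILES.

## Worked example

Build a small library from the bundled fixture molecules, then hop the
scaffolds of 2-phenylpyridine:

```bash
scaffhop-build-library --fixture 30 --seed 7 -o lib.smi
scaffhop -i "c1ccc(-c2ccccn2)cc1" -o out -n 3 --n_fragments 25 --seed 7 \
         --replace_scaffold_files lib.smi
```

which prints `3 candidates written to out/candidates.tsv` with

```
candidate_smiles     replaced_scaffold  replacement_scaffold  tanimoto  electroshape  mol_weight  clogp  hbd  hba  lipinski_pass
c1ccc(-c2ccncn2)cc1  c1ccncc1           c1cncnc1              0.56      0.6964        156.19      2.14   0    2    True
c1ccc(-c2cnccn2)cc1  c1ccncc1           c1cnccn1              0.56      0.6741        156.19      2.14   0    2    True
c1ccc(-c2ncccn2)cc1  c1ccncc1           c1cncnc1              0.5455    0.6533        156.19      2.14   0    2    True
```

The pyridine ring of the input was replaced by pyrimidine and pyrazine in
their symmetry-distinct orientations: each row is a new molecule, its
provenance (which scaffold was replaced and by what), its whole-molecule
Tanimoto similarity to the input (all ≥ the 0.5 threshold), its ElectroShape
similarity (higher = more similar charge/shape distribution, used for
ranking), and its drug-likeness properties. `out/` also contains one table
per query scaffold and a `manifest.txt` recording every parameter, the seed
and the library checksum, sufficient to re-run the experiment exactly.

Exit codes: 0 success, 1 usage error, 2 chemistry-fatal input (unparseable
SMILES — with the failure classified as syntax error, multi-component input,
invalid atom or valence violation — or a molecule without usable ring
scaffolds).

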