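"""Scaffold location, grafting, filters and the end-to-end hopping pipeline."""

import pytest
from rdkit import Chem

from scaffhop import (
    HoppingParams,
    build_library,
    ecfp4,
    graft,
    lipinski_pass,
    locate_scaffold,
    parse_smiles,
    run_hopping,
    tanimoto,
)
from scaffhop.decompose import ScaffoldRecord, enumerate_hiers_scaffolds


def canon(s):
    return Chem.CanonSmiles(s)


def scaffold(s, n_sys=1):
    return ScaffoldRecord(
        canonical_smiles=canon(s), kind="basis" if n_sys == 1 else "super", n_ring_systems=n_sys
    )


class TestLocate:
    def test_toluene_benzene_one_match_one_exit(self, records):
        matches = locate_scaffold(records["toluene"], scaffold("c1ccccc1"))
        assert len(matches) == 1
        (ev,) = matches[0].exit_vectors
        assert ev.bond_order == 1.0
        assert canon(Chem.MolToSmiles(Chem.RemoveHs(ev.fragment))).replace("[CH3:1]", "C")

    def test_whole_molecule_scaffold_has_no_exits(self, records):
        matches = locate_scaffold(records["naphthalene"], scaffold("c1ccc2ccccc2c1"))
        assert len(matches) == 1
        assert matches[0].exit_vectors == ()

    def test_dimethylbiphenyl_symmetry_distinct(self, records):
        matches = locate_scaffold(
            records["dimethylbiphenyl"], scaffold("c1ccc(-c2ccccc2)cc1", n_sys=2)
        )
        assert len(matches) == 1
        assert len(matches[0].exit_vectors) == 2

    def test_impossible_scaffold_is_internal_error(self, records):
        with pytest.raises(RuntimeError):
            locate_scaffold(records["toluene"], scaffold("c1ccncc1"))


class TestGraft:
    def test_toluene_to_pyridine_gives_three_picolines(self, records):
        (match,) = locate_scaffold(records["toluene"], scaffold("c1ccccc1"))
        products = graft(records["toluene"], match, scaffold("c1ccncc1"))
        assert {c.smiles for c in products} == {
            canon("Cc1ccccn1"),
            canon("Cc1cccnc1"),
            canon("Cc1ccncc1"),
        }

    def test_identity_replacement_recovers_parent(self, records):
        (match,) = locate_scaffold(records["toluene"], scaffold("c1ccccc1"))
        products = graft(records["toluene"], match, scaffold("c1ccccc1"))
        assert canon("Cc1ccccc1") in {c.smiles for c in products}

    def test_infeasible_attachment_returns_empty(self, records):
        # perfluorobenzene has no free valence anywhere
        (match,) = locate_scaffold(records["toluene"], scaffold("c1ccccc1"))
        assert graft(records["toluene"], match, scaffold("Fc1c(F)c(F)c(F)c(F)c1F")) == []

    def test_two_exits_onto_single_site_returns_empty(self, records):
        (match,) = locate_scaffold(
            records["dimethylbiphenyl"], scaffold("c1ccc(-c2ccccc2)cc1", n_sys=2)
        )
        # pentafluorobenzene: a single H-bearing carbon cannot host two exits
        assert graft(records["dimethylbiphenyl"], match, scaffold("Fc1cc(F)c(F)c(F)c1F")) == []

    def test_no_exit_vectors_yields_replacement_itself(self, records):
        (match,) = locate_scaffold(records["naphthalene"], scaffold("c1ccc2ccccc2c1"))
        products = graft(records["naphthalene"], match, scaffold("c1ccc2ncccc2c1"))
        assert [c.smiles for c in products] == [canon("c1ccc2ncccc2c1")]

    def test_products_contain_replacement_substructure(self, records):
        (match,) = locate_scaffold(records["toluene"], scaffold("c1ccccc1"))
        repl = scaffold("c1ccncc1")
        for cand in graft(records["toluene"], match, repl):
            mol = Chem.MolFromSmiles(cand.smiles)
            assert mol.HasSubstructMatch(Chem.MolFromSmiles(repl.canonical_smiles))

    def test_max_assignments_bounds_enumeration(self, records):
        (match,) = locate_scaffold(records["toluene"], scaffold("c1ccccc1"))
        limited = graft(records["toluene"], match, scaffold("c1ccncc1"), max_assignments=1)
        assert len(limited) == 1


class TestLipinski:
    def test_ethanol_passes(self):
        assert lipinski_pass(parse_smiles("CCO"))

    def test_large_molecule_fails_on_weight(self):
        # decapeptide-ish chain well above 500 Da
        smi = "CC(C)C" + "C(=O)NC(CC(C)C)" * 8 + "C(=O)O"
        rec = parse_smiles(smi)
        assert rec.ok
        assert not lipinski_pass(rec)

    def test_boundaries_are_inclusive(self):
        from scaffhop.engine import CandidateMolecule, _score_properties

        c = CandidateMolecule(smiles="x", replaced_scaffold="", replacement_scaffold="")
        mol = Chem.MolFromSmiles("CCO")
        _score_properties(c, mol)
        assert c.lipinski_pass
        # the rule is <=, so exactly 5 donors passes and a 6th fails
        assert lipinski_pass(parse_smiles("NCC(O)C(O)C(O)CO"))
        assert not lipinski_pass(parse_smiles("NCC(O)C(O)C(O)C(N)O"))


@pytest.fixture(scope="module")
def parent():
    return parse_smiles("c1ccc(-c2ccccn2)cc1")


@pytest.fixture(scope="module")
def params():
    return HoppingParams(
        n_per_fragment=10, tanimoto_threshold=0.3, n_fragment_candidates=10, seed=3
    )


class TestRunHopping:
    def test_acyclic_parent_fatal(self, toy_library):
        with pytest.raises(ValueError):
            run_hopping(parse_smiles("CCCC"), toy_library)

    def test_threshold_one_gives_empty(self, parent, toy_library):
        params = HoppingParams(tanimoto_threshold=1.0, n_fragment_candidates=10, seed=3)
        assert run_hopping(parent, toy_library, params) == []

    def test_unsatisfiable_core_gives_empty(self, parent, toy_library):
        params = HoppingParams(
            tanimoto_threshold=0.0, n_fragment_candidates=10, core_smiles="C(F)(F)F", seed=3
        )
        assert run_hopping(parent, toy_library, params) == []

    def test_every_candidate_satisfies_contract(self, parent, toy_library, params):
        cands = run_hopping(parent, toy_library, params)
        assert cands, "toy run should produce candidates"
        parent_fp = ecfp4(parent)
        for c in cands:
            rec = parse_smiles(c.smiles)
            assert rec.ok
            assert c.smiles != parent.canonical_smiles
            assert c.tanimoto_to_parent >= params.tanimoto_threshold
            assert c.tanimoto_to_parent == pytest.approx(tanimoto(parent_fp, ecfp4(rec)))
            assert rec.mol.HasSubstructMatch(Chem.MolFromSmiles(c.replacement_scaffold))
            assert 0.0 < c.electroshape_to_parent <= 1.0

    def test_matches_hand_run_pipeline(self, parent, toy_library):
        """The engine output equals the brute-force pipeline run step by step
        (per-scaffold cap lifted so the whole survivor set is comparable)."""
        from scaffhop.library import query_similar

        params = HoppingParams(
            n_per_fragment=1000, tanimoto_threshold=0.3, n_fragment_candidates=10, seed=3
        )
        parent_fp = ecfp4(parent)
        expected = set()
        for scaf in enumerate_hiers_scaffolds(parent):
            for repl, _sim in query_similar(toy_library, scaf, top_k=10):
                for match in locate_scaffold(parent, scaf):
                    for cand in graft(parent, match, repl):
                        if cand.smiles == parent.canonical_smiles:
                            continue
                        rec = parse_smiles(cand.smiles)
                        if tanimoto(parent_fp, ecfp4(rec)) >= params.tanimoto_threshold:
                            expected.add(cand.smiles)
        got = {c.smiles for c in run_hopping(parent, toy_library, params)}
        assert got == expected

    def test_threshold_monotonicity(self, parent, toy_library):
        def run(t):
            p = HoppingParams(tanimoto_threshold=t, n_fragment_candidates=10, seed=3)
            return {c.smiles for c in run_hopping(parent, toy_library, p)}

        assert run(0.7) <= run(0.5) <= run(0.3)

    def test_determinism(self, parent, toy_library, params):
        a = run_hopping(parent, toy_library, params)
        b = run_hopping(parent, toy_library, params)
        assert [(c.smiles, c.tanimoto_to_parent, c.electroshape_to_parent) for c in a] == [
            (c.smiles, c.tanimoto_to_parent, c.electroshape_to_parent) for c in b
        ]

    def test_n_monotonicity_prefix(self, parent, toy_library):
        def run(n):
            p = HoppingParams(
                n_per_fragment=n, tanimoto_threshold=0.3, n_fragment_candidates=10, seed=3
            )
            return [c.smiles for c in run_hopping(parent, toy_library, p)]

        small, large = run(1), run(2)
        assert set(small) <= set(large)

    def test_ranking_order(self, parent, toy_library, params):
        cands = run_hopping(parent, toy_library, params)
        keys = [(-c.electroshape_to_parent, -c.tanimoto_to_parent, c.smiles) for c in cands]
        assert keys == sorted(keys)

    def test_lipinski_filter_applied(self, parent, toy_library):
        p = HoppingParams(
            tanimoto_threshold=0.0, n_fragment_candidates=10, lipinski_filter=True, seed=3
        )
        for c in run_hopping(parent, toy_library, p):
            assert c.lipinski_pass
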