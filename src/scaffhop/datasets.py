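"""Bundled molecule collections.

``CURATED_RING_MOLECULES`` is a small set of ring-containing, drug-like
molecules used (together with enumerated heterocycle–linker–heterocycle
combinations) to build the fixture scaffold library, so the whole pipeline
runs and is testable without downloading any external compound collection.

``VALIDATION_COMPOUNDS`` is the ten-compound validation panel spanning the
size range the tool is meant to handle — small molecules, macrocyclic
peptides and large linear peptides from roughly 315 to 4813 Da.  The SMILES
were transcribed from the public records of each drug substance and each
structure's molecular formula was checked against its published formula.
"""

from __future__ import annotations

#: drug-like ring-containing molecules for the fixture scaffold library
CURATED_RING_MOLECULES: tuple[str, ...] = (
    "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "Cn1c(=O)c2c(ncn2C)n(C)c1=O",
    "CC(=O)Nc1ccc(O)cc1",
    "CN1CCC[C@H]1c1cccnc1",
    "O=C(c1ccccc1)c1ccncc1",
    "c1ccc(-c2ccccn2)cc1",
    "c1ccc(Cc2ccccc2)cc1",
    "O=C(Nc1ccccc1)c1ccccc1",
    "Clc1ccc(-c2nc3ccccc3[nH]2)cc1",
    "O=C1CCc2ccccc21",
    "c1ccc2c(c1)CCCN2",
    "O=c1[nH]c2ccccc2[nH]1",
    "c1ccc(-c2nnc(-c3ccccc3)o2)cc1",
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
    "CN(C)CCCN1c2ccccc2Sc2ccccc21",
    "Clc1ccccc1-c1nc2ccccc2s1",
    "O=C(O)c1ccccc1Nc1cccc(C(F)(F)F)c1",
    "Nc1ncnc2[nH]cnc12",
    "Nc1nc2ccccc2s1",
    "O=S(=O)(Nc1ccccn1)c1ccc(N)cc1",
    "CCN(CC)CCNC(=O)c1ccc(N)cc1",
    "Oc1ccc2ccccc2c1",
    "c1ccc(N2CCNCC2)cc1",
    "c1ccc(OCC2CNCCO2)cc1",
    "O=C(c1ccc(F)cc1)C1CCNCC1",
    "Clc1ccc2nc(N3CCNCC3)ccc2c1",
    "c1ccc(-c2csc(N3CCOCC3)n2)cc1",
    "Cc1nc2ccccc2[nH]c1=O",
    "O=c1cc(-c2ccccc2)oc2ccccc12",
    "O=c1c(-c2ccccc2)coc2ccccc12",
    "c1ccc(CN2CCC(c3ccccc3)CC2)cc1",
    "O=C(NC1CCCCC1)Nc1ccccc1",
    "c1cnc2[nH]ccc2c1",
    "c1ccc(-n2cncn2)cc1",
    "Cc1ccc(S(=O)(=O)N2CCCC2)cc1",
    "O=C(Cc1ccccc1)NCc1ccco1",
    "c1ccc(CCN2CCCC2)cc1",
    "Fc1ccc(C2CCNCC2)cc1",
    "c1ccc(COc2ccccc2)cc1",
    "N#Cc1ccc(-c2ccc3ccccc3n2)cc1",
    "O=C1NC(=O)C(c2ccccc2)(c2ccccc2)N1",
    "CC1(c2ccccc2)NC(=O)N(c2ccccc2)C1=O",
    "c1csc(-c2ccc3ccccc3n2)c1",
    "OCC1OC(n2cnc3c(N)ncnc32)CC1O",
    "Cc1cc2nc(N3CCN(C)CC3)nc(N)c2cc1C",
    "Clc1cccc(Cl)c1-c1nnc2ccccn12",
    "O=C(O)CCc1c[nH]c2ccccc12",
)

#: heterocycles written so that plain string concatenation attaches at the
#: final ring atom ("c1ccccc1C" is toluene); used by the fixture generator
FIXTURE_HETEROCYCLES: tuple[str, ...] = (
    "c1ccncc1",
    "c1cncnc1",
    "c1nccnc1",
    "c1ccsc1",
    "c1ccoc1",
    "c1cc[nH]c1",
    "c1[nH]cnc1",
    "c1ocnc1",
    "c1scnc1",
    "C1CCNCC1",
    "C1CCOCC1",
    "C1CCNC1",
    "C1CCCCC1",
    "c1ccc2[nH]ccc2c1",
    "c1ccc2ncccc2c1",
    "c1ccc2occc2c1",
)

FIXTURE_LINKERS: tuple[str, ...] = (
    "",
    "C",
    "CC",
    "CCC",
    "C(=O)",
    "C(=O)N",
    "CO",
    "CN",
    "OC",
    "NC(=O)",
    "C=C",
    "S",
)

#: validation panel: small molecules, macrocycles and peptides, 315-4813 Da
VALIDATION_COMPOUNDS: dict[str, str] = {
    # small molecules
    "celecoxib": "Cc1ccc(-c2cc(C(F)(F)F)nn2-c2ccc(S(N)(=O)=O)cc2)cc1",
    "rimonabant": "Cc1c(-c2ccc(Cl)cc2)c(C(=O)NN2CCCCC2)nn1-c1ccc(Cl)cc1Cl",
    "lapatinib": "CS(=O)(=O)CCNCc1ccc(-c2ccc3ncnc(Nc4ccc(OCc5cccc(F)c5)c(Cl)c4)c3c2)o1",
    "trametinib": "CN1C(=O)C(C)=C2N(c3cccc(NC(C)=O)c3)C(=O)N(C3CC3)C(=O)C2=C1Nc1ccc(I)cc1F",
    "venetoclax": (
        "CC1(C)CCC(CN2CCN(c3ccc(C(=O)NS(=O)(=O)c4ccc(NCC5CCOCC5)c([N+](=O)[O-])c4)cc3"
        "Oc3cnc4[nH]ccc4c3)CC2)=C(c2ccc(Cl)cc2)C1"
    ),
    # peptides / macrocycles
    "trofinetide": "NCC(=O)N1CCC[C@]1(C)C(=O)N[C@@H](CCC(=O)O)C(=O)O",
    "carfilzomib": (
        "O=C(CN1CCOCC1)N[C@@H](CCc1ccccc1)C(=O)N[C@@H](CC(C)C)C(=O)N[C@@H](Cc1ccccc1)"
        "C(=O)N[C@@H](CC(C)C)C(=O)[C@@]1(C)CO1"
    ),
    "pasireotide": (
        "O=C1[C@@H]2C[C@@H](OC(=O)NCCN)CN2C(=O)[C@H](Cc2ccc(OCc3ccccc3)cc2)NC(=O)"
        "[C@@H](CCCCN)NC(=O)[C@@H](Cc2c[nH]c3ccccc23)NC(=O)[C@H](c2ccccc2)NC(=O)"
        "[C@H](Cc2ccccc2)N1"
    ),
    "motixafortide": (
        "O=C(c1ccc(F)cc1)N[C@@H](CCCNC(=N)N)C(=O)N[C@@H](CCCNC(=N)N)C(=O)"
        "N[C@@H](Cc1ccc2ccccc2c1)C(=O)N[C@@H](CS1)C(=O)N[C@@H](Cc2ccc(O)cc2)C(=O)"
        "N[C@@H](CCCNC(N)=O)C(=O)N[C@@H](CCCCN)C(=O)N[C@H](CCCCN)C(=O)N2CCC[C@H]2C(=O)"
        "N[C@@H](Cc2ccc(O)cc2)C(=O)N[C@@H](CCCNC(=N)N)C(=O)N[C@@H](CCCNC(N)=O)C(=O)"
        "N[C@@H](CS1)C(=O)N[C@@H](CCCNC(=N)N)C(=O)N"
    ),
    "tirzepatide": (
        "N[C@@H](Cc1ccc(O)cc1)C(=O)NC(C)(C)C(=O)N[C@@H](CCC(=O)O)C(=O)NCC(=O)"
        "N[C@@H]([C@@H](C)O)C(=O)N[C@@H](Cc1ccccc1)C(=O)N[C@@H]([C@@H](C)O)C(=O)"
        "N[C@@H](CO)C(=O)N[C@@H](CC(=O)O)C(=O)N[C@@H](Cc1ccc(O)cc1)C(=O)N[C@@H](CO)"
        "C(=O)N[C@@H]([C@@H](C)CC)C(=O)NC(C)(C)C(=O)N[C@@H](CC(C)C)C(=O)"
        "N[C@@H](CC(=O)O)C(=O)N[C@@H](CCCCN)C(=O)N[C@@H]([C@@H](C)CC)C(=O)"
        "N[C@@H](C)C(=O)N[C@@H](CCC(N)=O)C(=O)N[C@@H](CCCCNC(=O)COCCOCCNC(=O)"
        "COCCOCCNC(=O)CC[C@H](NC(=O)CCCCCCCCCCCCCCCCCCC(=O)O)C(=O)O)C(=O)"
        "N[C@@H](C)C(=O)N[C@@H](Cc1ccccc1)C(=O)N[C@@H](C(C)C)C(=O)N[C@@H](CCC(N)=O)"
        "C(=O)N[C@@H](Cc1c[nH]c2ccccc12)C(=O)N[C@@H](CC(C)C)C(=O)"
        "N[C@@H]([C@@H](C)CC)C(=O)N[C@@H](C)C(=O)NCC(=O)NCC(=O)N1CCC[C@H]1C(=O)"
        "N[C@@H](CO)C(=O)N[C@@H](CO)C(=O)NCC(=O)N[C@@H](C)C(=O)N1CCC[C@H]1C(=O)"
        "N1CCC[C@H]1C(=O)N1CCC[C@H]1C(=O)N[C@@H](CO)C(N)=O"
    ),
}
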