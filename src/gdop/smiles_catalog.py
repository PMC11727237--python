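"""Bundled catalogue of valid drug-like SMILES for synthetic compounds.

Synthetic fixtures need real, parseable structures so fingerprints vary
across compounds without any generator dependency. The catalogue combines a
curated set of well-known drug molecules with combinatorially substituted
aromatic scaffolds and short homologous series; every entry parses with
rdkit (asserted in the test suite). Entries are indexed by compound number,
so structure assignment is deterministic.
"""

from __future__ import annotations

_DRUGS = [
    "CC(=O)Oc1ccccc1C(=O)O",            # aspirin
    "CC(=O)Nc1ccc(O)cc1",               # paracetamol
    "CC(C)Cc1ccc(C(C)C(=O)O)cc1",       # ibuprofen
    "Cn1cnc2c1c(=O)n(C)c(=O)n2C",       # caffeine
    "CN1CCCC1c1cccnc1",                 # nicotine
    "OC(=O)c1ccccc1O",                  # salicylic acid
    "NC(=O)c1ccccc1",                   # benzamide
    "Nc1ccc(S(N)(=O)=O)cc1",            # sulfanilamide
    "CC(N)Cc1ccccc1",                   # amphetamine
    "OCC(O)CO",                         # glycerol
    "NC(Cc1ccccc1)C(=O)O",              # phenylalanine
    "NC(Cc1c[nH]c2ccccc12)C(=O)O",      # tryptophan
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",       # citric acid
    "C1CCNCC1",                         # piperidine
    "c1ccc2[nH]ccc2c1",                 # indole
    "c1ccc2ncccc2c1",                   # quinoline
    "OCCN1CCOCC1",                      # hydroxyethylmorpholine
    "CC(=O)NCCc1c[nH]c2ccc(OC)cc12",    # melatonin
    "NCCc1ccc(O)c(O)c1",                # dopamine
    "NCCc1c[nH]cn1",                    # histamine
    "CN(C)CCc1c[nH]c2ccccc12",          # dimethyltryptamine
    "OC(=O)c1cccnc1",                   # niacin
    "NC(=O)c1cccnc1",                   # nicotinamide
    "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O",   # estradiol
    "CN1C2CCC1CC(OC(=O)c1ccccc1)C2",    # tropane ester
    "COc1cc2c(cc1OC)CCN(C)C2",          # tetrahydroisoquinoline
    "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",   # atenolol
    "CC(C)(C)NCC(O)c1ccc(O)c(CO)c1",    # salbutamol
    "Clc1ccccc1-c1nc2ccccc2[nH]1",      # chlorophenyl benzimidazole
    "O=C(O)c1ccc(N)cc1",                # PABA
]

_TEMPLATES = [
    "c1ccc({})cc1",        # monosubstituted benzene
    "Cc1ccc({})cc1",       # para-substituted toluene
    "c1ccnc({})c1",        # 2-substituted pyridine
    "Oc1ccc({})cc1",       # para-substituted phenol
    "NC(=O)c1ccc({})cc1",  # para-substituted benzamide
    "COc1ccc({})cc1",      # para-substituted anisole
    "Fc1ccc({})cc1",       # para-substituted fluorobenzene
    "Clc1ccc({})cc1",      # para-substituted chlorobenzene
    "c1ccc2cc({})ccc2c1",  # 2-substituted naphthalene
    "CC(C)c1ccc({})cc1",   # para-substituted cumene
    "c1csc({})c1",         # 2-substituted thiophene
]

_SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "C(C)(C)C", "O", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C#N", "C(=O)O", "C(=O)N", "C(=O)OC",
    "S(C)(=O)=O", "C(F)(F)F", "CCO", "CC(=O)O", "N2CCCC2", "N2CCOCC2",
    "C(=O)NC",
]


def _series() -> list[str]:
    out = []
    for n in range(1, 18):
        chain = "C" * n
        out.append(chain + "O")        # 1-alkanols
        out.append(chain + "C(=O)O")   # alkanoic acids
        out.append(chain + "N")        # 1-aminoalkanes
        out.append(chain + "C#N")      # alkanenitriles
    return out


def build_catalog() -> tuple[str, ...]:
    """Deterministic ordered catalogue of valid SMILES (~200 entries)."""
    scaffolds = [t.format(s) for t in _TEMPLATES for s in _SUBSTITUENTS]
    return tuple(_DRUGS + scaffolds + _series())


SMILES_CATALOG: tuple[str, ...] = build_catalog()
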