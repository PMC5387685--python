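"""Derive the fixture-panel expected-value table by independent means.

This script is the oracle for the fixture panel: every expected value is
computed here without calling the chemprofiler descriptor code.

* MW comes from hand-entered molecular formulas and a standard atomic-mass
  table (conventional atomic weights; the same values printed in the CRC
  periodic table).
* Counts (HBD, HBA, rings, aromatic rings, stereocenters, rotatable bonds,
  formal charges at pH 7, heavy atoms) and Fsp3 are hand-derived from the
  drawn structures and entered below as literals.
* The shape index (longest shortest heavy-atom chain, atom count with both
  ends included, divided by heavy-atom count) is computed by brute-force
  breadth-first search with networkx over the bond graph.
* Expected PAINS / structural-alert family hits and the phospholipidosis
  flag are asserted by hand from the catalog motifs.

Run from the repository root to (re)generate
``src/chemprofiler/data/fixture_expected.json``:

    python scripts/derive_fixture_expected.py
"""

import json
from fractions import Fraction
from pathlib import Path

import networkx as nx
from rdkit import Chem

MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.067, "Cl": 35.453, "F": 18.998}


def formula_mass(formula: dict[str, int]) -> float:
    return sum(MASS[el] * n for el, n in formula.items())


def bfs_shape_index(smiles: str) -> float:
    """Brute-force all-pairs BFS over the heavy-atom bond graph."""
    mol = Chem.MolFromSmiles(smiles)
    g = nx.Graph()
    g.add_nodes_from(a.GetIdx() for a in mol.GetAtoms())
    g.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds())
    n = g.number_of_nodes()
    if n == 1:
        return 1.0
    longest = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        longest = max(longest, max(lengths.values()))
    return (longest + 1) / n  # bond count -> atom count


# id -> (smiles, formula, hand-derived counts / fractions, expected alerts)
# counts: hbd, hba, rings, aromatic_rings, stereocenters, rotatable_bonds,
#         formal_charges_ph7, heavy_atoms; fsp3 as an exact fraction.
PANEL = {
    "methane":           ("C",                      {"C": 1, "H": 4},                    dict(hbd=0, hba=0, rings=0, aromatic_rings=0, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=1), Fraction(1, 1), [], [], False),
    "ethanol":           ("CCO",                    {"C": 2, "H": 6, "O": 1},            dict(hbd=1, hba=1, rings=0, aromatic_rings=0, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=3), Fraction(1, 1), [], [], False),
    "benzene":           ("c1ccccc1",               {"C": 6, "H": 6},                    dict(hbd=0, hba=0, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=6), Fraction(0, 1), [], [], False),
    "cyclohexane":       ("C1CCCCC1",               {"C": 6, "H": 12},                   dict(hbd=0, hba=0, rings=1, aromatic_rings=0, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=6), Fraction(1, 1), [], [], False),
    "n_hexane":          ("CCCCCC",                 {"C": 6, "H": 14},                   dict(hbd=0, hba=0, rings=0, aromatic_rings=0, stereocenters=0, rotatable_bonds=3, formal_charges_ph7=0, heavy_atoms=6), Fraction(1, 1), [], [], False),
    "neopentane":        ("CC(C)(C)C",              {"C": 5, "H": 12},                   dict(hbd=0, hba=0, rings=0, aromatic_rings=0, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=5), Fraction(1, 1), [], [], False),
    "aspirin":           ("CC(=O)Oc1ccccc1C(=O)O",  {"C": 9, "H": 8, "O": 4},            dict(hbd=1, hba=4, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=3, formal_charges_ph7=1, heavy_atoms=13), Fraction(1, 9), [], [], False),
    "glycine":           ("NCC(=O)O",               {"C": 2, "H": 5, "N": 1, "O": 2},    dict(hbd=2, hba=3, rings=0, aromatic_rings=0, stereocenters=0, rotatable_bonds=1, formal_charges_ph7=2, heavy_atoms=5), Fraction(1, 2), [], [], False),
    "l_alanine":         ("N[C@@H](C)C(=O)O",       {"C": 3, "H": 7, "N": 1, "O": 2},    dict(hbd=2, hba=3, rings=0, aromatic_rings=0, stereocenters=1, rotatable_bonds=1, formal_charges_ph7=2, heavy_atoms=6), Fraction(2, 3), [], [], False),
    "butan_2_ol":        ("CCC(C)O",                {"C": 4, "H": 10, "O": 1},           dict(hbd=1, hba=1, rings=0, aromatic_rings=0, stereocenters=1, rotatable_bonds=1, formal_charges_ph7=0, heavy_atoms=5), Fraction(1, 1), [], [], False),
    "catechol":          ("Oc1ccccc1O",             {"C": 6, "H": 6, "O": 2},            dict(hbd=2, hba=2, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=8), Fraction(0, 1), ["catechol_A"], [], False),
    "acrolein":          ("C=CC=O",                 {"C": 3, "H": 4, "O": 1},            dict(hbd=0, hba=1, rings=0, aromatic_rings=0, stereocenters=0, rotatable_bonds=1, formal_charges_ph7=0, heavy_atoms=4), Fraction(0, 1), [], ["michael_acceptor", "aldehyde"], False),
    "azetidinone":       ("O=C1CCN1",               {"C": 3, "H": 5, "N": 1, "O": 1},    dict(hbd=1, hba=2, rings=1, aromatic_rings=0, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=5), Fraction(2, 3), [], ["beta_lactam"], False),
    "tetrazole_1h":      ("c1nnn[nH]1",             {"C": 1, "H": 2, "N": 4},            dict(hbd=1, hba=4, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=1, heavy_atoms=5), Fraction(0, 1), [], [], False),
    "tetramethylammonium": ("C[N+](C)(C)C",         {"C": 4, "H": 12, "N": 1},           dict(hbd=0, hba=1, rings=0, aromatic_rings=0, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=1, heavy_atoms=5), Fraction(1, 1), [], [], False),
    "benzamide":         ("NC(=O)c1ccccc1",         {"C": 7, "H": 7, "N": 1, "O": 1},    dict(hbd=1, hba=2, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=1, formal_charges_ph7=0, heavy_atoms=9), Fraction(0, 1), [], [], False),
    "aniline":           ("Nc1ccccc1",              {"C": 6, "H": 7, "N": 1},            dict(hbd=1, hba=1, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=7), Fraction(0, 1), [], [], False),
    "benzylamine":       ("NCc1ccccc1",             {"C": 7, "H": 9, "N": 1},            dict(hbd=1, hba=1, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=1, formal_charges_ph7=1, heavy_atoms=8), Fraction(1, 7), [], [], False),
    "acetic_acid":       ("CC(=O)O",                {"C": 2, "H": 4, "O": 2},            dict(hbd=1, hba=2, rings=0, aromatic_rings=0, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=1, heavy_atoms=4), Fraction(1, 2), [], [], False),
    "phenol":            ("Oc1ccccc1",              {"C": 6, "H": 6, "O": 1},            dict(hbd=1, hba=1, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=7), Fraction(0, 1), [], [], False),
    "toluene":           ("Cc1ccccc1",              {"C": 7, "H": 8},                    dict(hbd=0, hba=0, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=7), Fraction(1, 7), [], [], False),
    "chlorobutane":      ("CCCCCl",                 {"C": 4, "H": 9, "Cl": 1},           dict(hbd=0, hba=0, rings=0, aromatic_rings=0, stereocenters=0, rotatable_bonds=2, formal_charges_ph7=0, heavy_atoms=5), Fraction(1, 1), [], ["alkyl_halide"], False),
    "imidazole":         ("c1c[nH]cn1",             {"C": 3, "H": 4, "N": 2},            dict(hbd=1, hba=2, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=5), Fraction(0, 1), [], [], False),
    "pyridine":          ("c1ccncc1",               {"C": 5, "H": 5, "N": 1},            dict(hbd=0, hba=1, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=6), Fraction(0, 1), [], [], False),
    "guanidine":         ("NC(=N)N",                {"C": 1, "H": 5, "N": 3},            dict(hbd=3, hba=3, rings=0, aromatic_rings=0, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=1, heavy_atoms=4), Fraction(0, 1), [], [], False),
    "benzenesulfonamide": ("NS(=O)(=O)c1ccccc1",    {"C": 6, "H": 7, "N": 1, "O": 2, "S": 1}, dict(hbd=1, hba=3, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=1, formal_charges_ph7=0, heavy_atoms=10), Fraction(0, 1), ["sulfonamide_A"], [], False),
    "n_methylaniline":   ("CNc1ccccc1",             {"C": 7, "H": 9, "N": 1},            dict(hbd=1, hba=1, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=1, formal_charges_ph7=0, heavy_atoms=8), Fraction(1, 7), ["anil_NH_alk_B"], [], False),
    "p_benzoquinone":    ("O=C1C=CC(=O)C=C1",       {"C": 6, "H": 4, "O": 2},            dict(hbd=0, hba=2, rings=1, aromatic_rings=0, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=8), Fraction(0, 1), ["quinone_A"], ["michael_acceptor", "quinone"], False),
    "o_phenylenediamine": ("Nc1ccccc1N",            {"C": 6, "H": 8, "N": 2},            dict(hbd=2, hba=2, rings=1, aromatic_rings=1, stereocenters=0, rotatable_bonds=0, formal_charges_ph7=0, heavy_atoms=8), Fraction(0, 1), [], ["ortho_aniline"], False),
    # cationic amphiphile by construction: tertiary aliphatic amine, two
    # aromatic rings, lipophilic (phospholipidosis-inducer profile)
    "cad_amphiphile":    ("CN(C)CCCc1ccc(-c2ccccc2)cc1", {"C": 17, "H": 21, "N": 1},     dict(hbd=0, hba=1, rings=2, aromatic_rings=2, stereocenters=0, rotatable_bonds=5, formal_charges_ph7=1, heavy_atoms=18), Fraction(5, 17), [], [], True),
}


def main() -> None:
    out = {}
    for mol_id, (smiles, formula, counts, fsp3, pains, sa, pld) in PANEL.items():
        entry = {"smiles": smiles}
        entry["mw"] = round(formula_mass(formula), 4)
        entry.update(counts)
        entry["fsp3"] = float(fsp3)
        entry["shape_index"] = bfs_shape_index(smiles)
        entry["pains_families"] = pains
        entry["structural_alert_families"] = sa
        entry["phospholipidosis_inducer"] = pld
        out[mol_id] = entry

    dest = Path(__file__).resolve().parent.parent / "src" / "chemprofiler" / "data" / "fixture_expected.json"
    dest.write_text(json.dumps(out, indent=1) + "\n")
    print(f"wrote {dest} ({len(out)} molecules)")


if __name__ == "__main__":
    main()
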