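"""Physicochemical descriptor panel for compound profiling.

Covers the classical oral-drug-likeness axes (MW, log P, log D at pH 7, TPSA,
H-bond donors/acceptors, flexibility, ring and stereocenter counts, Fsp3,
formal charges at pH 7), an ESOL-style aqueous solubility estimate (log S),
and a topological shape index used for biopharmaceutics (BDDCS-style)
mapping.

Conventions
-----------
* HBA is the Lipinski N+O atom count and HBD the count of N/O atoms bearing
  at least one hydrogen (the "OH + NH" convention). These definitions are
  used uniformly across the package, including inside QED.
* log P is the Crippen atom-contribution estimate.
* Ionization at pH 7 is handled by a small fixed SMARTS/pKa rule table
  (see ``IONIZABLE_GROUPS``), a deliberate, documented simplification: log D
  subtracts the closed-form Henderson-Hasselbalch partition penalty per
  ionizable group, and formal charges at pH 7 count atoms charged after
  applying the same rules (plus charges drawn in the input structure).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Literal

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

from .curation import CompoundRecord

__all__ = [
    "DescriptorVector",
    "IonizableGroup",
    "IONIZABLE_GROUPS",
    "compute_descriptors",
    "shape_index",
    "logd_ph7",
    "formal_charges_ph7",
    "logs_estimate",
    "count_rotatable_bonds",
    "count_basic_nitrogens",
]


@dataclass
class DescriptorVector:
    """The full descriptor panel for one compound."""

    mw: float                 # Da
    logp: float               # Crippen estimate, unitless
    logd_ph7: float           # pKa-corrected logP at pH 7
    tpsa: float               # Angstrom^2
    hbd: int                  # N/O atoms bearing >=1 H
    hba: int                  # N + O atom count
    rotatable_bonds: int
    rigid_bonds: int
    rings: int                # SSSR count
    aromatic_rings: int       # SSSR rings with all atoms aromatic
    max_ring_size: int        # 0 if acyclic
    stereocenters: int        # assigned + unassigned tetrahedral centers
    fsp3: float               # sp3 carbons / carbons, 0 if no carbon
    formal_charges_ph7: int   # count of charged atoms at pH 7 (not net charge)
    heavy_atoms: int
    logs: float               # log10(mol/L), ESOL-style estimate
    shape_index: float        # in (0, 1]; 1.0 for unbranched chains
    flexibility: float        # rotatable / (rotatable + rigid), 0 if no bonds

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class IonizableGroup:
    name: str
    smarts: str
    kind: Literal["acid", "base"]
    pka: float

    def pattern(self) -> Chem.Mol:
        return _compiled(self.smarts)


# Fixed rule-based ionization table. pKa values are typical textbook values
# for the isolated functional group; substituent effects are ignored.
IONIZABLE_GROUPS: tuple[IonizableGroup, ...] = (
    IonizableGroup("carboxylic_acid", "[CX3](=[OX1])[OX2H1]", "acid", 4.2),
    IonizableGroup("sulfonic_acid", "[SX4](=[OX1])(=[OX1])[OX2H1]", "acid", -1.0),
    IonizableGroup("tetrazole", "[nH]1nnnc1", "acid", 4.9),
    IonizableGroup("phenol", "[OX2H1][c]", "acid", 9.9),
    IonizableGroup("sulfonamide_nh", "[SX4](=[OX1])(=[OX1])[NX3;H1,H2]", "acid", 10.0),
    IonizableGroup(
        "aliphatic_amine",
        "[NX3;H2,H1,H0;+0;"
        "!$([NX3][CX3]=[OX1]);"   # amide
        "!$([NX3][CX3]=[SX1]);"   # thioamide
        "!$([NX3][CX3]=[NX2]);"   # amidine/guanidine N (handled below)
        "!$([NX3][SX4](=O)=O);"   # sulfonamide
        "!$([NX3]c)]",            # aniline (handled below)
        "base",
        9.5,
    ),
    IonizableGroup("aniline", "[NX3;H2,H1;+0;$([NX3]c);!$([NX3][CX3]=[OX1])]", "base", 4.6),
    IonizableGroup("imidazole", "c1c[nH]cn1", "base", 7.0),
    IonizableGroup("amidine_guanidine", "[CX3;+0](=[NX2;+0])[NX3;+0]", "base", 12.5),
)

_SMARTS_CACHE: dict[str, Chem.Mol] = {}


def _compiled(smarts: str) -> Chem.Mol:
    patt = _SMARTS_CACHE.get(smarts)
    if patt is None:
        patt = Chem.MolFromSmarts(smarts)
        if patt is None:
            raise ValueError(f"bad SMARTS: {smarts!r}")
        _SMARTS_CACHE[smarts] = patt
    return patt


def _count_group(mol: Chem.Mol, group: IonizableGroup) -> int:
    matches = mol.GetSubstructMatches(group.pattern(), uniquify=True)
    if group.name in ("tetrazole", "imidazole"):
        # a ring pattern can match in both directions; count distinct atom sets
        return len({frozenset(m) for m in matches})
    if group.name == "amidine_guanidine":
        # guanidine matches once per N; count distinct central carbons
        return len({m[0] for m in matches})
    return len(matches)


def count_basic_nitrogens(record: CompoundRecord) -> int:
    """Number of nitrogen centers protonated at pH 7 under the rule table."""
    mol = record.structure
    return sum(
        _count_group(mol, g) for g in IONIZABLE_GROUPS if g.kind == "base" and g.pka > 7.0
    )


def count_rotatable_bonds(mol: Chem.Mol) -> int:
    """Non-ring single bonds between two non-terminal heavy atoms, excluding
    amide C-N bonds."""
    amide = _compiled("[CX3](=[OX1])[NX3]")
    amide_bonds = set()
    for match in mol.GetSubstructMatches(amide):
        c_idx, _o, n_idx = match
        bond = mol.GetBondBetweenAtoms(c_idx, n_idx)
        if bond is not None:
            amide_bonds.add(bond.GetIdx())
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetIdx() in amide_bonds:
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() < 2 or b.GetDegree() < 2:  # heavy-atom degree
            continue
        n += 1
    return n


def shape_index(record: CompoundRecord) -> float:
    """Longest shortest heavy-atom chain (atom count, both ends included)
    divided by the heavy-atom count.

    1.0 for every unbranched acyclic molecule; < 1.0 whenever a ring or a
    branch shortens the longest chain relative to the atom count. Single
    atom -> 1/1 = 1.
    """
    mol = record.structure
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy == 0:
        raise ValueError("shape_index requires at least one heavy atom")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ValueError("shape_index requires a connected structure")
    if n_heavy == 1:
        return 1.0
    dmat = Chem.GetDistanceMatrix(mol)
    longest_chain = int(dmat.max()) + 1  # bond count -> atom count
    return longest_chain / n_heavy


def logd_ph7(record: CompoundRecord, logp: float | None = None) -> float:
    """log D at pH 7 from logP and the Henderson-Hasselbalch penalty of every
    ionizable group in the rule table.

    logD = logP - sum_acids log10(1 + 10^(7 - pKa))
                - sum_bases log10(1 + 10^(pKa - 7))

    With no ionizable group, logD == logP exactly.
    """
    mol = record.structure
    if logp is None:
        logp = Crippen.MolLogP(mol)
    penalty = 0.0
    for group in IONIZABLE_GROUPS:
        k = _count_group(mol, group)
        if not k:
            continue
        if group.kind == "acid":
            penalty += k * math.log10(1.0 + 10.0 ** (7.0 - group.pka))
        else:
            penalty += k * math.log10(1.0 + 10.0 ** (group.pka - 7.0))
    return logp - penalty


def formal_charges_ph7(record: CompoundRecord) -> int:
    """Count of charged atoms at pH 7 (not the net charge).

    Deprotonates acids with pKa < 7 (carboxylic/sulfonic acids, tetrazoles),
    protonates bases with pKa > 7 (non-amide aliphatic amines, amidines,
    guanidines), and keeps charges drawn in the input (e.g. quaternary
    ammonium).
    """
    mol = record.structure
    drawn = sum(1 for atom in mol.GetAtoms() if atom.GetFormalCharge() != 0)
    ionized = 0
    for group in IONIZABLE_GROUPS:
        fires = (group.kind == "acid" and group.pka < 7.0) or (
            group.kind == "base" and group.pka > 7.0
        )
        if fires:
            ionized += _count_group(mol, group)
    return drawn + ionized


def logs_estimate(
    logp: float, mw: float, rotatable_bonds: int, aromatic_proportion: float
) -> float:
    """ESOL-style linear aqueous-solubility estimate, log10(mol/L).

    log S = 0.16 - 0.63 logP - 0.0062 MW + 0.066 RB - 0.74 AP
    where AP is the aromatic heavy-atom fraction.
    """
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rotatable_bonds - 0.74 * aromatic_proportion


def _ring_counts(mol: Chem.Mol) -> tuple[int, int, int]:
    rings = mol.GetRingInfo().AtomRings()
    n_aromatic = sum(
        1 for ring in rings if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring)
    )
    max_size = max((len(r) for r in rings), default=0)
    return len(rings), n_aromatic, max_size


def compute_descriptors(record: CompoundRecord) -> DescriptorVector:
    """Compute the full descriptor panel for one compound. Deterministic."""
    mol = record.structure
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ValueError(
            f"{record.id}: disconnected structure; run curation (salt stripping) first"
        )

    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    hbd = sum(
        1
        for atom in mol.GetAtoms()
        if atom.GetAtomicNum() in (7, 8) and atom.GetTotalNumHs() > 0
    )
    hba = sum(1 for atom in mol.GetAtoms() if atom.GetAtomicNum() in (7, 8))
    rot = count_rotatable_bonds(mol)
    heavy_bonds = mol.GetNumBonds()
    rigid = heavy_bonds - rot
    rings, aromatic_rings, max_ring = _ring_counts(mol)
    stereocenters = len(
        Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    )
    carbons = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 6]
    sp3 = sum(1 for a in carbons if a.GetHybridization() == Chem.HybridizationType.SP3)
    fsp3 = sp3 / len(carbons) if carbons else 0.0
    heavy = mol.GetNumHeavyAtoms()
    n_aromatic_atoms = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    ap = n_aromatic_atoms / heavy if heavy else 0.0

    return DescriptorVector(
        mw=mw,
        logp=logp,
        logd_ph7=logd_ph7(record, logp=logp),
        tpsa=tpsa,
        hbd=hbd,
        hba=hba,
        rotatable_bonds=rot,
        rigid_bonds=rigid,
        rings=rings,
        aromatic_rings=aromatic_rings,
        max_ring_size=max_ring,
        stereocenters=stereocenters,
        fsp3=fsp3,
        formal_charges_ph7=formal_charges_ph7(record),
        heavy_atoms=heavy,
        logs=logs_estimate(logp, mw, rot, ap),
        shape_index=shape_index(record),
        flexibility=rot / heavy_bonds if heavy_bonds else 0.0,
    )
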