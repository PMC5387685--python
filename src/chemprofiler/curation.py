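"""Compound-set curation: reading, standardization, MW filtering, diversity selection.

The curation pipeline mirrors the preparation protocol commonly applied to
screening-library extracts before profiling: parse, keep the largest covalent
fragment (salt stripping), restrict to a molecular-weight window, then run a
sphere-exclusion (leader) diversity pass on circular fingerprints and cap the
set size by seeded random picking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Descriptors, rdFingerprintGenerator

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "CurationError",
    "read_compound_set",
    "records_from_smiles",
    "filter_mw_window",
    "diversity_select",
    "compute_fingerprint",
    "tanimoto",
    "write_compound_set",
]


class CurationError(ValueError):
    """Raised on malformed inputs or violated preconditions during curation."""


@dataclass
class CompoundRecord:
    """One identified molecule within a labelled dataset.

    ``structure`` holds the parsed (salt-stripped) RDKit molecule; ``smiles``
    is its canonical SMILES so records compare and serialize deterministically.
    """

    id: str
    smiles: str
    structure: Chem.Mol = field(repr=False, compare=False)
    dataset: str = ""

    @classmethod
    def from_mol(cls, mol: Chem.Mol, id: str, dataset: str = "") -> "CompoundRecord":
        mol = strip_salts(mol)
        return cls(id=id, smiles=Chem.MolToSmiles(mol), structure=mol, dataset=dataset)


def strip_salts(mol: Chem.Mol) -> Chem.Mol:
    """Keep the largest covalent fragment (by heavy-atom count; ties: first).

    Charged forms as drawn are preserved; no neutralization or tautomer
    canonicalization is attempted.
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return mol
    best = max(frags, key=lambda f: f.GetNumHeavyAtoms())
    Chem.SanitizeMol(best)
    return best


def records_from_smiles(
    entries: Iterable[tuple[str, str]], dataset_label: str = ""
) -> list[CompoundRecord]:
    """Build records from (smiles, id) pairs, skipping unparseable entries."""
    records = []
    for smi, mol_id in entries:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            logger.warning("skipping unparseable SMILES for %s: %r", mol_id, smi)
            continue
        records.append(CompoundRecord.from_mol(mol, id=mol_id, dataset=dataset_label))
    return records


def read_compound_set(
    path: str | Path, format: str = "smi", dataset_label: str = ""
) -> list[CompoundRecord]:
    """Read a compound set from a ``.smi`` ("SMILES<ws>ID" per line) or SDF file.

    Unparseable entries are logged and skipped. Raises :class:`CurationError`
    for an empty file or when more than half of the entries fail to parse
    (which usually means the declared format is wrong).
    """
    path = Path(path)
    if not path.exists():
        raise CurationError(f"no such file: {path}")

    records: list[CompoundRecord] = []
    n_total = 0
    n_failed = 0
    if format == "smi":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n_total += 1
            parts = line.split(None, 1)
            smi = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{lineno}"
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                n_failed += 1
                logger.warning("%s:%d unparseable SMILES %r", path.name, lineno, smi)
                continue
            records.append(CompoundRecord.from_mol(mol, id=mol_id, dataset=dataset_label))
    elif format == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for i, mol in enumerate(supplier):
            n_total += 1
            if mol is None:
                n_failed += 1
                logger.warning("%s: molblock %d unparseable", path.name, i)
                continue
            mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}_{i}"
            records.append(CompoundRecord.from_mol(mol, id=mol_id, dataset=dataset_label))
    else:
        raise CurationError(f"unknown format {format!r}; expected 'smi' or 'sdf'")

    if n_total == 0:
        raise CurationError(f"{path}: empty compound file")
    if n_failed > n_total / 2:
        raise CurationError(
            f"{path}: {n_failed}/{n_total} entries failed to parse; wrong format?"
        )
    if n_failed:
        logger.info("%s: skipped %d/%d unparseable entries", path.name, n_failed, n_total)
    return records


def filter_mw_window(
    records: Sequence[CompoundRecord], lo: float = 150.0, hi: float = 900.0
) -> list[CompoundRecord]:
    """Keep records with ``lo <= MW <= hi`` (inclusive), preserving input order."""
    if lo > hi:
        raise CurationError(f"invalid MW window: lo={lo} > hi={hi}")
    return [r for r in records if lo <= Descriptors.MolWt(r.structure) <= hi]


_FP_GENERATORS: dict[tuple[int, int], object] = {}


def _fp_generator(radius: int, n_bits: int):
    key = (radius, n_bits)
    if key not in _FP_GENERATORS:
        # Pharmacophoric ("feature") atom invariants give an open FCFP-style
        # circular fingerprint; functional-class rather than element identity.
        inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        _FP_GENERATORS[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits, atomInvariantsGenerator=inv
        )
    return _FP_GENERATORS[key]


def compute_fingerprint(record: CompoundRecord, radius: int = 2, n_bits: int = 2048):
    """Feature-invariant circular fingerprint (FCFP-like), 2048 bits by default."""
    return _fp_generator(radius, n_bits).GetFingerprint(record.structure)


def tanimoto(fp_a, fp_b) -> float:
    return DataStructs.TanimotoSimilarity(fp_a, fp_b)


def diversity_select(
    records: Sequence[CompoundRecord],
    tanimoto_threshold: float = 0.2,
    seed: int = 0,
    cap: int = 650,
    radius: int = 2,
    n_bits: int = 2048,
    metric: str = "similarity",
) -> list[CompoundRecord]:
    """Sphere-exclusion diversity selection with a seeded random size cap.

    A leader pass in input order keeps a record iff its Tanimoto similarity to
    every previously kept record is <= ``tanimoto_threshold`` (with
    ``metric="distance"`` the threshold applies to 1 - similarity instead:
    keep iff every distance >= threshold). If more than ``cap`` records
    survive, a uniform random subsample of size ``cap`` is drawn with ``seed``
    and returned in original input order. Deterministic given input order and
    seed.
    """
    if not records:
        raise CurationError("diversity_select requires at least one record")
    if not 0.0 < tanimoto_threshold < 1.0:
        raise CurationError(f"threshold must lie in (0, 1), got {tanimoto_threshold}")
    if metric not in ("similarity", "distance"):
        raise CurationError(f"metric must be 'similarity' or 'distance', got {metric!r}")

    kept: list[CompoundRecord] = []
    kept_fps: list = []
    for rec in records:
        fp = compute_fingerprint(rec, radius=radius, n_bits=n_bits)
        if metric == "similarity":
            ok = all(tanimoto(fp, other) <= tanimoto_threshold for other in kept_fps)
        else:
            ok = all(1.0 - tanimoto(fp, other) >= tanimoto_threshold for other in kept_fps)
        if ok:
            kept.append(rec)
            kept_fps.append(fp)

    if len(kept) > cap:
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(kept), size=cap, replace=False))
        kept = [kept[i] for i in idx]
    return kept


def write_compound_set(
    records: Sequence[CompoundRecord],
    path: str | Path,
    log_path: str | Path | None = None,
    log_rows: Sequence[tuple[str, str, str]] | None = None,
) -> None:
    """Write records as ``.smi`` plus an optional TSV curation log.

    ``log_rows`` are (id, action, reason) triples accumulated by the caller.
    """
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f"{rec.smiles} {rec.id}\n")
    if log_path is not None:
        with Path(log_path).open("w") as fh:
            fh.write("id\taction\treason\n")
            for row in log_rows or []:
                fh.write("\t".join(row) + "\n")
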