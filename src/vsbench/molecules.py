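"""Molecule records, physicochemical descriptor vectors, and pool I/O.

The unit of decoy selection is a :class:`MoleculeRecord`: an identifier, an
optional 3D point cloud of feature-typed atoms, and a seven-descriptor
physicochemical vector (H-bond acceptors/donors, logS, SlogP, molecular
weight, rotatable bonds, TPSA).  Pools tag each record as an *active* (a
ligand with confirmed target activity) or a *candidate* (a presumed-inactive
molecule from which decoys are drawn).

Descriptor values are model-dependent (logS and SlogP in particular), so
they are always obtained through a pluggable provider — either a
toolkit-backed adapter (:class:`RDKitDescriptorProvider`) or a descriptor
table read from CSV — never computed ad hoc inside the selection algorithms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Pharmacophoric feature types an atom may carry ("color" features).
FEATURE_TYPES = frozenset(
    {"donor", "acceptor", "anion", "cation", "aromatic", "hydrophobe"}
)

#: Descriptor order used throughout (and in CSV headers).
DESCRIPTOR_FIELDS = ("hba", "hbd", "logS", "slogp", "mw", "rotbonds", "tpsa")

_INT_FIELDS = ("hba", "hbd", "rotbonds")


class PoolError(ValueError):
    """Raised for malformed or inconsistent molecule pools."""


@dataclass(frozen=True)
class DescriptorVector:
    """Seven drug-like physicochemical descriptors.

    Parameters
    ----------
    hba, hbd : int
        Hydrogen-bond acceptor / donor counts.
    logS : float
        log10 aqueous solubility (mol/L).
    slogp : float
        Atom-contribution logP.
    mw : float
        Molecular weight in Da (> 0).
    rotbonds : int
        Number of rotatable bonds.
    tpsa : float
        Topological polar surface area in Å² (>= 0).
    """

    hba: int
    hbd: int
    logS: float
    slogp: float
    mw: float
    rotbonds: int
    tpsa: float

    def __post_init__(self) -> None:
        for name in _INT_FIELDS:
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite descriptor in {vals}")
        if self.mw <= 0:
            raise ValueError(f"mw must be > 0, got {self.mw}")
        if self.tpsa < 0:
            raise ValueError(f"tpsa must be >= 0, got {self.tpsa}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in DESCRIPTOR_FIELDS], dtype=float)


@dataclass(frozen=True)
class Atom:
    """One atom of a 3D point cloud: element, position (Å), feature tags."""

    element: str
    x: float
    y: float
    z: float
    tags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise ValueError("atom coordinates must be finite")
        bad = set(self.tags) - FEATURE_TYPES
        if bad:
            raise ValueError(f"unknown feature tags {sorted(bad)}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class MoleculeRecord:
    """A molecule: id, optional SMILES, optional tagged 3D atoms, descriptors."""

    id: str
    descriptors: Optional[DescriptorVector] = None
    smiles: Optional[str] = None
    atoms: Optional[tuple] = None  # tuple[Atom, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("molecule id must be non-empty")
        if self.atoms is not None:
            self.atoms = tuple(self.atoms)
            if len(self.atoms) == 0:
                raise ValueError(f"{self.id}: atom list present but empty")

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        if self.atoms is None:
            raise ValueError(f"{self.id}: no 3D atoms")
        return np.array([a.xyz for a in self.atoms])


@dataclass
class MoleculePool:
    """An ordered collection of records with active/candidate role labels."""

    records: list = field(default_factory=list)
    roles: dict = field(default_factory=dict)  # id -> "active" | "candidate"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PoolError(f"duplicate molecule ids: {sorted(dupes)}")
        for r in self.records:
            self.roles.setdefault(r.id, "candidate")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, mol_id: str) -> MoleculeRecord:
        for r in self.records:
            if r.id == mol_id:
                return r
        raise KeyError(mol_id)

    def actives(self) -> list:
        return [r for r in self.records if self.roles.get(r.id) == "active"]

    def candidates(self) -> list:
        return [r for r in self.records if self.roles.get(r.id) == "candidate"]


# ---------------------------------------------------------------------------
# descriptor providers
# ---------------------------------------------------------------------------


class RDKitDescriptorProvider:
    """Compute the seven descriptors from structure with RDKit.

    logS is estimated with the ESOL model (Delaney 2004):
    ``logS = 0.16 - 0.63 clogP - 0.0062 MW + 0.066 RB - 0.74 AP``
    where AP is the aromatic proportion of heavy atoms.  The model choice is
    recorded in :attr:`metadata` so downstream outputs can carry provenance.
    """

    metadata = {"provider": "rdkit", "logS_model": "ESOL (Delaney 2004)"}

    def __call__(self, mol: MoleculeRecord) -> DescriptorVector:
        from rdkit import Chem

        if mol.smiles is None:
            raise ValueError(f"{mol.id}: RDKit provider needs a SMILES")
        m = Chem.MolFromSmiles(mol.smiles)
        if m is None:
            raise ValueError(f"{mol.id}: unparseable SMILES {mol.smiles!r}")
        return self.from_rdkit_mol(m)

    @staticmethod
    def from_rdkit_mol(m) -> DescriptorVector:
        from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

        mw = Descriptors.MolWt(m)
        clogp = Crippen.MolLogP(m)
        rb = Lipinski.NumRotatableBonds(m)
        heavy = m.GetNumHeavyAtoms()
        aromatic = sum(1 for a in m.GetAtoms() if a.GetIsAromatic())
        ap = aromatic / heavy if heavy else 0.0
        logs = 0.16 - 0.63 * clogp - 0.0062 * mw + 0.066 * rb - 0.74 * ap
        return DescriptorVector(
            hba=Lipinski.NumHAcceptors(m),
            hbd=Lipinski.NumHDonors(m),
            logS=logs,
            slogp=clogp,
            mw=mw,
            rotbonds=rb,
            tpsa=rdMolDescriptors.CalcTPSA(m),
        )


def compute_descriptors(provider, mol: MoleculeRecord) -> DescriptorVector:
    """Populate all seven descriptors for ``mol`` through ``provider``.

    The provider is any callable ``MoleculeRecord -> DescriptorVector``.
    """
    vec = provider(mol)
    if not isinstance(vec, DescriptorVector):
        raise TypeError("provider must return a DescriptorVector")
    return vec


_FEATURE_FAMILY_MAP = {
    "Donor": "donor",
    "Acceptor": "acceptor",
    "NegIonizable": "anion",
    "PosIonizable": "cation",
    "Aromatic": "aromatic",
    "Hydrophobe": "hydrophobe",
    "LumpedHydrophobe": "hydrophobe",
}


def assign_feature_tags(rdkit_mol) -> dict:
    """Map heavy-atom indices to pharmacophore feature tags via RDKit's
    base feature definitions.  Returns ``{atom_index: frozenset(tags)}``."""
    import os

    from rdkit import Chem, RDConfig
    from rdkit.Chem import ChemicalFeatures

    fdef = os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
    factory = ChemicalFeatures.BuildFeatureFactory(fdef)
    tags: dict = {}
    for feat in factory.GetFeaturesForMol(rdkit_mol):
        mapped = _FEATURE_FAMILY_MAP.get(feat.GetFamily())
        if mapped is None:
            continue
        for idx in feat.GetAtomIds():
            tags.setdefault(idx, set()).add(mapped)
    return {i: frozenset(t) for i, t in tags.items()}


# ---------------------------------------------------------------------------
# ΔPK
# ---------------------------------------------------------------------------


def delta_pk(
    active: DescriptorVector,
    cand: DescriptorVector,
    mode: str = "raw",
    scales: Optional[Sequence[float]] = None,
) -> float:
    """Sum of absolute descriptor differences between two molecules.

    ``mode='raw'`` sums the seven absolute differences directly; with
    ``mode='scaled'`` each term is divided by the matching entry of
    ``scales`` (seven positive numbers), making the incommensurate units
    comparable.  The result is a weighted L1 metric: symmetric, zero iff the
    vectors are equal, and satisfying the triangle inequality.
    """
    a, c = active.as_array(), cand.as_array()
    diff = np.abs(a - c)
    if mode == "raw":
        return float(diff.sum())
    if mode == "scaled":
        if scales is None:
            raise ValueError("scaled mode requires scales")
        s = np.asarray(scales, dtype=float)
        if s.shape != (7,) or np.any(s <= 0) or not np.all(np.isfinite(s)):
            raise ValueError("scales must be 7 positive finite numbers")
        return float((diff / s).sum())
    raise ValueError(f"unknown delta_pk mode {mode!r}")


def mad_scales(pool: MoleculePool) -> np.ndarray:
    """Per-descriptor median absolute deviation over a pool, for scaled ΔPK.

    Descriptors whose MAD is zero (constant over the pool) fall back to 1 so
    the scaled metric stays defined.
    """
    mat = np.array([r.descriptors.as_array() for r in pool.records])
    med = np.median(mat, axis=0)
    mad = np.median(np.abs(mat - med), axis=0)
    mad[mad == 0] = 1.0
    return mad


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["id", *DESCRIPTOR_FIELDS]


def read_pool(path, format: str, provider=None) -> MoleculePool:
    """Read a molecule pool from ``descriptor_csv``, ``smiles_csv`` or ``sdf``.

    Malformed entries are skipped with a logged warning and counted; zero
    parseable records or duplicated ids raise :class:`PoolError`.  For
    ``smiles_csv`` and ``sdf`` a descriptor provider is required (defaults to
    :class:`RDKitDescriptorProvider`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "descriptor_csv":
        return _read_descriptor_csv(path)
    if format == "smiles_csv":
        return _read_smiles_csv(path, provider or RDKitDescriptorProvider())
    if format == "sdf":
        return _read_sdf(path, provider or RDKitDescriptorProvider())
    raise ValueError(f"unknown pool format {format!r}")


def _finish_pool(records: list, roles: dict, skipped: int, path: Path) -> MoleculePool:
    if skipped:
        logger.warning("%s: skipped %d malformed entries", path, skipped)
    if not records:
        raise PoolError(f"{path}: no parseable records")
    return MoleculePool(records=records, roles=roles)


def _read_descriptor_csv(path: Path) -> MoleculePool:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise PoolError(f"{path}: missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise PoolError(f"{path}: duplicate ids {dupes}")
    records, roles, skipped = [], {}, 0
    for _, row in df.iterrows():
        try:
            vec = DescriptorVector(
                hba=int(row["hba"]),
                hbd=int(row["hbd"]),
                logS=float(row["logS"]),
                slogp=float(row["slogp"]),
                mw=float(row["mw"]),
                rotbonds=int(row["rotbonds"]),
                tpsa=float(row["tpsa"]),
            )
            rec = MoleculeRecord(id=str(row["id"]), descriptors=vec)
        except (ValueError, TypeError) as exc:
            logger.warning("%s: skipping row %r: %s", path, row.get("id"), exc)
            skipped += 1
            continue
        records.append(rec)
        if "role" in df.columns and isinstance(row.get("role"), str):
            roles[rec.id] = row["role"]
    return _finish_pool(records, roles, skipped, path)


def _read_smiles_csv(path: Path, provider) -> MoleculePool:
    df = pd.read_csv(path)
    if not {"id", "smiles"} <= set(df.columns):
        raise PoolError(f"{path}: smiles_csv needs columns id,smiles")
    if df["id"].duplicated().any():
        dupes = sorted(df.loc[df["id"].duplicated(), "id"].unique())
        raise PoolError(f"{path}: duplicate ids {dupes}")
    records, roles, skipped = [], {}, 0
    for _, row in df.iterrows():
        rec = MoleculeRecord(id=str(row["id"]), smiles=str(row["smiles"]))
        try:
            rec.descriptors = compute_descriptors(provider, rec)
        except ValueError as exc:
            logger.warning("%s: skipping %s: %s", path, rec.id, exc)
            skipped += 1
            continue
        records.append(rec)
        if "role" in df.columns and isinstance(row.get("role"), str):
            roles[rec.id] = row["role"]
    return _finish_pool(records, roles, skipped, path)


def _read_sdf(path: Path, provider) -> MoleculePool:
    from rdkit import Chem

    records, skipped = [], 0
    supplier = Chem.SDMolSupplier(str(path), removeHs=False)
    for i, m in enumerate(supplier):
        if m is None:
            skipped += 1
            continue
        mol_id = m.GetProp("_Name") if m.HasProp("_Name") and m.GetProp("_Name") else f"mol{i}"
        atoms = None
        if m.GetNumConformers() > 0 and m.GetConformer().Is3D():
            conf = m.GetConformer()
            tag_map = assign_feature_tags(m)
            atoms = tuple(
                Atom(
                    element=a.GetSymbol(),
                    x=conf.GetAtomPosition(a.GetIdx()).x,
                    y=conf.GetAtomPosition(a.GetIdx()).y,
                    z=conf.GetAtomPosition(a.GetIdx()).z,
                    tags=tag_map.get(a.GetIdx(), frozenset()),
                )
                for a in m.GetAtoms()
                if a.GetAtomicNum() > 1
            )
        try:
            vec = RDKitDescriptorProvider.from_rdkit_mol(Chem.RemoveHs(m))
            records.append(
                MoleculeRecord(
                    id=mol_id, smiles=Chem.MolToSmiles(m), atoms=atoms, descriptors=vec
                )
            )
        except ValueError as exc:
            logger.warning("%s: skipping %s: %s", path, mol_id, exc)
            skipped += 1
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise PoolError(f"{path}: duplicate ids {dupes}")
    return _finish_pool(records, {}, skipped, path)


def write_pool(pool: MoleculePool, path) -> None:
    """Write a pool as a descriptor CSV (columns id,<7 descriptors>,role)."""
    rows = []
    for r in pool.records:
        if r.descriptors is None:
            raise PoolError(f"{r.id}: cannot write record without descriptors")
        row = {"id": r.id}
        row.update(
            {f: getattr(r.descriptors, f) for f in DESCRIPTOR_FIELDS}
        )
        row["role"] = pool.roles.get(r.id, "candidate")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
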