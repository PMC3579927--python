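"""Alignment-free 3D similarity: a USR-style comboscore provider.

A comboscore in [0, 2] combines a shape term and a pharmacophore ("color")
term, each in [0, 1]; the maximum value of 2 denotes identical molecules.
The bundled reference provider describes a conformer by ultrafast shape
recognition (USR) moments: for four reference points — the centroid, the
atom closest to the centroid, the atom farthest from the centroid, and the
atom farthest from that atom — it records the mean, standard deviation, and
(cube-rooted, sign-preserving) skew of the distribution of distances to all
atoms, giving 12 numbers in Å that are invariant to rigid motion.  The
color term applies the same moments per feature type.

Any callable ``(MoleculeRecord, MoleculeRecord) -> float in [0, 2]`` can
stand in as a comboscore provider (e.g. a table of precomputed values from
an external overlay program); the selection algorithms consume only the
scalar.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .molecules import FEATURE_TYPES, MoleculeRecord

__all__ = [
    "ShapeMoments",
    "ComboScore",
    "shape_moments",
    "shape_sim",
    "color_sim",
    "comboscore",
    "UsrComboProvider",
    "TableComboProvider",
]


@dataclass(frozen=True)
class ShapeMoments:
    """12 distance-distribution moments (4 reference points × mean/SD/∛skew, Å)."""

    values: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (12,):
            raise ValueError("ShapeMoments needs exactly 12 numbers")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite shape moment")
        # means and SDs (positions 0,1 of each triple) are non-negative
        if np.any(v.reshape(4, 3)[:, :2] < -1e-12):
            raise ValueError("negative mean/SD moment")
        object.__setattr__(self, "values", tuple(v))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class ComboScore:
    shape: float
    color: float

    def __post_init__(self):
        if not (0.0 <= self.shape <= 1.0 and 0.0 <= self.color <= 1.0):
            raise ValueError(f"components out of range: {self.shape}, {self.color}")

    @property
    def total(self) -> float:
        return self.shape + self.color


def _distribution_moments(d: np.ndarray) -> tuple:
    """mean, population SD, and signed cube root of the third central moment."""
    mu = float(d.mean())
    centered = d - mu
    sd = float(np.sqrt(np.mean(centered**2)))
    m3 = float(np.mean(centered**3))
    return mu, sd, float(np.cbrt(m3))


def shape_moments(coords) -> ShapeMoments:
    """USR moments of an atomic point cloud.

    Reference points, in order: centroid; atom closest to the centroid; atom
    farthest from the centroid; atom farthest from that atom.  Ties on the
    closest/farthest selections go to the lowest atom index, so the result
    is deterministic.  Rigid rotation/translation of the input leaves the
    moments unchanged.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 1:
        raise ValueError("coords must be a non-empty (n, 3) array")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    ctd = x.mean(axis=0)
    d_ctd = np.linalg.norm(x - ctd, axis=1)
    cst = x[int(np.argmin(d_ctd))]
    fct = x[int(np.argmax(d_ctd))]
    d_fct_all = np.linalg.norm(x - fct, axis=1)
    ftf = x[int(np.argmax(d_fct_all))]
    out = []
    for ref in (ctd, cst, fct, ftf):
        out.extend(_distribution_moments(np.linalg.norm(x - ref, axis=1)))
    return ShapeMoments(tuple(out))


def shape_sim(a: ShapeMoments, b: ShapeMoments) -> float:
    """Similarity in (0, 1]: ``1 / (1 + mean |a_i - b_i|)`` over the 12 moments."""
    l1 = float(np.abs(a.as_array() - b.as_array()).sum())
    return 1.0 / (1.0 + l1 / 12.0)


def _per_type_moments(rec: MoleculeRecord) -> dict:
    if rec.atoms is None:
        raise ValueError(f"{rec.id}: no 3D atoms; shape similarity needs coordinates")
    if all(not a.tags for a in rec.atoms):
        raise ValueError(
            f"{rec.id}: atoms carry no feature tags; run feature typing first"
        )
    out = {}
    for ft in sorted(FEATURE_TYPES):
        pts = [a.xyz for a in rec.atoms if ft in a.tags]
        if pts:
            out[ft] = shape_moments(np.array(pts))
    return out


def color_sim(a: MoleculeRecord, b: MoleculeRecord) -> float:
    """Pharmacophore-feature similarity in [0, 1].

    Mean, over feature types present in either molecule, of the per-type
    shape similarity restricted to atoms of that type; a type present in
    only one of the two contributes 0.
    """
    ma, mb = _per_type_moments(a), _per_type_moments(b)
    types = sorted(set(ma) | set(mb))
    if not types:
        return 0.0
    sims = [shape_sim(ma[t], mb[t]) if t in ma and t in mb else 0.0 for t in types]
    return float(np.mean(sims))


def comboscore(a: MoleculeRecord, b: MoleculeRecord) -> ComboScore:
    """Shape + color similarity; total in [0, 2], 2 for identical clouds."""
    if a.atoms is None or b.atoms is None:
        raise ValueError("comboscore needs 3D atoms on both molecules")
    s = shape_sim(shape_moments(a.coords()), shape_moments(b.coords()))
    c = color_sim(a, b)
    return ComboScore(shape=s, color=c)


class UsrComboProvider:
    """Comboscore provider backed by the USR reference implementation.

    Caches per-record moments by molecule id, so scoring one active against
    a large candidate pool touches each conformer once.  Single-conformer:
    each record's stored geometry is used as-is.
    """

    metadata = {"provider": "usr_reference", "conformers": "single"}

    def __init__(self):
        self._cache: dict = {}

    def _moments(self, rec: MoleculeRecord):
        key = rec.id
        if key not in self._cache:
            self._cache[key] = (
                shape_moments(rec.coords()),
                _per_type_moments(rec),
            )
        return self._cache[key]

    def __call__(self, a: MoleculeRecord, b: MoleculeRecord) -> float:
        sa, ta = self._moments(a)
        sb, tb = self._moments(b)
        s = shape_sim(sa, sb)
        types = sorted(set(ta) | set(tb))
        sims = [shape_sim(ta[t], tb[t]) if t in ta and t in tb else 0.0 for t in types]
        c = float(np.mean(sims)) if types else 0.0
        return ComboScore(shape=s, color=c).total


class TableComboProvider:
    """Comboscore provider reading precomputed pairwise values from CSV.

    Expected columns: ``active_id,candidate_id,comboscore``.  Lookups are
    symmetric in the two ids.
    """

    metadata = {"provider": "table"}

    def __init__(self, path):
        import pandas as pd

        df = pd.read_csv(Path(path))
        need = {"active_id", "candidate_id", "comboscore"}
        if not need <= set(df.columns):
            raise ValueError(f"{path}: need columns {sorted(need)}")
        self._table = {}
        for row in df.itertuples(index=False):
            v = float(row.comboscore)
            if not 0.0 <= v <= 2.0:
                raise ValueError(
                    f"comboscore {v} for ({row.active_id}, {row.candidate_id}) "
                    "outside [0, 2]"
                )
            self._table[(row.active_id, row.candidate_id)] = v
            self._table.setdefault((row.candidate_id, row.active_id), v)

    def __call__(self, a: MoleculeRecord, b: MoleculeRecord) -> float:
        try:
            return self._table[(a.id, b.id)]
        except KeyError:
            raise KeyError(f"no comboscore tabulated for pair ({a.id}, {b.id})")
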