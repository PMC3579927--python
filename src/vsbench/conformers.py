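"""Trajectory superposition, pairwise RMSD, and gromos clustering.

Receptor models for ensemble docking are picked from an MD trajectory by
(1) superposing every frame onto the first frame to remove rigid-body
motion, (2) computing the pairwise RMSD matrix over a binding-pocket atom
subset, (3) clustering with the gromos algorithm at a fixed RMSD cutoff
(0.75 Å in the reference protocol), and (4) taking centroids of the most
populated clusters (top five in the reference protocol, with room for an
explicitly added extra frame chosen on other grounds).

gromos clustering: repeatedly count, for each unassigned frame, its
neighbours within the cutoff; the frame with the most neighbours becomes a
cluster centroid, it and its neighbours form a cluster and are removed, and
the count repeats until no frames remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "ConformerEnsemble",
    "ClusterResult",
    "kabsch_superpose",
    "rmsd_matrix",
    "gromos_cluster",
    "select_centroids",
    "atoms_near",
    "read_pdb_frames",
    "read_xyz_frames",
]

_H_NAMES = {"H", "D"}


@dataclass
class ConformerEnsemble:
    """Frames of labelled atomic coordinates (Å), all with the same atoms."""

    frames: np.ndarray  # (n_frames, n_atoms, 3)
    atom_names: Optional[list] = None
    elements: Optional[list] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates")
        for attr in ("atom_names", "elements"):
            names = getattr(self, attr)
            if names is not None and len(names) != self.n_atoms:
                raise ValueError(f"{attr} length != atom count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


def kabsch_superpose(mobile, reference):
    """Optimal rigid-body alignment of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` with the proper rotation
    matrix (det +1) and translation minimising the RMSD of the paired point
    sets: ``aligned = mobile @ rotation.T + translation``.

    Both sets need >= 3 points and must not be collinear.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if mob.shape[0] < 3:
        raise ValueError("need at least 3 point pairs")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    for name, pts in (("mobile", mob_c), ("reference", ref_c)):
        if np.linalg.matrix_rank(pts, tol=1e-8 * max(1.0, np.abs(pts).max())) < 2:
            raise ValueError(f"degenerate (collinear) {name} geometry")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    r = rot.as_matrix()
    t = ref.mean(axis=0) - mob.mean(axis=0) @ r.T
    aligned = mob @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - ref) ** 2, axis=1))))
    return r, t, rmsd


def _superpose_onto_first(frames: np.ndarray) -> np.ndarray:
    out = np.empty_like(frames)
    out[0] = frames[0]
    for i in range(1, len(frames)):
        r, t, _ = kabsch_superpose(frames[i], frames[0])
        out[i] = frames[i] @ r.T + t
    return out


def rmsd_matrix(
    ens: ConformerEnsemble,
    mask: Optional[Sequence[int]] = None,
    superpose_first: bool = True,
) -> np.ndarray:
    """Symmetric pairwise RMSD matrix (Å) over the frames of an ensemble.

    With ``superpose_first`` every frame is first rigidly superposed onto
    frame 0 using all atoms; RMSDs are then computed directly on the
    ``mask`` atom subset (no further per-pair fitting), matching the
    superpose-then-cluster protocol.
    """
    if ens.n_frames < 2:
        raise ValueError("need at least 2 frames")
    frames = _superpose_onto_first(ens.frames) if superpose_first else ens.frames
    if mask is not None:
        idx = np.asarray(mask, dtype=int)
        if idx.size == 0:
            raise ValueError("mask selects no atoms")
        frames = frames[:, idx, :]
    diff = frames[:, None, :, :] - frames[None, :, :, :]
    m = np.sqrt(np.mean(np.sum(diff**2, axis=-1), axis=-1))
    return (m + m.T) / 2.0  # exact symmetry against fp round-off


@dataclass
class ClusterResult:
    """gromos clusters ordered by descending size; members include centroids."""

    clusters: list = field(default_factory=list)  # [(centroid_index, [members])]
    cutoff: float = 0.0

    def sizes(self) -> list:
        return [len(members) for _, members in self.clusters]

    def labels(self, n_frames: int) -> np.ndarray:
        lab = np.full(n_frames, -1, dtype=int)
        for k, (_, members) in enumerate(self.clusters):
            lab[list(members)] = k
        return lab


def gromos_cluster(m: np.ndarray, cutoff: float) -> ClusterResult:
    """Cluster frames from a pairwise RMSD matrix with the gromos algorithm.

    Iteratively, the unassigned frame with the most unassigned neighbours
    within ``cutoff`` becomes a centroid; it and those neighbours form a
    cluster and are removed.  Neighbour-count ties go to the lowest frame
    index.  Every frame ends in exactly one cluster; clusters are returned
    ordered by descending size (ties by earliest centroid index).
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("RMSD matrix must be square")
    if not np.allclose(m, m.T, atol=1e-8):
        raise ValueError("RMSD matrix must be symmetric")
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    n = m.shape[0]
    within = m <= cutoff
    unassigned = np.ones(n, dtype=bool)
    clusters = []
    while unassigned.any():
        counts = (within & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.flatnonzero(within[centroid] & unassigned)
        clusters.append((centroid, members.tolist()))
        unassigned[members] = False
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return ClusterResult(clusters=clusters, cutoff=float(cutoff))


def select_centroids(
    res: ClusterResult, top_k: int = 5, extra: Optional[Sequence[int]] = None
) -> list:
    """Centroid frame indices of the ``top_k`` most populated clusters.

    Size ties resolve to the earliest centroid index (already the cluster
    ordering).  If fewer clusters exist, the shorter list is returned with
    a warning.  ``extra`` appends explicitly chosen frame indices (e.g. a
    centroid included on solvent-accessibility grounds), deduplicated.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(res.clusters) < top_k:
        warnings.warn(
            f"only {len(res.clusters)} clusters available (top_k={top_k})",
            stacklevel=2,
        )
    picks = [centroid for centroid, _ in res.clusters[:top_k]]
    for idx in extra or []:
        if idx not in picks:
            picks.append(int(idx))
    return picks


def atoms_near(
    reference_frame,
    pocket_indices: Sequence[int],
    radius: float = 10.0,
    elements: Optional[Sequence[str]] = None,
    heavy_only: bool = True,
) -> np.ndarray:
    """Atom indices within ``radius`` Å (minimum distance) of a pocket atom set.

    The usual recipe for a clustering mask: every atom of the reference
    frame whose distance to the nearest pocket atom is at most ``radius``
    (default 10 Å).  With ``heavy_only`` and ``elements`` given, hydrogens
    are excluded.
    """
    x = np.asarray(reference_frame, dtype=float)
    pocket = x[np.asarray(pocket_indices, dtype=int)]
    if pocket.size == 0:
        raise ValueError("empty pocket atom set")
    dmin = np.min(
        np.linalg.norm(x[:, None, :] - pocket[None, :, :], axis=-1), axis=1
    )
    keep = dmin <= radius
    if heavy_only and elements is not None:
        keep &= np.array([e.strip().upper() not in _H_NAMES for e in elements])
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_pdb_frames(path) -> ConformerEnsemble:
    """Read a multi-MODEL PDB file; each MODEL becomes a frame."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("traj", str(Path(path)))
    frames, names, elements = [], None, None
    for model in structure:
        atoms = list(model.get_atoms())
        coords = np.array([a.get_coord() for a in atoms], dtype=float)
        if names is None:
            names = [a.get_name() for a in atoms]
            elements = [a.element or a.get_name()[0] for a in atoms]
        elif len(atoms) != len(names):
            raise ValueError(f"{path}: models differ in atom count")
        frames.append(coords)
    if not frames:
        raise ValueError(f"{path}: no models found")
    return ConformerEnsemble(
        frames=np.array(frames), atom_names=names, elements=elements
    )


def read_xyz_frames(path) -> ConformerEnsemble:
    """Read a concatenated multi-frame XYZ file (count / comment / atom lines)."""
    lines = Path(path).read_text().splitlines()
    frames, elements = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: truncated frame at line {i + 1}")
        els, coords = [], []
        for ln in block:
            parts = ln.split()
            els.append(parts[0])
            coords.append([float(p) for p in parts[1:4]])
        if elements is None:
            elements = els
        elif els != elements:
            raise ValueError(f"{path}: frames differ in atom labelling")
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return ConformerEnsemble(frames=np.array(frames, dtype=float), elements=elements)


def write_cluster_report(res: ClusterResult, path) -> None:
    """Write a cluster report CSV: cluster_rank,centroid_frame,size,member_frames."""
    import pandas as pd

    rows = [
        {
            "cluster_rank": k + 1,
            "centroid_frame": centroid,
            "size": len(members),
            "member_frames": ";".join(map(str, members)),
        }
        for k, (centroid, members) in enumerate(res.clusters)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
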