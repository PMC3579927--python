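"""Seeded generators for every input the pipeline consumes.

Three generators emulate the statistical structure the analysis stages
assume, with planted signal whose recovery is the point of the test suite:

* :func:`gen_pool` — a candidate pool with drug-like descriptor vectors and
  feature-typed 3D point clouds, in which a fraction of candidates are
  perturbed copies ("mimics") of the actives and should therefore win the
  decoy-score ranking;
* :func:`gen_screen` — an active/decoy docking score matrix over several
  receptor models, with actives drawn from a better (lower) score
  distribution than decoys, plus an optional duplicate-variant table for
  the score-averaging step;
* :func:`gen_conformers` — a conformer ensemble with ``n_blobs`` planted
  conformational states, separated by per-atom displacements much larger
  than the within-state jitter, for clustering recovery.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .conformers import ConformerEnsemble
from .molecules import Atom, DescriptorVector, MoleculePool, MoleculeRecord

__all__ = ["PoolSpec", "ScreenSpec", "gen_pool", "gen_screen", "gen_conformers"]

#: Drug-like sampling windows per descriptor: (low, high, integer?)
DEFAULT_DESCRIPTOR_RANGES = {
    "hba": (0, 10, True),
    "hbd": (0, 5, True),
    "logS": (-6.0, -1.0, False),
    "slogp": (-1.0, 6.0, False),
    "mw": (150.0, 550.0, False),
    "rotbonds": (0, 10, True),
    "tpsa": (20.0, 140.0, False),
}

DEFAULT_FEATURE_PROBS = {
    "hydrophobe": 0.40,
    "aromatic": 0.20,
    "donor": 0.15,
    "acceptor": 0.15,
    "cation": 0.05,
    "anion": 0.05,
}


@dataclass
class PoolSpec:
    """Specification of a synthetic actives + candidates pool."""

    n_actives: int = 11
    n_candidates: int = 500
    mimic_fraction: float = 0.3
    atoms_range: Tuple[int, int] = (10, 30)
    descriptor_ranges: dict = field(
        default_factory=lambda: dict(DEFAULT_DESCRIPTOR_RANGES)
    )
    feature_probs: dict = field(default_factory=lambda: dict(DEFAULT_FEATURE_PROBS))
    mimic_jitter: float = 0.3  # Å, atom-cloud perturbation of mimics
    seed: int = 0

    def __post_init__(self):
        if self.n_actives < 1 or self.n_candidates < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 <= self.mimic_fraction <= 1.0:
            raise ValueError("mimic_fraction must lie in [0, 1]")
        lo, hi = self.atoms_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid atoms_range")
        for name, (a, b, _) in self.descriptor_ranges.items():
            if b < a:
                raise ValueError(f"invalid range for {name}")


@dataclass
class ScreenSpec:
    """Specification of a synthetic active/decoy docking score matrix."""

    n_actives: int = 11
    n_decoys: int = 220
    n_models: int = 7
    mu_active: float = -9.0
    sd_active: float = 1.0
    mu_decoy: float = -6.5
    sd_decoy: float = 1.0
    model_jitter_sd: float = 0.5
    n_parents: Optional[int] = None  # duplicate-variant table
    variants_per_parent: int = 1
    seed: int = 0

    def __post_init__(self):
        if min(self.n_actives, self.n_decoys, self.n_models) < 1:
            raise ValueError("counts must be >= 1")
        if min(self.sd_active, self.sd_decoy) <= 0 or self.model_jitter_sd < 0:
            raise ValueError("score SDs must be positive")
        if self.variants_per_parent < 1:
            raise ValueError("variants_per_parent must be >= 1")


def _sample_descriptors(rng: np.random.Generator, ranges: dict) -> DescriptorVector:
    vals = {}
    for name, (lo, hi, is_int) in ranges.items():
        if is_int:
            vals[name] = int(rng.integers(lo, hi + 1))
        else:
            vals[name] = float(rng.uniform(lo, hi))
    if vals["mw"] <= 0:
        vals["mw"] = 1.0
    return DescriptorVector(**vals)


def _sample_atoms(rng: np.random.Generator, spec: PoolSpec) -> tuple:
    n = int(rng.integers(spec.atoms_range[0], spec.atoms_range[1] + 1))
    coords = rng.normal(0.0, 3.0, size=(n, 3))
    types = list(spec.feature_probs)
    probs = np.array([spec.feature_probs[t] for t in types], dtype=float)
    probs = probs / probs.sum()
    tags = rng.choice(len(types), size=n, p=probs)
    return tuple(
        Atom(element="C", x=c[0], y=c[1], z=c[2], tags=frozenset({types[t]}))
        for c, t in zip(coords, tags)
    )


def _perturb_descriptors(
    rng: np.random.Generator, vec: DescriptorVector, ranges: dict
) -> DescriptorVector:
    vals = {}
    for name, (lo, hi, is_int) in ranges.items():
        v = getattr(vec, name)
        if is_int:
            v = int(np.clip(v + rng.integers(-1, 2), max(lo, 0), hi))
        else:
            span = hi - lo
            v = float(np.clip(v + rng.normal(0.0, 0.02 * span), lo, hi))
            if name == "mw":
                v = max(v, 1.0)
            if name == "tpsa":
                v = max(v, 0.0)
        vals[name] = v
    return DescriptorVector(**vals)


def _perturb_atoms(rng: np.random.Generator, atoms: tuple, jitter: float) -> tuple:
    return tuple(
        Atom(
            element=a.element,
            x=a.x + rng.normal(0.0, jitter),
            y=a.y + rng.normal(0.0, jitter),
            z=a.z + rng.normal(0.0, jitter),
            tags=a.tags,
        )
        for a in atoms
    )


def gen_pool(spec: PoolSpec) -> MoleculePool:
    """Generate a pool of ``n_actives`` actives and ``n_candidates`` candidates.

    A ``mimic_fraction`` of the candidates are perturbed copies of randomly
    chosen actives (descriptors nudged slightly, atom cloud jittered by
    ``mimic_jitter`` Å with feature tags kept), so they carry small ΔPK and
    a comboscore near 2 against their source active; the remainder are
    drawn independently from the descriptor windows.  Deterministic per
    seed; ids are ``ACT###`` and ``CND###`` in generation order.
    """
    rng = np.random.default_rng(spec.seed)
    records, roles = [], {}
    actives = []
    for k in range(spec.n_actives):
        rec = MoleculeRecord(
            id=f"ACT{k + 1:03d}",
            descriptors=_sample_descriptors(rng, spec.descriptor_ranges),
            atoms=_sample_atoms(rng, spec),
        )
        actives.append(rec)
        records.append(rec)
        roles[rec.id] = "active"
    n_mimics = int(round(spec.mimic_fraction * spec.n_candidates))
    for k in range(spec.n_candidates):
        cid = f"CND{k + 1:03d}"
        if k < n_mimics:
            src = actives[int(rng.integers(0, len(actives)))]
            rec = MoleculeRecord(
                id=cid,
                descriptors=_perturb_descriptors(
                    rng, src.descriptors, spec.descriptor_ranges
                ),
                atoms=_perturb_atoms(rng, src.atoms, spec.mimic_jitter),
            )
        else:
            rec = MoleculeRecord(
                id=cid,
                descriptors=_sample_descriptors(rng, spec.descriptor_ranges),
                atoms=_sample_atoms(rng, spec),
            )
        records.append(rec)
        roles[cid] = "candidate"
    return MoleculePool(records=records, roles=roles)


def gen_screen(spec: ScreenSpec):
    """Generate a ligand × model docking score table with planted enrichment.

    Each ligand draws a base score from its class distribution (actives:
    ``Normal(mu_active, sd_active)``; decoys: ``Normal(mu_decoy,
    sd_decoy)``; lower = better) and each model column adds independent
    ``Normal(0, model_jitter_sd)`` jitter.  Returns ``(ScoreTable,
    variant_table)``; the variant table (parent_id, variant_id, score) is
    ``None`` unless ``n_parents`` is set.
    """
    from .screening import ScoreTable

    rng = np.random.default_rng(spec.seed)
    ligands = [f"ACT{k + 1:03d}" for k in range(spec.n_actives)] + [
        f"DEC{k + 1:03d}" for k in range(spec.n_decoys)
    ]
    labels = pd.Series(
        [True] * spec.n_actives + [False] * spec.n_decoys, index=ligands
    )
    base = np.concatenate(
        [
            rng.normal(spec.mu_active, spec.sd_active, size=spec.n_actives),
            rng.normal(spec.mu_decoy, spec.sd_decoy, size=spec.n_decoys),
        ]
    )
    n = len(ligands)
    jitter = (
        rng.normal(0.0, spec.model_jitter_sd, size=(n, spec.n_models))
        if spec.model_jitter_sd > 0
        else np.zeros((n, spec.n_models))
    )
    models = ["Homology"] + [f"model{k}" for k in range(1, spec.n_models)]
    scores = pd.DataFrame(base[:, None] + jitter, index=ligands, columns=models)
    table = ScoreTable(scores=scores, labels=labels)

    variants = None
    if spec.n_parents is not None:
        rows = []
        for p in range(spec.n_parents):
            pid = f"PAR{p + 1:03d}"
            mu = rng.normal(spec.mu_decoy, spec.sd_decoy)
            for v in range(spec.variants_per_parent):
                rows.append(
                    {
                        "parent_id": pid,
                        "variant_id": f"{pid}.{v + 1}",
                        "score": mu + rng.normal(0.0, spec.model_jitter_sd or 0.1),
                    }
                )
        variants = pd.DataFrame(rows)
    return table, variants


def gen_conformers(
    n_frames: int = 60,
    n_atoms: int = 30,
    n_blobs: int = 3,
    separation: float = 5.0,
    jitter_sd: float = 0.2,
    seed: int = 0,
    blob_weights: Optional[np.ndarray] = None,
):
    """Generate an ensemble with ``n_blobs`` planted conformational states.

    A base geometry is drawn once; each blob's reference conformation adds
    an independent per-atom displacement of RMS magnitude ``separation``
    (a genuine conformational change, so superposition cannot remove it).
    Frames add isotropic ``jitter_sd`` noise around their blob reference.
    Blob sizes follow ``blob_weights`` (default: descending ``n_blobs, …,
    1``-proportional weights, so cluster populations are distinct); frame
    order is a seeded interleaving.  Returns ``(ConformerEnsemble,
    labels)`` with the planted blob index of each frame.
    """
    if n_frames < 1 or n_atoms < 1 or n_blobs < 1:
        raise ValueError("counts must be >= 1")
    if n_frames < n_blobs:
        raise ValueError("need at least one frame per blob")
    if separation <= 0 or jitter_sd < 0:
        raise ValueError("separation must be > 0 and jitter_sd >= 0")
    rng = np.random.default_rng(seed)
    base = rng.normal(0.0, 4.0, size=(n_atoms, 3))
    refs = [
        base
        + rng.normal(0.0, separation / np.sqrt(3.0), size=(n_atoms, 3))
        for _ in range(n_blobs)
    ]
    if blob_weights is None:
        blob_weights = np.arange(n_blobs, 0, -1, dtype=float)
    w = np.asarray(blob_weights, dtype=float)
    if w.shape != (n_blobs,) or np.any(w <= 0):
        raise ValueError("blob_weights must be n_blobs positive numbers")
    counts = np.maximum(1, np.floor(w / w.sum() * n_frames).astype(int))
    while counts.sum() > n_frames:
        counts[int(np.argmax(counts))] -= 1
    while counts.sum() < n_frames:
        counts[int(np.argmin(counts))] += 1
    labels = np.repeat(np.arange(n_blobs), counts)
    labels = labels[rng.permutation(n_frames)]
    frames = np.empty((n_frames, n_atoms, 3))
    for f, b in enumerate(labels):
        noise = (
            rng.normal(0.0, jitter_sd, size=(n_atoms, 3)) if jitter_sd > 0 else 0.0
        )
        frames[f] = refs[b] + noise
    ens = ConformerEnsemble(frames=frames, elements=["C"] * n_atoms)
    return ens, labels
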