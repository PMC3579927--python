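"""Property-matched decoy selection by decoy score.

For a set of actives, decoys are drawn from a candidate pool so that each
decoy mimics an active's physicochemical profile while remaining a distinct
structure.  The selection key is the *decoy score*

    score = ΔPK + |comboscore − 2|

where ΔPK is the summed absolute difference of the seven physicochemical
descriptors and the comboscore (in [0, 2], 2 = identical) measures 3D
shape/pharmacophore similarity.  Smaller is a better mimic on both terms.

Selection is iterative with pool removal: actives are processed in order;
for each, every remaining candidate is scored, candidates are ranked
ascending, the top ``quota`` become that active's decoys and leave the
pool.  Decoy sets across actives are therefore pairwise disjoint by
construction.  Because of the removal step the result depends on the order
in which actives are processed; the order used is recorded in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .molecules import MoleculePool, MoleculeRecord, delta_pk

logger = logging.getLogger(__name__)

__all__ = ["DecoyScoreRow", "DecoyAssignment", "decoy_score", "select_decoys"]


@dataclass(frozen=True)
class DecoyScoreRow:
    """One active/candidate scoring: ΔPK, comboscore, and their combination."""

    active_id: str
    candidate_id: str
    delta_pk: float
    combo: float
    score: float

    def __post_init__(self):
        if not 0.0 <= self.combo <= 2.0:
            raise ValueError(f"comboscore {self.combo} outside [0, 2]")
        if self.delta_pk < 0:
            raise ValueError(f"negative delta_pk {self.delta_pk}")
        if abs(self.score - (self.delta_pk + abs(self.combo - 2.0))) > 1e-9:
            raise ValueError("score != delta_pk + |combo - 2|")


@dataclass
class DecoyAssignment:
    """Per-active ordered decoy picks, plus the active processing order."""

    per_active: dict = field(default_factory=dict)  # active_id -> [DecoyScoreRow]
    active_order: list = field(default_factory=list)

    def decoy_ids(self) -> set:
        return {row.candidate_id for rows in self.per_active.values() for row in rows}

    def to_frame(self) -> pd.DataFrame:
        """Flat table: active_id, rank, candidate_id, delta_pk, combo, score."""
        rows = []
        for aid in self.active_order:
            for rank, r in enumerate(self.per_active.get(aid, []), start=1):
                rows.append(
                    {
                        "active_id": aid,
                        "rank": rank,
                        "candidate_id": r.candidate_id,
                        "delta_pk": r.delta_pk,
                        "combo": r.combo,
                        "score": r.score,
                    }
                )
        return pd.DataFrame(rows)


def decoy_score(
    active: MoleculeRecord,
    cand: MoleculeRecord,
    combo_provider,
    delta_mode: str = "raw",
    scales=None,
) -> DecoyScoreRow:
    """Score one candidate against one active; lower = better mimic."""
    if active.descriptors is None or cand.descriptors is None:
        raise ValueError("both molecules need descriptor vectors")
    dpk = delta_pk(active.descriptors, cand.descriptors, mode=delta_mode, scales=scales)
    combo = float(combo_provider(active, cand))
    if not 0.0 <= combo <= 2.0:
        raise ValueError(
            f"combo provider returned {combo} for ({active.id}, {cand.id}); "
            "must lie in [0, 2]"
        )
    return DecoyScoreRow(
        active_id=active.id,
        candidate_id=cand.id,
        delta_pk=dpk,
        combo=combo,
        score=dpk + abs(combo - 2.0),
    )


def select_decoys(
    pool: MoleculePool,
    quota: int = 20,
    combo_provider=None,
    delta_mode: str = "raw",
    scales=None,
    exhaustion_policy: str = "error",
    active_order: Optional[Sequence[str]] = None,
) -> DecoyAssignment:
    """Iterative per-active top-``quota`` selection with pool removal.

    Parameters
    ----------
    pool
        Pool whose records are labelled active / candidate; candidate ids
        must be disjoint from active ids (guaranteed by pool construction).
    quota
        Decoys per active (default 20).
    combo_provider
        Callable ``(active, candidate) -> comboscore in [0, 2]``; defaults
        to the bundled USR reference provider.
    delta_mode, scales
        Passed to :func:`vsbench.molecules.delta_pk`.
    exhaustion_policy
        ``'error'`` raises when a processed active finds fewer than
        ``quota`` remaining candidates; ``'partial'`` keeps the short list
        and warns.
    active_order
        Optional explicit processing order (sequence of active ids);
        default is pool (file) order.

    Within each active the returned rows are sorted ascending by score,
    ties broken lexicographically by candidate id.
    """
    if quota < 1:
        raise ValueError("quota must be >= 1")
    if exhaustion_policy not in ("error", "partial"):
        raise ValueError(f"unknown exhaustion_policy {exhaustion_policy!r}")
    actives = pool.actives()
    if not actives:
        raise ValueError("pool contains no actives")
    if combo_provider is None:
        from .shape import UsrComboProvider

        combo_provider = UsrComboProvider()

    by_id = {a.id: a for a in actives}
    if active_order is not None:
        missing = set(active_order) - set(by_id)
        if missing:
            raise ValueError(f"active_order names unknown actives: {sorted(missing)}")
        ordered = [by_id[aid] for aid in active_order]
    else:
        ordered = actives

    remaining = {c.id: c for c in pool.candidates()}
    assignment = DecoyAssignment()
    for active in ordered:
        scored = [
            decoy_score(active, cand, combo_provider, delta_mode, scales)
            for cand in remaining.values()
        ]
        scored.sort(key=lambda r: (r.score, r.candidate_id))
        if len(scored) < quota:
            msg = (
                f"active {active.id}: only {len(scored)} candidates remain "
                f"(quota {quota})"
            )
            if exhaustion_policy == "error":
                raise ValueError(msg)
            logger.warning(msg)
        picked = scored[:quota]
        assignment.per_active[active.id] = picked
        assignment.active_order.append(active.id)
        for row in picked:
            del remaining[row.candidate_id]
    return assignment
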