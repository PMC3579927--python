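"""Enrichment analysis and score aggregation for docking screens.

Docking output is a ligand × receptor-model score table (lower = better,
kcal/mol-like).  The functions here cover the post-docking arithmetic of an
ensemble virtual screen:

* per-ligand aggregation over a receptor ensemble (best score),
* active-recovery curves (fraction of actives retrieved vs fraction of the
  database screened) and their truncated area under the curve — the usual
  early-recognition metric is the AUC over the top 10% of the ranking,
* averaging of scores over duplicate ionization/tautomer states of the same
  parent compound,
* rank consensus of two scoring programs by mean rank (Borda).

Ranks use average positions for tied scores, so the results do not depend
on input file order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ScoreTable",
    "RecoveryCurve",
    "read_score_table",
    "aggregate_ensemble",
    "recovery_curve",
    "auc_at_fraction",
    "retrieved_at_fraction",
    "average_duplicate_scores",
    "consensus_rank",
]


@dataclass
class ScoreTable:
    """Docking scores: ligand (rows) × receptor model (columns), lower = better."""

    scores: pd.DataFrame
    labels: Optional[pd.Series] = None  # bool, True = active

    def __post_init__(self):
        if self.scores.columns.duplicated().any():
            raise ValueError("duplicate model ids")
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate ligand ids")
        if not self.scores.notna().any(axis=1).all():
            bad = self.scores.index[~self.scores.notna().any(axis=1)].tolist()
            raise ValueError(f"ligands with no finite score: {bad}")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.scores.index)
            if self.labels.isna().any():
                raise ValueError("labels missing for some ligands")
            self.labels = self.labels.astype(bool)


def read_score_table(path) -> ScoreTable:
    """Read a long-format score CSV: ligand_id,model_id,score[,label]."""
    df = pd.read_csv(path)
    need = {"ligand_id", "model_id", "score"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    wide = df.pivot(index="ligand_id", columns="model_id", values="score")
    labels = None
    if "label" in df.columns:
        lab = df.drop_duplicates("ligand_id").set_index("ligand_id")["label"]
        labels = lab.isin(["active", True, 1, "1"]).reindex(wide.index)
    return ScoreTable(scores=wide, labels=labels)


def aggregate_ensemble(
    table: ScoreTable, models: Optional[Sequence[str]] = None, method: str = "best"
) -> pd.Series:
    """Collapse a receptor ensemble to one score per ligand.

    ``method='best'`` keeps each ligand's minimum (most negative) score over
    the selected model columns; ``'mean'`` averages them.
    """
    cols = list(models) if models is not None else list(table.scores.columns)
    missing = set(cols) - set(table.scores.columns)
    if missing:
        raise KeyError(f"unknown model ids: {sorted(missing)}")
    sub = table.scores[cols]
    if not sub.notna().any(axis=1).all():
        bad = sub.index[~sub.notna().any(axis=1)].tolist()
        raise ValueError(f"ligands with no finite score in selected models: {bad}")
    if method == "best":
        return sub.min(axis=1)
    if method == "mean":
        return sub.mean(axis=1)
    raise ValueError(f"unknown aggregation method {method!r}")


@dataclass
class RecoveryCurve:
    """Points (fraction screened, fraction of actives recovered), both in [0,1]."""

    fractions: np.ndarray
    recovered: np.ndarray

    def __post_init__(self):
        f, r = np.asarray(self.fractions, float), np.asarray(self.recovered, float)
        if f.shape != r.shape or f.ndim != 1 or f.size < 2:
            raise ValueError("curve needs matched 1-d coordinate arrays")
        if np.any(np.diff(f) < -1e-12) or np.any(np.diff(r) < -1e-12):
            raise ValueError("curve coordinates must be non-decreasing")
        self.fractions, self.recovered = f, r


def _ranks(scores: pd.Series) -> np.ndarray:
    # ascending scores (best first); tied scores share the average rank
    return rankdata(scores.to_numpy(), method="average")


def recovery_curve(scores: pd.Series, labels: pd.Series) -> RecoveryCurve:
    """Fraction of actives recovered after screening each fraction of the database.

    Ligands are ranked ascending by score (best = lowest).  The curve starts
    at (0, 0) and has one point after each ligand position k: the fraction
    of actives whose (tie-averaged) rank is ≤ k.  With every active present
    it ends at (1, 1).
    """
    labels = labels.reindex(scores.index).astype(bool)
    n = len(scores)
    n_act = int(labels.sum())
    if n_act == 0:
        raise ValueError("no actives among the scored ligands")
    if n_act == n:
        raise ValueError("no decoys among the scored ligands")
    ranks = _ranks(scores)
    act_ranks = np.sort(ranks[labels.to_numpy()])
    ks = np.arange(0, n + 1)
    recovered = np.searchsorted(act_ranks, ks, side="right") / n_act
    return RecoveryCurve(fractions=ks / n, recovered=recovered)


def _trapezoid_to(curve: RecoveryCurve, x: float) -> float:
    f, r = curve.fractions, curve.recovered
    if x >= f[-1]:
        return float(np.trapezoid(r, f))
    rx = float(np.interp(x, f, r))
    keep = f < x
    fs = np.append(f[keep], x)
    rs = np.append(r[keep], rx)
    return float(np.trapezoid(rs, fs))


def _ideal_curve(n_act: int, n: int) -> RecoveryCurve:
    ks = np.arange(0, n + 1)
    return RecoveryCurve(
        fractions=ks / n, recovered=np.minimum(ks, n_act) / n_act
    )


def auc_at_fraction(
    curve: RecoveryCurve,
    x: float,
    normalize: str = "none",
    n_actives: Optional[int] = None,
) -> float:
    """Trapezoidal area under a recovery curve over [0, x].

    ``normalize='none'`` returns the raw area, which lies in [0, x];
    ``'ideal'`` divides by the area of the perfect ranking for the same
    number of actives and ligands (requires ``n_actives``), giving a value
    in [0, 1] with 1 attained exactly by the perfect ranking.
    """
    if not 0.0 < x <= 1.0:
        raise ValueError("fraction x must lie in (0, 1]")
    raw = _trapezoid_to(curve, x)
    if normalize == "none":
        return raw
    if normalize == "ideal":
        if n_actives is None:
            raise ValueError("normalize='ideal' requires n_actives")
        n = len(curve.fractions) - 1
        ideal = _trapezoid_to(_ideal_curve(n_actives, n), x)
        return raw / ideal
    raise ValueError(f"unknown normalize {normalize!r}")


def retrieved_at_fraction(scores: pd.Series, labels: pd.Series, x: float) -> int:
    """Number of actives ranked within the top ``ceil(x·N)`` ligands."""
    if not 0.0 < x <= 1.0:
        raise ValueError("fraction x must lie in (0, 1]")
    labels = labels.reindex(scores.index).astype(bool)
    k = math.ceil(x * len(scores))
    ranks = _ranks(scores)
    return int(np.sum(ranks[labels.to_numpy()] <= k))


def average_duplicate_scores(rows: pd.DataFrame) -> pd.Series:
    """Mean score per parent over duplicate states of the same compound.

    ``rows`` must have columns ``parent_id, variant_id, score`` (one row per
    ionization state / tautomer).  Returns one mean score per distinct
    parent, indexed by parent_id.
    """
    need = {"parent_id", "variant_id", "score"}
    if not need <= set(rows.columns):
        raise ValueError(f"need columns {sorted(need)}")
    if len(rows) == 0:
        raise ValueError("empty score table")
    if not np.all(np.isfinite(rows["score"].to_numpy(dtype=float))):
        raise ValueError("non-finite score")
    return rows.groupby("parent_id", sort=False)["score"].mean()


def consensus_rank(
    rank_a: pd.Series, rank_b: pd.Series, method: str = "mean_rank"
) -> pd.DataFrame:
    """Combine two rankings of the same ligand set by mean rank (Borda).

    Inputs map ligand_id -> rank position (ties within an input should
    already carry average ranks).  The consensus key is the arithmetic mean
    of the two positions; ligands are ordered by that key, final ties broken
    lexicographically by ligand id.  Returns a DataFrame indexed by
    ligand_id in consensus order with columns ``mean_rank`` and ``rank``
    (1..n).
    """
    if method != "mean_rank":
        raise ValueError(f"unknown consensus method {method!r}")
    sa, sb = set(rank_a.index), set(rank_b.index)
    if sa != sb:
        raise ValueError(
            f"mismatched ligand sets; symmetric difference: {sorted(sa ^ sb)}"
        )
    mean = (rank_a + rank_b.reindex(rank_a.index)) / 2.0
    out = mean.to_frame("mean_rank")
    out["_id"] = out.index.astype(str)
    out = out.sort_values(["mean_rank", "_id"]).drop(columns="_id")
    out["rank"] = np.arange(1, len(out) + 1)
    return out
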