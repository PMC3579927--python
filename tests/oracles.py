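"""Independent brute-force re-implementations used as test oracles.

Everything here is written as plain step-by-step loops, deliberately
avoiding the vectorised code paths of the package, so each oracle is an
independent check rather than a mirror of the implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def oracle_select_decoys(pool, quota, combo_provider):
    """Step-by-step iterative decoy selection (raw ΔPK mode)."""
    actives = [r for r in pool.records if pool.roles[r.id] == "active"]
    cands = [r for r in pool.records if pool.roles[r.id] == "candidate"]
    result = {}
    for act in actives:
        scored = []
        for c in cands:
            dpk = sum(
                abs(a - b)
                for a, b in zip(act.descriptors.as_array(), c.descriptors.as_array())
            )
            combo = float(combo_provider(act, c))
            scored.append((dpk + abs(combo - 2.0), c.id))
        scored.sort()
        take = scored[: min(quota, len(scored))]
        result[act.id] = [(cid, s) for s, cid in take]
        taken = {cid for _, cid in take}
        cands = [c for c in cands if c.id not in taken]
    return result


def oracle_gromos(m, cutoff):
    """Literal restatement of the gromos iteration with explicit loops."""
    n = len(m)
    pool = set(range(n))
    clusters = []
    while pool:
        best, best_members = None, None
        for f in sorted(pool):
            members = [g for g in sorted(pool) if m[f][g] <= cutoff]
            if best is None or len(members) > len(best_members):
                best, best_members = f, members
        clusters.append((best, best_members))
        pool -= set(best_members)
    clusters.sort(key=lambda c: (-len(c[1]), c[0]))
    return clusters


def oracle_best_aggregate(score_df):
    """Elementwise minimum per ligand, by loops."""
    out = {}
    for lig in score_df.index:
        vals = [v for v in score_df.loc[lig].tolist() if v == v]  # drop NaN
        out[lig] = min(vals)
    return out


def oracle_borda(rank_a, rank_b):
    """Mean-rank consensus order by explicit sort on (mean, id)."""
    items = []
    for lig in rank_a.index:
        items.append(((rank_a[lig] + rank_b[lig]) / 2.0, str(lig)))
    items.sort()
    return [lig for _, lig in items]


def oracle_min_rmsd(mobile, reference, restarts=20, seed=0):
    """Minimum RMSD over rotations parameterised by quaternions."""
    mob = np.asarray(mobile, float)
    ref = np.asarray(reference, float)
    mob = mob - mob.mean(axis=0)
    ref = ref - ref.mean(axis=0)

    def f(q):
        q = q / np.linalg.norm(q)
        r = Rotation.from_quat(q).as_matrix()
        return np.sqrt(np.mean(np.sum((mob @ r.T - ref) ** 2, axis=1)))

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(restarts):
        res = minimize(
            f,
            rng.normal(size=4),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 10000},
        )
        best = min(best, res.fun)
    return float(best)


def oracle_auc_fine_grid(fractions, recovered, x, n_grid=200_001):
    """Truncated area by dense-grid interpolation + trapezoid."""
    g = np.linspace(0.0, x, n_grid)
    return float(np.trapezoid(np.interp(g, fractions, recovered), g))


def oracle_pairwise_rmsd(frames):
    """Plain double-loop pairwise RMSD (no superposition)."""
    n = len(frames)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d = np.asarray(frames[i]) - np.asarray(frames[j])
            m[i, j] = np.sqrt(np.mean(np.sum(d * d, axis=1)))
    return m
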