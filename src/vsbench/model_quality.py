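"""Summary arithmetic over stereochemical-quality (Ramachandran) reports.

A PROCHECK-style report gives the percentage of assessed residues (non-Gly,
non-Pro) falling in the most-favored, additional-allowed, generously-allowed
and disallowed regions of the Ramachandran plot.  These helpers do the
bookkeeping usually quoted alongside such a report: the cumulative
percentage of residues in the non-disallowed regions, and the residue count
a region percentage corresponds to.
"""

from __future__ import annotations

from typing import Mapping, Sequence

__all__ = [
    "cumulative_percent",
    "region_residue_count",
    "ramachandran_summary",
]

REGIONS = ("most_favored", "additional_allowed", "generously_allowed", "disallowed")


def cumulative_percent(percentages: Sequence[float]) -> float:
    """Sum of region percentages (e.g. all non-disallowed regions)."""
    vals = [float(p) for p in percentages]
    if any(p < 0 for p in vals):
        raise ValueError("percentages must be non-negative")
    return sum(vals)


def region_residue_count(percent: float, n_residues: int) -> int:
    """Residue count corresponding to a region percentage, rounded to integer."""
    if not 0 <= percent <= 100:
        raise ValueError("percent must lie in [0, 100]")
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    return round(percent / 100.0 * n_residues)


def ramachandran_summary(regions: Mapping[str, float], n_residues: int) -> dict:
    """Summarise a Ramachandran region distribution.

    ``regions`` maps the four region names to percentages of assessed
    residues.  Returns the cumulative non-disallowed percentage (raw and
    rounded to the nearest integer, as conventionally quoted) and the
    disallowed residue count.
    """
    missing = set(REGIONS) - set(regions)
    if missing:
        raise ValueError(f"missing regions: {sorted(missing)}")
    allowed = cumulative_percent([regions[r] for r in REGIONS[:-1]])
    return {
        "allowed_percent": allowed,
        "allowed_percent_rounded": round(allowed),
        "disallowed_percent": float(regions["disallowed"]),
        "disallowed_residues": region_residue_count(
            regions["disallowed"], n_residues
        ),
        "n_residues": int(n_residues),
    }
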