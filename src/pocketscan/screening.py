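"""Compound-library descriptor filter and docking-score cutoff.

Descriptors are consumed from tabular input, not computed: the filter
expects molecular weight (Da), rotatable-bond count, H-bond donor and
acceptor counts, polar surface area (Å²) and a predicted octanol/water
logP, plus an optional docking score (dimensionless, lower = better).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["REQUIRED_DESCRIPTORS", "filter_library", "filter_by_score"]

REQUIRED_DESCRIPTORS = (
    "molecular_weight",
    "rotatable_bonds",
    "hbond_donors",
    "hbond_acceptors",
    "polar_surface_area",
    "logp",
)

#: (column, predicate description) in evaluation order; boundary
#: strictness follows the published criteria exactly.
_CRITERIA: dict[str, tuple] = {
    "molecular_weight": ("<", 553.0),
    "rotatable_bonds": ("<=", 14),
    "hbond_donors": ("<=", 6),
    "hbond_acceptors": (">=", 3),
    "polar_surface_area": (">=", 30.0),
    "logp": (">=", -0.5),
}

_OPS = {
    "<": lambda x, t: x < t,
    "<=": lambda x, t: x <= t,
    ">=": lambda x, t: x >= t,
}


def filter_library(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the six-descriptor library filter.

    A record passes iff MW < 553 Da, rotatable bonds ≤ 14, donors ≤ 6,
    acceptors ≥ 3, PSA ≥ 30 Å² and logP ≥ −0.5, all simultaneously.
    Records with any missing descriptor are rejected with reason
    ``"incomplete"`` and not evaluated further.

    Returns
    -------
    passing : DataFrame
        Subset of rows meeting every criterion, original order kept.
    rejections : dict
        Criterion → number of records violating it (a record failing
        several criteria is counted under each), plus ``"incomplete"``.
    """
    missing_cols = [c for c in REQUIRED_DESCRIPTORS if c not in records.columns]
    if missing_cols:
        raise ValueError(f"missing descriptor column(s): {', '.join(missing_cols)}")
    desc = records[list(REQUIRED_DESCRIPTORS)]
    incomplete = desc.isna().any(axis=1)
    rejections: dict[str, int] = {"incomplete": int(incomplete.sum())}
    ok = ~incomplete
    for col, (op, threshold) in _CRITERIA.items():
        meets = _OPS[op](desc[col], threshold) & ~incomplete
        rejections[col] = int((~meets & ~incomplete).sum())
        ok &= meets
    return records[ok], rejections


def filter_by_score(records: pd.DataFrame, threshold: float = -8.0) -> pd.DataFrame:
    """Keep compounds scoring at or below the cutoff, ranked best first.

    Retained iff ``score`` ≤ threshold (−8 "or lower" is inclusive);
    sorted ascending by score, ties broken by ``id`` for stability.
    """
    if "score" not in records.columns:
        raise ValueError("records need a 'score' column")
    kept = records[records["score"] <= threshold]
    by = ["score", "id"] if "id" in kept.columns else ["score"]
    return kept.sort_values(by=by, kind="stable").reset_index(drop=True)
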