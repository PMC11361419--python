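"""Merging the two algorithms' consensus calls and summarizing transitions.

Two merge rules are provided. The complementary decision tree: (1) when both
algorithms agree on a status, assign it; (2) when exactly one algorithm
makes a call, assign that call; (3) when the algorithms conflict — or
neither calls — the species stays DDNE. The strict consensus variant
assigns a status only when both algorithms independently make the same
call. Species already assessed (Threatened or Non-Threatened before the
analysis) never change category. Transition summaries report the count
matrix, the per-category percent change 100*(after-before)/before, and each
category's share of the total pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ensemble_status import NO_CALL
from .synthetic_world import DDNE, NON_THREATENED, THREATENED

_VALID_CALLS = {THREATENED, NON_THREATENED, NO_CALL}
STATUSES = [THREATENED, NON_THREATENED, DDNE]


class SchemaError(ValueError):
    """Raised for invalid call tokens or mismatched species universes."""


def _check(call: str) -> None:
    if call not in _VALID_CALLS:
        raise SchemaError(f"invalid call token {call!r}")


def complementary_merge(call_rf: str, call_ann: str) -> str:
    """Three-branch complementary rule (symmetric in its arguments)."""
    _check(call_rf)
    _check(call_ann)
    if call_rf == call_ann:
        return DDNE if call_rf == NO_CALL else call_rf
    if call_rf == NO_CALL:
        return call_ann
    if call_ann == NO_CALL:
        return call_rf
    return DDNE  # conflicting non-NoCall calls


def strict_merge(call_rf: str, call_ann: str) -> str:
    """Both algorithms must make the same call; anything else stays DDNE."""
    _check(call_rf)
    _check(call_ann)
    if call_rf == call_ann and call_rf != NO_CALL:
        return call_rf
    return DDNE


def merge_calls(
    status_before: pd.Series,
    votes_rf: pd.DataFrame,
    votes_ann: pd.DataFrame,
    mode: str = "complementary",
) -> pd.DataFrame:
    """Build the FinalStatus table for a species universe.

    ``status_before`` maps every species to its pre-analysis status; the
    vote tables (indexed by species id, with a ``call`` column) cover the
    DDNE species that entered the predictive framework. DDNE species absent
    from the vote tables (e.g., unpredictable, too many missing traits)
    stay DDNE. Already assessed species keep their category.
    """
    merge = {"complementary": complementary_merge, "strict": strict_merge}.get(mode)
    if merge is None:
        raise ValueError(f"unknown merge mode {mode!r}")
    rows = []
    for sid, before in status_before.items():
        call_rf = votes_rf["call"].get(sid, NO_CALL)
        call_ann = votes_ann["call"].get(sid, NO_CALL)
        if before == DDNE:
            after = merge(call_rf, call_ann)
        else:
            after = before
        rows.append(
            {
                "species_id": sid,
                "status_before": before,
                "call_rf": call_rf,
                "call_ann": call_ann,
                "status_after": after,
                "merge_mode": mode,
            }
        )
    return pd.DataFrame(rows).set_index("species_id")


@dataclass
class TransitionSummary:
    counts: pd.DataFrame  # before x after count matrix
    before_totals: pd.Series
    after_totals: pd.Series
    pct_change: pd.Series  # 100*(after-before)/before per category
    share_before: pd.Series  # 100*count/total per category
    share_after: pd.Series
    total: int

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "before": {k: int(v) for k, v in self.before_totals.items()},
            "after": {k: int(v) for k, v in self.after_totals.items()},
            "pct_change": {k: round(float(v), 1) for k, v in self.pct_change.items()},
            "share_before_pct": {k: round(float(v), 1) for k, v in self.share_before.items()},
            "share_after_pct": {k: round(float(v), 1) for k, v in self.share_after.items()},
        }


def summary_from_counts(
    before_counts: dict[str, int], after_counts: dict[str, int], total: int | None = None
) -> TransitionSummary:
    """Pure transition arithmetic from category totals.

    Percent change per category is 100*(after-before)/before; shares are
    100*count/total. Full precision is kept internally; ``to_dict`` rounds
    to one decimal for reporting.
    """
    before = pd.Series(before_counts, dtype=float).reindex(STATUSES, fill_value=0.0)
    after = pd.Series(after_counts, dtype=float).reindex(STATUSES, fill_value=0.0)
    if total is None:
        total = int(before.sum())
    pct_change = 100.0 * (after - before) / before.replace(0.0, float("nan"))
    return TransitionSummary(
        counts=pd.DataFrame(),
        before_totals=before.astype(int),
        after_totals=after.astype(int),
        pct_change=pct_change,
        share_before=100.0 * before / total,
        share_after=100.0 * after / total,
        total=total,
    )


def transition_summary(
    before: pd.Series, after: pd.Series, total_pool: int | None = None
) -> TransitionSummary:
    """Count (before, after) transitions over a shared species universe."""
    if set(before.index) != set(after.index):
        raise SchemaError("before/after tables cover different species")
    after = after.reindex(before.index)
    counts = (
        pd.crosstab(before, after)
        .reindex(index=STATUSES, columns=STATUSES, fill_value=0)
        .rename_axis(index="before", columns="after")
    )
    summary = summary_from_counts(
        counts.sum(axis=1).to_dict(), counts.sum(axis=0).to_dict(),
        total=total_pool if total_pool is not None else len(before),
    )
    summary.counts = counts
    return summary
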