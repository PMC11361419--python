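"""Protected-area coverage, log-linear conservation targets, and achievement.

Each species' coverage is the percent of its range cells falling inside the
protected-area mask. Its conservation target depends on range size:
species with ranges below a small-range anchor (10,000 km² by default) need
100% of their range protected, species above a large-range anchor
(390,000 km²) need only 10%, and in between the target declines linearly in
log10 range size along the line through the two anchor points. Target
achievement is coverage divided by target (as a percent of the requirement
realized), capped at 100% with the uncapped value retained for audit.
Group comparisons use the standard rank tests (Kruskal–Wallis across three
or more status groups, two-sided rank-sum for pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .range_builder import GridAlignmentError, RangeRaster


class DomainError(ValueError):
    pass


@dataclass(frozen=True)
class TargetRule:
    """Species-specific target rule: linear in log10 range between anchors.

    target(r_full_km2) = t_full_pct and target(r_min_km2) = t_min_pct
    exactly; below/above the anchors the target is clamped.
    """

    r_full_km2: float = 10_000.0
    r_min_km2: float = 390_000.0
    t_full_pct: float = 100.0
    t_min_pct: float = 10.0

    def __post_init__(self) -> None:
        if not self.r_full_km2 < self.r_min_km2:
            raise DomainError("r_full_km2 must be below r_min_km2")
        if not self.t_full_pct > self.t_min_pct:
            raise DomainError("t_full_pct must exceed t_min_pct")

    @property
    def slope(self) -> float:
        return (self.t_min_pct - self.t_full_pct) / (
            math.log10(self.r_min_km2) - math.log10(self.r_full_km2)
        )

    @property
    def intercept(self) -> float:
        return self.t_full_pct - self.slope * math.log10(self.r_full_km2)


def conservation_target(range_km2, rule: TargetRule | None = None):
    """Percent of a species' range that should be protected, given its size."""
    if rule is None:
        rule = TargetRule()
    r = np.asarray(range_km2, dtype=float)
    if np.any(r <= 0):
        raise DomainError("range size must be positive")
    target = rule.intercept + rule.slope * np.log10(r)
    target = np.clip(target, rule.t_min_pct, rule.t_full_pct)
    target = np.where(r <= rule.r_full_km2, rule.t_full_pct, target)
    target = np.where(r >= rule.r_min_km2, rule.t_min_pct, target)
    return float(target) if np.isscalar(range_km2) else target


def mpa_coverage(range_raster: RangeRaster, pa_mask: np.ndarray) -> float:
    """Percent of the species' range cells inside the protected-area mask."""
    grid = range_raster.grid
    mask = np.asarray(pa_mask, dtype=bool)
    if mask.shape != (grid.rows, grid.cols):
        raise GridAlignmentError(
            f"PA mask shape {mask.shape} does not match grid ({grid.rows}, {grid.cols})"
        )
    if range_raster.n_cells == 0:
        raise DomainError(f"species {range_raster.species_id!r} has an empty range")
    flat = mask.ravel()
    return 100.0 * float(flat[range_raster.cells].sum()) / range_raster.n_cells


def achievement(coverage_pct: float, target_pct: float, cap: bool = True) -> tuple[float, float]:
    """Percent of the conservation target realized.

    Returns ``(achievement, uncapped)``: 100*coverage/target, capped at 100
    when ``cap`` with the raw value kept alongside for audit.
    """
    if target_pct <= 0:
        raise DomainError("target must be positive")
    raw = 100.0 * coverage_pct / target_pct
    return (min(raw, 100.0) if cap else raw), raw


def filter_pa_categories(categories: pd.Series, allowed=("Ia", "Ib", "II", "III", "IV")) -> pd.Series:
    """Boolean pre-filter for attribute-tagged protected areas: keep only the
    strict IUCN management classes (Ia–IV by default)."""
    return categories.isin(set(allowed))


def protection_table(
    ranges: dict[str, RangeRaster],
    pa_mask: np.ndarray,
    rule: TargetRule | None = None,
    cap: bool = True,
) -> pd.DataFrame:
    """ProtectionRecord frame: coverage, target and achievement per species.

    Species with empty ranges are skipped (coverage undefined).
    """
    if rule is None:
        rule = TargetRule()
    rows = []
    for sid in sorted(ranges):
        rr = ranges[sid]
        if rr.n_cells == 0:
            continue
        cov = mpa_coverage(rr, pa_mask)
        tgt = conservation_target(rr.area_km2, rule)
        ach, raw = achievement(cov, tgt, cap=cap)
        rows.append(
            {
                "species_id": sid,
                "range_km2": rr.area_km2,
                "coverage_pct": cov,
                "target_pct": tgt,
                "achievement_pct": ach,
                "achievement_uncapped_pct": raw,
            }
        )
    return pd.DataFrame(rows).set_index("species_id")


def compare_protection_groups(groups: dict[str, np.ndarray]) -> dict:
    """Rank tests across status groups of a protection metric.

    With three or more groups, a Kruskal–Wallis test; every pair also gets a
    two-sided Mann–Whitney rank-sum test. All groups must be nonempty.
    """
    clean = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(clean) < 2:
        raise DomainError("need at least two groups")
    for name, v in clean.items():
        if v.size == 0:
            raise DomainError(f"group {name!r} is empty")
    out: dict = {"pairwise": {}}
    if len(clean) >= 3:
        stat, p = stats.kruskal(*clean.values())
        out["kruskal"] = {"statistic": float(stat), "df": len(clean) - 1, "p_value": float(p)}
    names = sorted(clean)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = stats.mannwhitneyu(clean[a], clean[b], alternative="two-sided")
            out["pairwise"][f"{a}|{b}"] = {
                "U": float(res.statistic),
                "p_value": float(res.pvalue),
            }
    return out
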