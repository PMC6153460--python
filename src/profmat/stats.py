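"""Profiling-matrix characterisation.

Summarises a ternary matrix the way screening papers report them: matrix
dimensions, density, the fraction of cells with activity annotations,
per-assay hit rates, and a three-way classification of compounds into
consistently inactive (tested, never active), single-target (exactly one
active call) and multi-target (two or more active calls).  In dense but
incomplete matrices a compound can, in principle, have no tested cell at
all; such compounds form a fourth explicit class so that the four counts
always partition the compound set.

Percentages are rounded half-up to one decimal, matching the convention of
printed screening reports (banker's rounding would differ at exact .x5
boundaries).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .core import (
    Axis,
    LineStats,
    TernaryMatrix,
    _require_nondegenerate,
    active_counts,
    line_stats,
    matrix_density,
    tested_counts,
)

__all__ = [
    "CompoundClass",
    "MatrixProfile",
    "percent",
    "classify_compound",
    "compound_class_counts",
    "profile_matrix",
]


class CompoundClass(enum.Enum):
    CONSISTENTLY_INACTIVE = "consistently_inactive"
    SINGLE_TARGET = "single_target"
    MULTI_TARGET = "multi_target"
    ALL_UNTESTED = "all_untested"


def percent(count: int, total: int, decimals: int = 1) -> float:
    """100 * count / total, rounded half-up to ``decimals`` places.

    Exact decimal arithmetic on the integer counts, so printed-report
    boundary cases (e.g. 41/400 -> 10.3, not 10.2) come out right.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, ROUND_HALF_UP))


@dataclass(frozen=True)
class MatrixProfile:
    """Summary statistics of a profiling matrix."""

    n_compounds: int
    n_assays: int
    density: float
    active_cell_fraction: float
    n_consistently_inactive: int
    n_single_target: int
    n_multi_target: int
    n_all_untested: int
    pct_consistently_inactive: float
    pct_single_target: float
    pct_multi_target: float
    assay_hit_rates: tuple[float, ...]
    n_assays_hit_rate_below_1pct: int
    n_assays_zero_hits: int

    def to_dict(self, include_hit_rates: bool = False) -> dict:
        """Flat key-value report (JSON-friendly)."""
        d = {
            "n_compounds": self.n_compounds,
            "n_assays": self.n_assays,
            "density": self.density,
            "active_cell_fraction": self.active_cell_fraction,
            "n_consistently_inactive": self.n_consistently_inactive,
            "n_single_target": self.n_single_target,
            "n_multi_target": self.n_multi_target,
            "n_all_untested": self.n_all_untested,
            "pct_consistently_inactive": self.pct_consistently_inactive,
            "pct_single_target": self.pct_single_target,
            "pct_multi_target": self.pct_multi_target,
            "n_assays_hit_rate_below_1pct": self.n_assays_hit_rate_below_1pct,
            "n_assays_zero_hits": self.n_assays_zero_hits,
        }
        if include_hit_rates:
            d["assay_hit_rates"] = list(self.assay_hit_rates)
        return d


def classify_compound(m: TernaryMatrix, compound_id: str) -> CompoundClass:
    """Activity class of one compound, from its tested cells only."""
    i = m.compound_index(compound_id)
    n_tested = int(tested_counts(m, Axis.COMPOUND)[i])
    n_active = int(active_counts(m, Axis.COMPOUND)[i])
    return _classify(n_tested, n_active)


def _classify(n_tested: int, n_active: int) -> CompoundClass:
    if n_tested == 0:
        return CompoundClass.ALL_UNTESTED
    if n_active == 0:
        return CompoundClass.CONSISTENTLY_INACTIVE
    if n_active == 1:
        return CompoundClass.SINGLE_TARGET
    return CompoundClass.MULTI_TARGET


def compound_class_counts(m: TernaryMatrix) -> dict[CompoundClass, int]:
    """Counts of the four compound classes (vectorised over rows)."""
    _require_nondegenerate(m)
    tested = tested_counts(m, Axis.COMPOUND)
    active = active_counts(m, Axis.COMPOUND)
    untested = tested == 0
    return {
        CompoundClass.ALL_UNTESTED: int(untested.sum()),
        CompoundClass.CONSISTENTLY_INACTIVE: int((~untested & (active == 0)).sum()),
        CompoundClass.SINGLE_TARGET: int((active == 1).sum()),
        CompoundClass.MULTI_TARGET: int((active >= 2).sum()),
    }


def profile_matrix(m: TernaryMatrix) -> MatrixProfile:
    """Full characterisation of a (non-degenerate) profiling matrix."""
    _require_nondegenerate(m)
    counts = compound_class_counts(m)
    hit_stats = line_stats(m, Axis.ASSAY)
    hit_rates = tuple(ls.hit_rate for ls in hit_stats)
    return MatrixProfile(
        n_compounds=m.n_compounds,
        n_assays=m.n_assays,
        density=matrix_density(m),
        active_cell_fraction=m.n_active / (m.n_compounds * m.n_assays),
        n_consistently_inactive=counts[CompoundClass.CONSISTENTLY_INACTIVE],
        n_single_target=counts[CompoundClass.SINGLE_TARGET],
        n_multi_target=counts[CompoundClass.MULTI_TARGET],
        n_all_untested=counts[CompoundClass.ALL_UNTESTED],
        pct_consistently_inactive=percent(
            counts[CompoundClass.CONSISTENTLY_INACTIVE], m.n_compounds
        ),
        pct_single_target=percent(counts[CompoundClass.SINGLE_TARGET], m.n_compounds),
        pct_multi_target=percent(counts[CompoundClass.MULTI_TARGET], m.n_compounds),
        assay_hit_rates=hit_rates,
        n_assays_hit_rate_below_1pct=sum(1 for r in hit_rates if r < 0.01),
        n_assays_zero_hits=sum(1 for ls in hit_stats if ls.n_active == 0),
    )


def assay_hit_rate_table(m: TernaryMatrix) -> list[LineStats]:
    """Per-assay (assay_id, n_tested, n_active, hit_rate) rows."""
    return line_stats(m, Axis.ASSAY)
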