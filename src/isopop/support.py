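"""The CI-overlap rule for deciding which simulated scenarios are supported.

A simulated parameter set "explains" the empirical population when at least
two of the eight comparison statistics overlap AND those overlaps span at
least two of the four categories (diversity: Na, Ho, He; differentiation:
FST, Jost's D; inbreeding: FIS Nei/Weir; relatedness: r).  Overlap means the
two 95% CIs intersect when the empirical side has a CI, and otherwise that
the empirical point estimate falls inside the simulated CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .forward_sim import SimulationResult
from .sumstats import CATEGORY_OF_STATISTIC


@dataclass(frozen=True)
class EmpiricalIndex:
    """An empirical statistic, with a CI when the original analysis had one."""

    value: float
    ci: tuple[float, float] | None = None


@dataclass
class SupportDecision:
    overlaps: dict[str, bool]
    categories_hit: set[str]
    supported: bool
    missing: list[str] = field(default_factory=list)


def _intervals_overlap(a: tuple[float, float], b: tuple[float, float]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def evaluate_overlaps(
    sim_ci: dict[str, tuple[float, float]],
    empirical: dict[str, EmpiricalIndex],
) -> tuple[dict[str, bool], list[str]]:
    """Per-statistic overlap flags; statistics absent on either side are
    excluded and reported."""
    overlaps: dict[str, bool] = {}
    missing: list[str] = []
    for name in CATEGORY_OF_STATISTIC:
        if name not in sim_ci or name not in empirical:
            missing.append(name)
            continue
        emp = empirical[name]
        lo, hi = sim_ci[name]
        if emp.ci is not None:
            overlaps[name] = _intervals_overlap((lo, hi), emp.ci)
        else:
            overlaps[name] = lo <= emp.value <= hi
    return overlaps, missing


def decide(overlaps: dict[str, bool]) -> tuple[bool, set[str]]:
    """Apply the rule: >= 2 overlapping statistics spanning >= 2 categories."""
    hit = [name for name, ok in overlaps.items() if ok]
    categories = {CATEGORY_OF_STATISTIC[name] for name in hit}
    return len(hit) >= 2 and len(categories) >= 2, categories


def evaluate_support(
    sim: SimulationResult | dict[str, tuple[float, float]],
    empirical: dict[str, EmpiricalIndex],
) -> SupportDecision:
    """Decide whether one simulated parameter set explains the empirical data."""
    sim_ci = sim.ci if isinstance(sim, SimulationResult) else sim
    overlaps, missing = evaluate_overlaps(sim_ci, empirical)
    supported, categories = decide(overlaps)
    return SupportDecision(
        overlaps=overlaps,
        categories_hit=categories,
        supported=supported,
        missing=missing,
    )


#: Empirical indices of the focal (peninsula) population as printed in the
#: original comparison table: differentiation carries bootstrap CIs, the
#: other indices are point values.
BP_EMPIRICAL: dict[str, EmpiricalIndex] = {
    "Na": EmpiricalIndex(4.28),
    "Ho": EmpiricalIndex(0.55),
    "He": EmpiricalIndex(0.55),
    "Fst": EmpiricalIndex(0.122, (0.114, 0.129)),
    "JostD": EmpiricalIndex(0.282, (0.266, 0.297)),
    "Fis_nei": EmpiricalIndex(0.022),
    "Fis_weir": EmpiricalIndex(0.017),
    "r": EmpiricalIndex(0.44),
}
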