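"""Screening stage-shift (interception) simulator.

Cancers are assumed to progress through stages I -> II -> III -> IV.  A
screening test has a cumulative sensitivity per stage; its marginal
sensitivity at a stage is the difference from the previous stage's
cumulative value.  Individuals detectable at a stage comprise those newly
detectable there plus those who slipped undetected from the previous stage:

    detectable_s = original_s * marginal_s + slipped_{s-1}

If screening occurs at the stage they are intercepted (diagnosed there);
otherwise they slip onward.  The printed recurrence leaves the fate of the
original_s * (1 - marginal_s) remainder unstated, so two variants ship:

* ``literal`` — applies the recurrence exactly as written (default).
* ``conserving`` — mass-conserving reformulation: everyone arriving at a
  stage (original plus slipped) is screened with the marginal sensitivity,
  interceptees leave the flow, the remainder slips; undetected stage-IV
  residue is diagnosed at IV.  Total individuals are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

STAGES = ("I", "II", "III", "IV")


@dataclass
class StageCohort:
    original: dict[str, float]
    cumulative_sensitivity: dict[str, float]
    screened: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    marginal_sensitivity: dict[str, float] = field(default_factory=dict)
    detectable: dict[str, float] = field(default_factory=dict)
    intercepted: dict[str, float] = field(default_factory=dict)
    slipped: dict[str, float] = field(default_factory=dict)
    final_distribution: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cum = [self.cumulative_sensitivity[s] for s in STAGES]
        if any(c < 0 or c > 1 for c in cum):
            raise ValueError("cumulative sensitivities must lie in [0, 1]")
        if any(b < a - 1e-12 for a, b in zip(cum, cum[1:])):
            raise ValueError("cumulative sensitivities must be non-decreasing")
        if any(self.original[s] < 0 for s in STAGES):
            raise ValueError("negative stage count")
        marg = {}
        prev = 0.0
        for s in STAGES:
            marg[s] = self.cumulative_sensitivity[s] - prev
            prev = self.cumulative_sensitivity[s]
        if self.marginal_sensitivity:
            for s in STAGES:
                if abs(self.marginal_sensitivity[s] - marg[s]) > 1e-9:
                    raise ValueError(
                        f"marginal sensitivity at stage {s} inconsistent "
                        "with cumulative values"
                    )
        self.marginal_sensitivity = marg


def run_interception(cohort: StageCohort, variant: str = "literal") -> StageCohort:
    """Fill detectable/intercepted/slipped and the final stage distribution.

    literal: detectable_s = original_s * marginal_s + slipped_{s-1}; a
    screened stage intercepts its whole detectable pool, an unscreened stage
    lets it slip onward.  Individuals never entering the detectable pool are
    diagnosed at their original stage, so zero sensitivity reproduces the
    original distribution exactly.

    conserving: everyone arriving at a stage (original plus slipped) is
    screened with the marginal sensitivity; non-interceptees slip, and the
    stage-IV residue is diagnosed at IV.  Total mass is conserved exactly.
    """
    if variant not in ("literal", "conserving"):
        raise ValueError(f"unknown variant {variant!r}")
    slipped_prev = 0.0
    final = {s: 0.0 for s in STAGES}
    for s in STAGES:
        m = cohort.marginal_sensitivity[s]
        if variant == "literal":
            detectable = cohort.original[s] * m + slipped_prev
            # never-detectable remainder is diagnosed at its natural stage
            final[s] += cohort.original[s] * (1.0 - m)
            not_intercepted = detectable
        else:
            arriving = cohort.original[s] + slipped_prev
            detectable = arriving * m
            not_intercepted = arriving
        cohort.detectable[s] = detectable
        if cohort.screened[s]:
            cohort.intercepted[s] = detectable
            final[s] += detectable
            slipped_prev = not_intercepted - detectable
        else:
            cohort.intercepted[s] = 0.0
            slipped_prev = not_intercepted
        cohort.slipped[s] = slipped_prev
    final["IV"] += slipped_prev  # residue past stage IV is diagnosed at IV
    cohort.slipped["IV"] = 0.0
    cohort.final_distribution = final
    return cohort


@dataclass
class SurvivalTable:
    five_year_survival: dict[str, float]

    def __post_init__(self) -> None:
        for s, v in self.five_year_survival.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"survival at {s} outside [0, 1]")


def survival_gain(
    final_distribution: dict[str, float] | Sequence[float],
    table: SurvivalTable,
) -> float:
    """Count-weighted mean 5-year survival of a stage distribution."""
    if not isinstance(final_distribution, dict):
        final_distribution = dict(zip(STAGES, final_distribution))
    counts = np.array([final_distribution.get(s, 0.0) for s in STAGES])
    if (counts < 0).any():
        raise ValueError("negative count in distribution")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty stage distribution")
    surv = np.array([table.five_year_survival[s] for s in STAGES])
    return float((counts * surv).sum() / total)
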