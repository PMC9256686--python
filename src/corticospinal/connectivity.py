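"""Effective and functional connectivity between M1 and the spinal hemicord.

Effective connectivity is the slope of a within-participant least-squares
regression of spinal hemicord activity on M1 activity (an input–output
estimate); functional connectivity is the Pearson correlation of the same
two series.  Both are computed per participant on the 11-point condition
mean series, for the task window of each hand and the matched preceding
rest windows, and compared task-vs-rest across participants with the
two-tailed Wilcoxon signed-rank test.

"Contralateral"/"ipsilateral" are resolved relative to the moving hand at
call time; stored labels stay anatomical (L/R).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .design import BlockDesign, HANDS, contra_m1, ipsi_m1, ipsi_shc
from .prep import condition_series
from .stats import (
    StatResult,
    pearson_correlation,
    simple_regression,
    wilcoxon_signed_rank,
)


@dataclass(frozen=True)
class ConnectivityEstimate:
    """Slope (effective), r (functional) and R² for one directed pair."""

    participant_id: str
    source: str
    target: str
    condition: str
    slope: float
    intercept: float
    r: float
    r2: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


def effective_connectivity(
    m1: np.ndarray,
    shc: np.ndarray,
    participant_id: str = "",
    source: str = "",
    target: str = "",
    condition: str = "",
) -> ConnectivityEstimate:
    """Least-squares fit of SHc ~ M1 (M1 is the explanatory variable)."""
    slope, intercept, r, r2 = simple_regression(m1, shc)
    return ConnectivityEstimate(
        participant_id=participant_id,
        source=source,
        target=target,
        condition=condition,
        slope=slope,
        intercept=intercept,
        r=r,
        r2=r2,
    )


def participant_connectivity(
    ts,
    design: BlockDesign,
    order: str = "average-then-zscore",
    segment: str = "C7Th1",
) -> pd.DataFrame:
    """M1→ipsilateral-SHc estimates for both hemispheres, task and rest.

    For each hand, the contralateral and ipsilateral M1 are regressed onto
    the spinal hemicord on the side of the moving hand, over the task window
    and the matched rest window.
    """
    series = condition_series(ts, design, order=order)
    rows = []
    for hand in HANDS:
        target = ipsi_shc(hand, segment)
        for source in (contra_m1(hand), ipsi_m1(hand)):
            for kind in ("task", "rest"):
                cond = f"{kind}-{hand}"
                est = effective_connectivity(
                    series[(source, cond)],
                    series[(target, cond)],
                    participant_id=ts.participant_id,
                    source=source,
                    target=target,
                    condition=cond,
                )
                rows.append(est.__dict__)
    return pd.DataFrame(rows)


def cohort_connectivity(
    cohort: CohortDataset,
    order: str = "average-then-zscore",
    segment: str = "C7Th1",
) -> pd.DataFrame:
    """Connectivity table for every participant (long format)."""
    return pd.concat(
        [
            participant_connectivity(p, cohort.design, order=order, segment=segment)
            for p in cohort.participants
        ],
        ignore_index=True,
    )


def pairwise_connectivity(
    ts,
    design: BlockDesign,
    pairs: list[tuple[str, str]],
    order: str = "average-then-zscore",
) -> pd.DataFrame:
    """Generic source→target estimates for arbitrary region pairs.

    Covers ancillary contrasts such as interhemispheric M1–M1 connectivity
    without any dedicated machinery.
    """
    series = condition_series(ts, design, order=order)
    rows = []
    for source, target in pairs:
        for hand in HANDS:
            for kind in ("task", "rest"):
                cond = f"{kind}-{hand}"
                est = effective_connectivity(
                    series[(source, cond)],
                    series[(target, cond)],
                    participant_id=ts.participant_id,
                    source=source,
                    target=target,
                    condition=cond,
                )
                rows.append(est.__dict__)
    return pd.DataFrame(rows)


def _hand_pair_estimates(
    estimates: pd.DataFrame, hand: str, source_role: str, segment: str = "C7Th1"
) -> pd.DataFrame:
    source = {"contra": contra_m1, "ipsi": ipsi_m1}[source_role](hand)
    target = ipsi_shc(hand, segment)
    return estimates[(estimates.source == source) & (estimates.target == target)]


def compare_task_rest(
    estimates: pd.DataFrame,
    hand: str,
    source_role: str = "contra",
    measure: str = "slope",
    segment: str = "C7Th1",
) -> StatResult:
    """Wilcoxon signed-rank on within-participant task − rest differences.

    ``measure`` selects effective (``slope``) or functional (``r``)
    connectivity; raw r is compared (no Fisher transform) since the test is
    rank-based.
    """
    if measure not in ("slope", "r"):
        raise ValueError("measure must be 'slope' or 'r'")
    sub = _hand_pair_estimates(estimates, hand, source_role, segment)
    task = sub[sub.condition == f"task-{hand}"].set_index("participant_id")[measure]
    rest = sub[sub.condition == f"rest-{hand}"].set_index("participant_id")[measure]
    common = task.index.intersection(rest.index)
    if len(common) < 3:
        raise ValueError("need paired task and rest estimates for >= 3 participants")
    diffs = (task.loc[common] - rest.loc[common]).to_numpy()
    return wilcoxon_signed_rank(diffs)


def ec_activity_dependency(
    betas: pd.DataFrame,
    estimates: pd.DataFrame,
    hand: str,
    segment: str = "C7Th1",
) -> StatResult:
    """Correlation of contralateral M1 activity with ipsilateral-M1→SHc EC.

    Across participants: Pearson r between the contralateral M1 task beta and
    the ipsilateral M1 → ipsilateral SHc task slope for one hand.
    """
    beta_c = (
        betas[(betas.region == contra_m1(hand)) & (betas.hand == hand)]
        .set_index("participant_id")["beta"]
    )
    sub = _hand_pair_estimates(estimates, hand, "ipsi", segment)
    slope_i = sub[sub.condition == f"task-{hand}"].set_index("participant_id")["slope"]
    common = beta_c.index.intersection(slope_i.index)
    if len(common) < 3:
        raise ValueError("need >= 3 participants with both beta and slope")
    return pearson_correlation(beta_c.loc[common].to_numpy(),
                               slope_i.loc[common].to_numpy())
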