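"""Derived per-participant series: GLM activity estimates, block-mean
condition series and z-scored series.

Three products feed the downstream analyses:

* region-level GLM betas (one per region × hand), from an ordinary
  least-squares fit of each region's series on HRF-convolved hand boxcars
  plus nuisance regressors (motion confounds, a discrete-cosine drift basis
  with a 128 s cutoff, and an intercept), after discarding the initial
  volumes (default 8, the T1-equilibration period);
* 11-point condition mean series — each task (or matched preceding rest)
  block window averaged across the four blocks of a hand, aligned by
  within-block index;
* z-scored series (mean 0, sample SD 1), because signal variance differs
  between cortex and cord.

Ordering of averaging and z-scoring is configurable: the default averages
the raw blocks first and then z-scores each region using the pooled
mean/SD of its four condition series, so that task-window regression slopes
and correlations remain distinct quantities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortDataset, ParticipantTimeSeries
from .design import BlockDesign, HANDS
from .hemodynamics import convolve_hrf
from .stats import DegenerateDataError

CONDITIONS = tuple(f"{kind}-{hand}" for hand in HANDS for kind in ("task", "rest"))


def zscore_region(series: np.ndarray, ddof: int = 1) -> np.ndarray:
    """Transform a series to mean 0, sample SD 1; errors on zero variance."""
    x = np.asarray(series, dtype=float)
    sd = x.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateDataError("cannot z-score a zero-variance series")
    return (x - x.mean()) / sd


def dct_basis(n_trs: int, tr_seconds: float, cutoff_seconds: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass drift basis (constant term excluded).

    Columns are cos(π·k·(2t+1)/(2n)) for k = 1..K with K chosen so the
    slowest retained drift has period ≥ ``cutoff_seconds``.
    """
    if cutoff_seconds <= 0:
        return np.empty((n_trs, 0))
    k_max = int(np.floor(2.0 * n_trs * tr_seconds / cutoff_seconds))
    t = np.arange(n_trs)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_trs)) for k in range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_trs, 0))


def glm_design_matrix(
    design: BlockDesign,
    confounds: np.ndarray | None = None,
    highpass: float | None = 128.0,
) -> tuple[np.ndarray, list[str]]:
    """Full-run design matrix: [HRF⊛RHM, HRF⊛LHM, confounds, drift, const]."""
    n = design.n_trs
    cols = [convolve_hrf(design.boxcar(h), design.tr_seconds) for h in HANDS]
    names = list(HANDS)
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n:
            confounds = confounds.T
        if confounds.shape[0] != n:
            raise ValueError("confounds length does not match the design")
        for j in range(confounds.shape[1]):
            cols.append(confounds[:, j])
            names.append(f"confound_{j}")
    if highpass:
        drift = dct_basis(n, design.tr_seconds, highpass)
        for j in range(drift.shape[1]):
            cols.append(drift[:, j])
            names.append(f"drift_{j + 1}")
    cols.append(np.ones(n))
    names.append("const")
    return np.column_stack(cols), names


def fit_glm(
    ts: ParticipantTimeSeries,
    design: BlockDesign,
    confounds: np.ndarray | None = None,
    highpass: float | None = 128.0,
    drop_initial: int = 8,
) -> pd.DataFrame:
    """Region-level GLM: returns the two task betas per region.

    Regressors are built over the full design and then the first
    ``drop_initial`` volumes are cropped from both sides of the equation.
    """
    if ts.n_trs != design.n_trs:
        raise ValueError("series length does not match the design")
    X, names = glm_design_matrix(design, confounds=confounds, highpass=highpass)
    Xc = X[drop_initial:]
    Y = ts.values[:, drop_initial:].T
    if Xc.shape[0] <= Xc.shape[1]:
        raise ValueError("series too short for the design matrix after cropping")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient GLM design matrix")
    coef, _, _, _ = np.linalg.lstsq(Xc, Y, rcond=None)
    rows = []
    for hand in HANDS:
        j = names.index(hand)
        for r_idx, region in enumerate(ts.regions):
            rows.append(
                {
                    "participant_id": ts.participant_id,
                    "region": region,
                    "hand": hand,
                    "beta": float(coef[j, r_idx]),
                }
            )
    return pd.DataFrame(rows)


def cohort_betas(
    cohort: CohortDataset,
    use_confounds: bool = True,
    highpass: float | None = 128.0,
    drop_initial: int = 8,
) -> pd.DataFrame:
    """GLM beta table for every participant (long format)."""
    frames = [
        fit_glm(
            p,
            cohort.design,
            confounds=p.confounds if use_confounds else None,
            highpass=highpass,
            drop_initial=drop_initial,
        )
        for p in cohort.participants
    ]
    return pd.concat(frames, ignore_index=True)


def _windows(design: BlockDesign, condition: str) -> list[tuple[int, int]]:
    kind, _, hand = condition.partition("-")
    if hand not in HANDS:
        raise ValueError(f"unknown condition {condition!r}")
    if kind == "task":
        return design.task_blocks(hand)
    if kind == "rest":
        return design.rest_blocks_before(hand)
    raise ValueError(f"unknown condition {condition!r}")


def block_mean_series(
    series: np.ndarray, design: BlockDesign, condition: str
) -> np.ndarray:
    """Average the block windows of one condition, aligned by within-block index.

    ``condition`` is ``task-RHM``, ``rest-RHM``, ``task-LHM`` or ``rest-LHM``;
    rest windows are the rest blocks immediately preceding each task block of
    that hand.  With the default design the output has 11 points averaged
    across 4 blocks.
    """
    x = np.asarray(series, dtype=float)
    if x.size < design.n_trs:
        raise ValueError("series shorter than the design")
    windows = _windows(design, condition)
    width = min(n for _, n in windows)
    stack = np.stack([x[s : s + width] for s, _ in windows])
    return stack.mean(axis=0)


def condition_series(
    ts: ParticipantTimeSeries,
    design: BlockDesign,
    order: str = "average-then-zscore",
    regions: tuple[str, ...] | None = None,
) -> dict[tuple[str, str], np.ndarray]:
    """All four condition mean series for every region, z-scored per region.

    ``order="average-then-zscore"`` (default): block-average the raw series,
    then z-score each region with the pooled mean/SD of its four condition
    series.  ``order="zscore-then-average"``: z-score the full run first and
    average the z-scored blocks without further scaling.  Either way a region
    is standardised once, so windows cut from it keep distinct slope and
    correlation values.
    """
    regions = regions or ts.regions
    out: dict[tuple[str, str], np.ndarray] = {}
    if order == "zscore-then-average":
        for region in regions:
            z = zscore_region(ts.series(region))
            for cond in CONDITIONS:
                out[(region, cond)] = block_mean_series(z, design, cond)
    elif order == "average-then-zscore":
        for region in regions:
            raw = {
                cond: block_mean_series(ts.series(region), design, cond)
                for cond in CONDITIONS
            }
            pooled = np.concatenate(list(raw.values()))
            mu, sd = pooled.mean(), pooled.std(ddof=1)
            if sd == 0:
                raise DegenerateDataError(
                    f"region {region} has zero variance across conditions"
                )
            for cond, v in raw.items():
                out[(region, cond)] = (v - mu) / sd
    else:
        raise ValueError(f"unknown order {order!r}")
    return out


def mean_series_table(
    cohort: CohortDataset, order: str = "average-then-zscore"
) -> pd.DataFrame:
    """Long-format condition mean-series table for the whole cohort."""
    rows = []
    for p in cohort.participants:
        series = condition_series(p, cohort.design, order=order)
        for (region, cond), v in series.items():
            for t_idx, value in enumerate(v):
                rows.append(
                    {
                        "participant_id": p.participant_id,
                        "region": region,
                        "condition": cond,
                        "t_index": t_idx,
                        "value": float(value),
                    }
                )
    return pd.DataFrame(rows)
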