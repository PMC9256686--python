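"""Per-participant sign-constrained weights for the three-network model.

For each participant and hand, ipsilateral spinal hemicord activity is
modelled as a weighted sum of three network regressors — the two direct
corticospinal networks (contralateral and ipsilateral M1) and the indirect
network integrating both M1s — and the weights are found by bounded least
squares with the biologically motivated sign constraints:

    w_direct_contra ≥ 0,   w_direct_ipsi ≥ 0,   w_indirect ≤ 0,

an unconstrained intercept, and minimisation of the residual sum of
squares.  The problem is convex, so the bounded solver returns the global
optimum; weights pinned at a bound are reported as exactly 0 with a flag.

Two regressor bases are available:

* ``build_individual_regressors`` — the 11-point z-scored task mean series,
  with each column scaled by the participant's effective-connectivity
  slopes (direct-contra: slope_c·M1c(t); direct-ipsi: slope_i·M1i(t);
  indirect: slope_c·slope_i·mod(t), mod defaulting to the elementwise
  product of the two M1 series);
* ``fit_run_level_weights`` — full-run regressors rebuilt from GLM betas and
  the clean task drives, which puts the recovered weights on the
  generator's scale and is the basis for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .cohort import CohortDataset, ParticipantTimeSeries
from .design import BlockDesign, HANDS, contra_m1, ipsi_m1, ipsi_shc
from .hemodynamics import convolve_hrf
from .prep import condition_series, fit_glm
from .stats import StatResult, holm_bonferroni, pearson_correlation

WEIGHT_TERMS = ("w_direct_contra", "w_direct_ipsi", "w_indirect")

MODULATORS = {
    "product": lambda c, i: c * i,
    "contra": lambda c, i: c,
    "ipsi": lambda c, i: i,
    "sum": lambda c, i: c + i,
}


@dataclass
class IndividualWeights:
    """Constrained weight estimates for one participant × hand."""

    participant_id: str
    hand: str
    w_direct_contra: float
    w_direct_ipsi: float
    w_indirect: float
    intercept: float
    rss: float
    converged: bool
    bound_active: tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        if self.w_direct_contra < 0 or self.w_direct_ipsi < 0:
            raise ValueError("direct weights must satisfy w >= 0")
        if self.w_indirect > 0:
            raise ValueError("indirect weight must satisfy w <= 0")
        if self.rss < 0:
            raise ValueError("negative residual sum of squares")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_direct_contra, self.w_direct_ipsi, self.w_indirect])


def build_individual_regressors(
    m1_contra: np.ndarray,
    m1_ipsi: np.ndarray,
    shc_ipsi: np.ndarray,
    slope_contra: float,
    slope_ipsi: float,
    modulator: str = "product",
) -> tuple[np.ndarray, np.ndarray]:
    """Time × 3 regressor matrix and response for the individual model."""
    try:
        mod = MODULATORS[modulator]
    except KeyError:
        raise ValueError(f"unknown modulator {modulator!r}") from None
    m1c = np.asarray(m1_contra, dtype=float)
    m1i = np.asarray(m1_ipsi, dtype=float)
    y = np.asarray(shc_ipsi, dtype=float)
    if not (m1c.size == m1i.size == y.size):
        raise ValueError("series must have equal length")
    for name, s in (("slope_contra", slope_contra), ("slope_ipsi", slope_ipsi)):
        if not np.isfinite(s):
            raise ValueError(f"{name} is not finite")
    X = np.column_stack(
        [
            slope_contra * m1c,
            slope_ipsi * m1i,
            slope_contra * slope_ipsi * mod(m1c, m1i),
        ]
    )
    _check_columns(X)
    return X, y


def _check_columns(X: np.ndarray) -> None:
    norms = np.linalg.norm(X - X.mean(axis=0), axis=0)
    dead = np.flatnonzero(norms < 1e-12)
    if dead.size:
        raise ValueError(f"degenerate (constant) regressor columns at {dead.tolist()}")


def fit_constrained_weights(
    X: np.ndarray,
    y: np.ndarray,
    intercept: bool = True,
    participant_id: str = "",
    hand: str = "",
) -> IndividualWeights:
    """Bounded least squares over [0,∞) × [0,∞) × (−∞,0] (+ free intercept).

    The convex problem is solved to its global optimum (BVLS); when the
    unconstrained OLS solution is feasible the two coincide.  A fit that
    cannot improve on the intercept is not an error — weights may all sit at
    their bounds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("X must be a (time, 3) matrix")
    if X.shape[0] != y.size:
        raise ValueError("X and y have incompatible lengths")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 time points")
    _check_columns(X)
    if intercept:
        A = np.column_stack([X, np.ones(X.shape[0])])
        lb = np.array([0.0, 0.0, -np.inf, -np.inf])
        ub = np.array([np.inf, np.inf, 0.0, np.inf])
    else:
        A = X
        lb = np.array([0.0, 0.0, -np.inf])
        ub = np.array([np.inf, np.inf, 0.0])
    res = lsq_linear(A, y, bounds=(lb, ub), method="bvls", tol=1e-12)
    w = res.x
    # snap numerically-at-bound values to exactly 0
    w[0] = max(w[0], 0.0)
    w[1] = max(w[1], 0.0)
    w[2] = min(w[2], 0.0)
    active = (w[0] == 0.0, w[1] == 0.0, w[2] == 0.0)
    resid = y - A @ w
    return IndividualWeights(
        participant_id=participant_id,
        hand=hand,
        w_direct_contra=float(w[0]),
        w_direct_ipsi=float(w[1]),
        w_indirect=float(w[2]),
        intercept=float(w[3]) if intercept else 0.0,
        rss=float(resid @ resid),
        converged=bool(res.status >= 0),
        bound_active=active,
    )


@dataclass
class IndividualWeightResults:
    """Results facade over a fitted individual weight model."""

    weights: IndividualWeights
    n_obs: int

    def summary(self) -> str:
        w = self.weights
        flags = ["*" if a else " " for a in w.bound_active]
        return "\n".join(
            [
                f"Individual corticospinal weights — {w.participant_id} {w.hand}",
                f"  direct-contra  {w.w_direct_contra:+.4f}{flags[0]}",
                f"  direct-ipsi    {w.w_direct_ipsi:+.4f}{flags[1]}",
                f"  indirect       {w.w_indirect:+.4f}{flags[2]}",
                f"  intercept      {w.intercept:+.4f}",
                f"  RSS = {w.rss:.5f} over {self.n_obs} points"
                "   (* = constraint active)",
            ]
        )


class IndividualWeightModel:
    """Statsmodels-style wrapper around the constrained weight fit."""

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 participant_id: str = "", hand: str = ""):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        self.participant_id = participant_id
        self.hand = hand

    @classmethod
    def from_series(cls, m1_contra, m1_ipsi, shc_ipsi, slope_contra, slope_ipsi,
                    modulator: str = "product", participant_id: str = "",
                    hand: str = "") -> "IndividualWeightModel":
        X, y = build_individual_regressors(
            m1_contra, m1_ipsi, shc_ipsi, slope_contra, slope_ipsi, modulator
        )
        return cls(X, y, participant_id=participant_id, hand=hand)

    def fit(self) -> IndividualWeightResults:
        w = fit_constrained_weights(
            self.X, self.y, participant_id=self.participant_id, hand=self.hand
        )
        return IndividualWeightResults(weights=w, n_obs=self.y.size)


def cohort_individual_weights(
    cohort: CohortDataset,
    estimates: pd.DataFrame,
    hands: tuple[str, ...] = HANDS,
    modulator: str = "product",
    order: str = "average-then-zscore",
    segment: str = "C7Th1",
) -> pd.DataFrame:
    """Mean-series-basis weights (11-point task windows) for a whole cohort."""
    rows = []
    for p in cohort.participants:
        series = condition_series(p, cohort.design, order=order)
        for hand in hands:
            cond = f"task-{hand}"
            target = ipsi_shc(hand, segment)
            task = estimates[
                (estimates.participant_id == p.participant_id)
                & (estimates.condition == cond)
                & (estimates.target == target)
            ]
            slope_c = task[task.source == contra_m1(hand)]["slope"]
            slope_i = task[task.source == ipsi_m1(hand)]["slope"]
            if slope_c.empty or slope_i.empty:
                raise ValueError(
                    f"missing task slopes for {p.participant_id} {hand}"
                )
            model = IndividualWeightModel.from_series(
                series[(contra_m1(hand), cond)],
                series[(ipsi_m1(hand), cond)],
                series[(target, cond)],
                float(slope_c.iloc[0]),
                float(slope_i.iloc[0]),
                modulator=modulator,
                participant_id=p.participant_id,
                hand=hand,
            )
            rows.append(model.fit().weights.__dict__)
    df = pd.DataFrame(rows)
    return df.drop(columns=["bound_active"]).join(
        pd.DataFrame(
            [r["bound_active"] for r in rows],
            columns=[f"at_bound_{t}" for t in WEIGHT_TERMS],
        )
    )


def fit_run_level_weights(
    ts: ParticipantTimeSeries,
    design: BlockDesign,
    hand: str,
    drop_initial: int = 8,
    modulator: str = "product",
    use_confounds: bool = False,
    segment: str = "C7Th1",
) -> IndividualWeights:
    """Generative-scale weights from full-run drive-basis regressors.

    The clean M1 series are reconstructed as β_RHM·drive_RHM + β_LHM·drive_LHM
    per hemisphere (GLM betas times the HRF-convolved boxcars), and the
    full-run ipsilateral SHc series is sign-constrained-regressed on
    [M1c_hat, M1i_hat, mod(M1c_hat, M1i_hat)].  On noiseless data this
    recovers the generative weights exactly.
    """
    betas = fit_glm(
        ts, design, confounds=ts.confounds if use_confounds else None,
        drop_initial=drop_initial,
    )
    drives = {h: convolve_hrf(design.boxcar(h), design.tr_seconds) for h in HANDS}

    def clean_hat(region: str) -> np.ndarray:
        b = betas[betas.region == region].set_index("hand")["beta"]
        return b["RHM"] * drives["RHM"] + b["LHM"] * drives["LHM"]

    mod = MODULATORS[modulator]
    m1c = clean_hat(contra_m1(hand))[drop_initial:]
    m1i = clean_hat(ipsi_m1(hand))[drop_initial:]
    y = ts.series(ipsi_shc(hand, segment))[drop_initial:]
    X = np.column_stack([m1c, m1i, mod(m1c, m1i)])
    _check_columns(X)
    return fit_constrained_weights(
        X, y, participant_id=ts.participant_id, hand=hand
    )


def cohort_run_level_weights(
    cohort: CohortDataset,
    hands: tuple[str, ...] = HANDS,
    drop_initial: int = 8,
    modulator: str = "product",
) -> pd.DataFrame:
    rows = []
    for p in cohort.participants:
        for hand in hands:
            w = fit_run_level_weights(
                p, cohort.design, hand, drop_initial=drop_initial,
                modulator=modulator,
            )
            d = dict(w.__dict__)
            d.pop("bound_active")
            rows.append(d)
    return pd.DataFrame(rows)


def correlate_weights_ehi(
    weights: pd.DataFrame,
    metadata: pd.DataFrame,
    hand: str,
    holm: bool = False,
) -> pd.DataFrame:
    """Pearson r (two-tailed) of each weight term with the EHI score.

    Reported uncorrected by default; ``holm=True`` adds step-down adjusted
    p values across the three terms.  A constant weight vector (e.g. every
    participant pinned at the bound) is an undefined-correlation error.
    """
    sub = weights[weights.hand == hand].set_index("participant_id")
    ehi = metadata.set_index("participant_id")["ehi"]
    common = sub.index.intersection(ehi.index)
    if len(common) < 3:
        raise ValueError("need >= 3 participants with weights and EHI")
    rows = []
    for term in WEIGHT_TERMS:
        res: StatResult = pearson_correlation(
            sub.loc[common, term].to_numpy(), ehi.loc[common].to_numpy()
        )
        rows.append({"hand": hand, "term": term, "r": res.value, "p": res.p,
                     "n": res.n})
    out = pd.DataFrame(rows)
    if holm:
        out["p_holm"] = holm_bonferroni(out["p"].to_numpy())
    return out
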