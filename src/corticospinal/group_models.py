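"""Group-level corticospinal network models and swap-bootstrap comparison.

Across participants, spinal hemicord activity (the C7–Th1 ipsilateral-SHc
GLM beta) is modelled from products of per-participant activity and
connectivity quantities.  In the connectivity family each direct network
contributes a *single* term — its M1→SHc regression slope times the
corresponding M1 beta — and the indirect network contributes *interaction*
terms: the product of both slopes (the multiplication of the two
connectivities) modulated by either the contralateral or the ipsilateral M1
beta.  Model 1 ("full") carries the two single and the two interaction
terms; model 2 the two single terms only.  The activity family uses the M1
betas and their product.

Model comparison uses adjusted R² along with AIC/BIC, plus a swap-bootstrap
null: in each iteration a random subset of participants (each included with
probability ½) has its activity rows and slope rows independently permuted,
terms are rebuilt, both models refit, and ΔR² recorded; the observed ΔR² is
judged against the 2.5–97.5 percentile band of that null.

Columns and response are z-scored across participants before fitting (R²,
adjusted R² and the model F-test are invariant to this).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import contra_m1, ipsi_m1, ipsi_shc
from .stats import ModelFitMetrics, OLSFit, StatResult, ols_fit

#: Factors every term can draw on, resolved per participant.
FACTORS = ("beta_contra", "beta_ipsi", "slope_contra", "slope_ipsi")

TERM_DEFS: dict[str, tuple[str, ...]] = {
    "single_contra": ("slope_contra", "beta_contra"),
    "single_ipsi": ("slope_ipsi", "beta_ipsi"),
    "interaction_contra": ("slope_contra", "slope_ipsi", "beta_contra"),
    "interaction_ipsi": ("slope_contra", "slope_ipsi", "beta_ipsi"),
    "activity_contra": ("beta_contra",),
    "activity_ipsi": ("beta_ipsi",),
    "activity_interaction": ("beta_contra", "beta_ipsi"),
}


@dataclass(frozen=True)
class GroupModelSpec:
    """A named set of product terms predicting ipsilateral SHc activity."""

    name: str
    family: str  # "connectivity" | "activity"
    terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("a model needs at least one term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in model spec")
        unknown = [t for t in self.terms if t not in TERM_DEFS]
        if unknown:
            raise ValueError(f"unknown terms {unknown}")


#: The two headline connectivity models.
MODEL_FULL = GroupModelSpec(
    "model1", "connectivity",
    ("single_contra", "single_ipsi", "interaction_contra", "interaction_ipsi"),
)
MODEL_DIRECT_ONLY = GroupModelSpec(
    "model2", "connectivity", ("single_contra", "single_ipsi")
)

#: The activity-model family: single betas, both, and the full interaction model.
ACTIVITY_VARIANTS = (
    GroupModelSpec("activity_contra", "activity", ("activity_contra",)),
    GroupModelSpec("activity_ipsi", "activity", ("activity_ipsi",)),
    GroupModelSpec("activity_both", "activity", ("activity_contra", "activity_ipsi")),
    GroupModelSpec(
        "activity_full", "activity",
        ("activity_contra", "activity_ipsi", "activity_interaction"),
    ),
)


def hand_summary_table(
    betas: pd.DataFrame,
    estimates: pd.DataFrame,
    hand: str,
    segment: str = "C7Th1",
) -> pd.DataFrame:
    """Per-participant factor/response table for one hand.

    Columns: the four factors plus ``response`` (ipsilateral SHc beta).
    Raises if any participant lacks a required quantity.
    """
    b = betas[betas.hand == hand]
    beta_of = lambda region: b[b.region == region].set_index("participant_id")["beta"]
    target = ipsi_shc(hand, segment)
    task = estimates[
        (estimates.condition == f"task-{hand}") & (estimates.target == target)
    ]
    slope_of = lambda region: task[task.source == region].set_index(
        "participant_id"
    )["slope"]
    parts = {
        "beta_contra": beta_of(contra_m1(hand)),
        "beta_ipsi": beta_of(ipsi_m1(hand)),
        "slope_contra": slope_of(contra_m1(hand)),
        "slope_ipsi": slope_of(ipsi_m1(hand)),
        "response": beta_of(target),
    }
    df = pd.DataFrame(parts)
    if df.isna().any().any():
        bad = df[df.isna().any(axis=1)].index.tolist()
        raise ValueError(f"missing betas or slopes for participants {bad}")
    return df.reset_index().rename(columns={"index": "participant_id"})


def _zscore_cols(a: np.ndarray) -> np.ndarray:
    mu = a.mean(axis=0, keepdims=True)
    sd = a.std(axis=0, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance column in the term matrix")
    return (a - mu) / sd


def build_terms(
    summary: pd.DataFrame,
    spec: GroupModelSpec,
    zscore: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Participants × terms design matrix and the response vector."""
    missing = [f for f in FACTORS + ("response",) if f not in summary.columns]
    if missing:
        raise ValueError(f"summary table is missing columns {missing}")
    cols = {}
    for term in spec.terms:
        col = np.ones(len(summary))
        for factor in TERM_DEFS[term]:
            col = col * summary[factor].to_numpy()
        cols[term] = col
    X = pd.DataFrame(cols, index=summary["participant_id"])
    y = pd.Series(
        summary["response"].to_numpy(),
        index=summary["participant_id"],
        name="response",
    )
    if zscore:
        X = pd.DataFrame(
            _zscore_cols(X.to_numpy()), index=X.index, columns=X.columns
        )
        sd = y.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance response")
        y = (y - y.mean()) / sd
    return X, y


@dataclass
class GroupNetworkResults:
    """Fitted group network model: coefficients, metrics and the F-test."""

    spec: GroupModelSpec
    params: pd.Series
    bse: pd.Series
    metrics: ModelFitMetrics
    f: StatResult
    n: int
    _fit: OLSFit = field(repr=False, default=None)

    @property
    def r2(self) -> float:
        return self.metrics.r2

    @property
    def adjusted_r2(self) -> float:
        return self.metrics.adjusted_r2

    def to_dict(self) -> dict:
        return {
            "model": self.spec.name,
            "family": self.spec.family,
            "terms": list(self.spec.terms),
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "metrics": self.metrics.to_dict(),
            "f_test": self.f.to_dict(),
        }

    def summary(self) -> str:
        m = self.metrics
        lines = [
            f"Group network model: {self.spec.name} ({self.spec.family} family)",
            f"  n = {self.n} participants, {m.k} terms",
            f"  R2 = {m.r2:.4f}  adj. R2 = {m.adjusted_r2:.4f}  "
            f"AIC = {m.aic:.2f}  BIC = {m.bic:.2f}",
            f"  F({self.f.df[0]:.0f}, {self.f.df[1]:.0f}) = {self.f.value:.3f}, "
            f"p = {self.f.p:.4f}",
            "  coefficients:",
        ]
        for name, val in self.params.items():
            se = self.bse[name]
            lines.append(f"    {name:22s} {val:+.4f}  (se {se:.4f})")
        return "\n".join(lines)


class GroupNetworkModel:
    """Statsmodels-style wrapper: build from a summary table, ``fit()``.

    >>> model = GroupNetworkModel(summary, MODEL_FULL)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, summary: pd.DataFrame, spec: GroupModelSpec,
                 zscore: bool = True):
        self.spec = spec
        self.summary_table = summary
        self.X, self.y = build_terms(summary, spec, zscore=zscore)

    @classmethod
    def from_cohort_tables(cls, betas: pd.DataFrame, estimates: pd.DataFrame,
                           hand: str, spec: GroupModelSpec) -> "GroupNetworkModel":
        return cls(hand_summary_table(betas, estimates, hand), spec)

    def fit(self) -> GroupNetworkResults:
        fit = ols_fit(self.X.to_numpy(), self.y.to_numpy(), intercept=True)
        names = ["const", *self.X.columns]
        return GroupNetworkResults(
            spec=self.spec,
            params=pd.Series(fit.params, index=names),
            bse=pd.Series(fit.bse, index=names),
            metrics=fit.metrics,
            f=fit.f,
            n=len(self.y),
            _fit=fit,
        )


def fit_group_model(spec: GroupModelSpec, summary: pd.DataFrame) -> GroupNetworkResults:
    """Functional form of ``GroupNetworkModel(summary, spec).fit()``."""
    return GroupNetworkModel(summary, spec).fit()


def fit_activity_models(
    summary: pd.DataFrame,
    variants: tuple[GroupModelSpec, ...] = ACTIVITY_VARIANTS,
) -> list[GroupNetworkResults]:
    """Fit the activity-model family; results sorted by adjusted R² (desc)."""
    fits = [fit_group_model(v, summary) for v in variants]
    return sorted(fits, key=lambda r: -r.adjusted_r2)


# ---------------------------------------------------------------------------
# Swap-bootstrap model comparison
# ---------------------------------------------------------------------------

@dataclass
class BootstrapComparison:
    """Observed ΔR² against its swap-bootstrap null distribution."""

    spec1: GroupModelSpec
    spec2: GroupModelSpec
    n_iterations: int
    seed: int
    observed_r2_1: float
    observed_r2_2: float
    observed_delta: float
    null_delta: np.ndarray = field(repr=False)
    null_r2_1: np.ndarray = field(repr=False)
    null_r2_2: np.ndarray = field(repr=False)
    ci_low: float = 0.0
    ci_high: float = 0.0
    significant: bool = False

    def to_dict(self) -> dict:
        return {
            "model1": self.spec1.name,
            "model2": self.spec2.name,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
            "observed_r2_model1": float(self.observed_r2_1),
            "observed_r2_model2": float(self.observed_r2_2),
            "observed_delta_r2": float(self.observed_delta),
            "null_ci_2_5": float(self.ci_low),
            "null_ci_97_5": float(self.ci_high),
            "significant": bool(self.significant),
        }


def _r2_for_spec(spec: GroupModelSpec, factors: dict[str, np.ndarray],
                 y: np.ndarray) -> float:
    n = y.size
    cols = []
    for term in spec.terms:
        col = np.ones(n)
        for f in TERM_DEFS[term]:
            col = col * factors[f]
        sd = col.std(ddof=1)
        col = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        cols.append(col)
    A = np.column_stack([np.ones(n), *cols])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - float(resid @ resid) / tss


def bootstrap_compare(
    spec1: GroupModelSpec,
    spec2: GroupModelSpec,
    summary: pd.DataFrame,
    n_iterations: int = 1000,
    seed: int | None = None,
    subset: str = "all",
) -> BootstrapComparison:
    """Swap-bootstrap null for the model-1 vs model-2 ΔR² ("δ") comparison.

    Per iteration the activity rows (M1 betas) and the slope rows are
    permuted across participants with two independent permutations, both
    models' terms are rebuilt and refit, and R² of each plus
    ΔR² = R²(spec1) − R²(spec2) recorded.  The response rows stay in place,
    so the null breaks the participant alignment between predictors and
    response.  By default the whole cohort is permuted every iteration
    (``subset="all"``), which makes the procedure an exact randomisation
    test; ``subset="random"`` instead swaps only within a random participant
    subset (independent inclusion with probability ½, at least 2 members,
    ≤100 retries), a markedly conservative variant kept for comparison.

    Observed ΔR² is flagged significant when it falls outside the
    [2.5, 97.5] percentile interval of the null distribution, with the
    observed value included in the null set (the standard randomisation-test
    correction that keeps the level exact).
    """
    if n_iterations < 100:
        raise ValueError("need at least 100 bootstrap iterations")
    if seed is None:
        raise ValueError("a seed is required for a reproducible null")
    rng = np.random.default_rng(seed)
    n = len(summary)
    factors = {f: summary[f].to_numpy(copy=True) for f in FACTORS}
    y = summary["response"].to_numpy(dtype=float)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance response")
    y = (y - y.mean()) / sd

    obs1 = _r2_for_spec(spec1, factors, y)
    obs2 = _r2_for_spec(spec2, factors, y)

    act_keys = ("beta_contra", "beta_ipsi")
    slp_keys = ("slope_contra", "slope_ipsi")
    null1 = np.empty(n_iterations)
    null2 = np.empty(n_iterations)
    for it in range(n_iterations):
        if subset == "all":
            idx = np.arange(n)
        else:
            for _ in range(100):
                mask = rng.random(n) < 0.5
                if mask.sum() >= 2:
                    break
            else:
                raise RuntimeError("could not draw a subset with >= 2 participants")
            idx = np.flatnonzero(mask)
        perm_act = idx[rng.permutation(idx.size)]
        perm_slp = idx[rng.permutation(idx.size)]
        f_it = {k: v.copy() for k, v in factors.items()}
        for k in act_keys:
            f_it[k][idx] = factors[k][perm_act]
        for k in slp_keys:
            f_it[k][idx] = factors[k][perm_slp]
        null1[it] = _r2_for_spec(spec1, f_it, y)
        null2[it] = _r2_for_spec(spec2, f_it, y)

    null_delta = null1 - null2
    observed_delta = obs1 - obs2
    # randomisation correction: the observed statistic belongs to the null set
    lo, hi = np.percentile(np.append(null_delta, observed_delta), [2.5, 97.5])
    return BootstrapComparison(
        spec1=spec1,
        spec2=spec2,
        n_iterations=n_iterations,
        seed=seed,
        observed_r2_1=obs1,
        observed_r2_2=obs2,
        observed_delta=observed_delta,
        null_delta=null_delta,
        null_r2_1=null1,
        null_r2_2=null2,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(observed_delta < lo or observed_delta > hi),
    )
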