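"""Synthetic block-design BOLD cohorts with known corticospinal coupling.

The generator emulates the measured system: six region time series per
participant (left/right M1, left/right spinal hemicord at C5 and at C7–Th1)
under an alternating RHM/LHM block design.

Generative model, per participant and hand h (with c = hemisphere
contralateral to h, i = ipsilateral):

* clean M1 drives: ``M1_side(t) = a_contra·drive_h(t) + a_ipsi·drive_h'(t)``
  where ``drive`` is the HRF-convolved task boxcar of the hand that the
  hemisphere is contralateral (resp. ipsilateral) to;
* spinal hemicord at C7–Th1 on the side of the moving hand:
  ``SHc(t) = w_direct_contra·M1c(t) + w_direct_ipsi·M1i(t)
  + w_indirect·g(M1c, M1i)(t)`` with ``g`` the indirect-pathway drive,
  by default the elementwise product of the two clean M1 series;
* C5 hemicords carry noise only (control segment);
* i.i.d. Gaussian noise (and optionally a periodic physiological component
  on the spinal rows) is added to every region.

Sign conventions mirror the biology being modelled: direct-pathway weights
are non-negative, the indirect (bilateral-integration) weight non-positive.
Edinburgh Handedness Inventory (EHI) scores are linearly coupled to a chosen
ground-truth weight at a requested population correlation, with a marginal
of mean 84 and SD 13.4 before clipping to [−100, 100].
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .design import (
    BlockDesign,
    HANDS,
    REGIONS,
    contra_m1,
    ipsi_m1,
    ipsi_shc,
    make_design,
    other_hand,
)
from .hemodynamics import hand_drive

#: Selectable indirect-pathway generative drives.
INDIRECT_DRIVES: dict[str, Callable[[np.ndarray, np.ndarray], np.ndarray]] = {
    "product": lambda c, i: c * i,
    "sum": lambda c, i: c + i,
    "contra": lambda c, i: c,
    "ipsi": lambda c, i: i,
}


@dataclass
class ParticipantTruth:
    """Ground-truth generative parameters for one synthetic participant.

    Per-hand mappings are keyed ``"RHM"``/``"LHM"``.  ``a_contra``/``a_ipsi``
    are M1 activation amplitudes (BOLD % units, contralateral positive,
    ipsilateral near zero or negative); ``w_*`` are the corticospinal
    coupling weights with their sign constraints.
    """

    participant_id: str
    w_direct_contra: Mapping[str, float]
    w_direct_ipsi: Mapping[str, float]
    w_indirect: Mapping[str, float]
    a_contra: Mapping[str, float]
    a_ipsi: Mapping[str, float]
    noise_sd: float = 0.3
    ehi: float = 84.0
    physio_amplitude: float = 0.0
    physio_period_trs: float | None = None

    def __post_init__(self) -> None:
        for h in HANDS:
            if self.w_direct_contra[h] < 0 or self.w_direct_ipsi[h] < 0:
                raise ValueError("direct-pathway weights must be >= 0")
            if self.w_indirect[h] > 0:
                raise ValueError("indirect-pathway weight must be <= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not -100.0 <= self.ehi <= 100.0:
            raise ValueError("EHI must lie in [-100, 100]")
        if self.physio_amplitude and not self.physio_period_trs:
            raise ValueError("physio_amplitude requires physio_period_trs")

    def weight(self, name: str, hand: str) -> float:
        return float(getattr(self, name)[hand])


@dataclass
class ParticipantTimeSeries:
    """Regions × time BOLD matrix for one participant."""

    participant_id: str
    tr_seconds: float
    regions: tuple[str, ...]
    values: np.ndarray
    confounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.regions):
            raise ValueError("values must be a (n_regions, n_trs) matrix")
        if np.isnan(self.values).any():
            raise ValueError("time series contain missing values")
        unknown = set(self.regions) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown region labels {sorted(unknown)}")
        if self.confounds is not None:
            self.confounds = np.asarray(self.confounds, dtype=float)
            if self.confounds.shape[0] != self.values.shape[1]:
                raise ValueError("confounds must have one row per TR")

    @property
    def n_trs(self) -> int:
        return self.values.shape[1]

    def series(self, region: str) -> np.ndarray:
        try:
            return self.values[self.regions.index(region)]
        except ValueError as exc:
            raise KeyError(f"region {region!r} not in this time series") from exc


@dataclass
class CohortDataset:
    """A block design plus per-participant series, EHI metadata and, for
    synthetic cohorts, the generative ground truth."""

    design: BlockDesign
    participants: list[ParticipantTimeSeries]
    metadata: pd.DataFrame
    truth: list[ParticipantTruth] | None = None

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate participant ids")
        meta_ids = set(self.metadata["participant_id"])
        if meta_ids != set(ids):
            raise ValueError("metadata must have exactly one row per participant")
        if self.metadata["ehi"].isna().any():
            raise ValueError("EHI missing for some participants")
        for p in self.participants:
            if p.n_trs != self.design.n_trs:
                raise ValueError(
                    f"participant {p.participant_id}: series length {p.n_trs} "
                    f"does not match the design ({self.design.n_trs} TRs)"
                )

    @property
    def participant_ids(self) -> list[str]:
        return [p.participant_id for p in self.participants]

    def ehi(self) -> pd.Series:
        return self.metadata.set_index("participant_id")["ehi"]


@dataclass(frozen=True)
class TruthDistribution:
    """Population (mean, sd) of each generative parameter.

    Defaults describe the study conditions the generator emulates: strong
    positive direct-contra coupling (0.8), weaker direct-ipsi coupling (0.3),
    a negative indirect weight (−0.5), unit contralateral M1 amplitude and a
    near-zero, slightly negative ipsilateral amplitude with participant-level
    spread.  Sign constraints are enforced by folding the Gaussian draws.
    """

    w_direct_contra: tuple[float, float] = (0.8, 0.2)
    w_direct_ipsi: tuple[float, float] = (0.3, 0.15)
    w_indirect: tuple[float, float] = (-0.5, 0.2)
    a_contra: tuple[float, float] = (1.0, 0.2)
    a_ipsi: tuple[float, float] = (-0.1, 0.15)
    noise_sd: float = 0.3

    def draw(self, rng: np.random.Generator, participant_id: str) -> ParticipantTruth:
        def pos(ms):  # folded to respect the sign constraint
            return {h: abs(rng.normal(*ms)) for h in HANDS}

        def neg(ms):
            return {h: -abs(rng.normal(-ms[0], ms[1])) for h in HANDS}

        return ParticipantTruth(
            participant_id=participant_id,
            w_direct_contra=pos(self.w_direct_contra),
            w_direct_ipsi=pos(self.w_direct_ipsi),
            w_indirect=neg(self.w_indirect),
            a_contra=pos(self.a_contra),
            a_ipsi={h: rng.normal(*self.a_ipsi) for h in HANDS},
            noise_sd=self.noise_sd,
        )


@dataclass(frozen=True)
class EhiCoupling:
    """Which ground-truth weight drives the EHI score, and how strongly."""

    weight: str = "w_direct_contra"
    hand: str = "RHM"
    r: float = 0.7
    mean: float = 84.0
    sd: float = 13.4

    def __post_init__(self) -> None:
        if abs(self.r) > 1:
            raise ValueError("|target correlation| cannot exceed 1")
        if self.weight not in ("w_direct_contra", "w_direct_ipsi", "w_indirect"):
            raise ValueError(f"unknown weight {self.weight!r}")
        if self.hand not in HANDS:
            raise ValueError(f"unknown hand {self.hand!r}")


def clean_m1_series(truth: ParticipantTruth, design: BlockDesign) -> dict[str, np.ndarray]:
    """Noiseless M1 drives per hemisphere (``M1_L``, ``M1_R``)."""
    drives = {h: hand_drive(design, h) for h in HANDS}
    clean: dict[str, np.ndarray] = {}
    for hand in HANDS:
        # hemisphere contralateral to `hand` responds with a_contra[hand];
        # the same hemisphere is ipsilateral to the other hand.
        region = contra_m1(hand)
        clean[region] = (
            truth.a_contra[hand] * drives[hand]
            + truth.a_ipsi[other_hand(hand)] * drives[other_hand(hand)]
        )
    return clean


def clean_shc_series(
    truth: ParticipantTruth,
    design: BlockDesign,
    indirect_drive: str = "product",
) -> dict[str, np.ndarray]:
    """Noiseless C7–Th1 spinal hemicord series driven by the network model."""
    try:
        g = INDIRECT_DRIVES[indirect_drive]
    except KeyError:
        raise ValueError(f"unknown indirect drive {indirect_drive!r}") from None
    m1 = clean_m1_series(truth, design)
    out: dict[str, np.ndarray] = {}
    for hand in HANDS:
        m1c = m1[contra_m1(hand)]
        m1i = m1[ipsi_m1(hand)]
        out[ipsi_shc(hand)] = (
            truth.w_direct_contra[hand] * m1c
            + truth.w_direct_ipsi[hand] * m1i
            + truth.w_indirect[hand] * g(m1c, m1i)
        )
    return out


def generative_regressor_rms(
    truth: ParticipantTruth,
    design: BlockDesign,
    hand: str,
    drop_initial: int = 0,
    indirect_drive: str = "product",
) -> np.ndarray:
    """RMS amplitude of each clean network regressor for one participant × hand.

    Returns the root-mean-square of (M1 contra, M1 ipsi, indirect drive)
    clean series.  Multiplying a network weight by this factor converts it to
    the per-timepoint contribution scale, on which weights of terms with very
    different regressor amplitudes become comparable.
    """
    g = INDIRECT_DRIVES[indirect_drive]
    m1 = clean_m1_series(truth, design)
    m1c = m1[contra_m1(hand)][drop_initial:]
    m1i = m1[ipsi_m1(hand)][drop_initial:]
    return np.sqrt(
        np.array([(m1c**2).mean(), (m1i**2).mean(), (g(m1c, m1i) ** 2).mean()])
    )


def motion_confounds(rng: np.random.Generator, n_trs: int, n_params: int = 6,
                     step_sd: float = 0.02) -> np.ndarray:
    """Six smooth random-walk series standing in for rigid-body motion."""
    return np.cumsum(rng.normal(0.0, step_sd, size=(n_trs, n_params)), axis=0)


def simulate_participant(
    truth: ParticipantTruth,
    design: BlockDesign,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    indirect_drive: str = "product",
) -> ParticipantTimeSeries:
    """Simulate the six-region BOLD matrix for one participant.

    Deterministic given the seed (or generator) and parameters.
    """
    if rng is None:
        if seed is None:
            raise ValueError("provide a seed or an explicit generator")
        rng = np.random.default_rng(seed)
    n = design.n_trs
    m1 = clean_m1_series(truth, design)
    shc = clean_shc_series(truth, design, indirect_drive=indirect_drive)
    values = np.zeros((len(REGIONS), n))
    for idx, region in enumerate(REGIONS):
        if region in m1:
            values[idx] = m1[region]
        elif region in shc:
            values[idx] = shc[region]
        # C5 control rows stay at zero clean signal
    noise = rng.normal(0.0, truth.noise_sd, size=values.shape) if truth.noise_sd else 0.0
    values = values + noise
    if truth.physio_amplitude:
        t = np.arange(n)
        for idx, region in enumerate(REGIONS):
            if region.startswith("SHc"):
                phase = rng.uniform(0, 2 * np.pi)
                values[idx] += truth.physio_amplitude * np.sin(
                    2 * np.pi * t / truth.physio_period_trs + phase
                )
    conf = motion_confounds(rng, n)
    return ParticipantTimeSeries(
        participant_id=truth.participant_id,
        tr_seconds=design.tr_seconds,
        regions=REGIONS,
        values=values,
        confounds=conf,
    )


def simulate_cohort(
    n_participants: int = 13,
    design: BlockDesign | None = None,
    distribution: TruthDistribution | None = None,
    coupling: EhiCoupling | None = None,
    seed: int | None = None,
    indirect_drive: str = "product",
) -> CohortDataset:
    """Simulate a full cohort with EHI scores coupled to a ground-truth weight.

    EHI is a linear map of the chosen (sample-standardised) weight plus
    Gaussian noise scaled so the population correlation equals the requested
    target, then clipped to [−100, 100].
    """
    if n_participants < 3:
        raise ValueError("need at least 3 participants")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    design = design or make_design()
    distribution = distribution or TruthDistribution()
    coupling = coupling or EhiCoupling()
    ss = np.random.SeedSequence(seed)
    truth_rng = np.random.default_rng(ss.spawn(1)[0])
    ids = [f"sub-{i + 1:02d}" for i in range(n_participants)]
    truths = [distribution.draw(truth_rng, pid) for pid in ids]

    w = np.array([t.weight(coupling.weight, coupling.hand) for t in truths])
    sd_w = w.std(ddof=1)
    if sd_w == 0 and coupling.r != 0:
        raise ValueError(
            "zero-variance weight distribution cannot carry an EHI coupling"
        )
    z_w = (w - w.mean()) / sd_w if sd_w > 0 else np.zeros_like(w)
    eps = truth_rng.standard_normal(n_participants)
    raw = coupling.mean + coupling.sd * (
        coupling.r * z_w + np.sqrt(1.0 - coupling.r**2) * eps
    )
    ehi = np.clip(raw, -100.0, 100.0)
    truths = [replace(t, ehi=float(e)) for t, e in zip(truths, ehi)]

    child_seeds = ss.spawn(n_participants + 1)[1:]
    participants = [
        simulate_participant(t, design, rng=np.random.default_rng(cs),
                             indirect_drive=indirect_drive)
        for t, cs in zip(truths, child_seeds)
    ]
    metadata = pd.DataFrame({"participant_id": ids, "ehi": ehi})
    return CohortDataset(design=design, participants=participants,
                         metadata=metadata, truth=truths)


#: Population (mean, sd) of each per-participant factor in the group-level
#: summary generator.  Contralateral M1 responds around 1 (unit BOLD %),
#: ipsilateral M1 sits near zero with spread, the contralateral effective
#: connectivity is strongly positive and the ipsilateral one negative on
#: average with wide participant spread.
GROUP_FACTOR_DISTRIBUTION: dict[str, tuple[float, float]] = {
    "beta_contra": (1.0, 0.2),
    "beta_ipsi": (-0.1, 0.15),
    "slope_contra": (0.8, 0.2),
    "slope_ipsi": (-0.3, 0.3),
}

#: Default generating coefficients for the group connectivity model, on the
#: z-scored term scale: weak single (direct-network) effects and dominant
#: negative interaction (indirect-network) effects, the regime in which the
#: full model explains most of the spinal response while the direct-only
#: model explains little.
GROUP_MODEL_COEFFICIENTS: dict[str, float] = {
    "single_contra": 0.2,
    "single_ipsi": 0.1,
    "interaction_contra": -0.8,
    "interaction_ipsi": -0.6,
}


def simulate_group_summary(
    n_participants: int = 13,
    coefficients: Mapping[str, float] | None = None,
    noise_sd: float = 0.6,
    factor_distribution: Mapping[str, tuple[float, float]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate a per-participant summary table under the group network model.

    Factors (M1 betas and M1→SHc slopes) are drawn independently per
    participant; the response is a linear combination of the requested
    z-scored model terms plus Gaussian noise — i.e. a cohort generated
    *under* the group connectivity model, which is the ground truth for
    model-recovery and bootstrap-calibration simulations.  Terms with a zero
    (or omitted) coefficient contribute nothing, so passing only single-term
    coefficients generates a direct-networks-only world and an empty mapping
    generates the no-coupling null.

    Returns a DataFrame with participant_id, the four factors and the
    response.
    """
    from .group_models import TERM_DEFS  # local import avoids a cycle

    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    if n_participants < 3:
        raise ValueError("need at least 3 participants")
    coefficients = GROUP_MODEL_COEFFICIENTS if coefficients is None else coefficients
    dist = factor_distribution or GROUP_FACTOR_DISTRIBUTION
    rng = np.random.default_rng(seed)
    factors = {
        name: rng.normal(mu, sd, n_participants) for name, (mu, sd) in dist.items()
    }
    y = rng.normal(0.0, noise_sd, n_participants)
    for term, coef in coefficients.items():
        if coef == 0:
            continue
        col = np.ones(n_participants)
        for factor in TERM_DEFS[term]:
            col = col * factors[factor]
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"degenerate term {term} in the generator")
        y = y + coef * (col - col.mean()) / sd
    df = pd.DataFrame(factors)
    df.insert(0, "participant_id", [f"sub-{i + 1:02d}" for i in range(n_participants)])
    df["response"] = y
    return df


def truth_table(truths: list[ParticipantTruth]) -> pd.DataFrame:
    """Long-format ground-truth manifest (participant × hand × parameter)."""
    rows = []
    for t in truths:
        for h in HANDS:
            rows.append(
                {
                    "participant_id": t.participant_id,
                    "hand": h,
                    "w_direct_contra": t.w_direct_contra[h],
                    "w_direct_ipsi": t.w_direct_ipsi[h],
                    "w_indirect": t.w_indirect[h],
                    "a_contra": t.a_contra[h],
                    "a_ipsi": t.a_ipsi[h],
                    "noise_sd": t.noise_sd,
                    "ehi": t.ehi,
                }
            )
    return pd.DataFrame(rows)
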