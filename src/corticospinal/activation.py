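"""Activation-level statistics on region betas.

The spinal activation analysis asks whether task-evoked activity is
specific to the hand-motoneuron segment (C7–Th1 vs the C5 control level)
and lateralised to the side of the moving hand: a 2×2×2 within-subject
ANOVA with factors HAND (RHM/LHM), SEGMENT (C5/C7–Th1) and SIDE
(contralateral/ipsilateral SHc, resolved per hand), followed by
Holm–Bonferroni-adjusted paired comparisons.  A paired t-test contrasts
ipsilateral M1 activity between the two hands (the deactivation asymmetry).
"""

from __future__ import annotations

import pandas as pd

from .design import HANDS, contra_shc, ipsi_m1, ipsi_shc
from .stats import StatResult, holm_bonferroni, paired_t, rm_anova_3way

SEGMENTS = ("C5", "C7Th1")
SIDES = ("contra", "ipsi")

#: The default posthoc family: segment within side×hand, side within hand.
DEFAULT_CONTRASTS: tuple[tuple[str, tuple[str, str, str], tuple[str, str, str]], ...] = tuple(
    [
        (f"{hand}: C7Th1 vs C5 ({side})", ("C7Th1", side, hand), ("C5", side, hand))
        for hand in HANDS
        for side in SIDES
    ]
    + [
        (f"{hand}: ipsi vs contra (C7Th1)", ("C7Th1", "ipsi", hand), ("C7Th1", "contra", hand))
        for hand in HANDS
    ]
)


def shc_factor_table(betas: pd.DataFrame) -> pd.DataFrame:
    """Recode anatomical SHc betas into (hand, segment, side) factors.

    ``side`` is resolved relative to the moving hand: for RHM the right
    hemicord is ipsilateral, for LHM the left.
    """
    rows = []
    for hand in HANDS:
        for segment in SEGMENTS:
            for side, region_of in (("ipsi", ipsi_shc), ("contra", contra_shc)):
                region = region_of(hand, segment)
                sub = betas[(betas.hand == hand) & (betas.region == region)]
                for _, rec in sub.iterrows():
                    rows.append(
                        {
                            "participant_id": rec["participant_id"],
                            "hand": hand,
                            "segment": segment,
                            "side": side,
                            "beta": rec["beta"],
                        }
                    )
    return pd.DataFrame(rows)


def shc_anova(betas: pd.DataFrame) -> dict:
    """Three-way repeated-measures ANOVA on spinal hemicord betas.

    Returns all seven effects plus the two effects of scientific interest
    flagged for reporting: the SEGMENT main effect (hand-motoneuron-level
    specificity) and the SIDE×HAND interaction (lateralisation).
    """
    table = shc_factor_table(betas)
    results = rm_anova_3way(table, factors=("hand", "segment", "side"))
    by_name = {r.name: r for r in results}
    return {
        "effects": [r.to_dict() for r in results],
        "segment_effect": by_name["segment"].to_dict(),
        "side_by_hand": by_name["hand:side"].to_dict(),
    }


def posthoc_paired(
    betas: pd.DataFrame,
    contrasts=DEFAULT_CONTRASTS,
) -> pd.DataFrame:
    """Paired t per named contrast, Holm-adjusted across the family.

    Each contrast names two (segment, side, hand) cells of the SHc factor
    table; the t is computed on within-participant differences.
    """
    table = shc_factor_table(betas)
    cell = (
        table.set_index(["segment", "side", "hand", "participant_id"])
        .sort_index()["beta"]
    )
    rows = []
    for name, a, b in contrasts:
        xa = cell.loc[a].sort_index()
        xb = cell.loc[b].sort_index()
        common = xa.index.intersection(xb.index)
        res: StatResult = paired_t(xa.loc[common].to_numpy(), xb.loc[common].to_numpy())
        rows.append({"contrast": name, "t": res.value, "df": res.df, "p": res.p,
                     "n": res.n})
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_bonferroni(out["p"].to_numpy())
    return out


def ipsilateral_m1_asymmetry(betas: pd.DataFrame) -> StatResult:
    """Paired t on ipsilateral M1 betas, RHM vs LHM.

    Tests whether ipsilateral M1 deactivation is weaker during left-hand
    than right-hand movement.
    """
    vals = {}
    for hand in HANDS:
        region = ipsi_m1(hand)
        vals[hand] = (
            betas[(betas.hand == hand) & (betas.region == region)]
            .set_index("participant_id")["beta"]
            .sort_index()
        )
    common = vals["RHM"].index.intersection(vals["LHM"].index)
    return paired_t(vals["RHM"].loc[common].to_numpy(),
                    vals["LHM"].loc[common].to_numpy())
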