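"""Tabular formats and configuration.

All tables are plain TSV: tab-separated, header row, '.' decimal, UTF-8, no
quoting.  Time series travel in long format (participant_id, region,
t_index, value) with 0-based TR indices; the design as (start_tr, n_trs,
condition); metadata as (participant_id, ehi).  Ground truth rides in a
JSON manifest.  Reports are JSON with sorted keys so identical runs are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortDataset, ParticipantTimeSeries, ParticipantTruth
from .design import BlockDesign, REGIONS

TS_COLUMNS = ["participant_id", "region", "t_index", "value"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_design(design: BlockDesign, path: str | Path) -> None:
    df = pd.DataFrame(list(design.onsets), columns=["start_tr", "n_trs", "condition"])
    df.insert(0, "tr_seconds", design.tr_seconds)
    write_tsv(df, path)


def read_design(path: str | Path) -> BlockDesign:
    df = read_tsv(path)
    required = {"tr_seconds", "start_tr", "n_trs", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"design table must have columns {sorted(required)}")
    onsets = tuple(
        (int(r.start_tr), int(r.n_trs), str(r.condition)) for r in df.itertuples()
    )
    return BlockDesign(tr_seconds=float(df["tr_seconds"].iloc[0]), onsets=onsets)


def write_timeseries(cohort: CohortDataset, path: str | Path) -> None:
    frames = []
    for p in cohort.participants:
        n = p.n_trs
        for r_idx, region in enumerate(p.regions):
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": p.participant_id,
                        "region": region,
                        "t_index": np.arange(n),
                        "value": p.values[r_idx],
                    }
                )
            )
    write_tsv(pd.concat(frames, ignore_index=True), path)


def read_timeseries_table(
    path: str | Path,
    design: BlockDesign,
    metadata: pd.DataFrame,
    truth: list[ParticipantTruth] | None = None,
) -> CohortDataset:
    """Load and validate a long-format time-series table into a cohort.

    Checks: required columns, known region labels, no duplicate
    (participant, region, t) keys, every participant carries every region at
    the full design length.
    """
    df = read_tsv(path)
    missing = [c for c in TS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"time-series table is missing columns {missing}")
    unknown = set(df["region"].unique()) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown region labels {sorted(unknown)}")
    if df.duplicated(subset=["participant_id", "region", "t_index"]).any():
        raise ValueError("duplicate (participant, region, t_index) keys")
    participants = []
    for pid, group in df.groupby("participant_id", sort=True):
        values = np.full((len(REGIONS), design.n_trs), np.nan)
        for region, sub in group.groupby("region"):
            idx = sub["t_index"].to_numpy()
            if idx.size != design.n_trs or set(idx) != set(range(design.n_trs)):
                raise ValueError(
                    f"participant {pid}, region {region}: series length "
                    f"{idx.size} does not match the design ({design.n_trs})"
                )
            values[REGIONS.index(region)] = (
                sub.sort_values("t_index")["value"].to_numpy()
            )
        absent = [REGIONS[i] for i in range(len(REGIONS))
                  if np.isnan(values[i]).all()]
        if absent:
            raise ValueError(f"participant {pid} is missing regions {absent}")
        participants.append(
            ParticipantTimeSeries(
                participant_id=str(pid),
                tr_seconds=design.tr_seconds,
                regions=REGIONS,
                values=values,
            )
        )
    return CohortDataset(design=design, participants=participants,
                         metadata=metadata, truth=truth)


def write_truth(truths: list[ParticipantTruth], path: str | Path) -> None:
    payload = [dataclasses.asdict(t) for t in truths]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_truth(path: str | Path) -> list[ParticipantTruth]:
    payload = json.loads(Path(path).read_text())
    return [ParticipantTruth(**entry) for entry in payload]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(
        json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n"
    )


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Everything a full deterministic run needs.

    ``input_dir`` switches the pipeline from the synthetic generator to
    previously written tables.  Every random stage derives its stream from
    ``seed``.
    """

    seed: int = 7
    n_participants: int = 13
    tr_seconds: float = 2.6
    n_task_blocks: int = 8
    n_rest_blocks: int = 9
    task_block_trs: int = 11
    rest_block_trs: int = 11
    noise_sd: float = 0.3
    indirect_drive: str = "product"
    ehi_coupling_weight: str = "w_direct_contra"
    ehi_coupling_hand: str = "RHM"
    ehi_coupling_r: float = 0.7
    bootstrap_iterations: int = 1000
    model_hand: str = "LHM"
    weight_modulator: str = "product"
    drop_initial: int = 8
    highpass: float = 128.0
    zscore_order: str = "average-then-zscore"
    input_dir: str | None = None
    verbosity: str = "info"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        return cls(**data)


def ingest_deposited_tables(
    ehi_path: str | Path,
    activity_path: str | Path,
    slopes_path: str | Path,
) -> dict[str, pd.DataFrame]:
    """Adapter for user-supplied per-participant deposit tables.

    Maps externally deposited verification data (EHI scores, region
    activity betas, regression slopes) onto the internal schema.  Expected
    headers: ``participant_id, ehi`` / ``participant_id, region, hand,
    beta`` / ``participant_id, source, target, condition, slope``.  This is
    a documented adapter for a layout the deposit does not formally specify
    — it requires a local download and never touches the network.
    """
    ehi = read_tsv(ehi_path)
    activity = read_tsv(activity_path)
    slopes = read_tsv(slopes_path)
    for name, df, cols in (
        ("ehi", ehi, {"participant_id", "ehi"}),
        ("activity", activity, {"participant_id", "region", "hand", "beta"}),
        ("slopes", slopes, {"participant_id", "source", "target", "condition", "slope"}),
    ):
        if not cols.issubset(df.columns):
            raise ValueError(f"{name} table must have columns {sorted(cols)}")
    return {"metadata": ehi, "betas": activity, "estimates": slopes}
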