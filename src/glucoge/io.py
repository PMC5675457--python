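"""File formats: patient event CSV, model-set JSON, run configuration YAML.

The patient file is a 1-min-grid CSV with columns
``time_min, cho_g, basal_u_per_min, bolus_u, smbg_mgdl, cgm_mgdl``; empty
cells mean no event or reading at that minute (CGM rows appear every
5 min). Values are written at full floating-point precision so a
write/read round trip reproduces the dataset exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import PatientDataset, ScenarioConfig, MINUTES_PER_DAY
from .evolution import GEConfig
from .expressions import parse_phenotype, PREDICTION_HORIZON_SAMPLES
from .metrics import PenParams
from .physiology import MealEvent, InsulinDelivery
from .pipeline import SegmentModel, SegmentModelSet, SegmentSpec
from .signals import UniformSignal

__all__ = [
    "patient_to_frame",
    "frame_to_patient",
    "write_patient_csv",
    "read_patient_csv",
    "save_model_set",
    "load_model_set",
    "load_run_config",
]

PATIENT_COLUMNS = ["time_min", "cho_g", "basal_u_per_min", "bolus_u",
                   "smbg_mgdl", "cgm_mgdl"]


def patient_to_frame(dataset: PatientDataset) -> pd.DataFrame:
    """The per-patient event table on the 1-min grid."""
    n_min = len(dataset.insulin.basal)
    df = pd.DataFrame({"time_min": np.arange(n_min, dtype=float)})
    for col in PATIENT_COLUMNS[1:]:
        df[col] = np.nan
    df["basal_u_per_min"] = dataset.insulin.basal.values
    for ev in dataset.cho_events:
        i = int(math.floor(ev.time))
        if 0 <= i < n_min:
            df.loc[i, "cho_g"] = (ev.grams if np.isnan(df.loc[i, "cho_g"])
                                  else df.loc[i, "cho_g"] + ev.grams)
    for t, dose in dataset.insulin.boluses:
        i = int(math.floor(t))
        df.loc[i, "bolus_u"] = (dose if np.isnan(df.loc[i, "bolus_u"])
                                else df.loc[i, "bolus_u"] + dose)
    for t, val in dataset.smbg:
        df.loc[int(math.floor(t)), "smbg_mgdl"] = val
    step = int(dataset.cgm.dt)
    df.loc[::step, "cgm_mgdl"] = dataset.cgm.values[:len(df.loc[::step])]
    return df


def frame_to_patient(df: pd.DataFrame) -> PatientDataset:
    """Rebuild a :class:`PatientDataset` from the event table.

    Hypotreatment provenance and the surrogate's internal true-BG trace are
    not part of the interchange format and come back empty.
    """
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table lacks columns {missing}")
    cgm_rows = df[df["cgm_mgdl"].notna()]
    times = cgm_rows["time_min"].to_numpy()
    if len(times) < 2:
        raise ValueError("patient table holds fewer than two CGM readings")
    dt = float(times[1] - times[0])
    cgm = UniformSignal(cgm_rows["cgm_mgdl"].to_numpy(), t0=float(times[0]), dt=dt)
    cho = [MealEvent(float(r.time_min), float(r.cho_g))
           for r in df[df["cho_g"].notna()].itertuples()]
    boluses = [(float(r.time_min), float(r.bolus_u))
               for r in df[df["bolus_u"].notna()].itertuples()]
    smbg = [(float(r.time_min), float(r.smbg_mgdl))
            for r in df[df["smbg_mgdl"].notna()].itertuples()]
    basal = UniformSignal(df["basal_u_per_min"].to_numpy(dtype=float), t0=0.0, dt=1.0)
    return PatientDataset(cgm=cgm, cho_events=cho, hypotreatments=[],
                          insulin=InsulinDelivery(basal=basal, boluses=boluses),
                          smbg=smbg)


def write_patient_csv(dataset: PatientDataset, path: str | Path) -> None:
    patient_to_frame(dataset).to_csv(path, index=False)


def read_patient_csv(path: str | Path) -> PatientDataset:
    # round_trip parsing keeps the write/read cycle bit-exact
    return frame_to_patient(pd.read_csv(path, float_precision="round_trip"))


def save_model_set(models: SegmentModelSet, path: str | Path) -> None:
    """Serialize a piecewise model set; expressions persist as their
    canonical phenotype text, which reloads bit-exactly."""
    payload = {
        "horizon": models.horizon,
        "config": asdict(models.config),
        "pen_params": asdict(models.pen_params),
        "models": [
            {"label": m.segment.label, "start_min": m.segment.start_min,
             "end_min": m.segment.end_min, "phenotype": m.expression.to_text(),
             "fitness": m.fitness, "rng_seed": m.rng_seed}
            for m in models.models
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model_set(path: str | Path) -> SegmentModelSet:
    payload = json.loads(Path(path).read_text())
    models = [
        SegmentModel(
            segment=SegmentSpec(m["label"], m["start_min"], m["end_min"]),
            expression=parse_phenotype(m["phenotype"]),
            fitness=m["fitness"],
            rng_seed=m["rng_seed"],
        )
        for m in payload["models"]
    ]
    return SegmentModelSet(models=models, horizon=payload["horizon"],
                           config=GEConfig(**payload["config"]),
                           pen_params=PenParams(**payload["pen_params"]))


def load_run_config(path: str | Path) -> dict:
    """Structured run configuration: GE parameters, penalty constants,
    horizon, scenario overrides. Absent sections get defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return {
        "ge": GEConfig(**raw.get("ge", {})),
        "pen": PenParams(**raw.get("pen", {})),
        "scenario": ScenarioConfig(**raw.get("scenario", {})),
        "horizon": int(raw.get("horizon", PREDICTION_HORIZON_SAMPLES)),
    }
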