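"""Long-format CSV schemas for raw signals and reduced outputs.

The same schemas the generator writes are the import path for real data:
one CSV per record type plus a JSON provenance sidecar.
"""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import config as _config
from .config import PipelineConfig, StudyConfig
from .simulate import StudyDataset

_TABLES = ("animals", "filament_responses", "ct_records", "ivd_heights",
           "histology", "cyclic_traces", "creep_curves", "truth")


def write_dataset(ds: StudyDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(ds, name).to_csv(out / f"{name}.csv", index=False)
    prov = {
        "config": _config.config_to_dict(PipelineConfig(study=ds.config)),
        "seed": ds.config.seed,
        "excluded_ids": ds.excluded_ids,
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    return out


def read_dataset(in_dir) -> StudyDataset:
    src = Path(in_dir)
    prov = json.loads((src / "provenance.json").read_text())
    cfg = _config.config_from_dict(prov["config"]).study
    frames = {}
    for name in _TABLES:
        df = pd.read_csv(src / f"{name}.csv")
        if name == "animals" and "estrous_stage" in df:
            df["estrous_stage"] = df["estrous_stage"].where(
                df["estrous_stage"].notna(), None)
        frames[name] = df
    ds = StudyDataset(config=cfg, excluded_ids=list(prov.get("excluded_ids", [])),
                      **frames)
    ds.check_consistency()
    return ds
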