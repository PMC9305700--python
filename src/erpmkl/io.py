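"""Plain-text file formats: averaged-ERP cohorts, feature tables, reports.

Everything is delimited text or JSON so artifacts stay diffable and
reproducible; every written artifact carries the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureSchema, FeatureTable
from .preprocessing import EpochWindow, SubjectErp
from .synthetic import CHANNELS

__all__ = [
    "config_hash",
    "write_cohort",
    "read_cohort",
    "write_feature_table",
    "read_feature_table",
    "write_json",
    "read_json",
]

FLOAT_FMT = "%.17g"


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def write_cohort(
    cohort: list[SubjectErp],
    outdir: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """One TSV per (subject, paradigm, stimulus class) plus a manifest.

    Rows are samples, columns the midline channels, values in µV.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "channels": list(CHANNELS),
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "subjects": [],
    }
    for erp in cohort:
        sdir = outdir / erp.subject_id
        sdir.mkdir(exist_ok=True)
        entry = {
            "id": erp.subject_id,
            "group": erp.group,
            "fs_hz": erp.fs_hz,
            "windows_ms": {
                p: [w.t_min_ms, w.t_max_ms] for p, w in erp.windows.items()
            },
            "waveforms": [],
        }
        by_pc: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        for (paradigm, stimulus, channel), wave in erp.waveforms.items():
            by_pc.setdefault((paradigm, stimulus), {})[channel] = wave
        for (paradigm, stimulus), chans in sorted(by_pc.items()):
            fname = f"{paradigm}.{stimulus}.tsv"
            frame = pd.DataFrame({ch: chans[ch] for ch in CHANNELS if ch in chans})
            frame.to_csv(sdir / fname, sep="\t", index=False, float_format=FLOAT_FMT)
            entry["waveforms"].append(
                {"paradigm": paradigm, "stimulus": stimulus, "file": f"{erp.subject_id}/{fname}"}
            )
        manifest["subjects"].append(entry)
    write_json(outdir / "manifest.json", manifest)
    return outdir


def read_cohort(indir: str | Path) -> list[SubjectErp]:
    indir = Path(indir)
    manifest = read_json(indir / "manifest.json")
    cohort = []
    for entry in manifest["subjects"]:
        fs = float(entry["fs_hz"])
        erp = SubjectErp(
            subject_id=entry["id"],
            group=entry["group"],
            fs_hz=fs,
            windows={
                p: EpochWindow(w[0], w[1], fs)
                for p, w in entry["windows_ms"].items()
            },
        )
        for wf in entry["waveforms"]:
            frame = pd.read_csv(
                indir / wf["file"], sep="\t", float_precision="round_trip"
            )
            for ch in frame.columns:
                erp.waveforms[(wf["paradigm"], wf["stimulus"], ch)] = (
                    frame[ch].to_numpy(dtype=float)
                )
        cohort.append(erp)
    return cohort


def _schema_to_dict(schema: FeatureSchema) -> dict:
    return {
        "paradigms": list(schema.paradigms),
        "stimulus_classes": {k: list(v) for k, v in schema.stimulus_classes.items()},
        "channels": list(schema.channels),
        "peaks": {k: list(v) for k, v in schema.peaks.items()},
    }


def _schema_from_dict(d: dict) -> FeatureSchema:
    return FeatureSchema(
        paradigms=tuple(d["paradigms"]),
        stimulus_classes={k: tuple(v) for k, v in d["stimulus_classes"].items()},
        channels=tuple(d["channels"]),
        peaks={k: tuple(v) for k, v in d["peaks"].items()},
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """TSV (subject, group, features…) plus a ``<path>.schema.json`` sidecar."""
    path = Path(path)
    out = table.X.copy()
    out.insert(0, "group", table.y)
    out.index.name = "subject"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    if table.schema is not None:
        write_json(path.with_suffix(path.suffix + ".schema.json"),
                   _schema_to_dict(table.schema))


def read_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", index_col="subject", float_precision="round_trip"
    )
    y = frame.pop("group")
    schema_path = path.with_suffix(path.suffix + ".schema.json")
    schema = _schema_from_dict(read_json(schema_path)) if schema_path.exists() else None
    return FeatureTable(X=frame.astype(float), y=y, schema=schema)
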