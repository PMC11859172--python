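"""Trial files, template-library persistence and run configuration.

Trials are comma-separated text with a fixed header
(``time_s,r_knee,l_knee,r_ankle,l_ankle,r_hip,l_hip``) plus a JSON
sidecar (``<stem>.meta.json``) carrying subject id, raw label, sample
rate and normalization flags. A template library is a directory of
per-template trial files plus a ``manifest.json`` that fixes the library
ordering, labels and format version; classification results are
identical before and after a round-trip.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Literal, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .classify import TemplateLibrary, WeightVector
from .sequences import (
    CHANNELS,
    CLASS_ORDER,
    MovementSequence,
    SequenceError,
    Template,
)

__all__ = [
    "read_trial",
    "write_trial",
    "save_library",
    "load_library",
    "RunConfig",
    "FORMAT_VERSION",
]

FORMAT_VERSION = "1.0"
TRIAL_COLUMNS = ("time_s",) + CHANNELS


def _meta_path(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_trial(path: Union[str, Path], seq: MovementSequence) -> Path:
    """Write a trial and its metadata sidecar; lossless for float64."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(seq.n_samples) / seq.sample_rate
    df = pd.DataFrame({"time_s": t})
    for i, c in enumerate(CHANNELS):
        df[c] = seq.angles[i]
    df.to_csv(path, index=False)  # str(float) round-trips float64 exactly
    meta = {
        "format_version": FORMAT_VERSION,
        "subject_id": seq.subject_id,
        "label": seq.label,
        "sample_rate": seq.sample_rate,
        "time_normalized": seq.time_normalized,
        "scale_normalized": seq.scale_normalized,
        "meta": {k: v for k, v in seq.meta.items() if _json_safe(v)},
    }
    _meta_path(path).write_text(json.dumps(meta, indent=1))
    return path


def _json_safe(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def read_trial(path: Union[str, Path]) -> MovementSequence:
    """Read a trial file, validating columns, finiteness and length."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SequenceError(f"trial file {path.name} is missing column(s): {missing}")
    for c in TRIAL_COLUMNS:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(~np.isfinite(col.to_numpy(dtype=float)))
        if bad.size:
            raise SequenceError(
                f"non-numeric or non-finite value in {path.name}, "
                f"column {c!r}, row {int(bad[0])}"
            )
    if len(df) < 2:
        raise SequenceError(f"trial {path.name} has {len(df)} row(s); need >= 2")
    meta_file = _meta_path(path)
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    angles = np.vstack([df[c].to_numpy(dtype=float) for c in CHANNELS])
    return MovementSequence(
        angles=angles,
        label=meta.get("label"),
        subject_id=meta.get("subject_id", ""),
        sample_rate=float(meta.get("sample_rate", 60.0)),
        time_normalized=bool(meta.get("time_normalized", False)),
        scale_normalized=bool(meta.get("scale_normalized", False)),
        meta=meta.get("meta", {}),
    )


def save_library(directory: Union[str, Path], lib: TemplateLibrary) -> Path:
    """Persist a library: per-template files plus an ordering manifest."""
    directory = Path(directory)
    tdir = directory / "templates"
    tdir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, tpl in enumerate(lib):
        fname = f"{i:05d}_{tpl.template_id or 'tpl'}.csv"
        write_trial(tdir / fname, tpl)
        records.append(
            {
                "template_id": tpl.template_id,
                "file": f"templates/{fname}",
                "label": tpl.label,
                "subject_id": tpl.subject_id,
            }
        )
    manifest = {
        "format_version": FORMAT_VERSION,
        "templates": records,
        "provenance": {k: v for k, v in lib.provenance.items() if _json_safe(v)},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return directory


def load_library(directory: Union[str, Path]) -> TemplateLibrary:
    """Load a library, enforcing manifest/file agreement and known labels."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise SequenceError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    version = str(manifest.get("format_version", ""))
    if version.split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise SequenceError(
            f"library format version {version!r} is incompatible with {FORMAT_VERSION}"
        )
    missing = [
        r["template_id"]
        for r in manifest["templates"]
        if not (directory / r["file"]).exists()
    ]
    if missing:
        raise SequenceError(f"manifest references missing template file(s): {missing}")
    listed = {str(Path(r["file"]).name) for r in manifest["templates"]}
    orphans = sorted(
        p.name
        for p in (directory / "templates").glob("*.csv")
        if p.name not in listed
    )
    if orphans:
        raise SequenceError(f"template files not listed in manifest: {orphans}")
    templates = []
    for r in manifest["templates"]:
        if r["label"] not in CLASS_ORDER:
            raise SequenceError(
                f"library template {r['template_id']} has unknown class {r['label']!r}"
            )
        seq = read_trial(directory / r["file"])
        templates.append(
            Template(
                angles=seq.angles,
                label=r["label"],
                subject_id=r.get("subject_id", ""),
                sample_rate=seq.sample_rate,
                time_normalized=True,
                scale_normalized=True,
                meta=seq.meta,
                template_id=r["template_id"],
            )
        )
    return TemplateLibrary(templates=templates, provenance=manifest.get("provenance", {}))


@dataclass
class RunConfig:
    """Run configuration; the defaults are the final operating point
    (band half-width 50, k = 1, tuned fusion weights, optimal DTW)."""

    band_halfwidth: int = 50
    k: int = 1
    weights: str = "tuned"  # tuned | initial | path to a YAML mapping
    dtw_mode: Literal["optimal", "greedy"] = "optimal"
    scale_scope: Literal["per_channel", "per_trial"] = "per_trial"
    dtw_normalize: Literal["none", "mn", "path_len"] = "none"
    seed: int = 0
    library_dir: Optional[str] = None
    output_dir: Optional[str] = None

    def resolve_weights(self) -> WeightVector:
        if self.weights == "tuned":
            return WeightVector.tuned()
        if self.weights == "initial":
            return WeightVector.initial()
        mapping = yaml.safe_load(Path(self.weights).read_text())
        return WeightVector.from_mapping(mapping)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise SequenceError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
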