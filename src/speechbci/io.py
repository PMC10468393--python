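"""Dataset container I/O and configuration handling.

Datasets are stored in HDF5: ``/day<k>/trial<j>/{tx,sbp,labels,frame_labels}``
with per-trial attributes (sentence, mode, go_bin, start time, condition)
and a JSON manifest (seed, config hash, per-trial shape/dtype inventory).
Reads verify the shape manifest and refuse mismatching files with a diff
report.  Run configuration is YAML/JSON with unknown keys rejected; one
global seed fans out into named substreams (see
:func:`speechbci.pipeline.child_seed`).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import yaml

from .pipeline import PipelineConfig
from .simulator import SimConfig, TrialRecord


class IntegrityError(RuntimeError):
    pass


def _trial_key(t: TrialRecord, j: int) -> str:
    return f"day{t.day}/trial{j:05d}"


def save_dataset(trials: List[TrialRecord], manifest: Dict, path) -> None:
    shapes = {}
    with h5py.File(path, "w") as f:
        for j, t in enumerate(trials):
            g = f.create_group(_trial_key(t, j))
            g.create_dataset("tx", data=t.tx)
            g.create_dataset("sbp", data=t.sbp)
            g.create_dataset("labels", data=np.asarray(t.labels, dtype=np.int64))
            g.create_dataset("frame_labels",
                             data=np.asarray(t.frame_labels, dtype=np.int64))
            g.attrs["sentence"] = t.sentence
            g.attrs["mode"] = t.mode
            g.attrs["go_bin"] = t.go_bin
            g.attrs["trial_start_time"] = t.trial_start_time
            g.attrs["condition"] = t.condition or ""
            g.attrs["sentence_id"] = -1 if t.sentence_id is None else t.sentence_id
            shapes[_trial_key(t, j)] = {
                "tx": list(t.tx.shape), "sbp": list(t.sbp.shape),
                "labels": [len(t.labels)],
                "frame_labels": [len(t.frame_labels)],
            }
        f.attrs["manifest"] = json.dumps({**manifest, "shapes": shapes})


def load_dataset(path) -> Tuple[List[TrialRecord], Dict]:
    trials = []
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        shapes = manifest.pop("shapes")
        keys = [f"{d}/{t}" for d in sorted(f.keys())
                for t in sorted(f[d].keys())]
        found = {}
        for key in keys:
            g = f[key]
            found[key] = {
                "tx": list(g["tx"].shape), "sbp": list(g["sbp"].shape),
                "labels": list(g["labels"].shape),
                "frame_labels": list(g["frame_labels"].shape),
            }
        if found != shapes:
            diff = {k: (shapes.get(k), found.get(k))
                    for k in set(shapes) | set(found)
                    if shapes.get(k) != found.get(k)}
            raise IntegrityError(f"shape manifest mismatch: {diff}")
        for key in keys:
            g = f[key]
            sid = int(g.attrs["sentence_id"])
            trials.append(TrialRecord(
                day=int(key.split("/")[0][3:]),
                mode=str(g.attrs["mode"]),
                sentence=str(g.attrs["sentence"]),
                labels=g["labels"][...],
                tx=g["tx"][...], sbp=g["sbp"][...],
                go_bin=int(g.attrs["go_bin"]),
                frame_labels=g["frame_labels"][...],
                trial_start_time=float(g.attrs["trial_start_time"]),
                condition=str(g.attrs["condition"]) or None,
                sentence_id=None if sid < 0 else sid,
            ))
    return trials, manifest


def dataset_checksum(trials: List[TrialRecord]) -> str:
    """Platform-stable checksum over the integer features and labels."""
    h = hashlib.sha256()
    for t in trials:
        h.update(np.ascontiguousarray(t.tx, dtype=np.int64).tobytes())
        h.update(np.asarray(t.labels, dtype=np.int64).tobytes())
    return h.hexdigest()


def _from_dict(cls, d: dict):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for k, v in d.items():
        if dataclasses.is_dataclass(names[k].type) and isinstance(v, dict):
            kwargs[k] = _from_dict(names[k].type, v)
        elif k == "sim" and isinstance(v, dict):
            kwargs[k] = _from_dict(SimConfig, v)
        else:
            kwargs[k] = v
    return cls(**kwargs)


def load_run_config(path) -> PipelineConfig:
    """YAML/JSON pipeline configuration; unknown keys are an error."""
    with open(path, "r", encoding="utf-8") as fh:
        d = yaml.safe_load(fh) or {}
    return _from_dict(PipelineConfig, d)


def dump_run_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
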