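"""On-disk formats.

* **Interchange dataset** — one directory per subject containing
  ``trials.csv`` (metadata: subject_id, trial_id, valence, arousal,
  sampling_rate_hz, baseline_s, n_channels, channels) plus one ``.npy``
  array per trial (channels × samples, row order = channel list).
* **Windowed archive** — a ``.npz`` of the dataset arrays with a JSON
  sidecar recording the profile, label scheme and stage parameters.
* **Checkpoints** — a ``.npz`` of named parameter/buffer arrays plus a JSON
  manifest (config, seed, phase tag).  Round-trips are bit-exact.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import EmotionRating, LabelScheme, RawTrial, WindowedDataset
from .network import EmotionNet, NetworkConfig


# -- interchange dataset ----------------------------------------------------


def write_interchange(trials: Iterable[RawTrial], root: str | Path) -> Path:
    root = Path(root)
    by_subject: dict[int, list[RawTrial]] = {}
    for t in trials:
        by_subject.setdefault(t.subject_id, []).append(t)
    for sid, group in by_subject.items():
        sdir = root / f"subject_{sid:03d}"
        sdir.mkdir(parents=True, exist_ok=True)
        rows = []
        for t in group:
            np.save(sdir / f"trial_{t.trial_id:04d}.npy", t.data)
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "trial_id": t.trial_id,
                    "valence": t.rating.valence,
                    "arousal": t.rating.arousal,
                    "sampling_rate_hz": t.sampling_rate_hz,
                    "baseline_s": t.baseline_s,
                    "n_channels": len(t.channel_names),
                    "channels": "|".join(t.channel_names),
                }
            )
        # %.17g round-trips float64 exactly through text
        pd.DataFrame(rows).to_csv(sdir / "trials.csv", index=False, float_format="%.17g")
    return root


def read_interchange(root: str | Path) -> list[RawTrial]:
    root = Path(root)
    trials: list[RawTrial] = []
    for sdir in sorted(root.glob("subject_*")):
        meta = pd.read_csv(sdir / "trials.csv", float_precision="round_trip")
        arrays = sorted(sdir.glob("trial_*.npy"))
        if len(arrays) != len(meta):
            raise ValueError(
                f"{sdir}: {len(arrays)} trial files but {len(meta)} metadata rows"
            )
        for _, row in meta.iterrows():
            data = np.load(sdir / f"trial_{int(row.trial_id):04d}.npy")
            names = tuple(str(row.channels).split("|"))
            if data.shape[0] != int(row.n_channels) or len(names) != int(row.n_channels):
                raise ValueError(f"{sdir}: channel count mismatch for trial {row.trial_id}")
            trials.append(
                RawTrial(
                    subject_id=int(row.subject_id),
                    trial_id=int(row.trial_id),
                    data=data,
                    sampling_rate_hz=float(row.sampling_rate_hz),
                    channel_names=names,
                    baseline_s=float(row.baseline_s),
                    rating=EmotionRating(float(row.valence), float(row.arousal)),
                )
            )
    return trials


# -- windowed archive -------------------------------------------------------


def save_windowed(ds: WindowedDataset, path: str | Path, extra_meta: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        X=ds.X,
        ratings=ds.ratings,
        labels=ds.labels,
        subject_ids=ds.subject_ids,
        trial_ids=ds.trial_ids,
    )
    meta = {
        "window_s": ds.window_s,
        "sampling_rate_hz": ds.sampling_rate_hz,
        "scheme": {"mode": ds.scheme.mode, "threshold": ds.scheme.threshold},
    }
    if extra_meta:
        meta.update(extra_meta)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))
    return path


def load_windowed(path: str | Path) -> WindowedDataset:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path) as z:
        return WindowedDataset(
            X=z["X"],
            ratings=z["ratings"],
            labels=z["labels"],
            subject_ids=z["subject_ids"],
            trial_ids=z["trial_ids"],
            window_s=meta["window_s"],
            sampling_rate_hz=meta["sampling_rate_hz"],
            scheme=LabelScheme(**meta["scheme"]),
        )


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(model: EmotionNet, path: str | Path, phase: str = "pretrained") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, **state)
    manifest = {
        "config": dataclasses.asdict(model.config),
        "seed": model.seed,
        "phase": phase,
        "stages": model.stage_names(),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return path


def load_checkpoint(path: str | Path) -> tuple[EmotionNet, str]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = dict(manifest["config"])
    for key in ("fusion_channels", "fusion_pool", "hidden"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = NetworkConfig(**cfg_dict)
    model = EmotionNet(config, seed=manifest["seed"])
    with np.load(path) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model, manifest["phase"]


# -- result tables ----------------------------------------------------------


def write_fold_table(folds, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "target_subject": f.target_subject,
            "repeat": f.repeat_index,
            "n_test": f.n_test,
            "accuracy": f.metrics.accuracy,
            "f_score": f.metrics.f_score,
        }
        for f in folds
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def write_summary(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(summary, indent=2, default=str))
    return path
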