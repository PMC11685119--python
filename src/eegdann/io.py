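"""On-disk formats: delimited raw matrices + JSON sidecars, EDF input,
HDF5 feature containers, and checkpoint bundles.

Raw trials travel as ``<trial_id>.csv`` (channels x samples, one channel per
row) beside ``<trial_id>.json`` holding fs, channel names, subject, trial and
label. Feature containers are single HDF5 files with the DE stack, labels,
subjects, adjacency and a JSON manifest attribute. Checkpoints are ``.npz``
bundles of parameter arrays plus the JSON config needed to rebuild the model
(including normalisation statistics). All writes are atomic
(write-to-temp + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import h5py
import numpy as np

from .dann import DannModel, make_rng_streams
from .dataset import FeatureDataset, Normalizer
from .layout_features import BandScheme, ElectrodeLayout, RawRecording
from .satfem import GatBranchConfig, ResNetBranchConfig

__all__ = [
    "save_recordings",
    "load_recordings",
    "read_edf",
    "save_features",
    "load_features",
    "save_checkpoint",
    "load_checkpoint",
    "atomic_write_text",
]


def atomic_write_text(path: Path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- raw matrix + sidecar ----------------------------------------------------

def save_recordings(directory: Path, recordings: list[RawRecording]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        stem = rec.trial_id or f"{rec.subject_id}_trial"
        np.savetxt(directory / f"{stem}.csv", rec.samples, delimiter=",", fmt="%.6f")
        sidecar = {
            "fs": rec.fs,
            "channel_names": list(rec.channel_names),
            "subject_id": rec.subject_id,
            "trial_id": rec.trial_id,
            "label": rec.label,
        }
        atomic_write_text(directory / f"{stem}.json", json.dumps(sidecar, indent=2))


def load_recordings(directory: Path) -> list[RawRecording]:
    directory = Path(directory)
    out = []
    for sidecar_path in sorted(directory.glob("*.json")):
        if sidecar_path.name in ("ground_truth.json", "run_config.json", "manifest.json"):
            continue
        meta = json.loads(sidecar_path.read_text())
        csv_path = sidecar_path.with_suffix(".csv")
        if not csv_path.exists():
            raise FileNotFoundError(f"matrix file missing for sidecar {sidecar_path}")
        samples = np.loadtxt(csv_path, delimiter=",", ndmin=2)
        out.append(
            RawRecording(
                samples=samples,
                fs=float(meta["fs"]),
                channel_names=list(meta["channel_names"]),
                subject_id=meta.get("subject_id", ""),
                trial_id=meta.get("trial_id", ""),
                label=meta.get("label"),
            )
        )
    if not out:
        raise FileNotFoundError(f"no recordings found under {directory}")
    return out


def read_edf(path: Path, subject_id: str = "", trial_id: str = "",
             label: int | None = None) -> RawRecording:
    """Read an EDF file into a RawRecording (microvolts).

    Channel labels are matched to the layout case-insensitively downstream.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("EDF input requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return RawRecording(
        samples=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=subject_id,
        trial_id=trial_id or Path(path).stem,
        label=label,
    )


# -- feature container -------------------------------------------------------

def save_features(path: Path, data: FeatureDataset, manifest: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    full_manifest = {
        "bands": [list(b) for b in data.scheme.bands],
        "layout_version": data.layout.version,
        "n_windows": len(data),
        **(manifest or {}),
    }
    with h5py.File(path, "w") as h5:
        h5.create_dataset("de", data=data.de)
        h5.create_dataset("labels", data=data.labels)
        h5.create_dataset(
            "subjects", data=np.array([str(s) for s in data.subjects], dtype="S32")
        )
        h5.create_dataset("adjacency", data=data.adjacency)
        h5.attrs["manifest"] = json.dumps(full_manifest)


def load_features(path: Path, layout: ElectrodeLayout | None = None) -> FeatureDataset:
    layout = layout or ElectrodeLayout.default()
    with h5py.File(path, "r") as h5:
        manifest = json.loads(h5.attrs["manifest"])
        scheme = BandScheme(tuple(tuple(b) for b in manifest["bands"]))
        return FeatureDataset(
            de=h5["de"][...],
            labels=h5["labels"][...],
            subjects=np.array([s.decode() for s in h5["subjects"][...]]),
            layout=layout,
            adjacency=h5["adjacency"][...],
            scheme=scheme,
        )


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(path: Path, model: DannModel, normalizer: Normalizer,
                    config: dict) -> None:
    """Bundle weights + rebuild config + normalisation statistics."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    arrays = {f"param::{k}": v for k, v in state.items()}
    arrays["norm::mean"] = normalizer.mean
    arrays["norm::std"] = normalizer.std
    arrays["config::json"] = np.frombuffer(
        json.dumps(config).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: Path) -> tuple[DannModel, Normalizer, dict]:
    with np.load(path) as z:
        config = json.loads(bytes(z["config::json"]).decode())
        state = {
            k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")
        }
        normalizer = Normalizer(mean=z["norm::mean"], std=z["norm::std"])
    model = DannModel(
        n_classes=config["n_classes"],
        rng_streams=make_rng_streams(0),  # overwritten by the state dict
        gat_cfg=GatBranchConfig(**config["gat_cfg"]) if config.get("gat_cfg") else None,
        resnet_cfg=(ResNetBranchConfig(**config["resnet_cfg"])
                    if config.get("resnet_cfg") else None),
        use_activity=config["use_activity"],
        use_topology=config["use_topology"],
        use_dann=config["use_dann"],
        dropout=config["dropout"],
        n_nodes=config.get("n_nodes", 62),
        input_hw=tuple(config.get("input_hw", (9, 9))),
    )
    model.load_state_dict(state)
    model.eval()
    return model, normalizer, config


def config_to_jsonable(gat_cfg: GatBranchConfig, resnet_cfg: ResNetBranchConfig,
                       **extra) -> dict:
    return {
        "gat_cfg": {
            "in_dim": gat_cfg.in_dim,
            "hidden_dims": list(gat_cfg.hidden_dims),
            "readout": gat_cfg.readout,
            "leaky_slope": gat_cfg.leaky_slope,
            "sigma": gat_cfg.sigma,
        },
        "resnet_cfg": {
            "in_channels": resnet_cfg.in_channels,
            "conv1_out": resnet_cfg.conv1_out,
            "conv1_kernel": resnet_cfg.conv1_kernel,
            "conv1_stride": resnet_cfg.conv1_stride,
            "conv1_padding": resnet_cfg.conv1_padding,
            "stage_widths": list(resnet_cfg.stage_widths),
            "blocks_per_stage": resnet_cfg.blocks_per_stage,
            "composite_shortcut": resnet_cfg.composite_shortcut,
        },
        **extra,
    }
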