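"""HDF5 persistence for features, models, support sets and medoid stores.

Every file carries provenance attributes: the front-end pipeline order,
the configuration snapshot (JSON) and the seeds involved.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .audio import PIPELINE_ORDER, LogMelSpectrogram
from .config import ArchConfig
from .severity import MedoidModel
from .siamese import SiameseModel
from .support import SupportSet


def _write_provenance(f: h5py.File, config: dict | None) -> None:
    f.attrs["pipeline_order"] = json.dumps(list(PIPELINE_ORDER))
    if config is not None:
        f.attrs["config"] = json.dumps(config, sort_keys=True)


def _spec_meta(L: LogMelSpectrogram) -> dict:
    return dict(frame_hop_s=L.frame_hop_s, window_s=L.window_s,
                mel_bands=L.mel_bands, sample_rate=L.sample_rate)


def _store_spectrograms(group: h5py.Group, Ls: list) -> None:
    group.create_dataset("values", data=np.stack([L.values for L in Ls]))
    meta = _spec_meta(Ls[0])
    for k, v in meta.items():
        group.attrs[k] = v
    group.attrs["subjects"] = json.dumps([L.subject_id for L in Ls])


def _load_spectrograms(group: h5py.Group) -> list:
    values = group["values"][()]
    subjects = json.loads(group.attrs["subjects"])
    a = group.attrs
    return [
        LogMelSpectrogram(values[i], float(a["frame_hop_s"]), float(a["window_s"]),
                          int(a["mel_bands"]), int(a["sample_rate"]), subjects[i])
        for i in range(values.shape[0])
    ]


def save_features(path, segments: dict, config: dict | None = None) -> None:
    """Persist per-subject spectrogram lists (subject -> list of segments)."""
    with h5py.File(path, "w") as f:
        _write_provenance(f, config)
        for subject, Ls in segments.items():
            _store_spectrograms(f.create_group(f"subjects/{subject}"), Ls)


def load_features(path) -> dict:
    with h5py.File(path, "r") as f:
        return {name: _load_spectrograms(f[f"subjects/{name}"])
                for name in f["subjects"]}


def save_model(path, model: SiameseModel, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        _write_provenance(f, config)
        f.attrs["arch"] = json.dumps(dict(
            channels=list(model.arch.channels), kernels=list(model.arch.kernels),
            embedding=model.arch.embedding, init=model.arch.init,
            init_std=model.arch.init_std,
        ))
        f.attrs["input_shape"] = json.dumps(list(model.input_shape))
        f.attrs["seed"] = model.seed
        f.attrs["iteration"] = model.iteration
        for k, v in model.params.items():
            f.create_dataset(f"params/{k}", data=v)


def load_model(path) -> SiameseModel:
    with h5py.File(path, "r") as f:
        arch = ArchConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in json.loads(f.attrs["arch"]).items()
        })
        model = SiameseModel(arch, tuple(json.loads(f.attrs["input_shape"])),
                             seed=int(f.attrs["seed"]))
        for k in model.params:
            model.params[k] = f[f"params/{k}"][()]
        model.iteration = int(f.attrs["iteration"])
    return model


def save_support(path, S: SupportSet, config: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        _write_provenance(f, config)
        _store_spectrograms(f.create_group("healthy"), S.healthy)
        _store_spectrograms(f.create_group("depressed"), S.depressed)
        f.attrs["healthy_subjects"] = json.dumps(list(S.healthy_subjects))
        f.attrs["depressed_subjects"] = json.dumps(list(S.depressed_subjects))


def load_support(path) -> SupportSet:
    with h5py.File(path, "r") as f:
        return SupportSet(
            healthy=_load_spectrograms(f["healthy"]),
            depressed=_load_spectrograms(f["depressed"]),
            healthy_subjects=json.loads(f.attrs["healthy_subjects"]),
            depressed_subjects=json.loads(f.attrs["depressed_subjects"]),
        )


def save_medoids(path, medoids: MedoidModel, config: dict | None = None) -> None:
    if not medoids.medoid_segments:
        raise ValueError("medoid model has no stored spectrograms")
    with h5py.File(path, "w") as f:
        _write_provenance(f, config)
        _store_spectrograms(f.create_group("segments"), medoids.medoid_segments)
        f.create_dataset("hamd", data=np.asarray(medoids.medoid_hamd, dtype=np.float64))
        f.create_dataset("indices", data=np.asarray(medoids.medoid_indices))
        f.create_dataset("assignment", data=np.asarray(medoids.assignment))
        f.attrs["cost"] = medoids.cost
        f.attrs["subjects"] = json.dumps(list(medoids.medoid_subjects))


def load_medoids(path) -> MedoidModel:
    with h5py.File(path, "r") as f:
        return MedoidModel(
            medoid_indices=f["indices"][()],
            assignment=f["assignment"][()],
            medoid_hamd=f["hamd"][()],
            cost=float(f.attrs["cost"]),
            medoid_subjects=json.loads(f.attrs["subjects"]),
            medoid_segments=_load_spectrograms(f["segments"]),
        )
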