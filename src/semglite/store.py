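"""HDF5 persistence for labelled feature tensors.

Layout (schema version 1):

* ``/features`` — float32 array ``(n, window_len, n_channels, 1)``
* ``/labels`` — int32 gesture classes (1-based)
* ``/provenance/{subject_id,trial_id,window_start}``
* root attrs — ``feature_kind``, ``schema_version`` and the WindowSpec fields
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np

from .features import FEATURE_KINDS, FeatureTensor, WindowSpec

SCHEMA_VERSION = 1


def save_features(tensors: list[FeatureTensor], path, spec: WindowSpec | None = None) -> None:
    """Write tensors losslessly; an empty list produces a valid empty store."""
    spec = spec or WindowSpec()
    kind = tensors[0].feature_kind if tensors else "RAW"
    if any(t.feature_kind != kind for t in tensors):
        raise ValueError("mixed feature kinds in one store")
    data = (
        np.stack([t.data for t in tensors])
        if tensors
        else np.empty((0, spec.window_len, 0, 1), dtype=np.float32)
    )
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=data)
        f.create_dataset("labels", data=np.array([t.label for t in tensors], dtype=np.int32))
        prov = f.create_group("provenance")
        str_t = h5py.string_dtype()
        prov.create_dataset("subject_id", data=[t.subject_id for t in tensors], dtype=str_t)
        prov.create_dataset("trial_id", data=[t.trial_id for t in tensors], dtype=str_t)
        prov.create_dataset(
            "window_start", data=np.array([t.window_start for t in tensors], dtype=np.int64)
        )
        f.attrs["feature_kind"] = kind
        f.attrs["schema_version"] = SCHEMA_VERSION
        for fld in dataclasses.fields(spec):
            f.attrs[f"window_spec/{fld.name}"] = getattr(spec, fld.name)


def load_features(path, expect_channels: int | None = None) -> tuple[list[FeatureTensor], WindowSpec]:
    """Read a feature store back; validates schema, kind and channel count."""
    with h5py.File(path, "r") as f:
        version = int(f.attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise ValueError(f"{path}: schema version {version}, expected {SCHEMA_VERSION}")
        kind = str(f.attrs["feature_kind"])
        if kind not in FEATURE_KINDS:
            raise ValueError(f"{path}: unknown feature kind {kind!r}")
        spec = WindowSpec(
            **{
                fld.name: type(getattr(WindowSpec(), fld.name))(
                    f.attrs[f"window_spec/{fld.name}"]
                )
                for fld in dataclasses.fields(WindowSpec)
            }
        )
        data = f["features"][()]
        labels = f["labels"][()]
        subj = [s.decode() if isinstance(s, bytes) else str(s) for s in f["provenance/subject_id"][()]]
        trial = [s.decode() if isinstance(s, bytes) else str(s) for s in f["provenance/trial_id"][()]]
        starts = f["provenance/window_start"][()]
    if data.shape[0] and expect_channels is not None and data.shape[2] != expect_channels:
        raise ValueError(
            f"{path}: store has {data.shape[2]} channels, expected {expect_channels}"
        )
    tensors = [
        FeatureTensor(
            data[i], feature_kind=kind, label=int(labels[i]),
            subject_id=subj[i], trial_id=trial[i], window_start=int(starts[i]),
        )
        for i in range(data.shape[0])
    ]
    return tensors, spec
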