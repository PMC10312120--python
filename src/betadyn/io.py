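"""HDF5 epoch container I/O.

Layout::

    /channels/<name>/data   float, trials x samples
    /trials/rt_ms           optional, one reaction time per trial
    /meta/window            window label ("precue" | "pretarget")
    root attributes: fs, t0, dt

Round trips are lossless; the schema is validated on read and violations
raise :class:`~betadyn.containers.SchemaError` naming the offending field.
"""

from __future__ import annotations

import h5py
import numpy as np

from .containers import EpochSet, SchemaError

__all__ = ["read_epochs", "write_epochs"]


def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["fs"] = float(epochs.fs)
        fh.attrs["t0"] = float(epochs.t0)
        fh.attrs["dt"] = 1.0 / epochs.fs
        ch = fh.create_group("channels")
        ch.attrs["order"] = list(epochs.ch_names)
        for i, name in enumerate(epochs.ch_names):
            ch.create_group(name).create_dataset("data", data=epochs.data[:, i, :])
        tr = fh.create_group("trials")
        if epochs.rts is not None:
            tr.create_dataset("rt_ms", data=epochs.rts)
        fh.create_group("meta").attrs["window"] = epochs.window


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        for attr in ("fs", "t0", "dt"):
            if attr not in fh.attrs:
                raise SchemaError(f"missing required attribute '{attr}'")
        fs = float(fh.attrs["fs"])
        t0 = float(fh.attrs["t0"])
        if abs(float(fh.attrs["dt"]) - 1.0 / fs) > 1e-12:
            raise SchemaError("attribute 'dt' inconsistent with 'fs'")
        if "channels" not in fh:
            raise SchemaError("missing group 'channels'")
        if "order" in fh["channels"].attrs:
            names = tuple(str(n) for n in fh["channels"].attrs["order"])
        else:  # fall back to HDF5 (alphabetical) iteration order
            names = tuple(fh["channels"].keys())
        if not names:
            raise SchemaError("group 'channels' is empty")
        missing = [n for n in names if n not in fh["channels"]]
        if missing:
            raise SchemaError(f"missing group 'channels/{missing[0]}'")
        arrays = []
        for name in names:
            if "data" not in fh["channels"][name]:
                raise SchemaError(f"missing dataset 'channels/{name}/data'")
            arrays.append(np.asarray(fh["channels"][name]["data"]))
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise SchemaError("channel data shapes differ")
        data = np.stack(arrays, axis=1)
        rts = None
        if "trials" in fh and "rt_ms" in fh["trials"]:
            rts = np.asarray(fh["trials"]["rt_ms"])
            if rts.shape != (data.shape[0],):
                raise SchemaError("'trials/rt_ms' length does not match trials")
        if "meta" not in fh or "window" not in fh["meta"].attrs:
            raise SchemaError("missing attribute 'meta/window'")
        window = str(fh["meta"].attrs["window"])
    return EpochSet(data=data, fs=fs, t0=t0, ch_names=names,
                    window=window, rts=rts)
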