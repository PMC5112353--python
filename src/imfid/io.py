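"""Readers and writers for the package's on-disk containers.

Two formats are supported for channels x samples matrices: a delimited-text
layout (one channel per row, a ``# fs=...`` header) and an HDF5 container
with a ``data`` dataset plus ``fs`` / ``channel_names`` / ``noise_rows``
attributes.  Decompositions and trial sets use the same HDF5 container with
extra datasets.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .csp import TrialSet
from .identify import InformativeMask
from .memd import IMFDecomposition, SiftConfig
from .signals import MultichannelSignal

__all__ = ["save_signal", "load_signal", "save_signal_text", "load_signal_text",
           "save_decomposition", "load_decomposition", "save_trials",
           "load_trials", "save_mask_json", "load_mask_json"]


def save_signal_text(path, signal: MultichannelSignal) -> None:
    header = f"fs={signal.fs}"
    if signal.channel_names:
        header += " channels=" + ",".join(signal.channel_names)
    if signal.noise_rows:
        header += " noise_rows=" + ",".join(map(str, signal.noise_rows))
    np.savetxt(path, signal.data, header=header)


def load_signal_text(path) -> MultichannelSignal:
    fs, names, noise_rows = None, None, []
    with open(path) as fh:
        first = fh.readline()
    for tok in first.lstrip("# ").split():
        if tok.startswith("fs="):
            fs = float(tok[3:])
        elif tok.startswith("channels="):
            names = tok[9:].split(",")
        elif tok.startswith("noise_rows="):
            noise_rows = [int(x) for x in tok[11:].split(",") if x]
    if fs is None:
        raise ValueError(f"{path}: missing 'fs=' header")
    data = np.loadtxt(path)
    return MultichannelSignal(np.atleast_2d(data), fs=fs, channel_names=names,
                              noise_rows=noise_rows)


def save_signal(path, signal: MultichannelSignal) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=signal.data)
        f.attrs["fs"] = signal.fs
        if signal.channel_names:
            f.attrs["channel_names"] = signal.channel_names
        f.attrs["noise_rows"] = signal.noise_rows


def load_signal(path) -> MultichannelSignal:
    with h5py.File(path, "r") as f:
        names = f.attrs.get("channel_names")
        return MultichannelSignal(
            f["data"][()], fs=float(f.attrs["fs"]),
            channel_names=list(names) if names is not None else None,
            noise_rows=[int(i) for i in f.attrs.get("noise_rows", [])],
        )


def save_decomposition(path, decomp: IMFDecomposition) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("imfs", data=decomp.imfs)
        f.create_dataset("residual", data=decomp.residual)
        f.attrs["fs"] = decomp.fs
        f.attrs["noise_rows"] = decomp.noise_rows
        for k in ("kappa", "tau", "gamma", "max_sift_iters"):
            f.attrs[k] = getattr(decomp.config, k)
        f.attrs["max_imfs"] = decomp.config.max_imfs or 0


def load_decomposition(path) -> IMFDecomposition:
    with h5py.File(path, "r") as f:
        cfg = SiftConfig(
            kappa=int(f.attrs["kappa"]), tau=int(f.attrs["tau"]),
            gamma=float(f.attrs["gamma"]),
            max_sift_iters=int(f.attrs["max_sift_iters"]),
            max_imfs=int(f.attrs["max_imfs"]) or None,
        )
        return IMFDecomposition(
            imfs=f["imfs"][()], residual=f["residual"][()],
            fs=float(f.attrs["fs"]), config=cfg,
            noise_rows=[int(i) for i in f.attrs.get("noise_rows", [])],
        )


def save_trials(path, trials: TrialSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("trials", data=trials.trials)
        f.create_dataset("labels", data=trials.labels)
        f.attrs["fs"] = trials.fs


def load_trials(path) -> TrialSet:
    with h5py.File(path, "r") as f:
        return TrialSet(f["trials"][()], f["labels"][()], fs=float(f.attrs["fs"]))


def save_mask_json(path, mask: InformativeMask) -> None:
    Path(path).write_text(json.dumps(mask.to_json_dict(), indent=1))


def load_mask_json(path) -> InformativeMask:
    d = json.loads(Path(path).read_text())
    return InformativeMask(mask=np.asarray(d["mask"], dtype=bool))
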