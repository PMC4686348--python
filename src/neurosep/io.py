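"""CSV / YAML / HDF5 input-output.

Evoked-count trains use one CSV per culture named ``x(t)_<label>_<k>.csv``
with columns ``trial, event, u1, u2, x_1 .. x_<n_elec>`` (one row per
stimulation event).  Conditional-mean and KLD transients use long-format
CSVs ``x_u_<label>.csv`` (culture, electrode, trial, x_00, x_10, x_01,
x_11) and ``kld_<label>.csv`` (culture, electrode, trial, kld).  Trains
stored for a sparse subset of trials (e.g. every 10th) read back as arrays
with NaN-filled missing trials.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import EvokedCounts

__all__ = [
    "counts_filename",
    "write_counts_csv",
    "read_counts_csv",
    "write_xu_csv",
    "read_xu_csv",
    "write_kld_csv",
    "read_kld_csv",
    "save_config",
    "load_config",
    "write_trace_h5",
    "read_trace_h5",
]


def counts_filename(label: str, culture: int) -> str:
    return f"x(t)_{label}_{culture}.csv"


def write_counts_csv(path, counts: EvokedCounts, u: np.ndarray, trials=None) -> None:
    """Write a per-culture evoked-count train.

    ``trials`` optionally restricts the stored trials (1-based numbers,
    e.g. ``range(1, 100, 10)`` for the sparse layout).
    """
    c = counts.counts
    n_elec, n_trials, n_events = c.shape
    trials = list(range(1, n_trials + 1)) if trials is None else list(trials)
    rows = []
    for tr in trials:
        block = pd.DataFrame(
            c[:, tr - 1, :].T, columns=[f"x_{i + 1}" for i in range(n_elec)]
        )
        block.insert(0, "u2", u[1])
        block.insert(0, "u1", u[0])
        block.insert(0, "event", np.arange(1, n_events + 1))
        block.insert(0, "trial", tr)
        rows.append(block)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_counts_csv(path) -> tuple[EvokedCounts, np.ndarray]:
    """Read a count train; missing trials come back as NaN slices."""
    df = pd.read_csv(path)
    required = {"trial", "event", "u1", "u2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count CSV is missing column(s): {sorted(missing)}")
    elec_cols = [c for c in df.columns if c.startswith("x_")]
    if not elec_cols:
        raise ValueError("count CSV has no electrode columns (x_1, x_2, ...)")
    elec_cols = sorted(elec_cols, key=lambda c: int(c.split("_")[1]))
    trials_present = np.sort(df["trial"].unique())
    n_events = int(df["event"].max())
    n_trials = int(trials_present.max())
    counts = np.full((len(elec_cols), n_trials, n_events), np.nan)
    for tr in trials_present:
        block = df[df["trial"] == tr].sort_values("event")
        counts[:, tr - 1, :] = block[elec_cols].to_numpy().T
    first = df[df["trial"] == trials_present[0]].sort_values("event")
    u = first[["u1", "u2"]].to_numpy().T.astype(np.int8)
    return (
        EvokedCounts(counts=counts, trials=trials_present),
        u,
    )


def write_xu_csv(path, frames: dict[int, np.ndarray]) -> None:
    """Conditional-mean transients; ``frames[culture] = x_u`` arrays."""
    rows = []
    for culture, x_u in frames.items():
        n_elec, n_trials, _ = x_u.shape
        idx = pd.MultiIndex.from_product(
            [range(1, n_elec + 1), range(1, n_trials + 1)],
            names=["electrode", "trial"],
        )
        df = pd.DataFrame(
            x_u.reshape(-1, 4), index=idx, columns=["x_00", "x_10", "x_01", "x_11"]
        ).reset_index()
        df.insert(0, "culture", culture)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_xu_csv(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for culture, g in df.groupby("culture"):
        n_elec = int(g["electrode"].max())
        n_trials = int(g["trial"].max())
        arr = np.full((n_elec, n_trials, 4), np.nan)
        e = g["electrode"].to_numpy() - 1
        t = g["trial"].to_numpy() - 1
        arr[e, t] = g[["x_00", "x_10", "x_01", "x_11"]].to_numpy()
        out[int(culture)] = arr
    return out


def write_kld_csv(path, frames: dict[int, np.ndarray]) -> None:
    """KLD transients; ``frames[culture]`` is (n_elec, n_trials)."""
    rows = []
    for culture, d in frames.items():
        n_elec, n_trials = d.shape
        idx = pd.MultiIndex.from_product(
            [range(1, n_elec + 1), range(1, n_trials + 1)],
            names=["electrode", "trial"],
        )
        df = pd.DataFrame({"kld": d.ravel()}, index=idx).reset_index()
        df.insert(0, "culture", culture)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_kld_csv(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    out = {}
    for culture, g in df.groupby("culture"):
        n_elec = int(g["electrode"].max())
        n_trials = int(g["trial"].max())
        arr = np.full((n_elec, n_trials), np.nan)
        arr[g["electrode"] - 1, g["trial"] - 1] = g["kld"].to_numpy()
        out[int(culture)] = arr
    return out


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {
            (",".join(map(str, k)) if isinstance(k, tuple) else k): _to_plain(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(path, config) -> None:
    """Serialize a (nested-dataclass) config to YAML, keys = field names."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def load_config(path) -> dict:
    """Load a YAML config as a plain dict (builders live in pipeline)."""
    return yaml.safe_load(Path(path).read_text())


def write_trace_h5(path, traces, stim_times_ms: np.ndarray, fs: float = 25_000.0) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=np.atleast_2d(np.asarray(traces)))
        f.create_dataset("stim_times_ms", data=np.asarray(stim_times_ms))
        f.attrs["fs"] = fs


def read_trace_h5(path):
    import h5py

    from .simulate import VoltageTrace

    with h5py.File(path, "r") as f:
        return VoltageTrace(
            samples=f["samples"][...],
            stim_times=f["stim_times_ms"][...],
            fs=float(f.attrs["fs"]),
        )
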