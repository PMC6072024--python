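"""Buffered simulation recorders and per-rank output merging.

Each recorder keeps an in-memory block per logical rank and appends it to
that rank's temporary HDF5 file every ``buffer_steps`` steps, so a running
simulation can be monitored by reading the flushed prefix and long runs do
not accumulate results in RAM.  At the end of a run the per-rank files are
combined into one final file:

* spikes        — concatenated and sorted by (time, gid);
* somatic voltage — columns concatenated, ordered by gid;
* extracellular — summed elementwise (each rank holds the contributions of
  its own cells; superposition makes the sum exact).

Temporary files are deleted after a successful merge.  Final content is
independent of both the buffer size and the rank count.
"""

from __future__ import annotations

import os
from typing import Dict, List, Optional, Sequence

import h5py
import numpy as np

__all__ = [
    "SpikeRecorder", "VoltageRecorder", "LFPRecorder",
    "merge_spike_files", "merge_voltage_files", "merge_lfp_files",
]


def _require(paths: Sequence[str]) -> None:
    missing = [i for i, p in enumerate(paths) if not os.path.exists(p)]
    if missing:
        raise FileNotFoundError(
            f"missing rank output file(s) for rank(s) {missing}")


# ------------------------------------------------------------------- merging

def merge_spike_files(rank_files: Sequence[str], out_path: str,
                      csv_path: Optional[str] = None) -> str:
    """Merge per-rank spike files into one, sorted by (time, gid)."""
    _require(rank_files)
    times, gids = [], []
    for p in rank_files:
        with h5py.File(p, "r") as f:
            times.append(np.asarray(f["timestamps"], dtype=float))
            gids.append(np.asarray(f["gids"], dtype=np.int64))
    t = np.concatenate(times) if times else np.zeros(0)
    g = np.concatenate(gids) if gids else np.zeros(0, dtype=np.int64)
    order = np.lexsort((g, t))
    with h5py.File(out_path, "w") as f:
        f.create_dataset("timestamps", data=t[order])
        f.create_dataset("gids", data=g[order])
    if csv_path:
        np.savetxt(csv_path, np.column_stack([t[order], g[order]]),
                   fmt=("%.6f", "%d"), delimiter=",",
                   header="timestamps,gids", comments="")
    return out_path


def merge_voltage_files(rank_files: Sequence[str], out_path: str) -> str:
    """Concatenate per-rank voltage blocks; final columns ordered by gid."""
    _require(rank_files)
    blocks, gid_lists, time = [], [], None
    for p in rank_files:
        with h5py.File(p, "r") as f:
            blocks.append(np.asarray(f["data"], dtype=float))
            gid_lists.append(np.asarray(f["gids"], dtype=np.int64))
            time = np.asarray(f["time"], dtype=float)
    gids = np.concatenate(gid_lists)
    data = np.concatenate(blocks, axis=1) if blocks else np.zeros((0, 0))
    order = np.argsort(gids)
    with h5py.File(out_path, "w") as f:
        f.create_dataset("data", data=data[:, order])
        f.create_dataset("gids", data=gids[order])
        f.create_dataset("time", data=time)
    return out_path


def merge_lfp_files(rank_files: Sequence[str], out_path: str) -> str:
    """Sum per-rank extracellular contributions elementwise."""
    _require(rank_files)
    total, time, ids = None, None, None
    for p in rank_files:
        with h5py.File(p, "r") as f:
            block = np.asarray(f["data"], dtype=float)
            total = block if total is None else total + block
            time = np.asarray(f["time"], dtype=float)
            ids = np.asarray(f["electrode_id"], dtype=np.int64)
    with h5py.File(out_path, "w") as f:
        f.create_dataset("data", data=total)
        f.create_dataset("electrode_id", data=ids)
        f.create_dataset("time", data=time)
    return out_path


# ----------------------------------------------------------------- recorders

class _RankFile:
    """Appendable per-rank HDF5 temp file with named resizable datasets."""

    def __init__(self, path: str, shapes: Dict[str, int],
                 dtypes: Dict[str, type]):
        self.path = path
        self._f = h5py.File(path, "w")
        self._ds = {}
        for name, width in shapes.items():
            shape = (0,) if width is None else (0, width)
            maxshape = (None,) if width is None else (None, width)
            self._ds[name] = self._f.create_dataset(
                name, shape=shape, maxshape=maxshape,
                dtype=dtypes.get(name, float))

    def append(self, name: str, rows: np.ndarray) -> None:
        ds = self._ds[name]
        n0 = ds.shape[0]
        ds.resize(n0 + len(rows), axis=0)
        ds[n0:] = rows

    def set_static(self, name: str, data: np.ndarray) -> None:
        self._f.create_dataset(name, data=data)

    def flush(self) -> None:
        self._f.flush()

    def close(self) -> None:
        self._f.close()


class SpikeRecorder:
    """Per-rank buffered spike recorder; one merged file at the end."""

    def __init__(self, output_dir: str, file_name: str, n_ranks: int,
                 buffer_steps: int, csv_export: bool = False):
        self.output_dir = output_dir
        self.file_name = file_name
        self.n_ranks = n_ranks
        self.buffer_steps = buffer_steps
        self.csv_export = csv_export
        self._buf: List[List] = []
        self._files: List[_RankFile] = []

    def rank_path(self, rank: int) -> str:
        return os.path.join(self.output_dir,
                            f"tmp-rank{rank}-{self.file_name}")

    def begin(self) -> None:
        os.makedirs(self.output_dir, exist_ok=True)
        self._buf = [[] for _ in range(self.n_ranks)]
        self._files = [
            _RankFile(self.rank_path(r),
                      {"timestamps": None, "gids": None},
                      {"gids": np.int64})
            for r in range(self.n_ranks)]

    def record(self, rank: int, time_ms: float, gid: int) -> None:
        self._buf[rank].append((time_ms, gid))

    def step_end(self, step: int) -> None:
        if step % self.buffer_steps == 0:
            self._flush()

    def _flush(self) -> None:
        for rank, buf in enumerate(self._buf):
            if not buf:
                continue
            arr = np.asarray(buf, dtype=float)
            self._files[rank].append("timestamps", arr[:, 0])
            self._files[rank].append("gids", arr[:, 1].astype(np.int64))
            self._files[rank].flush()
            buf.clear()

    def end(self) -> str:
        self._flush()
        for f in self._files:
            f.close()
        paths = [self.rank_path(r) for r in range(self.n_ranks)]
        out = os.path.join(self.output_dir, self.file_name)
        csv = (os.path.splitext(out)[0] + ".csv") if self.csv_export else None
        merge_spike_files(paths, out, csv)
        for p in paths:
            os.remove(p)
        return out


class VoltageRecorder:
    """Buffered somatic-voltage recorder (time × gid columns)."""

    def __init__(self, output_dir: str, file_name: str, n_ranks: int,
                 buffer_steps: int, gids_by_rank: List[np.ndarray],
                 dt: float):
        self.output_dir = output_dir
        self.file_name = file_name
        self.n_ranks = n_ranks
        self.buffer_steps = buffer_steps
        self.gids_by_rank = [np.asarray(g, dtype=np.int64)
                             for g in gids_by_rank]
        self._col = [
            {int(g): i for i, g in enumerate(gs)} for gs in self.gids_by_rank]
        self.dt = dt
        self._buf: List[List[np.ndarray]] = []
        self._row: List[np.ndarray] = []
        self._times: List[List[float]] = []
        self._files: List[_RankFile] = []

    def rank_path(self, rank: int) -> str:
        return os.path.join(self.output_dir,
                            f"tmp-rank{rank}-{self.file_name}")

    def begin(self) -> None:
        os.makedirs(self.output_dir, exist_ok=True)
        self._buf = [[] for _ in range(self.n_ranks)]
        self._times = [[] for _ in range(self.n_ranks)]
        self._row = [np.zeros(len(g)) for g in self.gids_by_rank]
        self._files = []
        for r in range(self.n_ranks):
            f = _RankFile(self.rank_path(r),
                          {"data": len(self.gids_by_rank[r])}, {})
            f.set_static("gids", self.gids_by_rank[r])
            self._files.append(f)

    def record(self, rank: int, gid: int, value: float) -> None:
        self._row[rank][self._col[rank][gid]] = value

    def step_end(self, step: int) -> None:
        for rank in range(self.n_ranks):
            self._buf[rank].append(self._row[rank].copy())
            self._times[rank].append(step * self.dt)
        if step % self.buffer_steps == 0:
            self._flush()

    def _flush(self) -> None:
        for rank in range(self.n_ranks):
            if not self._buf[rank]:
                continue
            self._files[rank].append(
                "data", np.asarray(self._buf[rank]))
            self._buf[rank].clear()
            self._files[rank].flush()

    def end(self) -> str:
        self._flush()
        # the time vector is identical on every rank
        for r in range(self.n_ranks):
            self._files[r].set_static(
                "time", np.asarray(self._times[r]))
            self._files[r].close()
        paths = [self.rank_path(r) for r in range(self.n_ranks)]
        out = os.path.join(self.output_dir, self.file_name)
        merge_voltage_files(paths, out)
        for p in paths:
            os.remove(p)
        return out


class LFPRecorder:
    """Buffered extracellular-potential recorder (time × electrode site).

    Each rank accumulates the ``R @ I`` contributions of the cells it
    hosts; ranks are summed at merge time.
    """

    def __init__(self, output_dir: str, file_name: str, n_ranks: int,
                 buffer_steps: int, electrode_ids: np.ndarray, dt: float):
        self.output_dir = output_dir
        self.file_name = file_name
        self.n_ranks = n_ranks
        self.buffer_steps = buffer_steps
        self.electrode_ids = np.asarray(electrode_ids, dtype=np.int64)
        self.n_sites = len(self.electrode_ids)
        self.dt = dt
        self._phi: List[np.ndarray] = []
        self._buf: List[List[np.ndarray]] = []
        self._times: List[float] = []
        self._files: List[_RankFile] = []

    def rank_path(self, rank: int) -> str:
        return os.path.join(self.output_dir,
                            f"tmp-rank{rank}-{self.file_name}")

    def begin(self) -> None:
        os.makedirs(self.output_dir, exist_ok=True)
        self._phi = [np.zeros(self.n_sites) for _ in range(self.n_ranks)]
        self._buf = [[] for _ in range(self.n_ranks)]
        self._times = []
        self._files = []
        for r in range(self.n_ranks):
            f = _RankFile(self.rank_path(r), {"data": self.n_sites}, {})
            f.set_static("electrode_id", self.electrode_ids)
            self._files.append(f)

    def phi(self, rank: int) -> np.ndarray:
        """The mutable per-site accumulator for this rank and step."""
        return self._phi[rank]

    def step_end(self, step: int) -> None:
        self._times.append(step * self.dt)
        for rank in range(self.n_ranks):
            self._buf[rank].append(self._phi[rank].copy())
            self._phi[rank][:] = 0.0
        if step % self.buffer_steps == 0:
            self._flush()

    def _flush(self) -> None:
        for rank in range(self.n_ranks):
            if not self._buf[rank]:
                continue
            self._files[rank].append("data", np.asarray(self._buf[rank]))
            self._buf[rank].clear()
            self._files[rank].flush()

    def end(self) -> str:
        self._flush()
        for r in range(self.n_ranks):
            self._files[r].set_static("time", np.asarray(self._times))
            self._files[r].close()
        paths = [self.rank_path(r) for r in range(self.n_ranks)]
        out = os.path.join(self.output_dir, self.file_name)
        merge_lfp_files(paths, out)
        for p in paths:
            os.remove(p)
        return out
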