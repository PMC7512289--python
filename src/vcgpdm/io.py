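"""Trajectory tables, column-to-part maps, and plain-text configuration.

Trajectories are delimited-text tables, one row per frame and one column per
degree of freedom (joint angle, marker coordinate, ...).  A column map assigns
every column to one body part, written as ``"part:start-end"`` ranges, e.g.
``"0:0-29,1:30-59"`` for a two-part split of 60 columns (ranges inclusive).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectorySet",
    "parse_column_map",
    "format_column_map",
    "read_trajectories",
    "write_trajectory",
    "read_config",
    "write_config",
]


@dataclass
class TrajectorySet:
    """One or more observed sequences sharing columns and a column map.

    ``sequences``: list of (T_n, D) float arrays;
    ``column_map``: (D,) int array, part index per column;
    ``names``: optional column names; ``rate``: optional sampling rate (Hz).
    """

    sequences: list
    column_map: np.ndarray
    names: list | None = None
    rate: float | None = None

    def __post_init__(self) -> None:
        self.sequences = [np.atleast_2d(np.asarray(s, dtype=float)) for s in self.sequences]
        if not self.sequences:
            raise ValueError("need at least one sequence")
        D = self.sequences[0].shape[1]
        for s in self.sequences:
            if s.shape[1] != D:
                raise ValueError("all sequences must share the column count")
            if s.shape[0] < 1:
                raise ValueError("empty sequence")
        self.column_map = np.asarray(self.column_map, dtype=int)
        if self.column_map.shape != (D,):
            raise ValueError("column_map must assign every column exactly once")
        parts = np.unique(self.column_map)
        if not np.array_equal(parts, np.arange(parts.size)):
            raise ValueError("part indices must be 0..M-1")

    @property
    def n_parts(self) -> int:
        return int(self.column_map.max()) + 1

    @property
    def D(self) -> int:
        return int(self.column_map.shape[0])

    @property
    def lengths(self) -> list:
        return [s.shape[0] for s in self.sequences]

    def part_columns(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.column_map == i)

    def part_data(self, i: int) -> list:
        cols = self.part_columns(i)
        return [s[:, cols] for s in self.sequences]

    def stacked(self) -> np.ndarray:
        return np.vstack(self.sequences)

    def subset(self, idx) -> "TrajectorySet":
        return TrajectorySet(
            [self.sequences[k] for k in idx], self.column_map, self.names, self.rate
        )


def parse_column_map(spec: str, n_columns: int) -> np.ndarray:
    """Parse ``"0:0-1,1:2-3"`` into a per-column part index array."""
    cmap = np.full(n_columns, -1, dtype=int)
    for chunk in spec.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            part_s, rng = chunk.split(":")
            part = int(part_s)
            if "-" in rng:
                lo_s, hi_s = rng.split("-")
                lo, hi = int(lo_s), int(hi_s)
            else:
                lo = hi = int(rng)
        except ValueError as err:
            raise ValueError(f"malformed column-map chunk {chunk!r}") from err
        if not (0 <= lo <= hi < n_columns):
            raise ValueError(f"column range {lo}-{hi} out of bounds for D={n_columns}")
        cmap[lo : hi + 1] = part
    if np.any(cmap < 0):
        missing = np.flatnonzero(cmap < 0)
        raise ValueError(f"columns {missing.tolist()} not assigned to any part")
    return cmap


def format_column_map(column_map: np.ndarray) -> str:
    cmap = np.asarray(column_map, dtype=int)
    chunks = []
    start = 0
    for i in range(1, cmap.size + 1):
        if i == cmap.size or cmap[i] != cmap[start]:
            chunks.append(f"{cmap[start]}:{start}-{i - 1}")
            start = i
    return ",".join(chunks)


def _read_table(path) -> tuple[np.ndarray, list | None]:
    with open(path, "r") as fh:
        text = fh.read()
    first = text.splitlines()[0] if text.strip() else ""
    sep = "\t" if "\t" in first else ","
    # header auto-detection: a first row with any non-numeric cell is a header
    tokens = [t for t in first.replace(sep, " ").split() if t]
    has_header = False
    for t in tokens:
        try:
            float(t)
        except ValueError:
            has_header = True
            break
    df = pd.read_csv(
        _io.StringIO(text), sep=sep, header=0 if has_header else None,
        skipinitialspace=True, float_precision="round_trip",
    )
    bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = int(pd.to_numeric(df[col], errors="coerce").isna().idxmax())
        raise ValueError(f"non-numeric cell in {path} (column {col!r}, row {row})")
    names = [str(c) for c in df.columns] if has_header else None
    return df.to_numpy(dtype=float), names


def read_trajectories(paths, column_map_spec: str | np.ndarray) -> TrajectorySet:
    """Read one or more delimited-text trajectory files into a TrajectorySet."""
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    seqs, names = [], None
    for p in paths:
        arr, nm = _read_table(p)
        if seqs and arr.shape[1] != seqs[0].shape[1]:
            raise ValueError(
                f"{p} has {arr.shape[1]} columns, expected {seqs[0].shape[1]}"
            )
        seqs.append(arr)
        names = names or nm
    D = seqs[0].shape[1]
    if isinstance(column_map_spec, str):
        cmap = parse_column_map(column_map_spec, D)
    else:
        cmap = np.asarray(column_map_spec, dtype=int)
    return TrajectorySet(seqs, cmap, names=names)


def write_trajectory(path, array: np.ndarray, names: list | None = None) -> None:
    """Write one sequence as comma-separated text at full float precision."""
    df = pd.DataFrame(np.atleast_2d(array))
    if names is not None:
        df.columns = names
    df.to_csv(path, index=False, header=names is not None,
              float_format="%.17g")


def read_config(path) -> dict:
    """Plain ``key = value`` config file; values parsed as int/float/str."""
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            for cast in (int, float):
                try:
                    out[key] = cast(val)
                    break
                except ValueError:
                    continue
            else:
                out[key] = val
    return out


def write_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        for k, v in cfg.items():
            fh.write(f"{k} = {v}\n")
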