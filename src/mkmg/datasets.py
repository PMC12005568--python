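"""Bundled benchmark datasets and plain-text sample readers.

Seven small, widely analyzed benchmark datasets ship with the package as
CSV fixtures (one ``value`` column): bank waiting times (n=100), annual
maximum flood levels of the Susquehanna River (n=20), bladder-cancer
remission times (n=128), county vehicle fatalities (n=39), times between
failures of a repairable item (n=30), mathematics exam marks (n=48), and
national infant mortality rates per 1000 live births (n=26).

Count-valued datasets are stored and returned as integers even where the
continuous analysis uses them (the vehicle-fatalities data are fit as
continuous with the MPS tie rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["NamedDataset", "DATASETS", "load", "read_sample"]


@dataclass(frozen=True)
class NamedDataset:
    key: str
    values: np.ndarray
    n: int
    kind: str  # "continuous" | "count"
    note: str


_META = {
    "waiting_times": ("continuous", "waiting times (minutes) before service of 100 bank customers"),
    "flood_levels": ("continuous", "annual maximum flood levels, Susquehanna River at Harrisburg, 20 years"),
    "cancer_remission": ("continuous", "remission times (months) for 128 bladder cancer patients"),
    "vehicle_fatalities": ("count", "vehicle fatalities in 39 South Carolina counties, 2012"),
    "failure_times": ("continuous", "time between failures for 30 repairable items"),
    "exam_marks": ("count", "final mathematics exam marks of 48 slow-pace students"),
    "infant_mortality": ("count", "infant mortality rate per 1000 live births, 26 nations, 2021"),
}

DATASETS = tuple(_META)


def load(key: str) -> NamedDataset:
    """Load a bundled dataset by key; see :data:`DATASETS` for the keys."""
    if key not in _META:
        raise KeyError(f"unknown dataset {key!r}; choose from {DATASETS}")
    kind, note = _META[key]
    path = resources.files("mkmg").joinpath(f"data/{key}.csv")
    with path.open("r") as fh:
        values = _parse_stream(fh, kind)
    return NamedDataset(key=key, values=values, n=values.size, kind=kind, note=note)


def _parse_stream(fh, kind: str) -> np.ndarray:
    values = []
    for lineno, line in enumerate(fh, start=1):
        token = line.strip()
        if not token:
            continue
        if lineno == 1:
            try:
                float(token)
            except ValueError:
                continue  # header line
        try:
            v = float(token)
        except ValueError:
            raise ValueError(f"unparseable record on line {lineno}: {token!r}") from None
        values.append(v)
    arr = np.asarray(values, dtype=float)
    if kind == "continuous":
        if np.any(arr <= 0):
            raise ValueError("continuous data must be strictly positive")
    elif kind == "count":
        if np.any(arr < 0) or np.any(np.floor(arr) != arr):
            raise ValueError("count data must be nonnegative integers")
        arr = arr.astype(np.int64)
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return arr


def read_sample(path, kind: str = "continuous") -> np.ndarray:
    """Read a one-value-per-line text/CSV sample, validated per ``kind``.

    A single non-numeric header line is tolerated and skipped.
    """
    with open(path) as fh:
        return _parse_stream(fh, kind)
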