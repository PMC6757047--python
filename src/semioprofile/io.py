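"""Text I/O for peak lists, sample metadata and contaminant lists.

All on-disk formats are plain tab-separated text so that pipelines remain
inspectable with standard shell tools.  A peak-list file holds one row per
peak with its fragment spectrum packed as ``m1:i1;m2:i2;...``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Peak",
    "PeakList",
    "ContaminantEntry",
    "read_peak_lists",
    "write_peak_lists",
    "read_metadata",
    "write_metadata",
    "read_contaminants",
    "write_contaminants",
]


@dataclass
class Peak:
    """One deconvoluted chromatographic peak.

    Parameters
    ----------
    sample_id : str
        Sample the peak was observed in.
    rt : float
        Retention time in minutes (> 0).
    area : float
        Integrated peak area in arbitrary intensity units (>= 0).
    spectrum : dict
        Mapping fragment m/z (int, nominally 30-300) -> intensity.
    """

    sample_id: str
    rt: float
    area: float
    spectrum: dict[int, float]

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValueError(f"peak retention time must be positive, got {self.rt}")
        if self.area < 0:
            raise ValueError(f"peak area must be nonnegative, got {self.area}")
        if not self.spectrum:
            raise ValueError("peak spectrum must be non-empty")


@dataclass
class PeakList:
    """All peaks of one sample, kept sorted by retention time."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.rt)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class ContaminantEntry:
    """A known contamination: an RT window plus characteristic fragments."""

    rt_low: float
    rt_high: float
    mzs: frozenset[int]

    def __post_init__(self) -> None:
        if self.rt_low > self.rt_high:
            raise ValueError("contaminant window has rt_low > rt_high")
        if not self.mzs:
            raise ValueError("contaminant entry needs at least one characteristic m/z")


def _pack_spectrum(spectrum: Mapping[int, float]) -> str:
    return ";".join(f"{int(mz)}:{inten:.6g}" for mz, inten in sorted(spectrum.items()))


def _unpack_spectrum(text: str) -> dict[int, float]:
    out: dict[int, float] = {}
    for part in text.split(";"):
        mz, inten = part.split(":")
        out[int(mz)] = float(inten)
    return out


def write_peak_lists(peaklists: Mapping[str, PeakList], path: str | Path) -> None:
    """Write peak lists to one TSV (sample_id, rt_min, area, mz_list)."""
    rows = []
    for sid in peaklists:
        for p in peaklists[sid]:
            rows.append((sid, f"{p.rt:.6f}", f"{p.area:.6g}", _pack_spectrum(p.spectrum)))
    df = pd.DataFrame(rows, columns=["sample_id", "rt_min", "area", "mz_list"])
    df.to_csv(path, sep="\t", index=False)


def read_peak_lists(path: str | Path) -> dict[str, PeakList]:
    """Read a peak-list TSV (or CSV with the same columns) back into memory."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    out: dict[str, list[Peak]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample_id, []).append(
            Peak(row.sample_id, float(row.rt_min), float(row.area), _unpack_spectrum(row.mz_list))
        )
    return {sid: PeakList(sid, peaks) for sid, peaks in out.items()}


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def write_contaminants(entries: Iterable[ContaminantEntry], path: str | Path) -> None:
    """Write a contaminant list as CSV (rt_low, rt_high, mz_list)."""
    rows = [
        (e.rt_low, e.rt_high, ";".join(str(m) for m in sorted(e.mzs))) for e in entries
    ]
    pd.DataFrame(rows, columns=["rt_low", "rt_high", "mz_list"]).to_csv(path, index=False)


def read_contaminants(path: str | Path) -> list[ContaminantEntry]:
    df = pd.read_csv(path)
    return [
        ContaminantEntry(
            float(r.rt_low),
            float(r.rt_high),
            frozenset(int(m) for m in str(r.mz_list).split(";")),
        )
        for r in df.itertuples(index=False)
    ]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
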