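"""Exclusion filters, relative peak areas and response transforms.

Filter order follows the analytical narrative: known contaminants first
(RT window + characteristic m/z match), then the blank comparison on raw
areas (a substance is excluded when the blank-sample statistic equals or
exceeds the animal-sample statistic — ties go to exclusion).  Blanks are
excluded from all downstream statistics once the blank filter has run.
Relative areas are percentages of each sample's total included area, so
rows sum to 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

from .io import ContaminantEntry
from .peak_alignment import AlignedTable

__all__ = [
    "RelativeAreaTable",
    "TransformedResponse",
    "remove_contaminants",
    "blank_filter",
    "relative_areas",
    "transform_response",
    "preprocess",
]

TRANSFORM_MODES = ("normalised", "log_arcsine", "log1p")


@dataclass
class RelativeAreaTable:
    """Percent-normalised substance matrix with filter provenance."""

    rel: pd.DataFrame  # index sample_id, columns substance/range id, percent
    provenance: dict[str, int] = field(default_factory=dict)

    @property
    def n_substances(self) -> int:
        return self.rel.shape[1]


@dataclass
class TransformedResponse:
    """Response matrix under one of the model transforms."""

    y: pd.DataFrame
    mode: str


def remove_contaminants(
    table: AlignedTable, contaminants: Iterable[ContaminantEntry]
) -> AlignedTable:
    """Drop ranges matching a known-contaminant entry.

    A range is dropped iff its representative RT falls inside an entry's RT
    window AND its prominent m/z set intersects the entry's characteristic
    m/z.  An empty list is the identity.
    """
    entries = list(contaminants)
    drop: list[str] = []
    for row in table.ranges.itertuples(index=False):
        mzs = {int(m) for m in str(row.prominent_mz).split(";") if m}
        for e in entries:
            if e.rt_low <= row.representative_rt <= e.rt_high and mzs & set(e.mzs):
                drop.append(row.range_id)
                break
    keep = [c for c in table.areas.columns if c not in set(drop)]
    log = list(table.log) + [
        f"contaminant filter: removed {len(drop)} of {table.n_ranges} ranges"
        + (f" ({', '.join(drop)})" if drop else "")
    ]
    return AlignedTable(
        areas=table.areas[keep],
        ranges=table.ranges[table.ranges["range_id"].isin(keep)].reset_index(drop=True),
        log=log,
    )


def blank_filter(
    table: AlignedTable, blank_ids: Sequence[str], statistic: str = "mean"
) -> AlignedTable:
    """Exclude substances whose blank signal equals or exceeds the animal signal.

    Comparison uses raw areas (before relative normalisation) aggregated by
    ``statistic`` (mean or median) over blank vs animal samples.  Blank rows
    are removed from the returned table: they take no further part in the
    statistics.
    """
    blank_ids = [b for b in blank_ids if b in table.areas.index]
    if not blank_ids:
        raise ValueError("blank_filter requires at least one blank sample in the table")
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    agg = getattr(pd.DataFrame, statistic)
    animal_idx = table.areas.index.difference(blank_ids)
    blank_stat = agg(table.areas.loc[blank_ids])
    animal_stat = agg(table.areas.loc[animal_idx])
    drop = list(table.areas.columns[(blank_stat >= animal_stat).to_numpy()])
    keep = [c for c in table.areas.columns if c not in set(drop)]
    log = list(table.log) + [
        f"blank filter ({statistic}): removed {len(drop)} of {table.n_ranges} ranges; "
        f"{len(blank_ids)} blank samples dropped from the table"
    ]
    return AlignedTable(
        areas=table.areas.loc[animal_idx, keep],
        ranges=table.ranges[table.ranges["range_id"].isin(keep)].reset_index(drop=True),
        log=log,
    )


def relative_areas(table: AlignedTable) -> RelativeAreaTable:
    """Per-sample percent areas: 100 * area / sum of included areas."""
    totals = table.areas.sum(axis=1)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} sample(s) have zero total area; rows left all-zero",
            stacklevel=2,
        )
    safe = totals.replace(0, np.nan)
    rel = table.areas.div(safe, axis=0).fillna(0.0) * 100.0
    return RelativeAreaTable(
        rel=rel,
        provenance={"n_samples": rel.shape[0], "n_substances": rel.shape[1]},
    )


def transform_response(rel_table: RelativeAreaTable | pd.DataFrame, mode: str) -> TransformedResponse:
    """Apply one of the three model response transforms.

    ``normalised``: per-substance z-score across samples (sample SD, ddof=1;
    constant columns map to all-zeros with a warning).
    ``log1p``: elementwise ln(x+1).
    ``log_arcsine``: v = ln(x+0.001), linearly rescaled over the whole matrix
    to [-1, 1], then arcsine — one documented reading of a two-step
    "log then arcsine" recipe (log output is negative, outside arcsine's
    domain without rescaling).
    """
    rel = rel_table.rel if isinstance(rel_table, RelativeAreaTable) else rel_table
    if mode == "normalised":
        mean = rel.mean(axis=0)
        sd = rel.std(axis=0, ddof=1)
        const = sd == 0
        if const.any():
            warnings.warn(
                f"{int(const.sum())} constant column(s) set to zero under 'normalised'",
                stacklevel=2,
            )
        y = (rel - mean).div(sd.replace(0, np.nan), axis=1).fillna(0.0)
    elif mode == "log1p":
        y = np.log1p(rel)
    elif mode == "log_arcsine":
        v = np.log(rel + 0.001)
        vmin, vmax = float(v.min().min()), float(v.max().max())
        if vmax == vmin:
            scaled = v * 0.0
        else:
            scaled = 2.0 * (v - vmin) / (vmax - vmin) - 1.0
        y = np.arcsin(scaled)
    else:
        raise ValueError(f"unknown transform mode {mode!r}; expected one of {TRANSFORM_MODES}")
    return TransformedResponse(y=pd.DataFrame(y, index=rel.index, columns=rel.columns), mode=mode)


def preprocess(
    table: AlignedTable,
    contaminants: Iterable[ContaminantEntry] = (),
    blank_ids: Sequence[str] = (),
    blank_statistic: str = "mean",
) -> RelativeAreaTable:
    """Contaminant filter -> blank filter -> relative areas."""
    n0 = table.n_ranges
    table = remove_contaminants(table, contaminants)
    n1 = table.n_ranges
    if blank_ids:
        table = blank_filter(table, blank_ids, blank_statistic)
    n2 = table.n_ranges
    out = relative_areas(table)
    out.provenance.update(
        {
            "ranges_in": n0,
            "removed_contaminants": n0 - n1,
            "removed_blank_filter": n1 - n2,
            "substances_final": n2,
        }
    )
    return out
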