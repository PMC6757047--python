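"""Retention-time alignment of deconvoluted peak lists.

Turns per-sample peak lists into a samples x retention-time-range area
matrix.  A retention-time range is a 1-D gap cluster of peaks across samples
presumed to be one substance, described by a representative RT and a small
set of prominent fragment m/z.  The stage chain is:

1. per-batch RT adjustment (global shift against a reference batch, anchored
   on high-occurrence ranges of a first unadjusted grouping pass),
2. gap-based RT grouping (new range whenever the sorted-RT gap exceeds a
   tolerance; one peak per sample per range, resolved by proximity to the
   range median RT, ties by larger area),
3. occurrence filtering (a range must appear in a minimum number of samples),
4. prominent-mass extraction with an automated spectral-consistency check
   (mean pairwise Jaccard similarity of per-peak top-k fragment sets),
5. quantification over the prominent m/z.

Absent peaks quantify as 0, not missing, because the downstream relative
area divides by the sum over all included ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import Peak, PeakList

__all__ = [
    "RtRange",
    "AlignedTable",
    "adjust_rt_per_batch",
    "group_retention_times",
    "filter_by_occurrence",
    "extract_and_verify_masses",
    "quantify_ranges",
    "align_peak_lists",
]

DEFAULT_GAP_TOL = 0.05  # minutes
DEFAULT_MIN_OCCURRENCE = 14
DEFAULT_TOP_K = 5
DEFAULT_JACCARD_MIN = 0.5


@dataclass
class RtRange:
    """One retention-time range (putative substance) and its member peaks."""

    range_id: str
    rt_low: float
    rt_high: float
    representative_rt: float
    occurrence: int
    members: dict[str, Peak] = field(default_factory=dict)  # sample_id -> peak
    prominent_mz: tuple[int, ...] = ()
    verified: bool = False

    def __post_init__(self) -> None:
        if not (self.rt_low <= self.representative_rt <= self.rt_high):
            raise ValueError("representative RT must lie inside [rt_low, rt_high]")
        if self.occurrence < 1:
            raise ValueError("a range needs at least one member")


@dataclass
class AlignedTable:
    """Samples x ranges area matrix plus per-range metadata."""

    areas: pd.DataFrame  # index sample_id, columns range_id
    ranges: pd.DataFrame  # one row per retained range
    log: list[str] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.areas.shape[0]

    @property
    def n_ranges(self) -> int:
        return self.areas.shape[1]


def _pool_peaks(peaklists: Mapping[str, PeakList]) -> list[Peak]:
    pooled = [p for sid in peaklists for p in peaklists[sid]]
    # sort by (rt, sample, area) so grouping is independent of input order
    pooled.sort(key=lambda p: (p.rt, p.sample_id, p.area))
    return pooled


def group_retention_times(
    peaklists: Mapping[str, PeakList],
    gap_tol: float = DEFAULT_GAP_TOL,
    log: list[str] | None = None,
) -> list[RtRange]:
    """Cluster pooled peaks into retention-time ranges by the gap rule.

    Pooled peaks are sorted by RT; a new range starts whenever the gap to
    the previous peak exceeds ``gap_tol``.  If one sample contributed
    several peaks to a range, the peak closest to the range median RT is
    kept (ties resolved toward the larger area); discards are logged.
    """
    if gap_tol <= 0:
        raise ValueError("gap_tol must be positive")
    log = log if log is not None else []
    pooled = _pool_peaks(peaklists)
    if not pooled:
        return []
    clusters: list[list[Peak]] = [[pooled[0]]]
    for prev, cur in zip(pooled, pooled[1:]):
        if cur.rt - prev.rt > gap_tol:
            clusters.append([cur])
        else:
            clusters[-1].append(cur)
    ranges: list[RtRange] = []
    for i, members in enumerate(clusters):
        med = float(np.median([p.rt for p in members]))
        kept: dict[str, Peak] = {}
        for p in members:
            q = kept.get(p.sample_id)
            if q is None:
                kept[p.sample_id] = p
                continue
            # keep the peak nearer the median; tie -> larger area
            better = (abs(p.rt - med), -p.area) < (abs(q.rt - med), -q.area)
            drop = q if better else p
            if better:
                kept[p.sample_id] = p
            log.append(
                f"range {i + 1}: sample {p.sample_id} contributed several peaks; "
                f"dropped peak at rt={drop.rt:.4f}"
            )
        ranges.append(
            RtRange(
                range_id=f"R{i + 1:04d}",
                rt_low=min(p.rt for p in members),
                rt_high=max(p.rt for p in members),
                representative_rt=med,
                occurrence=len(kept),
                members=kept,
            )
        )
    return ranges


def adjust_rt_per_batch(
    peaklists: Mapping[str, PeakList],
    batch_map: Mapping[str, str],
    reference_batch: str,
    gap_tol: float = DEFAULT_GAP_TOL,
    anchor_min_frac: float = 0.8,
    anchor_gap_tol: float = 0.2,
) -> tuple[dict[str, PeakList], dict[str, float], list[str]]:
    """Shift each batch's RTs onto a reference batch.

    Anchors are ranges (from an unadjusted grouping pass at the coarser
    ``anchor_gap_tol``, so that batch offsets up to that size still land in
    a shared range) present in at least ``anchor_min_frac`` of both the
    batch's and the reference batch's samples; the shift is the negated
    median anchor RT offset.  A batch with no anchors gets shift 0 and a
    warning record.  Returns (shifted peak lists, per-batch shifts, log).
    """
    missing = [s for s in peaklists if s not in batch_map]
    if missing:
        raise ValueError(f"samples missing from batch_map: {missing[:5]}")
    batches = sorted(set(batch_map[s] for s in peaklists))
    if reference_batch not in batches:
        raise ValueError(f"reference batch {reference_batch!r} has no samples")

    log: list[str] = []
    ranges = group_retention_times(peaklists, max(anchor_gap_tol, gap_tol))
    by_batch: dict[str, list[str]] = {b: [] for b in batches}
    for s in peaklists:
        by_batch[batch_map[s]].append(s)

    def batch_rts(rng: RtRange, batch: str) -> list[float]:
        return [p.rt for sid, p in rng.members.items() if batch_map[sid] == batch]

    shifts: dict[str, float] = {}
    for b in batches:
        if b == reference_batch:
            shifts[b] = 0.0
            continue
        offsets = []
        for rng in ranges:
            rts_b = batch_rts(rng, b)
            rts_ref = batch_rts(rng, reference_batch)
            if (
                len(rts_b) >= anchor_min_frac * len(by_batch[b])
                and len(rts_ref) >= anchor_min_frac * len(by_batch[reference_batch])
            ):
                offsets.append(np.median(rts_b) - np.median(rts_ref))
        if offsets:
            shifts[b] = -float(np.median(offsets))
            log.append(f"batch {b}: shift {shifts[b]:+.4f} min from {len(offsets)} anchors")
        else:
            shifts[b] = 0.0
            log.append(f"warning: batch {b} has no anchor matches; shift set to 0")

    shifted: dict[str, PeakList] = {}
    for sid, pl in peaklists.items():
        dt = shifts[batch_map[sid]]
        if dt == 0.0:
            shifted[sid] = pl
        else:
            shifted[sid] = PeakList(
                sid,
                [Peak(p.sample_id, p.rt + dt, p.area, dict(p.spectrum)) for p in pl],
            )
    return shifted, shifts, log


def filter_by_occurrence(
    ranges: Sequence[RtRange],
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
    log: list[str] | None = None,
) -> list[RtRange]:
    """Keep ranges occurring in at least ``min_occurrence`` samples."""
    if min_occurrence < 1:
        raise ValueError("min_occurrence must be >= 1")
    kept = [r for r in ranges if r.occurrence >= min_occurrence]
    if log is not None:
        log.append(
            f"occurrence filter (>= {min_occurrence}): kept {len(kept)} of {len(ranges)} ranges"
        )
    return kept


def _top_k_mz(spectrum: Mapping[int, float], top_k: int) -> frozenset[int]:
    ordered = sorted(spectrum.items(), key=lambda kv: (-kv[1], kv[0]))
    return frozenset(mz for mz, _ in ordered[:top_k])


def extract_and_verify_masses(
    rt_range: RtRange,
    top_k: int = DEFAULT_TOP_K,
    jaccard_min: float = DEFAULT_JACCARD_MIN,
) -> RtRange:
    """Extract the range's prominent m/z and check spectral consistency.

    Prominent m/z are the ``top_k`` fragments by total intensity over member
    peaks.  The range verifies when the mean pairwise Jaccard similarity of
    the members' per-peak top-k fragment sets reaches ``jaccard_min`` — an
    automated surrogate for manual inspection of the mass spectra.  A
    single-member range verifies by convention.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if not 0 <= jaccard_min <= 1:
        raise ValueError("jaccard_min must be in [0, 1]")
    totals: dict[int, float] = {}
    for p in rt_range.members.values():
        for mz, inten in p.spectrum.items():
            totals[mz] = totals.get(mz, 0.0) + inten
    prominent = tuple(sorted(_top_k_mz(totals, top_k)))
    sets = [_top_k_mz(p.spectrum, top_k) for p in rt_range.members.values()]
    if len(sets) < 2:
        verified = True
    else:
        sims = [len(a & b) / len(a | b) for a, b in combinations(sets, 2)]
        verified = float(np.mean(sims)) >= jaccard_min
    return replace(rt_range, prominent_mz=prominent, verified=verified)


def quantify_ranges(
    peaklists: Mapping[str, PeakList],
    ranges: Sequence[RtRange],
    sample_ids: Sequence[str] | None = None,
) -> AlignedTable:
    """Quantify each (sample, range) cell over the range's prominent m/z.

    The cell is the member peak's summed intensity over the prominent
    fragments, falling back to the peak's total area when its spectrum has
    none of them; samples without a member peak get 0.
    """
    sample_ids = list(sample_ids) if sample_ids is not None else sorted(peaklists)
    mat = np.zeros((len(sample_ids), len(ranges)))
    idx = {s: i for i, s in enumerate(sample_ids)}
    for j, rng in enumerate(ranges):
        for sid, p in rng.members.items():
            if sid not in idx:
                continue
            val = sum(p.spectrum.get(mz, 0.0) for mz in rng.prominent_mz)
            mat[idx[sid], j] = val if val > 0 else p.area
    areas = pd.DataFrame(mat, index=pd.Index(sample_ids, name="sample_id"),
                         columns=[r.range_id for r in ranges])
    meta = pd.DataFrame(
        {
            "range_id": [r.range_id for r in ranges],
            "rt_low": [r.rt_low for r in ranges],
            "rt_high": [r.rt_high for r in ranges],
            "representative_rt": [r.representative_rt for r in ranges],
            "occurrence": [r.occurrence for r in ranges],
            "prominent_mz": [";".join(map(str, r.prominent_mz)) for r in ranges],
            "verified": [r.verified for r in ranges],
        }
    )
    return AlignedTable(areas=areas, ranges=meta)


def align_peak_lists(
    peaklists: Mapping[str, PeakList],
    gap_tol: float = DEFAULT_GAP_TOL,
    min_occurrence: int = DEFAULT_MIN_OCCURRENCE,
    top_k: int = DEFAULT_TOP_K,
    jaccard_min: float = DEFAULT_JACCARD_MIN,
    batch_map: Mapping[str, str] | None = None,
    reference_batch: str | None = None,
) -> AlignedTable:
    """Full alignment chain: (batch shift) -> group -> filter -> verify -> quantify."""
    log: list[str] = []
    if batch_map is not None and reference_batch is not None:
        peaklists, shifts, shift_log = adjust_rt_per_batch(
            peaklists, batch_map, reference_batch, gap_tol
        )
        log.extend(shift_log)
    ranges = group_retention_times(peaklists, gap_tol, log)
    ranges = filter_by_occurrence(ranges, min_occurrence, log)
    ranges = [extract_and_verify_masses(r, top_k, jaccard_min) for r in ranges]
    n_unverified = sum(not r.verified for r in ranges)
    if n_unverified:
        log.append(f"{n_unverified} ranges failed the spectral-consistency check; dropped")
    ranges = [r for r in ranges if r.verified]
    table = quantify_ranges(peaklists, ranges)
    table.log = log
    return table
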