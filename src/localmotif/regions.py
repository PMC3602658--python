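"""Calling, merging and de-duplicating locally enriched regions.

A position x is significant when P_dep(x) falls below a width-dependent
threshold (stricter for narrow kernels, reflecting the larger effective
number of tests) AND P_ind(x) < 0.01.  Each maximal run of consecutive
significant positions [x1, x2] is expanded by h/2 on both sides to form the
reported region.  Same-width overlapping regions are unioned; across widths,
each transitively-overlapping group is collapsed to a single representative
by the two-thirds rule: keep the largest region unless a smaller one holds
more than 2/3 of its sites, in which case keep the smallest such region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motif_scan import SiteCollection
from .null_model import NullDistribution
from .parzen import EnrichmentProfile

#: P_dep significance thresholds per kernel half-width h/2.
DEFAULT_PDEP_THRESHOLDS = {200: 1e-3, 100: 5e-4, 50: 2e-4, 20: 1e-4, 10: 5e-5}
DEFAULT_PIND_THRESHOLD = 0.01


@dataclass
class EnrichedRegion:
    """One called region: significant core [x1, x2] widened by h/2."""

    motif_id: str
    x1: int
    x2: int
    half_width: int
    n_sites: int = 0
    min_p_dep: float = float("nan")
    p_ind_at_peak: float = float("nan")

    @property
    def region_start(self) -> int:
        return self.x1 - self.half_width

    @property
    def region_end(self) -> int:
        return self.x2 + self.half_width

    @property
    def span(self) -> int:
        """Width in bp of the expanded region, ends inclusive."""
        return self.region_end - self.region_start + 1

    def overlaps(self, other: "EnrichedRegion") -> bool:
        return (
            self.region_start <= other.region_end
            and other.region_start <= self.region_end
        )


def count_sites_in(
    sites: SiteCollection, start: int, end: int, category: str = "strong"
) -> int:
    """Sites of the input set anchored within [start, end], ends inclusive."""
    total = 0
    for g in sites.per_sequence:
        pos = sites.positions(g, category)
        total += int(((pos >= start) & (pos <= end)).sum())
    return total


def call_regions(
    null: NullDistribution,
    obs: EnrichmentProfile,
    sites: SiteCollection | None = None,
    p_dep_thresholds: dict[int, float] | None = None,
    p_ind_threshold: float = DEFAULT_PIND_THRESHOLD,
) -> list[EnrichedRegion]:
    """Convert per-position empirical p-values into enriched regions.

    Runs separated by even a single non-significant bp stay separate here;
    :func:`merge_same_width` later unions regions whose h/2 expansions
    overlap.  ``sites`` (the input set's collection) populates ``n_sites``.
    """
    if (null.x_start, null.x_stop) != (obs.x_start, obs.x_stop):
        raise ValueError("null and observed profile grids differ")
    if null.motif_id != obs.motif_id:
        raise ValueError("null and observed profile motifs differ")
    thresholds = dict(DEFAULT_PDEP_THRESHOLDS)
    if p_dep_thresholds:
        thresholds.update(p_dep_thresholds)
    hw = obs.kernel.half_width
    if hw not in thresholds:
        raise KeyError(
            f"no P_dep threshold configured for half-width {hw}; "
            "pass p_dep_thresholds explicitly"
        )
    p_dep = null.p_dep
    p_ind = null.p_ind
    sig = (p_dep < thresholds[hw]) & (p_ind < p_ind_threshold)
    regions: list[EnrichedRegion] = []
    for x1, x2 in _runs(sig):
        seg = slice(x1, x2 + 1)
        peak = x1 + _peak_offset(p_dep[seg], obs.scores[seg])
        region = EnrichedRegion(
            motif_id=obs.motif_id,
            x1=obs.x_start + x1,
            x2=obs.x_start + x2,
            half_width=hw,
            min_p_dep=float(p_dep[seg].min()),
            p_ind_at_peak=float(p_ind[peak]),
        )
        if sites is not None:
            region.n_sites = count_sites_in(
                sites, region.region_start, region.region_end
            )
        regions.append(region)
    return regions


def _runs(mask: np.ndarray):
    """Maximal runs of True, as (first, last) index pairs."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for a, b in zip(starts, ends):
        yield int(idx[a]), int(idx[b])


def _peak_offset(p_dep_seg: np.ndarray, score_seg: np.ndarray) -> int:
    """Peak = min P_dep, ties broken by max S_local, then leftmost."""
    cand = np.nonzero(p_dep_seg == p_dep_seg.min())[0]
    return int(cand[score_seg[cand].argmax()])


def merge_same_width(
    regions: list[EnrichedRegion], sites: SiteCollection | None = None
) -> list[EnrichedRegion]:
    """Union overlapping regions sharing one motif and half-width.

    The merged region keeps the members' min P_dep (and that member's peak
    P_ind) and recounts ``n_sites`` over the union when ``sites`` is given.
    """
    if not regions:
        return []
    if len({(r.motif_id, r.half_width) for r in regions}) != 1:
        raise ValueError("merge_same_width requires one motif and one width")
    merged: list[EnrichedRegion] = []
    for r in sorted(regions, key=lambda r: (r.region_start, r.region_end)):
        if merged and r.region_start <= merged[-1].region_end:
            prev = merged[-1]
            prev.x1 = min(prev.x1, r.x1)
            prev.x2 = max(prev.x2, r.x2)
            if r.min_p_dep < prev.min_p_dep:
                prev.min_p_dep = r.min_p_dep
                prev.p_ind_at_peak = r.p_ind_at_peak
        else:
            merged.append(
                EnrichedRegion(
                    r.motif_id, r.x1, r.x2, r.half_width,
                    r.n_sites, r.min_p_dep, r.p_ind_at_peak,
                )
            )
    if sites is not None:
        for r in merged:
            r.n_sites = count_sites_in(sites, r.region_start, r.region_end)
    return merged


def remove_cross_width_redundancy(
    regions: list[EnrichedRegion],
) -> list[EnrichedRegion]:
    """Collapse each group of overlapping regions (any widths) to one.

    Keep the largest region (by span) unless a smaller region contains
    strictly more than 2/3 of the largest's sites; then keep the *smallest*
    region satisfying that bound.  Ties on span go to the region with more
    sites, then the smaller ``region_start``.
    """
    if not regions:
        return []
    if len({r.motif_id for r in regions}) != 1:
        raise ValueError("redundancy removal operates on one motif at a time")
    ordered = sorted(regions, key=lambda r: (r.region_start, r.region_end))
    groups: list[list[EnrichedRegion]] = [[ordered[0]]]
    reach = ordered[0].region_end
    for r in ordered[1:]:
        if r.region_start <= reach:
            groups[-1].append(r)
        else:
            groups.append([r])
        reach = max(reach, r.region_end)
    kept = [_resolve_group(g) for g in groups]
    return sorted(kept, key=lambda r: r.region_start)


def _resolve_group(group: list[EnrichedRegion]) -> EnrichedRegion:
    largest = max(group, key=lambda r: (r.span, r.n_sites, -r.region_start))
    bound = (2.0 / 3.0) * largest.n_sites
    qualifiers = [
        r for r in group if r.span < largest.span and r.n_sites > bound
    ]
    if not qualifiers:
        return largest
    return min(qualifiers, key=lambda r: (r.span, -r.n_sites, r.region_start))


def regions_to_frame(regions: list[EnrichedRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif_id": r.motif_id,
                "region_start": r.region_start,
                "region_end": r.region_end,
                "x1": r.x1,
                "x2": r.x2,
                "half_width": r.half_width,
                "n_sites": r.n_sites,
                "min_P_dep": r.min_p_dep,
                "P_ind": r.p_ind_at_peak,
            }
            for r in regions
        ],
        columns=[
            "motif_id", "region_start", "region_end", "x1", "x2",
            "half_width", "n_sites", "min_P_dep", "P_ind",
        ],
    )


def write_regions(regions: list[EnrichedRegion], path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)
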