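"""Global over-representation and per-region follow-up statistics.

The Over-Representation Index (ORI) summarises *global* enrichment of a
motif in a promoter set S against the genomic universe, counting sites in
the 1 kb upstream of the TSS (window [-1000, 0)):

    ORI = (Density_S / Density_genomic) * (Proportion_S / Proportion_genomic)

where Density is sites per sequence and Proportion the fraction of sequences
with at least one site.  P_ORI is the fraction of GC-matched sampled sets
with a strictly higher ORI.

Two per-region follow-ups use the same resampling machinery: enrichment of
*weak* sites inside a called region (weak hits overlapping a strong hit of
the same motif are excluded), and a conservation Z-score comparing a
user-supplied per-base score track over the region's site bases against
bases at identical TSS-relative offsets in randomly selected promoters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sequence_io
from .motif_scan import SiteCollection
from .null_model import GCClusterModel, sample_matched_indices
from .regions import EnrichedRegion
from .sequence_io import PromoterSet

ORI_WINDOW = (-1000, 0)  # half-open upstream counting window


@dataclass
class ORIResult:
    motif_id: str
    density_s: float
    density_genomic: float
    proportion_s: float
    proportion_genomic: float
    ori: float
    p_ori: float = float("nan")


def upstream_counts(
    sites: SiteCollection, gene_ids, category: str = "strong"
) -> np.ndarray:
    """Per-gene count of sites anchored in the [-1000, 0) upstream window."""
    lo, hi = ORI_WINDOW
    out = np.zeros(len(gene_ids), dtype=np.int64)
    for i, g in enumerate(gene_ids):
        pos = sites.positions(g, category)
        out[i] = int(((pos >= lo) & (pos < hi)).sum())
    return out


def _ori_from_counts(
    counts_s: np.ndarray, counts_genomic: np.ndarray
) -> tuple[float, float, float, float, float]:
    dg = counts_genomic.mean()
    pg = (counts_genomic > 0).mean()
    if dg == 0 or pg == 0:
        raise ValueError(
            "motif has no genomic upstream sites: ORI undefined "
            "(zero genomic density/proportion)"
        )
    ds = counts_s.mean()
    ps = (counts_s > 0).mean()
    return ds, float(dg), ps, float(pg), float((ds / dg) * (ps / pg))


def ori(
    sites_s: SiteCollection,
    sites_genomic: SiteCollection,
    gene_ids_s,
    gene_ids_genomic,
) -> ORIResult:
    """ORI of a motif in S versus the genomic universe (no p-value yet)."""
    cs = upstream_counts(sites_s, gene_ids_s)
    cg = upstream_counts(sites_genomic, gene_ids_genomic)
    ds, dg, ps, pg, value = _ori_from_counts(cs, cg)
    return ORIResult(
        motif_id=sites_s.motif_id,
        density_s=float(ds),
        density_genomic=dg,
        proportion_s=float(ps),
        proportion_genomic=pg,
        ori=value,
    )


def p_ori(
    obs: ORIResult,
    genomic: PromoterSet,
    sites_genomic: SiteCollection,
    model: GCClusterModel,
    input_set: PromoterSet,
    n_samples: int = 10000,
    seed: int = 0,
) -> float:
    """P_ORI: fraction of GC-matched sampled sets with ORI strictly above.

    Note the strict ">" — a sampled set tying the observed ORI does not count
    against it (this mirrors the deliberate asymmetry with P_dep's ">=").
    """
    counts_genomic = upstream_counts(sites_genomic, genomic.gene_ids)
    dg = counts_genomic.mean()
    pg = (counts_genomic > 0).mean()
    if dg == 0 or pg == 0:
        raise ValueError("zero genomic density/proportion: P_ORI undefined")
    profiles = sequence_io.gc_profile_matrix(input_set, impute_with=model.bin_means)
    cluster_counts = model.counts_for(profiles)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_samples):
        idx = sample_matched_indices(model, cluster_counts, rng)
        c = counts_genomic[idx]
        sampled = (c.mean() / dg) * ((c > 0).mean() / pg)
        if sampled > obs.ori:
            exceed += 1
    return exceed / n_samples


@dataclass
class WeakSiteTest:
    region: EnrichedRegion
    n_weak_obs: int
    null_mean: float
    null_median: float
    p_value: float
    n_samples: int


def _weak_region_counts(
    sites: SiteCollection, gene_ids, start: int, end: int
) -> np.ndarray:
    """Per-gene weak-site counts in [start, end], excluding strong-overlaps."""
    out = np.zeros(len(gene_ids), dtype=np.int64)
    for i, g in enumerate(gene_ids):
        out[i] = sum(
            1
            for s in sites.sites(g, "weak")
            if not s.overlaps_strong and start <= s.position <= end
        )
    return out


def weak_site_enrichment(
    region: EnrichedRegion,
    sites_s: SiteCollection,
    genomic: PromoterSet,
    sites_genomic: SiteCollection,
    model: GCClusterModel,
    input_set: PromoterSet,
    n_samples: int = 10000,
    seed: int = 0,
) -> WeakSiteTest:
    """Are weak sites of the motif concentrated in this called region?

    Counts non-strong-overlapping weak sites inside the expanded region in S
    and compares with GC-matched sampled sets; p = fraction of samples with a
    count >= the observed one.
    """
    if region.motif_id != sites_s.motif_id:
        raise ValueError("region and site collection motifs differ")
    start, end = region.region_start, region.region_end
    n_obs = int(_weak_region_counts(sites_s, list(sites_s.per_sequence), start, end).sum())
    per_gene = _weak_region_counts(sites_genomic, genomic.gene_ids, start, end)
    profiles = sequence_io.gc_profile_matrix(input_set, impute_with=model.bin_means)
    cluster_counts = model.counts_for(profiles)
    rng = np.random.default_rng(seed)
    sampled = np.empty(n_samples)
    for r in range(n_samples):
        idx = sample_matched_indices(model, cluster_counts, rng)
        sampled[r] = per_gene[idx].sum()
    return WeakSiteTest(
        region=region,
        n_weak_obs=n_obs,
        null_mean=float(sampled.mean()),
        null_median=float(np.median(sampled)),
        p_value=float((sampled >= n_obs).mean()),
        n_samples=n_samples,
    )


class ScoreTrack:
    """Per-base score track in TSS-relative coordinates.

    Backed by a TSV with columns ``gene_id``, ``position``, ``score``; any
    per-base annotation (PhastCons, phyloP, synthetic tracks) fits.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = {"gene_id", "position", "score"} - set(frame.columns)
        if missing:
            raise ValueError(f"score track missing columns: {sorted(missing)}")
        self._by_gene: dict[str, dict[int, float]] = {
            g: dict(zip(sub["position"].astype(int), sub["score"].astype(float)))
            for g, sub in frame.groupby("gene_id", sort=False)
        }

    @classmethod
    def read_tsv(cls, path) -> "ScoreTrack":
        return cls(pd.read_csv(path, sep="\t"))

    def value(self, gene_id: str, position: int) -> float:
        try:
            return self._by_gene[gene_id][position]
        except KeyError:
            raise KeyError(
                f"score track has no value for {gene_id!r} at position {position}"
            ) from None

    def values(self, pairs) -> np.ndarray:
        return np.array([self.value(g, p) for g, p in pairs])


@dataclass
class ConservationZ:
    region: EnrichedRegion
    n_bases: int
    mean_obs: float
    null_mean: float
    null_sd: float
    z: float


def site_base_offsets(
    sites: SiteCollection, region: EnrichedRegion, category: str = "strong"
) -> list[tuple[str, int]]:
    """(gene_id, TSS-relative base) pairs covered by the region's sites."""
    w = sites.width
    pairs = []
    for g in sites.per_sequence:
        for s in sites.sites(g, category):
            if region.region_start <= s.position <= region.region_end:
                start = s.position - (w - 1) // 2
                pairs.extend((g, b) for b in range(start, start + w))
    return pairs


def conservation_z(
    region: EnrichedRegion,
    sites_s: SiteCollection,
    track: ScoreTrack,
    genomic: PromoterSet,
    n_samples: int = 1000,
    seed: int = 0,
    min_sites: int = 10,
) -> ConservationZ:
    """Z-score of the track over the region's site bases vs random promoters.

    The null keeps each base's TSS-relative offset fixed and redraws only the
    promoter it comes from, uniformly from the genomic set (not
    GC-stratified), so positional trends in the track are controlled for.
    Regions with fewer than ``min_sites`` sites are rejected as underpowered.
    """
    n_region_sites = sum(
        1
        for g in sites_s.per_sequence
        for s in sites_s.sites(g, "strong")
        if region.region_start <= s.position <= region.region_end
    )
    if n_region_sites < min_sites:
        raise ValueError(
            f"region has {n_region_sites} sites; need >= {min_sites} "
            "for a stable conservation Z-score"
        )
    pairs = site_base_offsets(sites_s, region)
    obs_vals = track.values(pairs)
    offsets = np.array([p for _, p in pairs], dtype=int)
    rng = np.random.default_rng(seed)
    gene_ids = genomic.gene_ids
    means = np.empty(n_samples)
    for r in range(n_samples):
        picks = rng.integers(0, len(gene_ids), size=offsets.size)
        means[r] = track.values(
            [(gene_ids[gi], int(b)) for gi, b in zip(picks, offsets)]
        ).mean()
    null_mean = float(means.mean())
    null_sd = float(means.std(ddof=1))
    if null_sd == 0:
        raise ValueError("degenerate (constant) score track: Z undefined")
    mean_obs = float(obs_vals.mean())
    return ConservationZ(
        region=region,
        n_bases=int(offsets.size),
        mean_obs=mean_obs,
        null_mean=null_mean,
        null_sd=null_sd,
        z=(mean_obs - null_mean) / null_sd,
    )
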