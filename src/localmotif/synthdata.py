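"""Synthetic promoter universes with controlled GC structure and implants.

The generator emulates the two features of real promoter collections that
the method's null model exists for: (1) a mixture of GC classes, one of them
with elevated GC near the TSS (CpG-island-like promoters), and (2) motif
instances implanted at controlled TSS-relative positions and insertion
rates.  Backgrounds are i.i.d. per position — no dinucleotide structure or
repeats — which is enough to exercise every scoring and resampling path.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp

import numpy as np
import pandas as pd

from .motif_scan import MotifMatrix
from .sequence_io import PromoterSequence, PromoterSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GCClassSpec:
    """One GC class: baseline GC fraction plus a Gaussian bump at the TSS."""

    label: str
    baseline_gc: float
    tss_bump: float = 0.0
    bump_halfwidth: int = 300
    proportion: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_gc + self.tss_bump < 1:
            raise ValueError(
                f"class {self.label}: baseline + bump must lie in (0, 1)"
            )
        if not 0 < self.baseline_gc < 1:
            raise ValueError(f"class {self.label}: baseline must lie in (0, 1)")
        if self.proportion < 0:
            raise ValueError(f"class {self.label}: negative proportion")

    def gc_probability(self, positions: np.ndarray) -> np.ndarray:
        bump = self.tss_bump * np.exp(
            -(positions.astype(float) ** 2) / (2.0 * self.bump_halfwidth**2)
        )
        return self.baseline_gc + bump


def generate_universe(
    n: int,
    classes: list[GCClassSpec],
    span: tuple[int, int] = (-3000, 2000),
    seed: int = 0,
    label: str = "synthetic_universe",
) -> PromoterSet:
    """Draw ``n`` promoters i.i.d. per position with class-specific GC.

    Class sizes are the exact rounded proportions (remainders go to the
    earliest classes); the class label is recorded as a header tag.  The
    member order is shuffled so class blocks do not survive into downstream
    subsetting.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    props = np.array([c.proportion for c in classes], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("class proportions must sum to 1")
    sizes = np.floor(props * n).astype(int)
    for i in range(n - sizes.sum()):
        sizes[i % len(sizes)] += 1
    rng = np.random.default_rng(seed)
    positions = np.arange(span[0], span[1])
    members: list[PromoterSequence] = []
    counter = 0
    for spec, size in zip(classes, sizes):
        if size == 0:
            continue
        p_gc = spec.gc_probability(positions)
        is_gc = rng.random((size, positions.size)) < p_gc[None, :]
        # within GC: G vs C equiprobable; within AT: A vs T equiprobable
        second = rng.random((size, positions.size)) < 0.5
        codes = np.where(is_gc, np.where(second, 2, 1), np.where(second, 0, 3))
        for row in codes:
            counter += 1
            members.append(
                PromoterSequence(
                    gene_id=f"g{counter:06d}",
                    seq=_BASES[row].tobytes().decode(),
                    span_start=span[0],
                    span_end=span[1],
                    tags={"class": spec.label},
                )
            )
    order = rng.permutation(len(members))
    return PromoterSet([members[i] for i in order], label=label)


@dataclass
class ImplantSpec:
    """Where and how often to implant instances of a motif.

    ``positional_sd`` > 0 draws the implant midpoint from a rounded Gaussian
    around ``center``; with ``uniform_half_range`` set, a discrete uniform
    over ``center ± uniform_half_range`` is used instead.
    """

    motif: MotifMatrix
    center: int
    positional_sd: float = 0.0
    uniform_half_range: int | None = None
    insertion_rate: float = 1.0
    strand_policy: str = "gene_strand"  # or "both"

    def __post_init__(self) -> None:
        if not 0.0 <= self.insertion_rate <= 1.0:
            raise ValueError("insertion_rate must lie in [0, 1]")
        if self.strand_policy not in ("gene_strand", "both"):
            raise ValueError(f"bad strand_policy {self.strand_policy!r}")


def implant(
    pset: PromoterSet, spec: ImplantSpec, seed: int = 0
) -> tuple[PromoterSet, pd.DataFrame]:
    """Implant one motif instance into a fraction of the sequences.

    ``round(rate * N)`` sequences are chosen without replacement; each gets
    one word sampled column-wise from the motif's probability matrix,
    overwriting the background at the drawn midpoint.  Returns the new set
    and an implant log (gene_id, position, strand, word).
    """
    rng = np.random.default_rng(seed)
    w = spec.motif.width
    span_start = pset.members[0].span_start
    span_end = pset.members[0].span_end
    spread = (
        spec.uniform_half_range
        if spec.uniform_half_range is not None
        else int(np.ceil(4 * spec.positional_sd))
    )
    lo_mid = spec.center - spread
    hi_mid = spec.center + spread
    if lo_mid - (w - 1) // 2 < span_start or hi_mid - (w - 1) // 2 + w > span_end:
        raise ValueError(
            f"implant center {spec.center} (spread {spread}) too close to the "
            f"span edge [{span_start}, {span_end})"
        )
    n_sel = int(round(spec.insertion_rate * len(pset)))
    selected = set(rng.choice(len(pset), size=n_sel, replace=False).tolist())
    probs = spec.motif.probabilities
    new_members: list[PromoterSequence] = []
    log_rows = []
    for i, m in enumerate(pset):
        if i not in selected:
            new_members.append(m)
            continue
        while True:
            if spec.uniform_half_range is not None:
                mid = int(rng.integers(lo_mid, hi_mid + 1))
            else:
                mid = spec.center + int(round(rng.normal(0.0, spec.positional_sd)))
            if lo_mid <= mid <= hi_mid:
                break
        word = "".join(
            "ACGT"[rng.choice(4, p=probs[:, j])] for j in range(w)
        )
        strand = "+"
        if spec.strand_policy == "both" and rng.random() < 0.5:
            strand = "-"
            word = word.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        start = mid - (w - 1) // 2
        off = start - span_start
        seq = m.seq[:off] + word + m.seq[off + w :]
        new_members.append(
            PromoterSequence(m.gene_id, seq, span_start, span_end, dict(m.tags))
        )
        log_rows.append((m.gene_id, mid, strand, word))
    log = pd.DataFrame(log_rows, columns=["gene_id", "position", "strand", "word"])
    return PromoterSet(new_members, label=pset.label), log


# ---------------------------------------------------------------------------
# Reference study conditions: fixed motifs and universe compositions used by
# the simulation studies (and the test-suite/acceptance checks built on them).

#: Two GC classes: a CpG-island-like class (GC elevated toward the TSS) and a
#: GC-poor class, roughly mirroring the bimodality of mammalian promoters.
DEFAULT_CLASSES = [
    GCClassSpec("gc_high", baseline_gc=0.52, tss_bump=0.18,
                bump_halfwidth=300, proportion=0.5),
    GCClassSpec("gc_low", baseline_gc=0.38, tss_bump=0.0, proportion=0.5),
]


def common_motif(**kwargs) -> MotifMatrix:
    """A 6-bp moderately specific motif with frequent background hits.

    Column counts allow one "wobble" position, so strong hits occur at a
    realistic TFBS density (order 1 per promoter in a 5-kb window) — used
    where the null/calibration machinery needs non-degenerate scores.  The
    relative-score cutoffs (strong 0.92, weak 0.90) were fixed to give that
    density against the i.i.d. background of :func:`generate_universe`.
    """
    kwargs.setdefault("strong_fraction", 0.92)
    kwargs.setdefault("weak_fraction", 0.90)
    counts = np.array(
        [
            #  T   G   A   C   G   T
            [2., 2., 70., 2., 2., 6.],   # A
            [2., 10., 4., 70., 10., 6.],  # C
            [6., 60., 4., 6., 60., 6.],  # G
            [70., 8., 2., 2., 8., 62.],  # T
        ]
    )
    return MotifMatrix("common6", counts, **kwargs)


def implant_motif(**kwargs) -> MotifMatrix:
    """A sharp 8-bp AT-rich motif with rare background hits.

    Near-consensus columns make implanted words score strong while random
    background rarely reaches the strong threshold — the implant/recovery
    simulations use this motif.  Cutoffs (strong 0.95, weak 0.90) keep
    background strong hits rare (~0.4 per 5-kb promoter) while roughly half
    of the words sampled from the matrix itself score strong, the remainder
    landing in the weak band.
    """
    kwargs.setdefault("strong_fraction", 0.95)
    kwargs.setdefault("weak_fraction", 0.90)
    counts = np.array(
        [
            #   T    A    T    A    A    A    T    A
            [3., 85., 3., 85., 85., 80., 5., 80.],   # A
            [2., 3., 2., 3., 3., 4., 2., 4.],        # C
            [2., 4., 2., 4., 4., 8., 2., 8.],        # G
            [85., 0., 85., 0., 0., 0., 83., 0.],     # T
        ]
    )
    return MotifMatrix("sharp8", counts, **kwargs)
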