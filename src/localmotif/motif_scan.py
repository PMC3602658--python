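"""PWM parsing and TFBS prediction in promoter sets.

Motif matrices come in as JASPAR PFM or TRANSFAC count blocks (parsed via
Bio.motifs) and are scored as log2-odds against a background mononucleotide
model.  A window is a *strong* hit when its relative score

    rel = (score - min_score) / (max_score - min_score)

reaches ``strong_fraction``, and a *weak* hit when it lies in
``[weak_fraction, strong_fraction)`` — the MATCH/TRANSFAC relative-score
convention.  Both strands are scanned; a site is anchored at the floor of its
match midpoint in TSS-relative coordinates, so Parzen peaks sit symmetrically
over the biological site.  Windows containing ``N`` never score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .sequence_io import PromoterSet

BASES = "ACGT"
_ENC = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T -> 0..3 and anything else -> 4."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class MotifMatrix:
    """A motif count matrix plus its scoring configuration.

    ``counts`` has shape ``(4, w)`` with rows in A, C, G, T order.  The
    pseudocount (default 0.8) is split across rows proportionally to the
    background before columns are normalised to probabilities.
    """

    motif_id: str
    counts: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    strong_fraction: float = 0.85
    weak_fraction: float = 0.70

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 4:
            raise ValueError(
                f"{self.motif_id}: counts must be 4 x w with w >= 4, "
                f"got {self.counts.shape}"
            )
        if (self.counts < 0).any():
            raise ValueError(f"{self.motif_id}: negative counts")
        if not np.isclose(self.background.sum(), 1.0):
            raise ValueError(f"{self.motif_id}: background must sum to 1")
        if not (0 < self.weak_fraction < self.strong_fraction <= 1):
            raise ValueError(
                f"{self.motif_id}: need 0 < weak_fraction < strong_fraction <= 1"
            )
        colsums = (
            self.counts + self.pseudocount * self.background[:, None]
        ).sum(axis=0)
        if (colsums <= 0).any():
            raise ValueError(
                f"{self.motif_id}: zero-count column with no pseudocount"
            )
        if self.max_score <= self.min_score:
            raise ValueError(f"{self.motif_id}: degenerate score range")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @cached_property
    def probabilities(self) -> np.ndarray:
        padded = self.counts + self.pseudocount * self.background[:, None]
        return padded / padded.sum(axis=0, keepdims=True)

    @cached_property
    def log_odds(self) -> np.ndarray:
        """log2(p / background), shape (4, w); -inf where p is zero."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probabilities / self.background[:, None])

    @cached_property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=0).sum())

    @cached_property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probabilities.argmax(axis=0))

    def relative_score(self, word: str) -> float:
        """Relative log-odds score of one w-length word (forward strand)."""
        idx = encode(word)
        if len(idx) != self.width or (idx > 3).any():
            raise ValueError("word must be ACGT-only and match motif width")
        score = self.log_odds[idx, np.arange(self.width)].sum()
        return float((score - self.min_score) / (self.max_score - self.min_score))

    def reverse_complement(self) -> "MotifMatrix":
        return MotifMatrix(
            motif_id=self.motif_id,
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
            strong_fraction=self.strong_fraction,
            weak_fraction=self.weak_fraction,
        )


@dataclass
class Site:
    """One predicted TFBS, anchored at the floor of its match midpoint."""

    position: int
    strand: str
    score: float
    rel_score: float
    category: str  # "strong" | "weak"
    overlaps_strong: bool = False


@dataclass
class SiteCollection:
    """Predicted sites of one motif across an ordered promoter set.

    ``per_sequence`` has one entry per scanned gene (possibly an empty list),
    in set order; ``n`` is the total count over all sequences.
    """

    motif_id: str
    width: int
    per_sequence: dict[str, list[Site]]

    def n(self, category: str = "strong") -> int:
        return sum(len(self.sites(g, category)) for g in self.per_sequence)

    def sites(self, gene_id: str, category: str = "strong") -> list[Site]:
        sel = self.per_sequence[gene_id]
        if category == "all":
            return list(sel)
        return [s for s in sel if s.category == category]

    def positions(self, gene_id: str, category: str = "strong") -> np.ndarray:
        return np.array(
            [s.position for s in self.sites(gene_id, category)], dtype=int
        )

    def subset(self, gene_ids) -> "SiteCollection":
        return SiteCollection(
            self.motif_id, self.width,
            {g: list(self.per_sequence[g]) for g in gene_ids},
        )


def parse_motifs(path, dialect: str, **matrix_kwargs) -> list[MotifMatrix]:
    """Parse a motif file in ``jaspar_pfm`` or ``transfac`` dialect.

    Extra keyword arguments (pseudocount, background, strong/weak fractions)
    are forwarded to every resulting :class:`MotifMatrix`.
    """
    fmt = {"jaspar_pfm": "jaspar", "transfac": "transfac"}.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown motif dialect: {dialect!r}")
    try:
        with open(path) as handle:
            parsed = bio_motifs.parse(handle, fmt)
    except Exception as exc:  # Bio raises bare ValueError/KeyError
        raise ValueError(f"malformed {dialect} file {path}: {exc}") from exc
    if not parsed:
        raise ValueError(f"malformed {dialect} file {path}: no matrix blocks found")
    result = []
    for i, m in enumerate(parsed):
        try:
            counts = np.array([m.counts[b] for b in BASES], dtype=float)
        except Exception as exc:
            raise ValueError(
                f"malformed {dialect} file {path}, block {i + 1}: {exc}"
            ) from exc
        motif_id = getattr(m, "matrix_id", None) or m.name
        if not motif_id and hasattr(m, "get"):  # TRANSFAC records
            motif_id = m.get("AC") or m.get("ID")
        motif_id = motif_id or f"motif_{i + 1}"
        result.append(MotifMatrix(motif_id=motif_id, counts=counts, **matrix_kwargs))
    return result


def _score_matrix(idx: np.ndarray, lut: np.ndarray, w: int) -> np.ndarray:
    """Sum LUT columns over sliding windows; rows are sequences."""
    n_win = idx.shape[1] - w + 1
    scores = np.zeros((idx.shape[0], n_win))
    for j in range(w):
        scores += lut[idx[:, j : j + n_win], j]
    return scores


def scan(pset: PromoterSet, motif: MotifMatrix, chunk: int = 512) -> SiteCollection:
    """Predict strong and weak sites of ``motif`` on both strands of ``pset``.

    Overlapping hits are all kept; weak hits whose w-bp window intersects a
    strong hit's window of the same motif are flagged ``overlaps_strong`` so
    the weak-site enrichment test can exclude them.
    """
    w = motif.width
    span = motif.max_score - motif.min_score
    # Row 4 (N) scores -inf: any window touching an N never becomes a hit.
    lut = np.vstack([motif.log_odds, np.full((1, w), -np.inf)])
    lut_rc = np.vstack([motif.log_odds[::-1, ::-1], np.full((1, w), -np.inf)])

    per_sequence: dict[str, list[Site]] = {}
    members = pset.members
    for lo in range(0, len(members), chunk):
        block = members[lo : lo + chunk]
        if len({len(m) for m in block}) != 1:
            raise ValueError("all sequences in a set must share one span")
        idx = np.vstack([encode(m.seq) for m in block])
        with np.errstate(invalid="ignore"):
            rel_f = (_score_matrix(idx, lut, w) - motif.min_score) / span
            rel_r = (_score_matrix(idx, lut_rc, w) - motif.min_score) / span
        for row, m in enumerate(block):
            sites: list[Site] = []
            for rel, strand in ((rel_f[row], "+"), (rel_r[row], "-")):
                hit_starts = np.nonzero(rel >= motif.weak_fraction)[0]
                for a in hit_starts:
                    r = float(rel[a])
                    sites.append(
                        Site(
                            position=m.span_start + int(a) + (w - 1) // 2,
                            strand=strand,
                            score=float(
                                r * span + motif.min_score
                            ),
                            rel_score=r,
                            category=(
                                "strong" if r >= motif.strong_fraction else "weak"
                            ),
                        )
                    )
            sites.sort(key=lambda s: (s.position, s.strand))
            _flag_weak_overlaps(sites, w)
            per_sequence[m.gene_id] = sites
    # restore set order (chunking preserves it already, but be explicit)
    per_sequence = {g: per_sequence[g] for g in pset.gene_ids}
    return SiteCollection(motif.motif_id, w, per_sequence)


def _flag_weak_overlaps(sites: list[Site], w: int) -> None:
    strong_pos = np.array(
        sorted(s.position for s in sites if s.category == "strong"), dtype=int
    )
    if strong_pos.size == 0:
        return
    for s in sites:
        if s.category != "weak":
            continue
        # two w-bp windows with midpoints p, q overlap iff |p - q| <= w - 1
        j = np.searchsorted(strong_pos, s.position)
        near = []
        if j > 0:
            near.append(strong_pos[j - 1])
        if j < strong_pos.size:
            near.append(strong_pos[j])
        s.overlaps_strong = any(abs(s.position - q) <= w - 1 for q in near)


# ---------------------------------------------------------------------------
# Site table TSV (columns per the promoter-set file conventions)

SITE_COLUMNS = ["gene_id", "motif_id", "position", "strand", "score", "class"]


def write_sites(collections, path, gene_ids=None) -> None:
    """Write one or more :class:`SiteCollection` objects as a site TSV."""
    if isinstance(collections, SiteCollection):
        collections = [collections]
    rows = []
    for coll in collections:
        for g in gene_ids or coll.per_sequence:
            for s in coll.per_sequence[g]:
                rows.append(
                    (g, coll.motif_id, s.position, s.strand, s.score, s.category)
                )
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites(path, width_by_motif: dict[str, int], gene_ids=None) -> dict[str, SiteCollection]:
    """Read a site TSV back into per-motif :class:`SiteCollection` objects.

    ``width_by_motif`` supplies motif widths (not stored in the table);
    ``gene_ids`` fixes the sequence universe so genes without sites still get
    empty entries.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    out: dict[str, SiteCollection] = {}
    for motif_id, sub in df.groupby("motif_id", sort=False):
        if motif_id not in width_by_motif:
            raise ValueError(f"no width known for motif {motif_id!r}")
        per_seq: dict[str, list[Site]] = {
            g: [] for g in (gene_ids if gene_ids is not None else sub["gene_id"].unique())
        }
        for rec in sub.itertuples(index=False):
            per_seq.setdefault(rec.gene_id, []).append(
                Site(
                    position=int(rec.position),
                    strand=str(rec.strand),
                    score=float(rec.score),
                    rel_score=float("nan"),
                    category=getattr(rec, "_5", None) or rec[5],
                )
            )
        w = width_by_motif[motif_id]
        for sites in per_seq.values():
            sites.sort(key=lambda s: (s.position, s.strand))
            _flag_weak_overlaps(sites, w)
        out[motif_id] = SiteCollection(motif_id, w, per_seq)
    return out
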