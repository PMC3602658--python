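"""TSS-anchored promoter sequences: FASTA I/O and GC-content profiles.

All coordinates are TSS-relative: position 0 is the first transcribed base,
upstream positions are negative, and every window is half-open ``[start, end)``
on a 1-bp integer grid.  Sequences are stored 5'->3' on the gene's strand, so
"upstream" always means "to the left" regardless of the genomic strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: GC profile geometry: 100-bp bins tiling [-1000, +1000).
GC_BIN_SIZE = 100
GC_SPAN = (-1000, 1000)
N_GC_BINS = (GC_SPAN[1] - GC_SPAN[0]) // GC_BIN_SIZE


@dataclass
class PromoterSequence:
    """One promoter window anchored at its gene's TSS.

    Parameters
    ----------
    gene_id:
        Unique identifier (first whitespace-delimited FASTA header token).
    seq:
        Nucleotides over ``{A, C, G, T, N}``; stored uppercase.  Characters
        outside this alphabet are mapped to ``N``.
    span_start, span_end:
        TSS-relative half-open window covered by ``seq``.
    tags:
        Pass-through ``key=value`` metadata from the FASTA header (e.g.
        ``tss=chr1:12345:+`` for genome-anchored output, or a simulation
        class label).
    """

    gene_id: str
    seq: str
    span_start: int = -3000
    span_end: int = 2000
    tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = self.seq.upper()
        if any(c not in "ACGTN" for c in set(s)):
            s = "".join(c if c in "ACGTN" else "N" for c in s)
        self.seq = s
        if len(self.seq) != self.span_end - self.span_start:
            raise ValueError(
                f"{self.gene_id}: sequence length {len(self.seq)} does not "
                f"match span [{self.span_start}, {self.span_end})"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """Return bases in the TSS-relative window ``[start, end)``."""
        if start < self.span_start or end > self.span_end:
            raise ValueError(
                f"window [{start}, {end}) outside span "
                f"[{self.span_start}, {self.span_end})"
            )
        off = start - self.span_start
        return self.seq[off : off + (end - start)]

    def reverse_complement(self) -> "PromoterSequence":
        """Mirror the sequence about the window centre, keeping the span.

        This reads the opposite strand of the same window; GC content per
        100-bp bin is preserved bin-for-bin under mirroring.
        """
        return PromoterSequence(
            gene_id=self.gene_id,
            seq=self.seq.translate(_COMPLEMENT)[::-1],
            span_start=self.span_start,
            span_end=self.span_end,
            tags=dict(self.tags),
        )


@dataclass
class PromoterSet:
    """An ordered set of promoter sequences sharing one span."""

    members: list[PromoterSequence]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("PromoterSet requires at least one sequence")
        ids = [m.gene_id for m in self.members]
        if len(set(ids)) != len(ids):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        self._index = {g: i for i, g in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[PromoterSequence]:
        return iter(self.members)

    def __getitem__(self, gene_id: str) -> PromoterSequence:
        return self.members[self._index[gene_id]]

    @property
    def gene_ids(self) -> list[str]:
        return [m.gene_id for m in self.members]

    def subset(self, gene_ids: Iterable[str], label: str = "") -> "PromoterSet":
        return PromoterSet([self[g] for g in gene_ids], label=label)

    def subset_indices(self, idx: Iterable[int], label: str = "") -> "PromoterSet":
        return PromoterSet([self.members[i] for i in idx], label=label)


def read_promoters(
    fasta_path, span_start: int = -3000, span_end: int = 2000, label: str = ""
) -> PromoterSet:
    """Read a promoter FASTA into a :class:`PromoterSet`.

    Records whose length does not equal ``span_end - span_start`` are skipped
    with a logged error; duplicate gene ids raise.  Header tags of the form
    ``key=value`` after the id are kept as metadata.
    """
    members = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        tags = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                key, val = token.split("=", 1)
                tags[key] = val
        if len(rec.seq) != span_end - span_start:
            log.error(
                "skipping %s: length %d != declared span width %d",
                rec.id, len(rec.seq), span_end - span_start,
            )
            continue
        members.append(
            PromoterSequence(rec.id, str(rec.seq), span_start, span_end, tags)
        )
    return PromoterSet(members, label=label or str(fasta_path))


def write_promoters(pset: PromoterSet, fasta_path) -> None:
    """Write a :class:`PromoterSet` as FASTA, preserving header tags."""
    records = []
    for m in pset:
        desc = " ".join(f"{k}={v}" for k, v in m.tags.items())
        records.append(SeqRecord(Seq(m.seq), id=m.gene_id, description=desc))
    SeqIO.write(records, str(fasta_path), "fasta")


def gc_profile(seq: PromoterSequence) -> np.ndarray:
    """GC fraction per 100-bp bin over [-1000, +1000): a vector of 20 values.

    ``N`` bases count toward neither numerator nor denominator; a bin with no
    countable base is returned as NaN (to be imputed with the genomic mean of
    that bin, see :func:`gc_profile_matrix`).
    """
    if seq.span_start > GC_SPAN[0] or seq.span_end < GC_SPAN[1]:
        raise ValueError(
            f"{seq.gene_id}: span [{seq.span_start}, {seq.span_end}) does not "
            f"cover the GC profile region [{GC_SPAN[0]}, {GC_SPAN[1]})"
        )
    return _profile_from_bytes(
        np.frombuffer(seq.subseq(*GC_SPAN).encode(), dtype=np.uint8)[None, :]
    )[0]


def _profile_from_bytes(arr: np.ndarray) -> np.ndarray:
    gc = (arr == ord("G")) | (arr == ord("C"))
    countable = arr != ord("N")
    shape = (arr.shape[0], N_GC_BINS, GC_BIN_SIZE)
    gc_counts = gc.reshape(shape).sum(axis=2)
    tot = countable.reshape(shape).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = gc_counts / tot
    prof[tot == 0] = np.nan
    return prof


def gc_profile_matrix(
    pset: PromoterSet, impute_with: np.ndarray | None = None
) -> np.ndarray:
    """GC profiles for a whole set, shape ``(N, 20)``.

    NaN bins (all-N) are imputed with ``impute_with`` (per-bin genomic means)
    when given, otherwise with the column means of this matrix.  A fully
    missing column without ``impute_with`` raises.
    """
    payload = "".join(m.subseq(*GC_SPAN) for m in pset)
    arr = np.frombuffer(payload.encode(), dtype=np.uint8).reshape(
        len(pset), GC_SPAN[1] - GC_SPAN[0]
    )
    prof = _profile_from_bytes(arr)
    if np.isnan(prof).any():
        if impute_with is None:
            impute_with = np.nanmean(prof, axis=0)
            if np.isnan(impute_with).any():
                raise ValueError("a GC bin is missing in every sequence")
        nan_r, nan_c = np.nonzero(np.isnan(prof))
        prof[nan_r, nan_c] = np.asarray(impute_with)[nan_c]
    return prof
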