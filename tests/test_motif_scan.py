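import math

import numpy as np
import pytest

from localmotif import motif_scan as ms
from localmotif.sequence_io import PromoterSequence, PromoterSet

JASPAR_TEXT = """>MA0999.1 testmotif
A  [ 10  0  2 85  0  3 ]
C  [  5  3 80  2  1  2 ]
G  [ 70  2 10  5  2  5 ]
T  [ 15 95  8  8 97 90 ]
"""

TRANSFAC_TEXT = """ID  testmotif
BF  synthetic
P0      A      C      G      T
01      10      5      70      15      G
02      0      3      2      95      T
03      2      80      10      8      C
04      85      2      5      8      A
05      0      1      2      97      T
06      3      2      5      90      T
XX
//
"""


@pytest.fixture
def jaspar_motif(tmp_path):
    p = tmp_path / "m.pfm"
    p.write_text(JASPAR_TEXT)
    return ms.parse_motifs(p, "jaspar_pfm")[0]


class TestParsing:
    def test_jaspar_pfm(self, jaspar_motif):
        assert jaspar_motif.motif_id == "MA0999.1"
        assert jaspar_motif.width == 6
        assert jaspar_motif.consensus == "GTCATT"
        # columns sum to 1 after pseudocount normalisation
        np.testing.assert_allclose(jaspar_motif.probabilities.sum(axis=0), 1.0)

    def test_transfac_equals_jaspar(self, tmp_path, jaspar_motif):
        p = tmp_path / "m.dat"
        p.write_text(TRANSFAC_TEXT)
        mt = ms.parse_motifs(p, "transfac")[0]
        np.testing.assert_array_equal(mt.counts, jaspar_motif.counts)
        assert mt.motif_id == "testmotif"

    def test_malformed_fails(self, tmp_path):
        p = tmp_path / "bad.pfm"
        p.write_text(">m1\nA [ 1 2 ]\nC [ 1 ]\n")
        with pytest.raises(ValueError, match="malformed"):
            ms.parse_motifs(p, "jaspar_pfm")

    def test_zero_column_without_pseudocount(self):
        counts = np.tile([8.0, 1.0, 1.0, 2.0], (5, 1)).T
        counts[:, 2] = 0.0
        with pytest.raises(ValueError, match="zero-count column"):
            ms.MotifMatrix("z", counts, pseudocount=0.0)
        ms.MotifMatrix("ok", counts, pseudocount=0.8)  # pseudocount rescues


def _one_seq_set(seq, start=-50):
    return PromoterSet([PromoterSequence("g1", seq, start, start + len(seq))])


class TestScan:
    def test_consensus_word_is_single_strong_hit_at_midpoint(self, jaspar_motif):
        # low-similarity background: poly-A cannot reach the weak threshold
        seq = "A" * 30 + jaspar_motif.consensus + "A" * 24
        coll = ms.scan(_one_seq_set(seq), jaspar_motif)
        strong = coll.sites("g1", "strong")
        assert len(strong) == 1
        # match starts at -50 + 30 = -20, midpoint floor((w-1)/2) = +2
        assert strong[0].position == -18
        assert strong[0].strand == "+"
        assert strong[0].rel_score == pytest.approx(1.0)

    def test_all_n_sequence_has_no_sites(self, jaspar_motif):
        coll = ms.scan(_one_seq_set("N" * 60), jaspar_motif)
        assert coll.sites("g1", "strong") == [] and coll.sites("g1", "weak") == []

    def test_planted_mid_scoring_word_is_weak(self, jaspar_motif):
        # Independent evaluation: score a one-mismatch word directly from the
        # log-odds table and check it lands inside the configured weak band.
        word = "GTCATA"  # consensus with last base T->A
        lo = jaspar_motif.log_odds
        score = sum(lo["ACGT".index(b), j] for j, b in enumerate(word))
        rel = (score - jaspar_motif.min_score) / (
            jaspar_motif.max_score - jaspar_motif.min_score
        )
        motif = ms.MotifMatrix(
            "banded", jaspar_motif.counts,
            strong_fraction=min(0.99, rel + 0.05),
            weak_fraction=max(0.01, rel - 0.05),
        )
        coll = ms.scan(_one_seq_set("A" * 30 + word + "A" * 24), motif)
        weak = coll.sites("g1", "weak")
        assert [s.position for s in weak] == [-18]
        assert weak[0].rel_score == pytest.approx(rel)

    def test_strand_symmetry_mirrors_positions(self):
        # odd width keeps the midpoint anchor exactly mirror-symmetric
        counts = np.array(
            [
                [90.0, 2.0, 2.0, 5.0, 10.0],
                [2.0, 90.0, 3.0, 80.0, 5.0],
                [3.0, 3.0, 90.0, 10.0, 80.0],
                [5.0, 5.0, 5.0, 5.0, 5.0],
            ]
        )
        motif = ms.MotifMatrix("odd5", counts, strong_fraction=0.9, weak_fraction=0.8)
        rng = np.random.default_rng(17)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        pset = _one_seq_set(seq, start=-200)
        rc_set = PromoterSet([pset.members[0].reverse_complement()])
        fwd = ms.scan(pset, motif)
        rev = ms.scan(rc_set, motif)
        flip = {"+": "-", "-": "+"}
        # midpoint p in [-200, 200) maps to (-1 - p) under the mirror
        expected = sorted(
            ((-1 - s.position), flip[s.strand]) for s in fwd.sites("g1", "all")
        )
        got = sorted((s.position, s.strand) for s in rev.sites("g1", "all"))
        assert got == expected

    def test_lower_strong_fraction_is_monotone(self, universe, jaspar_motif):
        sub = universe.subset_indices(range(30))
        counts = []
        for frac in (0.95, 0.90, 0.85):
            m = ms.MotifMatrix(
                "m", jaspar_motif.counts,
                strong_fraction=frac, weak_fraction=0.5,
            )
            counts.append(ms.scan(sub, m).n("strong"))
        assert counts[0] <= counts[1] <= counts[2]

    def test_matches_exhaustive_rescoring_oracle(self, jaspar_motif):
        rng = np.random.default_rng(23)
        motif = ms.MotifMatrix(
            "m", jaspar_motif.counts, strong_fraction=0.85, weak_fraction=0.70
        )
        w = motif.width
        comp = str.maketrans("ACGTN", "TGCAN")
        for trial in range(20):
            seq = "".join(
                rng.choice(list("ACGTN"), size=60, p=[0.24, 0.24, 0.24, 0.24, 0.04])
            )
            pset = _one_seq_set(seq, start=-30)
            got = {
                (s.position, s.strand, s.category)
                for s in ms.scan(pset, motif).sites("g1", "all")
            }
            expect = set()
            for a in range(60 - w + 1):
                for strand in "+-":
                    word = seq[a : a + w]
                    if strand == "-":
                        word = word.translate(comp)[::-1]
                    if "N" in word:
                        continue
                    score = sum(
                        motif.log_odds["ACGT".index(b), j]
                        for j, b in enumerate(word)
                    )
                    rel = (score - motif.min_score) / (
                        motif.max_score - motif.min_score
                    )
                    if rel >= motif.weak_fraction:
                        cat = "strong" if rel >= motif.strong_fraction else "weak"
                        expect.add((-30 + a + (w - 1) // 2, strand, cat))
            assert got == expect


class TestSiteTable:
    def test_round_trip(self, tmp_path, universe, common_sites):
        sub_ids = universe.gene_ids[:20]
        coll = common_sites.subset(sub_ids)
        path = tmp_path / "sites.tsv"
        ms.write_sites(coll, path)
        back = ms.read_sites(
            path, {coll.motif_id: coll.width}, gene_ids=sub_ids
        )[coll.motif_id]
        for g in sub_ids:
            a = [(s.position, s.strand, s.category, s.overlaps_strong)
                 for s in coll.sites(g, "all")]
            b = [(s.position, s.strand, s.category, s.overlaps_strong)
                 for s in back.sites(g, "all")]
            assert a == b
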