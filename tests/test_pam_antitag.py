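import math
import random

import numpy as np
import pytest

import crisprself as cs
from crisprself._seq import revcomp
from crisprself.genome_io import Genome, GenomicInterval
from crisprself.pam import (
    anti_tag_score,
    build_pfm,
    extract_flanks,
    subtype_motif,
)

from _helpers import random_dna


class TestExtractFlanks:
    def test_plus_strand_coordinate_identity(self):
        seq = "".join(random.Random(0).choice("ACGT") for _ in range(60))
        g = Genome("g", {"c1": seq})
        up, down = extract_flanks(g, GenomicInterval("c1", 10, 40, "+"), 3, 5)
        assert up == seq[7:10]
        assert down == seq[40:45]

    def test_minus_strand_flanks_are_swapped_and_complemented(self):
        seq = "".join(random.Random(1).choice("ACGT") for _ in range(60))
        g = Genome("g", {"c1": seq})
        up, down = extract_flanks(g, GenomicInterval("c1", 10, 40, "-"), 3, 5)
        assert up == revcomp(seq[40:43])
        assert down == revcomp(seq[5:10])

    def test_truncation_at_contig_edges(self):
        g = Genome("g", {"c1": "ACGTACGTACGTACGTACGTAC"})
        up, down = extract_flanks(g, GenomicInterval("c1", 2, 20, "+"), 10, 10)
        assert up == "AC" and down == "AC"

    def test_frame_consistency_under_genome_mirror(self):
        rng = random.Random(4)
        seq = random_dna(rng, 200)
        g = Genome("g", {"c1": seq})
        iv = GenomicInterval("c1", 50, 80, "+")
        mirror = GenomicInterval("c1", 200 - 80, 200 - 50, "-")
        assert extract_flanks(g, iv, 6, 6) == extract_flanks(
            g.reverse_complemented(), mirror, 6, 6
        )

    def test_study_fixture_pam_strings(self, study_sg, study_hits):
        # the planted I-E site carries a 5'-AAC-3' PAM upstream; the
        # planted II-A site a 5'-CTAAGT-3' PAM downstream
        by_start = {h.target.start: h for h in study_hits}
        g = study_sg.genome
        ie = [t for t in study_sg.truth.self_targets
              if t["upstream_flank"] == "AAC"][0]
        assert subtype_motif(g, by_start[ie["start"]], "I-E") == "AAC"
        iia = [t for t in study_sg.truth.self_targets
               if t["downstream_flank"] == "CTAAGT"][0]
        assert subtype_motif(g, by_start[iia["start"]], "II-A") == "CTAAGT"


class TestBuildPfm:
    def test_uniform_column_has_zero_information(self):
        pfm = build_pfm(["A", "C", "G", "T"])
        assert pfm.information_content()[0] == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_columns_have_two_bits(self):
        pfm = build_pfm(["AAT"] * 10)
        assert np.allclose(pfm.information_content(), 2.0)

    def test_two_thirds_column_matches_entropy_oracle(self):
        from scipy.stats import entropy

        pfm = build_pfm(["AAT", "AAT", "AAC"])
        expected_h = entropy([2 / 3, 1 / 3], base=2)
        assert pfm.information_content()[2] == pytest.approx(
            2.0 - expected_h, abs=1e-9
        )
        # and against a hand computation
        hand = -(2 / 3 * math.log2(2 / 3) + 1 / 3 * math.log2(1 / 3))
        assert pfm.information_content()[2] == pytest.approx(2 - hand, abs=1e-12)

    def test_counts_sum_to_n_sequences(self):
        rng = random.Random(2)
        seqs = [random_dna(rng, 8) for _ in range(25)]
        pfm = build_pfm(seqs)
        assert (pfm.column_totals == 25).all()
        assert pfm.n_sequences == 25

    def test_n_bases_excluded_from_column(self):
        pfm = build_pfm(["ANT", "AAT", "AAT"])
        assert pfm.column_totals.tolist() == [3, 2, 3]
        assert pfm.counts[1].sum() == 2

    def test_ic_bounds_property(self):
        rng = random.Random(3)
        for _ in range(30):
            seqs = [random_dna(rng, 6) for _ in range(rng.randrange(1, 12))]
            ic = build_pfm(seqs).information_content()
            assert ((ic >= -1e-12) & (ic <= 2.0 + 1e-12)).all()
            for i, col in enumerate(build_pfm(seqs).counts):
                if (col > 0).sum() == 1:  # monomorphic iff IC == 2
                    assert ic[i] == pytest.approx(2.0)
                else:
                    assert ic[i] < 2.0

    def test_errors(self):
        with pytest.raises(ValueError):
            build_pfm([])
        with pytest.raises(ValueError):
            build_pfm(["AA", "AAA"])


def _enum_pairs(anti: str, tag: str) -> int:
    """Brute-force count of antiparallel WC pairs between anti-tag and tag."""
    wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
    return sum(
        1 for i in range(len(tag)) if (anti[i], tag[len(tag) - 1 - i]) in wc
    )


class TestAntiTagScore:
    def test_perfect_reverse_complement_scores_full(self):
        s = anti_tag_score("GTTTTC", "GAAAAC", 6)
        assert s.matched_pairs == 6
        assert s.crrna_tag == "GAAAAC" and s.anti_tag == "GUUUUC"

    def test_near_perfect_hexamer_scores_five_of_six(self):
        # the canonical worked case: anti-tag 5'-CUUUUC-3' against the
        # repeat 3' end 5'-GAAAAC-3' pairs at five of six positions
        s = anti_tag_score("CTTTTC", "TTTGAAAAC", 6)
        assert s.matched_pairs == 5
        assert s.is_anti_tag()  # >= 4 of 6 -> anti-tag present

    @pytest.mark.parametrize("anti", ["AAAAAA", "GUUUUC", "CCCCCC", "UUUUUG"])
    def test_matches_enumeration_oracle(self, anti):
        tag = "GAAAAC"
        s = anti_tag_score(anti.replace("U", "T"), tag, 6)
        assert s.matched_pairs == _enum_pairs(anti, tag)

    def test_symmetry_under_simultaneous_revcomp(self):
        rng = random.Random(8)
        rc = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(20):
            tag = "".join(rng.choice("ACGU") for _ in range(6))
            anti = "".join(rng.choice("ACGU") for _ in range(6))
            a = _enum_pairs(anti, tag)
            b = _enum_pairs(
                "".join(rc[x] for x in reversed(tag)),
                "".join(rc[x] for x in reversed(anti)),
            )
            assert a == b

    def test_errors(self):
        with pytest.raises(ValueError):
            anti_tag_score("CTTTTC", "GAA", 6)
        with pytest.raises(ValueError):
            anti_tag_score("CT", "GAAAAC", 6)
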