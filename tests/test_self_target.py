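import random

import pytest

import crisprself as cs
from crisprself._seq import revcomp
from crisprself.genome_io import Genome
from crisprself.selftarget import scan_spacer, unique_sts_count

from _helpers import naive_scan, random_dna


def _hitset(hits):
    return {(iv.contig_id, iv.start, iv.strand, len(off)) for iv, off in hits}


class TestScanSpacer:
    def test_rejects_bad_input(self):
        g = Genome("g", {"c1": "ACGT" * 20})
        with pytest.raises(ValueError):
            scan_spacer(g, "ACGTN" * 4)
        with pytest.raises(ValueError):
            scan_spacer(g, "ACGT")  # too short
        with pytest.raises(ValueError):
            scan_spacer(g, "ACGTACGTACGTACGTAC", max_mismatches=-1)

    def test_absent_spacer_gives_empty(self):
        rng = random.Random(0)
        g = Genome("g", {"c1": "A" * 5000})
        assert scan_spacer(g, "C" + random_dna(rng, 20) + "G") == []

    def test_agrees_with_naive_oracle(self):
        rng = random.Random(5)
        for trial in range(20):
            n = rng.randrange(500, 4000)
            seq = random_dna(rng, n)
            spacer = random_dna(rng, rng.randrange(18, 35))
            if trial % 2 == 0:  # plant a (possibly mutated) copy
                m = rng.randrange(0, 3)
                copy = list(spacer)
                for p in rng.sample(range(len(spacer)), m):
                    copy[p] = rng.choice([b for b in "ACGT" if b != copy[p]])
                pos = rng.randrange(0, n - len(spacer))
                seq = seq[:pos] + "".join(copy) + seq[pos + len(spacer):]
            g = Genome("g", {"c1": seq})
            mm = rng.randrange(0, 4)
            assert _hitset(scan_spacer(g, spacer, mm)) == naive_scan(
                {"c1": seq}, spacer, mm
            )

    def test_planted_two_mismatch_site_respects_budget(self):
        rng = random.Random(9)
        spacer = random_dna(rng, 30)
        copy = list(spacer)
        copy[5] = {"A": "C", "C": "A", "G": "T", "T": "G"}[copy[5]]
        copy[20] = {"A": "G", "C": "T", "G": "A", "T": "C"}[copy[20]]
        seq = random_dna(rng, 2000) + "".join(copy) + random_dna(rng, 2000)
        g = Genome("g", {"c1": seq})
        hits2 = scan_spacer(g, spacer, 2)
        assert [(iv.start, off) for iv, off in hits2] == [(2000, (5, 20))]
        assert scan_spacer(g, spacer, 1) == []

    def test_monotone_in_mismatch_budget(self):
        rng = random.Random(13)
        spacer = random_dna(rng, 20)
        pieces = [random_dna(rng, 2000)]
        for m in (0, 1, 2, 3):  # plant copies at increasing distance
            copy = list(spacer)
            for p in rng.sample(range(20), m):
                copy[p] = rng.choice([b for b in "ACGT" if b != copy[p]])
            pieces += ["".join(copy), random_dna(rng, 2000)]
        g = Genome("g", {"c1": "".join(pieces)})
        prev = None
        for m in range(4):
            cur = {(iv.start, iv.strand) for iv, _ in scan_spacer(g, spacer, m)}
            if prev is not None:
                assert prev <= cur
            assert len(cur) >= m + 1
            prev = cur

    def test_strand_involution(self):
        rng = random.Random(21)
        spacer = random_dna(rng, 25)
        seq = random_dna(rng, 3000) + spacer + random_dna(rng, 3000)
        g = Genome("g", {"c1": seq})
        fwd = scan_spacer(g, spacer, 1)
        rev = scan_spacer(g.reverse_complemented(), spacer, 1)
        n = len(seq)
        flipped = {
            (n - iv.end, {"+": "-", "-": "+"}[iv.strand], len(off))
            for iv, off in rev
        }
        assert flipped == {(iv.start, iv.strand, len(off)) for iv, off in fwd}

    def test_n_in_genome_never_matches(self):
        spacer = "ACGTACGTACGTACGTACGT"
        g = Genome("g", {"c1": "TTTT" + spacer.replace("C", "N", 1) + "TTTT"})
        assert scan_spacer(g, spacer, 0) == []
        hits = scan_spacer(g, spacer, 1)
        assert any(iv.start == 4 for iv, _ in hits)


class TestFindSelfTargets:
    def test_spacer_only_in_own_array_gives_no_hits(self):
        cfg = cs.study_fixture_config(seed=23, contig_length=400_000)
        cfg.self_targets = []
        cfg.anti_repeats = []
        sg = cs.synthesize_genome(cfg)
        arrays = cs.detect_arrays(sg.genome)
        assert cs.find_self_targets(sg.genome, arrays) == []

    def test_planted_protospacers_all_found(self, study_sg, study_hits):
        truth = {(t["start"], t["end"], t["strand"])
                 for t in study_sg.truth.self_targets}
        got = {(h.target.start, h.target.end, h.target.strand)
               for h in study_hits}
        assert got == truth
        assert unique_sts_count(study_hits) == len(study_sg.truth.self_targets)

    def test_no_hit_overlaps_an_array(self, study_arrays, study_hits):
        for h in study_hits:
            assert not any(h.target.overlaps(a.interval) for a in study_arrays)

    def test_hits_carry_protospacer_and_gene_annotation(self, study_sg, study_hits):
        by_start = {t["start"]: t for t in study_sg.truth.self_targets}
        for h in study_hits:
            t = by_start[h.target.start]
            assert h.spacer_sequence == t["spacer"]
            assert h.protospacer_sequence == t["spacer"]  # 0-mismatch plants
            assert h.n_mismatches == 0
            if t["target_gene_product"]:
                assert h.target_gene is not None
                assert h.target_gene.product == t["target_gene_product"]

    def test_duplicate_spacers_collapse_to_one_unique(self):
        rng = random.Random(31)
        repeat = random_dna(rng, 30)
        sp = ["A" + random_dna(rng, 28) + "C", "C" + random_dna(rng, 28) + "G"]
        # two arrays sharing spacer sp[0]; one protospacer planted
        body1 = repeat + sp[0] + repeat + sp[1] + repeat
        body2 = repeat + sp[0] + repeat + "T" + random_dna(rng, 28) + "A" + repeat
        bg = random_dna(rng, 60_000)
        seq = (bg[:10_000] + body1 + bg[10_000:30_000] + body2
               + bg[30_000:50_000] + sp[0] + bg[50_000:])
        g = Genome("dup", {"c1": seq})
        arrays = cs.detect_arrays(g)
        assert len(arrays) == 2
        hits = cs.find_self_targets(g, arrays)
        assert unique_sts_count(hits) == 1
        assert len(hits) == 1  # the in-array copies are excluded
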