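import random

import pytest

import crisprself as cs
from crisprself._seq import revcomp
from crisprself.arrays import consensus_repeat, orient_array
from crisprself.genome_io import Genome

from _helpers import build_planted_genome, random_dna


class TestConsensusRepeat:
    @pytest.mark.parametrize(
        "seqs,expected",
        [
            (["ACGT", "ACGT", "ACGT"], "ACGT"),  # identity
            (["ACGT", "ACGA", "ACGT"], "ACGT"),  # majority vote
            (["ACGT", "ACGA"], "ACGA"),  # column tie -> smallest base
        ],
    )
    def test_majority_vote(self, seqs, expected):
        assert consensus_repeat(seqs) == expected

    def test_off_length_units_do_not_vote(self):
        assert consensus_repeat(["ACGT", "ACGT", "ACG"]) == "ACGT"

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            consensus_repeat([])


class TestDetectArrays:
    def test_planted_exact_array_recovered(self):
        rng = random.Random(42)
        repeat = random_dna(rng, 36)
        spacers = ["A" + random_dna(rng, 28) + "C",
                   "C" + random_dna(rng, 28) + "G",
                   "G" + random_dna(rng, 28) + "T"]
        genome, pos, body = build_planted_genome(rng, repeat, spacers)
        (arr,) = cs.detect_arrays(genome)
        assert len(arr.repeats) == 4 and len(arr.spacers) == 3
        assert (arr.start, arr.end) == (pos, pos + len(body))
        assert arr.consensus_repeat in (repeat, revcomp(repeat))
        got = [s.sequence for s in arr.spacers]
        assert got in (spacers, [revcomp(s) for s in reversed(spacers)])

    def test_random_genome_yields_no_arrays(self):
        rng = random.Random(7)
        genome = Genome("r", {"c1": random_dna(rng, 100_000)})
        assert cs.detect_arrays(genome) == []

    def test_short_contig_silently_yields_nothing(self):
        assert cs.detect_arrays(Genome("s", {"c1": "ACGTACGT"})) == []

    def test_strand_symmetry(self):
        rng = random.Random(3)
        repeat = random_dna(rng, 30)
        spacers = ["A" + random_dna(rng, 30) + "C",
                   "C" + random_dna(rng, 30) + "G",
                   "T" + random_dna(rng, 30) + "A"]
        genome, pos, body = build_planted_genome(rng, repeat, spacers)
        fwd = cs.detect_arrays(genome)
        rev = cs.detect_arrays(genome.reverse_complemented())
        n = len(genome.contigs["c1"])
        assert [(n - a.end, n - a.start) for a in rev] == [
            (a.start, a.end) for a in fwd
        ]
        # oriented content is identical regardless of input strand
        assert {a.consensus_repeat for a in rev} == {
            a.consensus_repeat for a in fwd
        }

    def test_study_fixture_recovers_all_planted_arrays(self, study_sg, study_arrays):
        truth = study_sg.truth.arrays
        assert len(study_arrays) == len(truth) == 5
        for t, a in zip(truth, study_arrays):
            assert (a.start, a.end) == (t["start"], t["end"])
            assert len(a.spacers) == t["n_spacers"]
            assert a.consensus_repeat == t["consensus_repeat"]
            assert a.orientation == "+"

    def test_structural_invariants(self, study_arrays):
        params = cs.DetectionParams()
        prev_end = -1
        for a in study_arrays:
            assert len(a.repeats) == len(a.spacers) + 1
            assert a.start > prev_end  # non-overlapping, genome order
            prev_end = a.end
            L = len(a.consensus_repeat)
            assert params.min_repeat_len <= L <= params.max_repeat_len
            for s in a.spacers:
                assert params.min_spacer_len <= len(s.sequence) <= params.max_spacer_len
            # consensus stability: recompute from reported units
            assert consensus_repeat([r.sequence for r in a.repeats]) == \
                a.consensus_repeat

    def test_subtype_metadata_attached_by_ordinal(self, study_sg):
        labels = {i: t["subtype"] for i, t in enumerate(study_sg.truth.arrays)}
        arrays = cs.detect_arrays(study_sg.genome, subtypes=labels)
        assert [a.subtype for a in arrays] == [
            t["subtype"] for t in study_sg.truth.arrays
        ]


def _toy_array(repeat="ACGTACGTACGTACGTACGTA", n_spacers=2, last_muts=0):
    """Build a CrisprArray in memory with optional trailer decay."""
    import random as _r

    rng = _r.Random(0)
    spacers = [random_dna(rng, 25) for _ in range(n_spacers)]
    units = [repeat] * (n_spacers + 1)
    if last_muts:
        tail = list(units[-1])
        for i in range(last_muts):
            pos = len(tail) - 1 - i
            tail[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tail[pos]]
        units[-1] = "".join(tail)
    seq = "T" * 200
    parts, starts, cursor = [], [], len(seq)
    for u, s in zip(units, spacers + [None]):
        starts.append(cursor)
        parts.append(u)
        cursor += len(u)
        if s:
            parts.append(s)
            cursor += len(s)
    full = seq + "".join(parts) + "G" * 200
    genome = Genome("toy", {"c1": full})
    from crisprself.arrays import _build_array

    return genome, _build_array("c1", full, starts, len(repeat))


class TestOrientArray:
    def test_degenerate_trailer_keeps_orientation(self):
        genome, arr = _toy_array(last_muts=3)
        oriented = orient_array(arr, genome)
        assert oriented.orientation == "+"

    def test_orientation_is_involution_under_genome_flip(self):
        genome, arr = _toy_array(last_muts=3)
        a1 = orient_array(arr, genome)
        a2 = orient_array(arr.reverse_complemented(), genome)
        assert a1.consensus_repeat == a2.consensus_repeat
        assert [r.sequence for r in a1.repeats] == [r.sequence for r in a2.repeats]

    def test_at_rich_tie_break_assigns_leader(self):
        # mismatch tie; left flank is all T (AT 100%), right all G (0%)
        genome, arr = _toy_array(last_muts=0)
        assert orient_array(arr, genome).orientation == "+"

    def test_manual_override_wins(self):
        genome, arr = _toy_array(last_muts=3)
        assert orient_array(arr, genome, override="-").orientation == "-"

    def test_reverse_complement_reverses_and_complements(self):
        _, arr = _toy_array(last_muts=1)
        rc = arr.reverse_complemented()
        assert rc.orientation == "-"
        assert rc.consensus_repeat == revcomp(arr.consensus_repeat)
        assert [s.sequence for s in rc.spacers] == [
            revcomp(s.sequence) for s in reversed(arr.spacers)
        ]
        assert rc.reverse_complemented().consensus_repeat == arr.consensus_repeat
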