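"""De novo CRISPR array detection.

A CRISPR array is a run of near-identical direct repeats (the units)
separated by unique spacers; n repeat units flank n-1 spacers.  Detection
is a seed-and-extend exact-repeat finder: exact k-mer matches (k=8 by
default) at a spacing compatible with one repeat + one spacer seed a
candidate repeat pair, the pair is extended to the maximal exact match,
and the candidate is then chained outward in both directions by scanning
for further units within the spacer-length envelope at or above the
identity floor relative to the initial unit.

The terminal unit of a run is allowed to decay below the identity floor
by a small slack (``trailer_slack`` extra mismatches) before the run is
cut, because trailer repeats of real arrays are commonly degenerate and
downstream mutation analysis depends on keeping them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from ._seq import at_fraction, mismatch_offsets, revcomp
from .genome_io import Genome, GenomicInterval


@dataclass(frozen=True)
class DetectionParams:
    """Detector envelope; defaults are the conventional CRT-like ranges."""

    min_repeat_len: int = 19
    max_repeat_len: int = 40
    min_spacer_len: int = 18
    max_spacer_len: int = 60
    min_repeats: int = 3
    identity_floor: float = 0.8
    seed_k: int = 8
    trailer_slack: int = 2
    flank_len: int = 150  # leader/trailer window used for orientation

    def __post_init__(self):
        if not 0 < self.min_repeat_len <= self.max_repeat_len:
            raise ValueError("bad repeat length range")
        if not 0 < self.min_spacer_len <= self.max_spacer_len:
            raise ValueError("bad spacer length range")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")
        if not 0 < self.identity_floor <= 1:
            raise ValueError("identity_floor must be in (0, 1]")
        if self.seed_k > self.min_repeat_len:
            raise ValueError("seed_k must not exceed min_repeat_len")


@dataclass(frozen=True)
class RepeatUnit:
    interval: GenomicInterval
    sequence: str
    mismatch_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class Spacer:
    interval: GenomicInterval
    sequence: str
    index: int  # 0 = leader-proximal under the array's chosen orientation


@dataclass
class CrisprArray:
    array_id: str
    contig_id: str
    repeats: list[RepeatUnit]
    spacers: list[Spacer]
    consensus_repeat: str
    orientation: str = "+"
    subtype: str | None = None

    def __post_init__(self):
        if len(self.repeats) != len(self.spacers) + 1:
            raise ValueError("an array must have exactly one more repeat than spacers")

    @property
    def start(self) -> int:
        return min(r.interval.start for r in self.repeats)

    @property
    def end(self) -> int:
        return max(r.interval.end for r in self.repeats)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.contig_id, self.start, self.end)

    def reverse_complemented(self) -> "CrisprArray":
        """Flip orientation: reverse unit order, complement all sequences.

        Genomic intervals are untouched; only the reading frame flips.
        """
        cons = revcomp(self.consensus_repeat)
        repeats = [
            RepeatUnit(
                r.interval,
                revcomp(r.sequence),
                tuple(_mismatches_vs(revcomp(r.sequence), cons)),
            )
            for r in reversed(self.repeats)
        ]
        spacers = [
            Spacer(s.interval, revcomp(s.sequence), i)
            for i, s in enumerate(reversed(self.spacers))
        ]
        return CrisprArray(
            self.array_id,
            self.contig_id,
            repeats,
            spacers,
            cons,
            "-" if self.orientation == "+" else "+",
            self.subtype,
        )


def _mismatches_vs(seq: str, cons: str) -> list[int]:
    n = min(len(seq), len(cons))
    return mismatch_offsets(seq[:n], cons[:n])


def consensus_repeat(repeat_sequences) -> str:
    """Column-wise majority consensus over the modal-length sequences.

    Sequences of the modal length vote per column (modal-length tie broken
    toward the smaller length); base ties resolve to the alphabetically
    smallest base.  Off-length units do not vote but are still compared to
    the result by callers.
    """
    seqs = list(repeat_sequences)
    if not seqs:
        raise ValueError("consensus_repeat requires at least one sequence")
    lengths = Counter(len(s) for s in seqs)
    top = max(lengths.values())
    modal_len = min(L for L, c in lengths.items() if c == top)
    voters = [s for s in seqs if len(s) == modal_len]
    cols = []
    for i in range(modal_len):
        counts = Counter(s[i] for s in voters if s[i] in "ACGT")
        if not counts:
            cols.append("N")
            continue
        best = max(counts.values())
        cols.append(min(b for b, c in counts.items() if c == best))
    return "".join(cols)


def _mm_limited(a: str, b: str, limit: int) -> int:
    """Hamming distance with early exit once ``limit`` is exceeded."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N" or y == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _seed_pairs(enc: np.ndarray, k: int, dmin: int, dmax: int):
    """Yield (p, q) start pairs of identical k-mers with q-p in [dmin, dmax]."""
    n = len(enc)
    if n < k:
        return []
    m = n - k + 1
    codes = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(k):
        codes = codes * 4 + enc[j : m + j]
        ok &= enc[j : m + j] < 4
    pos = np.nonzero(ok)[0]
    codes = codes[ok]
    order = np.argsort(codes, kind="stable")
    codes, pos = codes[order], pos[order]
    pairs = []
    i = 0
    m2 = len(codes)
    while i < m2:
        j = i + 1
        while j < m2 and codes[j] == codes[i]:
            j += 1
        if j - i > 1:
            grp = np.sort(pos[i:j])
            for a in range(len(grp)):
                for b in range(a + 1, len(grp)):
                    d = grp[b] - grp[a]
                    if d > dmax:
                        break
                    if d >= dmin:
                        pairs.append((int(grp[a]), int(grp[b])))
        i = j
    pairs.sort()
    return pairs


def _extend_seed(seq: str, p: int, q: int, params: DetectionParams):
    """Extend an exact k-mer pair to a maximal exact repeat; None if unusable."""
    n = len(seq)
    d = q - p
    k = params.seed_k
    cap = min(params.max_repeat_len, d - params.min_spacer_len)
    if cap < params.min_repeat_len:
        return None
    left = 0
    while (
        left + k < cap
        and p - left - 1 >= 0
        and seq[p - left - 1] == seq[q - left - 1]
        and seq[p - left - 1] != "N"
    ):
        left += 1
    right = 0
    while (
        left + k + right < cap
        and q + k + right < n
        and seq[p + k + right] == seq[q + k + right]
        and seq[p + k + right] != "N"
    ):
        right += 1
    length = left + k + right
    if length < params.min_repeat_len:
        return None
    spacer_len = d - length
    if not params.min_spacer_len <= spacer_len <= params.max_spacer_len:
        return None
    return p - left, length


def _chain(seq: str, start0: int, start1: int, length: int, params: DetectionParams):
    """Grow a unit run outward from an initial exact pair.

    Returns the list of unit start positions in genome order.  A unit
    within the identity floor extends the run; a unit within the floor
    plus trailer_slack is kept but terminates the run on that side.
    """
    cons = seq[start0 : start0 + length]
    mm_allow = int(length * (1 - params.identity_floor))
    n = len(seq)
    starts = [start0, start1]

    def best_at(lo: int, hi: int):
        best = None
        for s in range(lo, hi + 1):
            if s < 0 or s + length > n:
                continue
            mm = _mm_limited(cons, seq[s : s + length], mm_allow + params.trailer_slack)
            if best is None or mm < best[1]:
                best = (s, mm)
        return best

    while True:  # rightward
        last_end = starts[-1] + length
        best = best_at(last_end + params.min_spacer_len,
                       last_end + params.max_spacer_len)
        if best is None or best[1] > mm_allow + params.trailer_slack:
            break
        starts.append(best[0])
        if best[1] > mm_allow:
            break
    while True:  # leftward
        first = starts[0]
        best = best_at(first - length - params.max_spacer_len,
                       first - length - params.min_spacer_len)
        if best is None or best[1] > mm_allow + params.trailer_slack:
            break
        starts.insert(0, best[0])
        if best[1] > mm_allow:
            break
    return starts


def _refine_boundaries(
    seq: str, starts: list[int], length: int, params: DetectionParams,
    conservation_floor: float = 0.8,
):
    """Adjust unit boundaries by cross-unit column conservation.

    Pairwise exact extension of the seed can overrun the true repeat
    boundary wherever the two seeded spacers coincide by chance; with the
    full unit run available, a column belongs to the repeat only if a
    large majority of units agree on its base.  Boundary columns below
    ``conservation_floor`` are trimmed and conserved columns just outside
    are annexed, within the length envelope.  Returns (starts, length) or
    None when the refined repeat falls below the minimum length.
    """
    n = len(seq)
    n_units = len(starts)
    gaps = [starts[i + 1] - starts[i] for i in range(n_units - 1)]

    def conservation(col: int) -> float:
        counts: dict[str, int] = {}
        for s in starts:
            p = s + col
            if not 0 <= p < n:
                return 0.0
            b = seq[p]
            if b in "ACGT":
                counts[b] = counts.get(b, 0) + 1
        return max(counts.values()) / n_units if counts else 0.0

    lo, hi = 0, length  # repeat spans relative columns [lo, hi)

    def fits(new_len: int) -> bool:
        return (
            params.min_repeat_len <= new_len <= params.max_repeat_len
            and all(
                params.min_spacer_len <= g - new_len <= params.max_spacer_len
                for g in gaps
            )
        )

    while fits(hi - lo + 1) and conservation(lo - 1) >= conservation_floor:
        lo -= 1
    while fits(hi - lo + 1) and conservation(hi) >= conservation_floor:
        hi += 1
    while hi - lo > params.min_repeat_len and conservation(lo) < conservation_floor:
        if not fits(hi - lo - 1):
            break
        lo += 1
    while hi - lo > params.min_repeat_len and conservation(hi - 1) < conservation_floor:
        if not fits(hi - lo - 1):
            break
        hi -= 1
    new_len = hi - lo
    if not fits(new_len):
        return None
    return [s + lo for s in starts], new_len


def _build_array(
    contig_id: str, seq: str, starts: list[int], length: int
) -> CrisprArray:
    unit_seqs = [seq[s : s + length] for s in starts]
    cons = consensus_repeat(unit_seqs)
    repeats = [
        RepeatUnit(
            GenomicInterval(contig_id, s, s + length),
            u,
            tuple(_mismatches_vs(u, cons)),
        )
        for s, u in zip(starts, unit_seqs)
    ]
    spacers = [
        Spacer(
            GenomicInterval(contig_id, starts[i] + length, starts[i + 1]),
            seq[starts[i] + length : starts[i + 1]],
            i,
        )
        for i in range(len(starts) - 1)
    ]
    return CrisprArray("", contig_id, repeats, spacers, cons)


def orient_array(
    array: CrisprArray,
    genome: Genome,
    flank_len: int = 150,
    override: str | None = None,
) -> CrisprArray:
    """Choose array orientation (degenerate-trailer, AT-rich-leader rules).

    The orientation is picked so the terminal repeat carries at least as
    many consensus mismatches as the first repeat; a tie is broken toward
    placing the leader on the side whose ``flank_len``-nt flank has the
    higher A+T fraction.  ``override`` ('+' or '-') always wins.
    """
    if override in ("+", "-"):
        return array if array.orientation == override else array.reverse_complemented()
    first_mm = len(array.repeats[0].mismatch_positions)
    last_mm = len(array.repeats[-1].mismatch_positions)
    if first_mm > last_mm:
        return array.reverse_complemented()
    if first_mm < last_mm:
        return array
    seq = genome.contigs[array.contig_id]
    left = seq[max(0, array.start - flank_len) : array.start]
    right = seq[array.end : array.end + flank_len]
    if array.orientation == "-":
        left, right = right, left  # leader side in oriented frame
    if at_fraction(left) >= at_fraction(right):
        return array
    return array.reverse_complemented()


def detect_arrays(
    genome: Genome,
    params: DetectionParams | None = None,
    subtypes: dict | None = None,
    orientation_overrides: dict | None = None,
) -> list[CrisprArray]:
    """Detect CRISPR arrays in every contig of a genome.

    Returned arrays are non-overlapping, reported in genome order, and
    oriented (see :func:`orient_array`).  ``subtypes`` and
    ``orientation_overrides`` are optional metadata maps keyed by array
    ordinal (0-based, genome order) or by ``(contig_id, start)``.
    """
    params = params or DetectionParams()
    dmin = params.min_repeat_len + params.min_spacer_len
    dmax = params.max_repeat_len + params.max_spacer_len
    candidates: list[CrisprArray] = []

    for contig_id, seq in genome.contigs.items():
        if len(seq) < 2 * params.min_repeat_len + params.min_spacer_len:
            continue
        claimed: list[tuple[int, int]] = []

        def is_claimed(p: int) -> bool:
            return any(s <= p < e for s, e in claimed)

        for p, q in _seed_pairs(genome.encoded(contig_id), params.seed_k, dmin, dmax):
            if is_claimed(p) and is_claimed(q):
                continue
            ext = _extend_seed(seq, p, q, params)
            if ext is None:
                continue
            start0, length = ext
            starts = _chain(seq, start0, start0 + (q - p), length, params)
            if len(starts) < params.min_repeats:
                continue
            if any(
                not params.min_spacer_len
                <= starts[i + 1] - starts[i] - length
                <= params.max_spacer_len
                for i in range(len(starts) - 1)
            ):
                continue
            refined = _refine_boundaries(seq, starts, length, params)
            if refined is None:
                continue
            starts, length = refined
            arr = _build_array(contig_id, seq, starts, length)
            candidates.append(arr)
            claimed.append((arr.start, arr.end))

    # Overlap resolution: more repeat units wins, then the longer span.
    candidates.sort(
        key=lambda a: (-len(a.repeats), -(a.end - a.start), a.contig_id, a.start)
    )
    kept: list[CrisprArray] = []
    for arr in candidates:
        if not any(
            k.contig_id == arr.contig_id and k.start < arr.end and arr.start < k.end
            for k in kept
        ):
            kept.append(arr)
    order = {cid: i for i, cid in enumerate(genome.contigs)}
    kept.sort(key=lambda a: (order[a.contig_id], a.start))

    out = []
    for i, arr in enumerate(kept):
        arr.array_id = f"{arr.contig_id}_array{i + 1}"
        key_pos = (arr.contig_id, arr.start)
        override = None
        if orientation_overrides:
            override = orientation_overrides.get(i, orientation_overrides.get(key_pos))
        arr = orient_array(arr, genome, params.flank_len, override)
        if subtypes:
            arr.subtype = subtypes.get(i, subtypes.get(key_pos, arr.subtype))
        out.append(arr)
    return out


def write_arrays_tsv(arrays, path) -> None:
    import pandas as pd

    rows = [
        {
            "array_id": a.array_id,
            "contig": a.contig_id,
            "start": a.start,
            "end": a.end,
            "n_repeats": len(a.repeats),
            "n_spacers": len(a.spacers),
            "consensus_repeat": a.consensus_repeat,
            "orientation": a.orientation,
            "subtype": a.subtype or "",
        }
        for a in arrays
    ]
    pd.DataFrame(
        rows,
        columns=[
            "array_id", "contig", "start", "end", "n_repeats", "n_spacers",
            "consensus_repeat", "orientation", "subtype",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_arrays_gff3(arrays, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in arrays:
            fh.write(
                f"{a.contig_id}\tcrisprself\tCRISPR_array\t{a.start + 1}\t{a.end}"
                f"\t.\t{a.orientation}\t.\tID={a.array_id}"
                f";consensus={a.consensus_repeat}\n"
            )
            for r in a.repeats:
                fh.write(
                    f"{a.contig_id}\tcrisprself\trepeat_unit\t{r.interval.start + 1}"
                    f"\t{r.interval.end}\t.\t{a.orientation}\t.\t"
                    f"Parent={a.array_id};array_id={a.array_id}\n"
                )
            for s in a.spacers:
                fh.write(
                    f"{a.contig_id}\tcrisprself\tspacer\t{s.interval.start + 1}"
                    f"\t{s.interval.end}\t.\t{a.orientation}\t.\t"
                    f"Parent={a.array_id};array_id={a.array_id};index={s.index}\n"
                )
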