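"""Mutation calling in the repeats flanking a self-targeting spacer.

Repeat decay around a self-targeting spacer is one escape route from
CRISPR autoimmunity: mutations in the flanking repeats can abolish crRNA
maturation or effector binding.  Each flanking repeat unit is compared
position-by-position against the array's consensus repeat; every
mismatch is reported with its offset, the consensus base, the observed
base, and a positional class (5'-end / middle / 3'-end by thirds of the
consensus length).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

from .arrays import CrisprArray, RepeatUnit


@dataclass(frozen=True)
class RepeatMutation:
    offset: int  # 0-based offset in the consensus
    consensus_base: str
    observed_base: str
    positional_class: str  # {5'-end, middle, 3'-end}


@dataclass
class FlankingRepeatReport:
    array_id: str
    spacer_index: int
    upstream_repeat: RepeatUnit
    downstream_repeat: RepeatUnit
    upstream_mutations: list[RepeatMutation]
    downstream_mutations: list[RepeatMutation]
    #: bases by which each unit is shorter/longer than the consensus;
    #: length-discordant tails are reported here, never as substitutions
    upstream_length_difference: int = 0
    downstream_length_difference: int = 0


def positional_class(offset: int, consensus_length: int) -> str:
    """Class by thirds of the consensus (ceil division for boundaries)."""
    b1 = ceil(consensus_length / 3)
    b2 = ceil(2 * consensus_length / 3)
    if offset < b1:
        return "5'-end"
    if offset < b2:
        return "middle"
    return "3'-end"


def _compare(unit: RepeatUnit, consensus: str) -> tuple[list[RepeatMutation], int]:
    # Gapless comparison anchored at the 5' end; the unmatched tail of a
    # length-discordant unit is an indel annotation, not substitutions.
    n = min(len(unit.sequence), len(consensus))
    muts = [
        RepeatMutation(i, consensus[i], unit.sequence[i],
                       positional_class(i, len(consensus)))
        for i in range(n)
        if unit.sequence[i] != consensus[i]
    ]
    return muts, len(unit.sequence) - len(consensus)


def call_repeat_mutations(array: CrisprArray, spacer_index: int) -> FlankingRepeatReport:
    """Mutations in the two repeats flanking one spacer.

    Under the array's chosen orientation the upstream repeat is
    ``repeats[spacer_index]`` and the downstream repeat is
    ``repeats[spacer_index + 1]``.
    """
    if not 0 <= spacer_index < len(array.spacers):
        raise IndexError(
            f"spacer index {spacer_index} out of range for array "
            f"{array.array_id} with {len(array.spacers)} spacers"
        )
    up = array.repeats[spacer_index]
    down = array.repeats[spacer_index + 1]
    up_muts, up_dlen = _compare(up, array.consensus_repeat)
    down_muts, down_dlen = _compare(down, array.consensus_repeat)
    return FlankingRepeatReport(
        array.array_id, spacer_index, up, down, up_muts, down_muts,
        up_dlen, down_dlen,
    )


def write_reports_tsv(reports, path) -> None:
    import pandas as pd

    rows = []
    for rep in reports:
        for side, muts, dlen in (
            ("upstream", rep.upstream_mutations, rep.upstream_length_difference),
            ("downstream", rep.downstream_mutations, rep.downstream_length_difference),
        ):
            rows.append(
                {
                    "array_id": rep.array_id,
                    "spacer_index": rep.spacer_index,
                    "side": side,
                    "n_mutations": len(muts),
                    "offsets": ",".join(str(m.offset) for m in muts),
                    "classes": ",".join(m.positional_class for m in muts),
                    "length_difference": dlen,
                }
            )
    pd.DataFrame(
        rows,
        columns=["array_id", "spacer_index", "side", "n_mutations",
                 "offsets", "classes", "length_difference"],
    ).to_csv(path, sep="\t", index=False)
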