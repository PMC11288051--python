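"""Comparative descriptive statistics of CRISPR arrays by subtype.

Per subtype: repeat- and spacer-length abundance histograms (counted per
unit, i.e. every repeat unit and every spacer contributes), modal
lengths (ties toward the smaller length), and the spacers-per-array
distribution summarised by median and quartiles under the inclusive
linear-interpolation method.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass
class SubtypeStats:
    subtype: str
    repeat_length_histogram: dict[int, int]
    spacer_length_histogram: dict[int, int]
    modal_repeat_length: int
    modal_spacer_length: int | None
    spacers_per_array: list[int]
    median_spacers: float
    q1_spacers: float
    q3_spacers: float


def _mode(hist: dict[int, int]) -> int | None:
    if not hist:
        return None
    top = max(hist.values())
    return min(k for k, v in hist.items() if v == top)


def quartiles(values) -> tuple[float, float, float]:
    """(Q1, median, Q3) by inclusive linear interpolation."""
    arr = np.sort(np.asarray(list(values), dtype=float))
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def subtype_statistics(arrays) -> list[SubtypeStats]:
    """Descriptive stats per subtype; unlabelled arrays fall under 'unknown'.

    Subtypes with zero arrays are simply absent; a notice is logged for
    any requested label that contributed nothing.
    """
    by_subtype: dict[str, list] = {}
    for a in arrays:
        by_subtype.setdefault(a.subtype or "unknown", []).append(a)

    out = []
    for subtype in sorted(by_subtype):
        group = by_subtype[subtype]
        if not group:
            log.info("subtype %s has no arrays; omitted", subtype)
            continue
        rep_hist = Counter(len(r.sequence) for a in group for r in a.repeats)
        sp_hist = Counter(len(s.sequence) for a in group for s in a.spacers)
        spacer_counts = [len(a.spacers) for a in group]
        q1, med, q3 = quartiles(spacer_counts)
        out.append(
            SubtypeStats(
                subtype=subtype,
                repeat_length_histogram=dict(sorted(rep_hist.items())),
                spacer_length_histogram=dict(sorted(sp_hist.items())),
                modal_repeat_length=_mode(rep_hist),
                modal_spacer_length=_mode(sp_hist),
                spacers_per_array=spacer_counts,
                median_spacers=med,
                q1_spacers=q1,
                q3_spacers=q3,
            )
        )
    return out


def write_stats_tsv(stats, path) -> None:
    import pandas as pd

    rows = [
        {
            "subtype": s.subtype,
            "n_arrays": len(s.spacers_per_array),
            "modal_repeat_length": s.modal_repeat_length,
            "modal_spacer_length": s.modal_spacer_length,
            "median_spacers_per_array": s.median_spacers,
            "q1_spacers_per_array": s.q1_spacers,
            "q3_spacers_per_array": s.q3_spacers,
            "repeat_length_histogram": ";".join(
                f"{k}:{v}" for k, v in s.repeat_length_histogram.items()
            ),
            "spacer_length_histogram": ";".join(
                f"{k}:{v}" for k, v in s.spacer_length_histogram.items()
            ),
        }
        for s in stats
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
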