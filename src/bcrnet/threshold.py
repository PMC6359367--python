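"""Distance-threshold selection by the HCDR3-ratio criterion.

For each candidate Levenshtein threshold t, the pooled graph is built,
components of fewer than ``min_component_size`` vertices are set aside,
and each remaining component's HCDR3 ratio is computed. Vertex counts are
binned by ratio in tenths; the chosen threshold is the one that maximizes
the number of vertices living in components with ratio below the cutoff
(default 0.3). Too small a t fragments lineages (vertices fall into the
excluded small components); too large a t fuses unrelated lineages
(components drift above the cutoff); the argmax balances both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import cdr3, network
from .cdr3 import Hcdr3Annotation
from .distance import NeighborPair
from .repertoire import RepertoireCollection

#: Ratio bins: left-closed, right-open tenths; the last bin includes 1.0.
BIN_EDGES = [(i / 10, (i + 1) / 10) for i in range(10)]


@dataclass
class SweepRecord:
    t: int
    bins: dict[tuple[float, float], int] = field(default_factory=dict)
    vertices_low_ratio: int = 0
    n_excluded_small: int = 0

    def total_binned(self) -> int:
        return sum(self.bins.values())


def _bin_index(ratio: float) -> int:
    # ratio == 1.0 folds into the top bin
    return min(int(ratio * 10), 9)


def sweep(
    collection: RepertoireCollection,
    pairs: Iterable[NeighborPair],
    t_range: Iterable[int] = range(1, 21),
    min_component_size: int = 3,
    ratio_cutoff: float = 0.3,
    annotations: Mapping[int, Hcdr3Annotation] | None = None,
) -> list[SweepRecord]:
    """One SweepRecord per threshold in ``t_range``.

    ``pairs`` must cover the largest threshold swept. Components smaller
    than ``min_component_size`` are excluded from the binning (their vertex
    count is reported in ``n_excluded_small``); the low-ratio tally uses a
    strict ``ratio < ratio_cutoff`` comparison.
    """
    pairs = list(pairs)
    if annotations is None:
        annotations = cdr3.annotate_collection(collection)
    records: list[SweepRecord] = []
    for t in t_range:
        graph = network.build_graph(collection, pairs, t)
        comps = network.components(graph)
        rec = SweepRecord(t=t, bins={edges: 0 for edges in BIN_EDGES})
        for comp in comps:
            if comp.n_vertices < min_component_size:
                rec.n_excluded_small += comp.n_vertices
                continue
            ratio = cdr3.hcdr3_ratio(comp, annotations)
            rec.bins[BIN_EDGES[_bin_index(ratio)]] += comp.n_vertices
            if ratio < ratio_cutoff:
                rec.vertices_low_ratio += comp.n_vertices
        records.append(rec)
    return records


def select_threshold(records: Sequence[SweepRecord]) -> int:
    """Threshold with the most vertices in low-ratio components.

    Ties resolve toward the smaller t, which minimizes inclusion of
    unrelated sequences. Invariant to record order.
    """
    if not records:
        raise ValueError("no sweep records")
    best = max(sorted(records, key=lambda r: r.t), key=lambda r: r.vertices_low_ratio)
    # max() keeps the first of equals on the t-sorted list -> smallest t
    return best.t


def sweep_frame(records: Sequence[SweepRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict = {"t": rec.t}
        for (lo, hi), count in rec.bins.items():
            row[f"ratio_{lo:.1f}_{hi:.1f}"] = count
        row["vertices_low_ratio"] = rec.vertices_low_ratio
        row["n_excluded_small"] = rec.n_excluded_small
        rows.append(row)
    return pd.DataFrame(rows)


def write_sweep_tsv(records: Sequence[SweepRecord], path) -> None:
    sweep_frame(records).to_csv(path, sep="\t", index=False)
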