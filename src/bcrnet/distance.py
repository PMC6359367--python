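"""Levenshtein distances and threshold neighbor enumeration.

The lineage network treats each unique V_H sequence as a vertex and joins
pairs whose Levenshtein distance (minimum single-character insertions,
deletions and substitutions) does not exceed a threshold. Enumerating the
neighbor pairs is the only quadratic step of the pipeline, so it avoids
materializing the full distance matrix: sequences are bucketed by length
(a pair whose lengths differ by more than t cannot be within t) and each
remaining pair is tested with a banded computation that abandons the
alignment as soon as the distance provably exceeds t. Neither shortcut
changes the result relative to brute-force all-pairs.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import edlib
import pandas as pd

from .repertoire import RepertoireCollection


class NeighborPair(NamedTuple):
    """An edge candidate: vertex ids in canonical order and their distance."""

    vertex_id_a: int
    vertex_id_b: int
    ld: int


def levenshtein(a: str, b: str, k: int | None = None) -> int:
    """Levenshtein distance between two strings.

    With ``k`` set, computation is banded: the exact distance is returned
    when it is <= k, otherwise -1. Empty strings are legal; the distance
    degenerates to the other string's length.
    """
    if a == b:
        return 0
    if not a or not b:
        d = len(a) or len(b)
        return d if k is None or d <= k else -1
    if k is None:
        return edlib.align(a, b, task="distance")["editDistance"]
    if abs(len(a) - len(b)) > k:
        return -1
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def neighbors_within(collection: RepertoireCollection, t: int) -> list[NeighborPair]:
    """All vertex pairs with ``1 <= LD <= t``, in canonical (a, b) order.

    Equivalent to brute-force all-vs-all; length bucketing and the banded
    distance are performance devices only.
    """
    if t < 1:
        raise ValueError("threshold must be >= 1")
    # sort by length so the inner loop can stop once lengths drift apart
    verts = sorted(collection.vertices, key=lambda v: (len(v.sequence), v.vertex_id))
    pairs: list[NeighborPair] = []
    for i, va in enumerate(verts):
        la = len(va.sequence)
        for vb in verts[i + 1 :]:
            if len(vb.sequence) - la > t:
                break
            d = levenshtein(va.sequence, vb.sequence, k=t)
            if d != -1 and d >= 1:
                a, b = sorted((va.vertex_id, vb.vertex_id))
                pairs.append(NeighborPair(a, b, d))
    pairs.sort()
    return pairs


def pairs_to_frame(pairs: Iterable[NeighborPair]) -> pd.DataFrame:
    return pd.DataFrame(pairs, columns=["vertex_id_a", "vertex_id_b", "ld"])


def write_pairs_tsv(pairs: Iterable[NeighborPair], path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def read_pairs_tsv(path) -> list[NeighborPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        NeighborPair(int(r.vertex_id_a), int(r.vertex_id_b), int(r.ld))
        for r in df.itertuples()
    ]
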