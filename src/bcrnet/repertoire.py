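"""Core containers for a deduplicated V_H repertoire observed over time.

A repertoire here is the pooled set of unique heavy-chain variable-domain
(V_H) nucleotide sequences observed across an ordered series of sampling
time points, each sequence carrying a read count per time point. Sequences
are the *vertices* of the homology network built downstream; a sequence
observed at several time points is a single vertex.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

#: Default sampling schedule: pre-immune baseline, two boosts, sacrifice.
DEFAULT_TIMEPOINTS: tuple[str, ...] = ("wk0", "wk2", "wk4", "wk5")

_VALID_NT = frozenset("ACGTN")


@dataclass
class VhVertex:
    """One unique V_H nucleotide sequence with per-time-point read counts."""

    vertex_id: int
    sequence: str
    counts: dict[str, int]
    hcdr3_aa: str | None = None

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class RepertoireCollection:
    """Pooled, deduplicated vertex set over all time points.

    Invariants (see :meth:`validate`): vertex sequences are pairwise
    distinct, every vertex has counts for every declared time point
    (zero-filled) with at least one positive, and ``totals`` is the
    column sum of the count matrix.
    """

    timepoints: tuple[str, ...]
    vertices: list[VhVertex] = field(default_factory=list)

    @property
    def totals(self) -> dict[str, int]:
        tot = {t: 0 for t in self.timepoints}
        for v in self.vertices:
            for t in self.timepoints:
                tot[t] += v.counts.get(t, 0)
        return tot

    def __len__(self) -> int:
        return len(self.vertices)

    def __iter__(self):
        return iter(self.vertices)

    def vertex(self, vertex_id: int) -> VhVertex:
        return self._by_id[vertex_id]

    @property
    def _by_id(self) -> dict[int, VhVertex]:
        return {v.vertex_id: v for v in self.vertices}

    # -- construction -------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, Mapping[str, int]],
        timepoints: Iterable[str] = DEFAULT_TIMEPOINTS,
    ) -> "RepertoireCollection":
        """Build a collection from ``{sequence: {timepoint: count}}``.

        Vertex ids are assigned 0..n-1 in order of decreasing total count,
        ties broken by sequence, so ids are reproducible for a given table.
        """
        tps = tuple(timepoints)
        rows = []
        for seq, per_tp in counts.items():
            filled = {t: int(per_tp.get(t, 0)) for t in tps}
            rows.append((seq, filled))
        rows.sort(key=lambda r: (-sum(r[1].values()), r[0]))
        vertices = [
            VhVertex(vertex_id=i, sequence=seq, counts=filled)
            for i, (seq, filled) in enumerate(rows)
        ]
        coll = cls(timepoints=tps, vertices=vertices)
        coll.validate()
        return coll

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated container invariant."""
        seen: set[str] = set()
        for v in self.vertices:
            if not v.sequence:
                raise ValueError(f"vertex {v.vertex_id}: empty sequence")
            bad = set(v.sequence) - _VALID_NT
            if bad:
                raise ValueError(
                    f"vertex {v.vertex_id}: non-nucleotide characters {sorted(bad)}"
                )
            if v.sequence in seen:
                raise ValueError(f"duplicate sequence at vertex {v.vertex_id}")
            seen.add(v.sequence)
            if set(v.counts) != set(self.timepoints):
                raise ValueError(
                    f"vertex {v.vertex_id}: counts not aligned to timepoints"
                )
            if any(c < 0 for c in v.counts.values()):
                raise ValueError(f"vertex {v.vertex_id}: negative count")
            if sum(v.counts.values()) == 0:
                raise ValueError(f"vertex {v.vertex_id}: all counts zero")

    # -- IO ------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Wide AIRR-flavoured table: sequence_id, sequence, duplicate_count_<tp>."""
        data = {
            "sequence_id": [v.vertex_id for v in self.vertices],
            "sequence": [v.sequence for v in self.vertices],
        }
        for t in self.timepoints:
            data[f"duplicate_count_{t}"] = [v.counts[t] for v in self.vertices]
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RepertoireCollection":
        prefix = "duplicate_count_"
        tps = tuple(c[len(prefix):] for c in df.columns if c.startswith(prefix))
        vertices = [
            VhVertex(
                vertex_id=int(row["sequence_id"]),
                sequence=str(row["sequence"]),
                counts={t: int(row[prefix + t]) for t in tps},
            )
            for _, row in df.iterrows()
        ]
        coll = cls(timepoints=tps, vertices=vertices)
        coll.validate()
        return coll

    @classmethod
    def from_tsv(cls, path) -> "RepertoireCollection":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_long_tsv(cls, path, timepoints=None) -> "RepertoireCollection":
        """Read a long-form (sequence, timepoint, count) table.

        This is the preprocessing bypass: an externally corrected unique-
        sequence table enters the pipeline here.
        """
        df = pd.read_csv(path, sep="\t")
        tps = tuple(timepoints) if timepoints else tuple(
            dict.fromkeys(df["timepoint"].astype(str))
        )
        counts: dict[str, dict[str, int]] = {}
        for _, row in df.iterrows():
            counts.setdefault(str(row["sequence"]), {}).setdefault(
                str(row["timepoint"]), 0
            )
            counts[str(row["sequence"])][str(row["timepoint"])] += int(row["count"])
        return cls.from_counts(counts, tps)

    def summary(self) -> dict:
        return {
            "n_unique_sequences": len(self),
            "timepoints": list(self.timepoints),
            "totals": self.totals,
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)
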