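"""Clonal-frequency time courses and candidate-lineage ranking.

A vertex's clonal frequency at a time point is its read count divided by
that time point's total read count, so frequencies sum to one within each
transcript set. A component's average clonal frequency is the mean over
all of its member vertices (zero-count members included by default, since
a lineage member unseen at a time point genuinely has frequency zero
there). Antigen-driven lineages are expected to gain unique members
(diversification) and frequency mass (preferential proliferation) between
the first and last time points; candidates are components that clear joint
thresholds on both changes, ranked by the sum of their ranks on the two.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .network import Component
from .repertoire import RepertoireCollection, VhVertex


def clonal_frequency(
    vertex: VhVertex, timepoint: str, collection: RepertoireCollection
) -> float:
    """Read count of the vertex over the time point's total read count."""
    total = collection.totals[timepoint]
    if total == 0:
        raise ValueError(f"no reads at {timepoint}: frequency undefined")
    return vertex.counts[timepoint] / total


def avg_clonal_frequency(
    component: Component,
    timepoint: str,
    collection: RepertoireCollection,
    mode: str = "all",
) -> float:
    """Mean clonal frequency over the component's members.

    ``mode="all"`` averages over every member vertex (zero counts
    included); ``mode="active"`` averages only over members with a nonzero
    count, returning 0.0 when none are active.
    """
    if mode not in ("all", "active"):
        raise ValueError(f"unknown mode {mode!r}")
    by_id = collection._by_id
    freqs = [
        clonal_frequency(by_id[vid], timepoint, collection)
        for vid in component.vertex_ids
    ]
    if mode == "active":
        freqs = [f for f in freqs if f > 0]
        if not freqs:
            return 0.0
    return sum(freqs) / len(freqs)


@dataclass
class ComponentDynamics:
    component_id: int
    n_vertices: int
    n_vertices_active: dict[str, int] = field(default_factory=dict)
    avg_freq: dict[str, float] = field(default_factory=dict)
    delta_vertices: int = 0
    delta_avg_freq: float = 0.0
    fold_freq: float = 1.0
    candidate_score: float = 0.0


def component_dynamics(
    component: Component,
    collection: RepertoireCollection,
    mode: str = "all",
) -> ComponentDynamics:
    """Per-time-point activity and frequency, with first-to-last deltas.

    The frequency fold change is additively smoothed (one pseudo-read
    added to the component's total at each endpoint) so a lineage absent
    at baseline gets a finite, large fold rather than a division by zero.
    """
    tps = collection.timepoints
    if len(tps) < 2:
        raise ValueError("dynamics require at least two time points")
    by_id = collection._by_id
    dyn = ComponentDynamics(
        component_id=component.component_id, n_vertices=component.n_vertices
    )
    for t in tps:
        dyn.n_vertices_active[t] = sum(
            1 for vid in component.vertex_ids if by_id[vid].counts[t] > 0
        )
        dyn.avg_freq[t] = avg_clonal_frequency(component, t, collection, mode=mode)
    first, last = tps[0], tps[-1]
    dyn.delta_vertices = dyn.n_vertices_active[last] - dyn.n_vertices_active[first]
    dyn.delta_avg_freq = dyn.avg_freq[last] - dyn.avg_freq[first]
    dyn.fold_freq = _smoothed_fold(component, collection, first, last)
    return dyn


def _smoothed_fold(
    component: Component, collection: RepertoireCollection, first: str, last: str
) -> float:
    by_id = collection._by_id
    n = component.n_vertices

    def smoothed_avg(t: str) -> float:
        count = sum(by_id[vid].counts[t] for vid in component.vertex_ids) + 1
        return count / collection.totals[t] / n

    return smoothed_avg(last) / smoothed_avg(first)


def rank_candidates(
    dynamics_list: Sequence[ComponentDynamics],
    min_delta_vertices: int = 5,
    min_fold_freq: float = 2.0,
) -> list[ComponentDynamics]:
    """Components passing both expansion thresholds, best-ranked first.

    Each passing component is ranked separately on member gain and on
    frequency fold change (1 = largest); ``candidate_score`` is the rank
    sum, lower is better, ties broken by component id. Raising either
    threshold can only shrink the candidate list.
    """
    passing = [
        d
        for d in dynamics_list
        if d.delta_vertices >= min_delta_vertices and d.fold_freq >= min_fold_freq
    ]
    if not passing:
        return []
    by_dv = sorted(passing, key=lambda d: (-d.delta_vertices, d.component_id))
    by_ff = sorted(passing, key=lambda d: (-d.fold_freq, d.component_id))
    rank_dv = {d.component_id: i + 1 for i, d in enumerate(by_dv)}
    rank_ff = {d.component_id: i + 1 for i, d in enumerate(by_ff)}
    for d in passing:
        d.candidate_score = rank_dv[d.component_id] + rank_ff[d.component_id]
    return sorted(passing, key=lambda d: (d.candidate_score, d.component_id))


def dynamics_frame(dynamics_list: Sequence[ComponentDynamics]) -> pd.DataFrame:
    rows = []
    for d in sorted(dynamics_list, key=lambda x: x.component_id):
        row: dict = {"component_id": d.component_id, "n_vertices": d.n_vertices}
        for t, n in d.n_vertices_active.items():
            row[f"active_{t}"] = n
        for t, f in d.avg_freq.items():
            row[f"avg_freq_{t}"] = f
        row["delta_vertices"] = d.delta_vertices
        row["delta_avg_freq"] = d.delta_avg_freq
        row["fold_freq"] = d.fold_freq
        row["candidate_score"] = d.candidate_score
        rows.append(row)
    return pd.DataFrame(rows)


def write_dynamics_tsv(dynamics_list: Sequence[ComponentDynamics], path) -> None:
    dynamics_frame(dynamics_list).to_csv(path, sep="\t", index=False)
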