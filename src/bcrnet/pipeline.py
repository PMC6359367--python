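"""End-to-end orchestration: reads in, ranked candidate lineages out.

Stage order: preprocess -> neighbor pairs -> threshold sweep/selection ->
graph/components/naming -> HCDR3 annotation -> dynamics -> candidate
ranking. Every stage writes its tabular output into the run directory, so
a run can be resumed or inspected mid-way, and the final JSON report
collects the census and the candidates. The report contains no
timestamps: two runs on identical inputs and config are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import cdr3, distance, dynamics, network, plots, threshold
from .preprocess import PrimerPair, preprocess_fastq
from .repertoire import RepertoireCollection

log = logging.getLogger("bcrnet")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to/from JSON or YAML."""

    fastq: dict[str, str] = field(default_factory=dict)  # timepoint -> path
    sequence_table: str | None = None  # long TSV bypass (sequence, timepoint, count)
    timepoints: list[str] | None = None
    forward_primer: str = PrimerPair.forward
    reverse_primer: str = PrimerPair.reverse
    primer_max_mismatches: int = 2
    quality_q: int = 20
    quality_p: float = 1.0
    ld_merge: int = 1
    merge_ratio: float = 0.1
    sweep_min: int = 1
    sweep_max: int = 20
    min_component_size: int = 3
    ratio_cutoff: float = 0.3
    fixed_threshold: int | None = None  # skip selection and use this t
    min_delta_vertices: int = 5
    min_fold_freq: float = 2.0
    avg_mode: str = "all"
    outdir: str = "bcrnet_run"
    seed: int = 0
    figures: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls(**data)

    def validate(self) -> None:
        if not self.fastq and not self.sequence_table:
            raise ValueError("no input: provide fastq paths or a sequence_table")
        for tp, p in self.fastq.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"{tp}: {p}")
        if self.sequence_table and not Path(self.sequence_table).exists():
            raise FileNotFoundError(self.sequence_table)
        if self.sweep_min < 1 or self.sweep_max < self.sweep_min:
            raise ValueError("invalid sweep range")


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the run report (also written
    to ``<outdir>/report.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config)}

    # -- preprocess ----------------------------------------------------
    t0 = _stage("preprocess")
    if config.sequence_table:
        collection = RepertoireCollection.from_long_tsv(
            config.sequence_table, timepoints=config.timepoints
        )
        report["preprocess"] = {"bypass": True,
                                "n_unique_sequences": len(collection)}
    else:
        primers = PrimerPair(
            forward=config.forward_primer,
            reverse=config.reverse_primer,
            max_mismatches=config.primer_max_mismatches,
        )
        collection, pre_report = preprocess_fastq(
            config.fastq,
            primers=primers,
            q=config.quality_q,
            p=config.quality_p,
            ld_merge=config.ld_merge,
            ratio=config.merge_ratio,
        )
        report["preprocess"] = pre_report
    if len(collection) == 0:
        raise RuntimeError("preprocess: no sequences survived; aborting")
    collection.to_tsv(outdir / "sequences.tsv")
    report["n_unique_sequences"] = len(collection)
    report["totals"] = collection.totals
    log.info("preprocess: %d unique sequences (%.1fs)",
             len(collection), time.perf_counter() - t0)

    # -- distances -----------------------------------------------------
    t0 = _stage("distance")
    t_max = max(config.sweep_max, config.fixed_threshold or 0)
    pairs = distance.neighbors_within(collection, t_max)
    distance.write_pairs_tsv(pairs, outdir / "pairs.tsv")
    log.info("distance: %d pairs within %d (%.1fs)",
             len(pairs), t_max, time.perf_counter() - t0)

    # -- HCDR3 annotation ---------------------------------------------
    t0 = _stage("cdr3")
    annotations = cdr3.annotate_collection(collection)
    cdr3.write_annotations_tsv(annotations, outdir / "hcdr3.tsv")
    n_found = sum(1 for a in annotations.values() if a.status == "found")
    report["hcdr3_annotated"] = n_found
    log.info("cdr3: %d/%d annotated (%.1fs)",
             n_found, len(collection), time.perf_counter() - t0)

    # -- threshold sweep ----------------------------------------------
    t0 = _stage("sweep")
    records = threshold.sweep(
        collection,
        pairs,
        t_range=range(config.sweep_min, config.sweep_max + 1),
        min_component_size=config.min_component_size,
        ratio_cutoff=config.ratio_cutoff,
        annotations=annotations,
    )
    threshold.write_sweep_tsv(records, outdir / "sweep.tsv")
    selected_t = (
        config.fixed_threshold
        if config.fixed_threshold is not None
        else threshold.select_threshold(records)
    )
    report["selected_threshold"] = selected_t
    report["sweep"] = {
        str(r.t): {"vertices_low_ratio": r.vertices_low_ratio,
                   "excluded_small": r.n_excluded_small}
        for r in records
    }
    log.info("sweep: selected t=%d (%.1fs)", selected_t, time.perf_counter() - t0)

    # -- graph & components -------------------------------------------
    t0 = _stage("cluster")
    graph = network.build_graph(collection, pairs, selected_t)
    comps = network.name_components(network.components(graph), collection)
    retained, census = network.filter_singletons(comps)
    network.write_membership_tsv(comps, outdir / "components.tsv")
    network.write_graphml(graph, outdir / "graph.graphml")
    mst_edges = []
    for comp in retained:
        mst_edges.extend(
            (comp.component_id, e.vertex_id_a, e.vertex_id_b, e.ld)
            for e in network.mst(comp, pairs)
        )
    with open(outdir / "mst.tsv", "w") as fh:
        fh.write("component_id\tvertex_id_a\tvertex_id_b\tld\n")
        for row in mst_edges:
            fh.write("\t".join(map(str, row)) + "\n")
    report["census"] = dict(census, n_edges=graph.number_of_edges())
    log.info("cluster: %(total_components)d components, "
             "%(singleton_components)d singletons, %(retained_components)d retained"
             % census + " (%.1fs)" % (time.perf_counter() - t0))

    # -- dynamics & candidates ----------------------------------------
    t0 = _stage("dynamics")
    dyns = [
        dynamics.component_dynamics(c, collection, mode=config.avg_mode)
        for c in retained
    ]
    candidates = dynamics.rank_candidates(
        dyns,
        min_delta_vertices=config.min_delta_vertices,
        min_fold_freq=config.min_fold_freq,
    )
    dynamics.write_dynamics_tsv(dyns, outdir / "dynamics.tsv")
    report["candidates"] = [
        {
            "component_id": d.component_id,
            "n_vertices": d.n_vertices,
            "delta_vertices": d.delta_vertices,
            "fold_freq": round(d.fold_freq, 6),
            "candidate_score": d.candidate_score,
        }
        for d in candidates
    ]
    log.info("dynamics: %d candidates (%.1fs)",
             len(candidates), time.perf_counter() - t0)

    if config.figures:
        plots.sweep_heatmap(records, outdir / "fig_sweep_heatmap.png")
        plots.low_ratio_histogram(records, config.ratio_cutoff,
                                  outdir / "fig_low_ratio.png")
        plots.dynamics_scatter(dyns, candidates, outdir / "fig_dynamics.png")

    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
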