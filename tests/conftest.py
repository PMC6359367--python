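from __future__ import annotations

import pytest

from bcrnet import RunConfig, SimConfig, run_pipeline, simulate_repertoire
from bcrnet.repertoire import RepertoireCollection

TPS = ("wk0", "wk2", "wk4", "wk5")


@pytest.fixture()
def toy_collection() -> RepertoireCollection:
    """Four hand-picked sequences with easy-to-reason-about counts."""
    return RepertoireCollection.from_counts(
        {
            "ACGTACGTACGT": {"wk0": 10, "wk5": 7},
            "ACGTACGTACGA": {"wk0": 5},
            "ACGTACGAACGA": {"wk5": 3},
            "TTTTGGGGCCCC": {"wk0": 5, "wk5": 10},
        },
        timepoints=("wk0", "wk5"),
    )


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A compact simulated time course shared by the integration tests."""
    cfg = SimConfig(
        n_lineages=6,
        n_expanded=2,
        reads_per_timepoint={tp: 700 for tp in TPS},
        n_baseline_daughters=5,
        novel_daughters_per_boost=4,
        seed=11,
    )
    outdir = tmp_path_factory.mktemp("sim_small")
    paths, truth = simulate_repertoire(cfg, outdir)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def small_run(small_sim, tmp_path_factory):
    """Full pipeline output on the small simulation."""
    _cfg, paths, _truth = small_sim
    rundir = tmp_path_factory.mktemp("run_small")
    rc = RunConfig(
        fastq={tp: str(p) for tp, p in paths.items()},
        outdir=str(rundir),
        figures=False,
    )
    report = run_pipeline(rc)
    return report, rundir


@pytest.fixture(scope="session")
def small_run_collection(small_run) -> RepertoireCollection:
    _report, rundir = small_run
    return RepertoireCollection.from_tsv(rundir / "sequences.tsv")
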