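"""Synthetic immunization time-course repertoires with ground truth.

The generator emulates the clonal processes the pipeline is built to
detect. A single germline V_H backbone (chicken-like: one functional V
gene, diversity concentrated at the junction) spawns ``n_lineages``
founders, each with its own HCDR3 and a set of framework substitutions
that keeps founders at least ``inter_lineage_floor`` edits apart.
Each lineage diversifies into daughters by up to ``intra_lineage_mutations``
point mutations per daughter; substitutions land in the HCDR3 window with
low probability (``cdr3_mut_prob``), mimicking the purifying selection
that keeps HCDR3 conserved within a lineage. A chosen subset of lineages
is antigen-reactive: from the first boost on, their sampling weight is
multiplied up to ``expansion_factor`` and they gain novel daughters at
every later time point — the diversification-plus-proliferation signature
the candidate ranking looks for. Reads carry the amplification primers,
random strand orientation, per-base substitution errors at ``error_rate``,
and Phred qualities of 37 except for a small injected fraction with one
low-quality base (these exercise the quality filter).

Everything derives from a single seeded NumPy generator in documented
order, so identical configs produce byte-identical FASTQ output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement
from sklearn.metrics import adjusted_rand_score

from . import cdr3 as cdr3_mod
from .distance import levenshtein
from .preprocess import DEFAULT_FORWARD_PRIMER, DEFAULT_REVERSE_PRIMER
from .repertoire import RepertoireCollection

_BASES = np.array(list("ACGT"))
# junction scaffold: ...FR3 YYC [cdr3] WGQG FR4...
_CDR3_AA_LEN = 12
_FR4_AA_LEN = 8
# amino acids allowed in randomized positions: no Cys/Trp, so the junction
# anchors stay unique, and no Met/stop ambiguity
_SAFE_AA = list("ADEFGHIKLNPQRSTVY")

_CODONS = {
    "A": "GCT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT", "H": "CAT",
    "I": "ATT", "K": "AAA", "L": "CTT", "N": "AAT", "P": "CCT", "Q": "CAA",
    "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT", "Y": "TAT", "C": "TGT",
    "W": "TGG", "M": "ATG",
}


@dataclass
class SimConfig:
    """Generative parameters for one synthetic immunization time course."""

    n_lineages: int = 20
    n_expanded: int = 3
    founder_length: int = 350
    intra_lineage_mutations: int = 4
    inter_lineage_floor: int = 40
    expansion_factor: float = 10.0
    reads_per_timepoint: dict[str, int] = field(
        default_factory=lambda: {"wk0": 5000, "wk2": 5000, "wk4": 5000, "wk5": 5000}
    )
    error_rate: float = 0.001
    seed: int = 0
    n_baseline_daughters: int = 7
    novel_daughters_per_boost: int = 5
    cdr3_mut_prob: float = 0.05
    low_quality_fraction: float = 0.01
    revcomp_fraction: float = 0.5
    forward_primer: str = DEFAULT_FORWARD_PRIMER
    reverse_primer: str = DEFAULT_REVERSE_PRIMER

    def __post_init__(self):
        if self.n_expanded > self.n_lineages:
            raise ValueError("n_expanded cannot exceed n_lineages")
        if self.inter_lineage_floor <= 2 * self.intra_lineage_mutations:
            raise ValueError(
                "inter_lineage_floor must exceed twice the intra-lineage "
                "mutation load, or lineages are not separable"
            )
        for rate in (self.error_rate, self.cdr3_mut_prob,
                     self.low_quality_fraction, self.revcomp_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    @property
    def timepoints(self) -> tuple[str, ...]:
        return tuple(self.reads_per_timepoint)


@dataclass
class SimTruth:
    """Ground truth emitted alongside the synthetic reads."""

    config: SimConfig
    lineages: pd.DataFrame  # lineage_id, founder_sequence, founder_hcdr3, expanded
    reads: pd.DataFrame  # read_id, timepoint, lineage_id, expanded
    variant_lineage: dict[str, int]  # true (pre-error) insert -> lineage_id

    @property
    def expanded_lineages(self) -> set[int]:
        return set(self.lineages.loc[self.lineages["expanded"], "lineage_id"])


class _Scaffold:
    def __init__(self, rng: np.random.Generator, founder_length: int):
        aa_len = founder_length // 3
        fr1_len = aa_len - 3 - _CDR3_AA_LEN - 4 - _FR4_AA_LEN
        if fr1_len < 5:
            raise ValueError("founder_length too short for a V_H-like scaffold")
        self.fr1_len = fr1_len
        self.cdr3_nt = (3 * (fr1_len + 3), 3 * (fr1_len + 3 + _CDR3_AA_LEN))
        # anchor codons (YYC and WGQG) excluded from founder framework edits
        anchor = set(range(3 * fr1_len, 3 * (fr1_len + 3)))
        anchor |= set(
            range(3 * (fr1_len + 3 + _CDR3_AA_LEN),
                  3 * (fr1_len + 3 + _CDR3_AA_LEN + 4))
        )
        nt_len = 3 * aa_len
        self.framework_nt = sorted(
            set(range(nt_len)) - anchor - set(range(*self.cdr3_nt))
        )
        fr1 = [str(rng.choice(_SAFE_AA)) for _ in range(fr1_len)]
        germ_cdr3 = self.random_cdr3_aa(rng)
        fr4 = [str(rng.choice(_SAFE_AA)) for _ in range(_FR4_AA_LEN)]
        aa = "".join(fr1) + "YYC" + germ_cdr3 + "WGQG" + "".join(fr4)
        nt = "".join(_CODONS[x] for x in aa)
        # pad to the requested length with a trailing partial codon
        tail = "".join(str(rng.choice(_BASES)) for _ in range(founder_length - nt_len))
        self.germline = nt + tail

    def random_cdr3_aa(self, rng: np.random.Generator) -> str:
        return "".join(str(rng.choice(_SAFE_AA)) for _ in range(_CDR3_AA_LEN))


def _substitute(rng: np.random.Generator, seq: list[str], pos: int) -> None:
    alternatives = [b for b in "ACGT" if b != seq[pos]]
    seq[pos] = alternatives[rng.integers(len(alternatives))]


def _make_founder(
    rng: np.random.Generator, scaffold: _Scaffold, config: SimConfig
) -> tuple[str, str]:
    """A founder: fresh HCDR3 plus ``inter_lineage_floor`` framework edits."""
    for _ in range(200):
        seq = list(scaffold.germline)
        new_cdr3_aa = scaffold.random_cdr3_aa(rng)
        lo, _hi = scaffold.cdr3_nt
        seq[lo : lo + 3 * _CDR3_AA_LEN] = list(
            "".join(_CODONS[x] for x in new_cdr3_aa)
        )
        positions = rng.choice(
            scaffold.framework_nt, size=config.inter_lineage_floor, replace=False
        )
        for pos in positions:
            _substitute(rng, seq, int(pos))
        founder = "".join(seq)
        ann = cdr3_mod.extract_hcdr3(founder)
        if ann.status == "found" and ann.hcdr3_aa == new_cdr3_aa:
            return founder, new_cdr3_aa
    raise RuntimeError("could not generate a valid founder; widen the scaffold")


def _make_daughter(
    rng: np.random.Generator, founder: str, scaffold: _Scaffold, config: SimConfig,
    existing: set[str],
) -> str:
    lo, hi = scaffold.cdr3_nt
    non_window = [i for i in range(len(founder)) if not lo <= i < hi]
    for _ in range(50):
        seq = list(founder)
        k = int(rng.integers(1, config.intra_lineage_mutations + 1))
        for _ in range(k):
            if rng.random() < config.cdr3_mut_prob:
                pos = int(rng.integers(lo, hi))
            else:
                pos = non_window[rng.integers(len(non_window))]
            _substitute(rng, seq, pos)
        daughter = "".join(seq)
        if daughter not in existing:
            return daughter
    raise RuntimeError("could not generate a distinct daughter")


def simulate_repertoire(
    config: SimConfig, outdir: str | Path | None = None
) -> tuple[dict[str, Path], SimTruth]:
    """Generate the time course; optionally write FASTQ + truth to disk.

    Returns a map timepoint -> FASTQ path (empty when ``outdir`` is None)
    and the :class:`SimTruth`. Output is a pure function of the config.
    """
    rng = np.random.default_rng(config.seed)
    tps = config.timepoints
    scaffold = _Scaffold(rng, config.founder_length)

    # founders, enforcing the pairwise separation floor
    founders: list[str] = []
    founder_cdr3: list[str] = []
    for _ in range(config.n_lineages):
        for _attempt in range(200):
            cand, cand_cdr3 = _make_founder(rng, scaffold, config)
            if all(
                levenshtein(cand, f, k=config.inter_lineage_floor - 1) == -1
                for f in founders
            ):
                founders.append(cand)
                founder_cdr3.append(cand_cdr3)
                break
        else:
            raise RuntimeError("founder separation infeasible; lower the floor")
    expanded = set(range(config.n_expanded))

    # variant pools: baseline daughters for everyone; expanded lineages gain
    # novel daughters at each post-baseline time point
    pools: dict[int, list[str]] = {}
    seen: set[str] = set(founders)
    birth_tp: dict[str, int] = {}  # variant -> index of first active time point
    for li, founder in enumerate(founders):
        pool = [founder]
        birth_tp[founder] = 0
        for _ in range(config.n_baseline_daughters):
            d = _make_daughter(rng, founder, scaffold, config, seen)
            seen.add(d)
            pool.append(d)
            birth_tp[d] = 0
        if li in expanded:
            for tp_idx in range(1, len(tps)):
                for _ in range(config.novel_daughters_per_boost):
                    d = _make_daughter(rng, founder, scaffold, config, seen)
                    seen.add(d)
                    pool.append(d)
                    birth_tp[d] = tp_idx
        pools[li] = pool

    lineage_weight = rng.lognormal(mean=0.0, sigma=0.5, size=config.n_lineages)

    fwd = config.forward_primer
    rev_rc = reverse_complement(config.reverse_primer)
    read_rows: list[tuple[str, str, int, bool]] = []
    fastq_per_tp: dict[str, list[str]] = {tp: [] for tp in tps}
    variant_lineage = {v: li for li, pool in pools.items() for v in pool}

    for tp_idx, tp in enumerate(tps):
        # sampling weights: lineage weight x expansion schedule x variant weight
        active: list[tuple[int, str]] = []
        weights: list[float] = []
        for li in range(config.n_lineages):
            mult = 1.0
            if li in expanded and tp_idx > 0:
                # ramp: sqrt(f) at the first boost, full f afterwards
                mult = config.expansion_factor ** (0.5 if tp_idx == 1 else 1.0)
            for vi, variant in enumerate(pools[li]):
                if birth_tp[variant] > tp_idx:
                    continue
                vweight = 4.0 if vi == 0 else 1.0  # founder dominates its lineage
                active.append((li, variant))
                weights.append(lineage_weight[li] * mult * vweight)
        probs = np.asarray(weights) / sum(weights)
        counts = rng.multinomial(config.reads_per_timepoint[tp], probs)
        serial = 0
        for (li, variant), count in zip(active, counts):
            for _ in range(count):
                insert = variant
                n_err = rng.binomial(len(insert), config.error_rate)
                if n_err:
                    seq = list(insert)
                    for pos in rng.choice(len(insert), size=n_err, replace=False):
                        _substitute(rng, seq, int(pos))
                    insert = "".join(seq)
                full = fwd + insert + rev_rc
                quals = np.full(len(full), 37, dtype=int)
                low_q = rng.random() < config.low_quality_fraction
                if low_q:
                    quals[rng.integers(len(full) // 4, len(full))] = 15
                if rng.random() < config.revcomp_fraction:
                    full = reverse_complement(full)
                    quals = quals[::-1]
                read_id = f"{tp}_r{serial:06d}_L{li:02d}"
                serial += 1
                qual_str = "".join(chr(q + 33) for q in quals)
                fastq_per_tp[tp].append(f"@{read_id}\n{full}\n+\n{qual_str}\n")
                read_rows.append((read_id, tp, li, li in expanded))

    lineages = pd.DataFrame(
        {
            "lineage_id": range(config.n_lineages),
            "founder_sequence": founders,
            "founder_hcdr3": founder_cdr3,
            "expanded": [li in expanded for li in range(config.n_lineages)],
        }
    )
    reads = pd.DataFrame(
        read_rows, columns=["read_id", "timepoint", "lineage_id", "expanded"]
    )
    truth = SimTruth(
        config=config, lineages=lineages, reads=reads,
        variant_lineage=variant_lineage,
    )

    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for tp in tps:
            path = outdir / f"vh_{tp}.fastq"
            path.write_text("".join(fastq_per_tp[tp]))
            paths[tp] = path
        lineages.to_csv(outdir / "truth_lineages.tsv", sep="\t", index=False)
        reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
        (outdir / "sim_config.json").write_text(
            json.dumps(asdict(config), indent=2, sort_keys=True)
        )
    else:
        truth.fastq_per_tp = fastq_per_tp  # type: ignore[attr-defined]
    return paths, truth


# -- ground-truth evaluation -------------------------------------------


def assign_true_lineages(
    collection: RepertoireCollection, truth: SimTruth
) -> list[int]:
    """True lineage label per vertex: exact variant match, else nearest founder."""
    founders = list(truth.lineages["founder_sequence"])
    labels = []
    for v in collection.vertices:
        if v.sequence in truth.variant_lineage:
            labels.append(truth.variant_lineage[v.sequence])
        else:
            dists = [levenshtein(v.sequence, f) for f in founders]
            labels.append(int(np.argmin(dists)))
    return labels


def lineage_recovery_ari(collection, comps, truth: SimTruth) -> float:
    """Adjusted Rand index of component membership against lineage truth."""
    true_labels = assign_true_lineages(collection, truth)
    comp_label = {vid: c.component_id for c in comps for vid in c.vertex_ids}
    pred = [comp_label[v.vertex_id] for v in collection.vertices]
    return float(adjusted_rand_score(true_labels, pred))
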