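"""Raw amplicon reads -> deduplicated, error-corrected unique-sequence table.

Three stages, mirroring standard immunoglobulin amplicon practice:

1. **Primer annotation** — locate the forward primer at the 5' end and the
   reverse primer (as its reverse complement) at the 3' end, tolerating a
   bounded number of mismatches; re-orient reverse-complemented reads; trim
   both primers. Reads without both primers are rejected, not errors.
2. **Quality filtering** — the ``qXpY`` rule: a read passes when at least
   fraction ``p`` of its bases have Phred quality >= ``q`` (default
   ``q20p100``: every base at Q20+). Ambiguous bases (N) are treated as
   quality 0 and so fail any ``q > 0`` filter.
3. **Error correction** — a greedy abundance-ranked absorption: within each
   time point, unique sequences are visited in decreasing read count; a
   sequence is absorbed into an already-retained sequence when their edit
   distance is <= ``ld_merge`` and its raw count is at most ``ratio`` times
   the parent's raw count. This approximates hierarchical-clustering
   correctors and is deliberately simple and replaceable: an externally
   corrected sequence table can enter the pipeline instead
   (:meth:`bcrnet.repertoire.RepertoireCollection.from_long_tsv`).

Reads are expected pre-merged (single sequence per fragment); paired-end
overlap merging belongs upstream (e.g. fastp).
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import edlib
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .repertoire import DEFAULT_TIMEPOINTS, RepertoireCollection

_VALID_NT = frozenset("ACGTN")

#: Heavy-chain variable-domain amplification primers (chicken IgY FR1 / FR4).
DEFAULT_FORWARD_PRIMER = "ACTCAGCCGTCCTCGGTGTC"
DEFAULT_REVERSE_PRIMER = "ACTGACCTAGGACGGTCAGG"


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    timepoint: str

    def __post_init__(self):
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: {len(self.sequence)} bases vs "
                f"{len(self.qualities)} quality scores"
            )

    def reverse_complement(self) -> "RawRead":
        return replace(
            self,
            sequence=reverse_complement(self.sequence),
            qualities=tuple(reversed(self.qualities)),
        )


@dataclass(frozen=True)
class PrimerPair:
    forward: str = DEFAULT_FORWARD_PRIMER
    reverse: str = DEFAULT_REVERSE_PRIMER
    max_mismatches: int = 2

    def __post_init__(self):
        if not self.forward or not self.reverse:
            raise ValueError("both primers must be non-empty")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


def _hamming_at(read: str, primer: str, pos: int) -> int:
    window = read[pos : pos + len(primer)]
    if len(window) < len(primer):
        return len(primer)
    return sum(a != b for a, b in zip(window, primer))


def _find_primer(read: str, primer: str, max_mm: int, from_end: bool) -> int | None:
    """Position of the best sliding Hamming match, preferring the read end.

    Scans positions outward from the anchored end (5' start for the forward
    primer, 3' end for the reverse-complemented reverse primer) and returns
    the first position within ``max_mm`` mismatches.
    """
    n, m = len(read), len(primer)
    if m > n:
        return None
    if from_end:
        positions: Iterable[int] = range(n - m, -1, -1)
    else:
        positions = range(0, n - m + 1)
    for pos in positions:
        if _hamming_at(read, primer, pos) <= max_mm:
            return pos
    return None


def annotate_primers(read: RawRead, primers: PrimerPair) -> RawRead | None:
    """Orient a read forward-primer-first and trim both primers.

    Returns the trimmed insert read, or ``None`` (rejection) when either
    primer is absent within ``primers.max_mismatches`` on both strands.
    Raises ``ValueError`` on non-nucleotide characters.
    """
    if not read.sequence:
        raise ValueError(f"{read.read_id}: empty read")
    bad = set(read.sequence) - _VALID_NT
    if bad:
        raise ValueError(f"{read.read_id}: invalid characters {sorted(bad)}")

    rev_rc = reverse_complement(primers.reverse)
    for oriented in (read, read.reverse_complement()):
        fpos = _find_primer(
            oriented.sequence, primers.forward, primers.max_mismatches, from_end=False
        )
        if fpos is None:
            continue
        start = fpos + len(primers.forward)
        rpos = _find_primer(
            oriented.sequence[start:], rev_rc, primers.max_mismatches, from_end=True
        )
        if rpos is None:
            continue
        end = start + rpos
        if end <= start:
            continue
        return replace(
            oriented,
            sequence=oriented.sequence[start:end],
            qualities=oriented.qualities[start:end],
        )
    return None


def quality_filter(read: RawRead, q: int = 20, p: float = 1.0) -> bool:
    """``qXpY`` rule: pass iff fraction of bases with Phred >= q is >= p.

    N bases count as quality 0 regardless of the reported score.
    """
    if not read.sequence:
        return p <= 0.0
    good = sum(
        1
        for base, qual in zip(read.sequence, read.qualities)
        if base != "N" and qual >= q
    )
    return good / len(read.sequence) >= p


def error_correct(
    reads_by_timepoint: Mapping[str, Mapping[str, int] | Iterable[str]],
    ld_merge: int = 1,
    ratio: float = 0.1,
    timepoints: Iterable[str] | None = None,
) -> RepertoireCollection:
    """Collapse likely sequencing errors and pool time points into vertices.

    Within each time point, unique sequences are visited in descending raw
    count (ties: lexicographic); a sequence is absorbed into the most
    abundant retained sequence with edit distance <= ``ld_merge`` whose raw
    count satisfies ``child/parent <= ratio``; its reads transfer to the
    parent, so read mass is conserved. Survivors are then merged across
    time points by exact sequence identity.
    """
    tps = tuple(timepoints) if timepoints is not None else tuple(reads_by_timepoint)
    if not tps:
        tps = DEFAULT_TIMEPOINTS
    pooled: dict[str, dict[str, int]] = {}
    for tp in tps:
        raw = reads_by_timepoint.get(tp, {})
        counter = Counter(raw) if not isinstance(raw, Mapping) else Counter(dict(raw))
        corrected = _correct_one_timepoint(counter, ld_merge, ratio)
        for seq, count in corrected.items():
            pooled.setdefault(seq, {})[tp] = count
    if not pooled:
        import warnings

        warnings.warn("error_correct: no reads supplied; empty collection")
        return RepertoireCollection(timepoints=tps, vertices=[])
    return RepertoireCollection.from_counts(pooled, tps)


def _correct_one_timepoint(
    counter: Counter, ld_merge: int, ratio: float
) -> dict[str, int]:
    order = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    # retained sequences with raw and accumulated counts, in retention order
    retained: list[str] = []
    raw_count: dict[str, int] = {}
    acc_count: dict[str, int] = {}
    for seq, count in order:
        parent = None
        for cand in retained:
            # retention order is descending raw count: once the ratio test
            # can no longer pass, no later candidate can either
            if count > ratio * raw_count[cand]:
                break
            if abs(len(seq) - len(cand)) > ld_merge:
                continue
            d = edlib.align(seq, cand, task="distance", k=ld_merge)["editDistance"]
            if d != -1:
                parent = cand
                break
        if parent is None:
            retained.append(seq)
            raw_count[seq] = count
            acc_count[seq] = count
        else:
            acc_count[parent] += count
    return acc_count


# -- FASTQ ingestion ---------------------------------------------------


def read_fastq(path, timepoint: str) -> Iterator[RawRead]:
    """Yield reads from a FASTQ file, transparently handling gzip."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            yield RawRead(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
                timepoint=timepoint,
            )


def preprocess_fastq(
    paths: Mapping[str, object],
    primers: PrimerPair | None = None,
    q: int = 20,
    p: float = 1.0,
    ld_merge: int = 1,
    ratio: float = 0.1,
) -> tuple[RepertoireCollection, dict]:
    """Full preprocessing of per-time-point FASTQ files.

    Returns the corrected collection and a per-stage accounting report
    (reads in / primer-rejected / quality-failed / passed, per time point).
    """
    primers = primers or PrimerPair()
    tps = tuple(paths)
    counters: dict[str, Counter] = {tp: Counter() for tp in tps}
    report: dict = {"timepoints": {}, "params": {
        "q": q, "p": p, "ld_merge": ld_merge, "ratio": ratio,
        "max_mismatches": primers.max_mismatches,
    }}
    for tp in tps:
        n_in = n_primer_rej = n_qual_fail = 0
        for read in read_fastq(paths[tp], tp):
            n_in += 1
            trimmed = annotate_primers(read, primers)
            if trimmed is None:
                n_primer_rej += 1
                continue
            if not quality_filter(trimmed, q=q, p=p):
                n_qual_fail += 1
                continue
            counters[tp][trimmed.sequence] += 1
        report["timepoints"][tp] = {
            "reads_in": n_in,
            "primer_rejected": n_primer_rej,
            "quality_failed": n_qual_fail,
            "reads_passed": n_in - n_primer_rej - n_qual_fail,
            "unique_before_correction": len(counters[tp]),
        }
    collection = error_correct(counters, ld_merge=ld_merge, ratio=ratio, timepoints=tps)
    per_tp_unique = {
        tp: sum(1 for v in collection if v.counts[tp] > 0) for tp in tps
    }
    for tp in tps:
        report["timepoints"][tp]["unique_after_correction"] = per_tp_unique[tp]
    report["n_unique_sequences"] = len(collection)
    return collection, report
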