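# Methods

## Model and procedure

`bcrnet` treats a longitudinal V_H amplicon experiment as a graph problem.
Each unique V_H nucleotide sequence surviving preprocessing is a vertex
carrying a read count per sampling time point; vertices are connected when
their Levenshtein distance (insertions, deletions, substitutions, over the
full transcript, not just the CDR3) is at or below a threshold t, and the
connected components of this graph are taken as clonal lineages. Two
opposing failure modes govern t: too low, and heavily mutated lineage
members fragment into separate components; too high, and unrelated
lineages fuse. The HCDR3 ratio arbitrates: members of a true lineage
inherit one junction from their common ancestor and HCDR3 accumulates
replacement mutations slowly, so distinct-HCDR3-count over vertex-count is
far below 1 for coherent components and near 1 for fused or spurious ones.
The pipeline sweeps t, bins vertices by their component's ratio in tenths,
and keeps the t that maximizes vertices in components with ratio < 0.3.
Candidate antigen-reactive lineages are then components that both gained
active members and grew in average clonal frequency from the first to the
last time point.

## Stage-by-stage choices

**Primer annotation.** Reads are searched for the forward primer (sliding
Hamming match scanning from the 5' end) and the reverse complement of the
reverse primer (scanning from the 3' end), on both strands, with
`max_mismatches` = 2 by default. Indels inside a primer are not tolerated;
with 20-mer primers and post-filter error rates this loses a negligible
read fraction and keeps matching O(n). Both primers are trimmed; the
insert between them is the V_H sequence used everywhere downstream.
Paired-end merging is out of scope: reads must arrive merged (any standard
overlap merger works upstream).

**Quality filter.** The `qXpY` family: pass iff at least fraction `p` of
bases have Phred ≥ `q`. Defaults q=20, p=1.0 ("q20p100"). `N` bases are
treated as quality 0, so any `q > 0` filter rejects reads containing them.
Degenerate settings (`q=0` or `p=0`) pass everything, which the property
tests pin down.

**Error correction.** A deliberately simple, documented stand-in for
hierarchical-clustering correctors: within a time point, unique sequences
are visited in decreasing raw count (ties broken lexicographically); a
sequence is absorbed into the most abundant already-retained sequence
within `ld_merge` = 1 edits whose raw count is ≥ 1/`ratio` = 10× its own,
transferring its reads. The ratio test uses pre-absorption counts so the
visit order never becomes stale and the result is order-independent. Read
mass is conserved exactly. The stage is replaceable: a table corrected by
any external tool can enter the pipeline directly
(`RepertoireCollection.from_long_tsv` / the `sequence_table` config key),
and every downstream result is then identical to the FASTQ route on the
same table (tested).

**Distance layer.** Levenshtein distances come from edlib's banded
bit-parallel aligner; pair enumeration sorts sequences by length, skips
pairs whose length difference already exceeds t, and passes `k = t` so the
alignment abandons early. These are performance devices only — the test
suite proves exact agreement with a full dynamic-programming matrix on
random pairs and with brute-force all-vs-all enumeration on 500-sequence
fixtures.

**Graph layer.** networkx supplies graph construction, connected
components, and GraphML export. Components are named 1.. by decreasing
pooled vertex count; the tie rule (total read count, then lexicographically
smallest member sequence) makes naming deterministic. The per-component
minimum spanning tree — a visualization skeleton, not a biological claim —
is a hand-rolled Kruskal over edges sorted by (distance, vertex a, vertex
b), so tied weights resolve identically on every run and platform;
networkx's MST weight is used as a cross-check in tests.

**HCDR3 extraction.** Motif-based, no germline alignment: translate in a
fixed reading frame (default 0, because the trimmed insert starts in-frame
when the forward primer sits in framework 1; configurable), take the
*last* W-G-x-G occurrence as the J anchor (the J-region motif is the
3'-most), and the last cysteine before it as the second CYS; HCDR3 is the
peptide strictly between them. Translation stops before the anchor yield
status `stop_codon`; missing anchors yield `not_found`. Unannotated
vertices count in the ratio denominator by default (they dilute the ratio
downward, a conservative direction for threshold selection); excluding
them is a switch.

**Threshold sweep.** Ratio bins are left-closed right-open tenths of
[0, 1], with 1.0 folded into the top bin; the low-ratio tally uses a
strict `< 0.3` comparison. Components with fewer than `min_component_size`
= 3 vertices are excluded from binning — with one or two members the ratio
is quantized to {0.5, 1} and carries no signal. The sweep range defaults
to 1..20; ties in the argmax resolve toward smaller t, the direction that
admits fewer unrelated sequences. The 0.3 cutoff is a config parameter,
not auto-detected: it sits in the empty band of the strongly bimodal ratio
distribution that both real and simulated repertoires show.

**Dynamics.** Average clonal frequency includes zero-count members (a
lineage member unseen at a time point has frequency zero there; an
active-only mode exists). The frequency fold change is additively
smoothed — one pseudo-read added to the component's total at both
endpoints — so lineages absent at baseline get a large finite fold rather
than infinity. Candidate thresholds default to ≥ 5 gained members and
≥ 2× frequency; both are config keys. The rank-sum score replaces a
by-eye scatter-plot selection with a reproducible ordering; monotonicity
(raising either threshold never adds a candidate) is property-tested.

## The simulator

The generator emulates exactly the processes the method assumes, and its
defaults are the reference study conditions used by the acceptance checks:
20 founder lineages, 3 expanded, 350-nt founders, ≤ 4 intra-lineage
mutations per daughter, ≥ 40 edits between founders, 10× expansion, four
time points of 5,000 reads, 0.1% per-base substitution error.

* **Backbone.** All founders derive from one germline scaffold
  (framework – YYC – 12-aa CDR3 – WGQG – framework), mimicking the
  single-functional-V situation in chicken where repertoire diversity is
  concentrated at the junction; each founder gets a fresh random CDR3 and
  40 framework substitutions, with stop codons and anchor damage rejected
  at generation time. 350 nt is not a codon multiple; the scaffold uses
  348 nt plus two trailing bases, like an amplicon cut mid-codon.
* **Diversification.** Daughters carry 1..4 substitutions; each lands in
  the CDR3 window with probability 0.05 (below the ~0.10 of a uniform
  model), encoding the low HCDR3 replacement rate that the ratio statistic
  relies on. Expanded lineages add 5 novel daughters at every
  post-baseline time point — the member-gain signal.
* **Expansion.** Lineage sampling weights are log-normal (σ = 0.5);
  expanded lineages are multiplied by √10 at the first boost and 10 from
  the second boost on — the frequency-gain signal. Read counts per time
  point are multinomial, so totals are exact.
* **Reads.** Each read is forward primer + variant + reverse-complemented
  reverse primer, flipped to the reverse strand with probability 0.5;
  substitution errors at 0.1%/base hit the insert; qualities are Q37
  except that 1% of reads get one injected Q15 base to exercise the
  quality filter. All randomness flows from a single seeded NumPy
  generator in fixed order, so output is byte-reproducible.

What the simulator does **not** model — and what passing tests therefore
do not establish about real data: gene-conversion donor tracts (mutations
are independent point edits), selection gradients within a lineage,
indels in reads or true variants, PCR chimeras and amplification bias,
quality degradation along the read, and lineages that share a recent
common ancestor (founders are well-separated by construction). On real
repertoires the lineage partition is not knowable, thresholds interact
with the upstream error corrector, and the candidate list is a ranking to
screen, not a verdict.

## Numerical and scale notes

Clonal frequencies normalize to 1 per time point to ~1e-14 (pure
summation error); the acceptance checks assert 1e-9. The only quadratic
step is pair enumeration; at the reference scale (~1,700 unique sequences
after correction) a full run takes ~25 s on one CPU, and the test suite
sizes its fixtures (700-read and 20,000-read simulations) to keep the
whole suite in a few minutes. At the scale of a real MiSeq repertoire
(~10^5 unique sequences) pair enumeration is the stage to parallelize;
the length-bucketed, banded design keeps it feasible but it is not
engineered here for that scale.

Degenerate inputs: empty FASTQ input aborts the pipeline with a
stage-attributed error; an empty time point makes clonal frequency
undefined there (raised, not silently zero); a disconnected vertex set
passed to the MST routine is a contract violation and raises.

## Known limitations

* Error correction is a greedy approximation, not a reimplementation of
  any published corrector; at very high error rates or very uneven
  abundance distributions it will under- or over-collapse. Use the
  table-bypass route if you have a trusted corrector.
* HCDR3 extraction fails on reads whose frame is shifted by upstream
  indels; such vertices are carried with status `not_found` and dilute
  ratios rather than being repaired.
* The candidate rule compares first vs last time point only; a lineage
  that expands and then contracts within the course can be missed.
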