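"""HCDR3 extraction and the per-component HCDR3 ratio.

The heavy-chain CDR3 is the hypervariable loop between two conserved
junction anchors: the second cysteine at the end of framework 3 and the
tryptophan of the J-region W-G-x-G motif. Extraction here is motif-based
(no germline alignment): the sequence is translated in a fixed reading
frame, the last W-G-x-G occurrence is taken as the J anchor, and the last
cysteine preceding it as the 2nd-CYS; HCDR3 is everything strictly
between them.

The HCDR3 ratio of a component is the number of distinct HCDR3 peptides
among its members divided by its vertex count. Members of a genuine clonal
lineage share (near-)identical HCDR3s, so coherent components score low;
a component that has absorbed unrelated sequences scores high. This makes
the ratio the diagnostic for choosing the distance threshold.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .network import Component
from .repertoire import RepertoireCollection

_J_ANCHOR = re.compile(r"WG.G")


@dataclass(frozen=True)
class Hcdr3Annotation:
    vertex_id: int
    hcdr3_aa: str | None
    frame: int
    status: str  # "found" | "not_found" | "stop_codon"


def translate_frame(sequence: str, frame: int = 0) -> str:
    """Translate in the given frame, dropping any trailing partial codon."""
    sub = sequence[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    return str(Seq(sub).translate())


def extract_hcdr3(sequence: str, frame: int = 0, vertex_id: int = -1) -> Hcdr3Annotation:
    """Locate the HCDR3 peptide between the 2nd-CYS and the J-anchor Trp.

    Status is ``not_found`` when either anchor is missing, ``stop_codon``
    when translation hits a stop before the J anchor.
    """
    if len(sequence) < 9:
        raise ValueError("sequence shorter than 9 nt cannot contain a junction")
    peptide = translate_frame(sequence, frame)
    matches = list(_J_ANCHOR.finditer(peptide))
    if not matches:
        return Hcdr3Annotation(vertex_id, None, frame, "not_found")
    anchor_w = matches[-1].start()
    cys = peptide.rfind("C", 0, anchor_w)
    if cys == -1:
        return Hcdr3Annotation(vertex_id, None, frame, "not_found")
    if "*" in peptide[:anchor_w]:
        return Hcdr3Annotation(vertex_id, None, frame, "stop_codon")
    loop = peptide[cys + 1 : anchor_w]
    if not loop:
        return Hcdr3Annotation(vertex_id, None, frame, "not_found")
    return Hcdr3Annotation(vertex_id, loop, frame, "found")


def annotate_collection(
    collection: RepertoireCollection, frame: int = 0
) -> dict[int, Hcdr3Annotation]:
    """Annotate every vertex; also fills ``VhVertex.hcdr3_aa`` in place."""
    annotations: dict[int, Hcdr3Annotation] = {}
    for v in collection.vertices:
        ann = extract_hcdr3(v.sequence, frame=frame, vertex_id=v.vertex_id)
        v.hcdr3_aa = ann.hcdr3_aa
        annotations[v.vertex_id] = ann
    return annotations


def hcdr3_ratio(
    component: Component,
    annotations: Mapping[int, Hcdr3Annotation],
    include_unannotated: bool = True,
) -> float:
    """Distinct HCDR3 peptides over vertex count for one component.

    Vertices without a recovered HCDR3 count toward the denominator by
    default (they dilute the ratio downward); ``include_unannotated=False``
    restricts the denominator to annotated vertices instead.
    """
    peptides = {
        annotations[vid].hcdr3_aa
        for vid in component.vertex_ids
        if annotations[vid].status == "found"
    }
    if include_unannotated:
        denom = component.n_vertices
    else:
        denom = sum(
            1 for vid in component.vertex_ids if annotations[vid].status == "found"
        )
    if denom == 0:
        return 0.0
    return len(peptides) / denom


def annotations_frame(annotations: Mapping[int, Hcdr3Annotation]) -> pd.DataFrame:
    rows = sorted(annotations.values(), key=lambda a: a.vertex_id)
    return pd.DataFrame(
        {
            "vertex_id": [a.vertex_id for a in rows],
            "frame": [a.frame for a in rows],
            "status": [a.status for a in rows],
            "hcdr3_aa": [a.hcdr3_aa or "" for a in rows],
        }
    )


def write_annotations_tsv(annotations: Mapping[int, Hcdr3Annotation], path) -> None:
    annotations_frame(annotations).to_csv(path, sep="\t", index=False)
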