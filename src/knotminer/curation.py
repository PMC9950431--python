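"""Redundancy removal by greedy identity clustering.

Mirrors the CD-HIT convention: records are processed longest-first
(ties by id), each joining the first existing cluster whose
representative is at least ``threshold`` identical, where identity is
the number of identical aligned positions divided by the length of the
shorter sequence under a global BLOSUM62 alignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .seq_io import SeqRecord


@dataclass
class Cluster:
    representative: str
    members: list[str]
    threshold: float


def _make_aligner(gap_open: float = 11.0, gap_extend: float = 1.0,
                  ) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity with the shorter sequence as denominator."""
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    ident = 0
    for (as_, ae), (bs, be) in zip(*aln.aligned):
        ident += sum(1 for x, y in zip(a[as_:ae], b[bs:be]) if x == y)
    return ident / min(len(a), len(b))


def greedy_cluster(records: Sequence[SeqRecord], threshold: float = 0.99,
                   ) -> list[Cluster]:
    """Partition records into identity clusters around long representatives.

    Deterministic: processing order is decreasing length then id, so the
    result does not depend on input order.  Every input id lands in
    exactly one cluster, and representatives are never shorter than any
    of their members.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    clusters: list[Cluster] = []
    reps: dict[str, str] = {}
    for rec in ordered:
        placed = False
        for cl in clusters:
            if pairwise_identity(rec.residues, reps[cl.representative]) \
                    >= threshold:
                cl.members.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=rec.id, members=[rec.id],
                                    threshold=threshold))
            reps[rec.id] = rec.residues
    return clusters


def representatives(records: Sequence[SeqRecord],
                    clusters: Sequence[Cluster]) -> list[SeqRecord]:
    """The representative record of each cluster, in cluster order."""
    by_id = {r.id: r for r in records}
    return [by_id[c.representative] for c in clusters]
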