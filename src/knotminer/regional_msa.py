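"""Cysteine-anchored regional multiple alignment.

ICK domains share an absolutely conserved cysteine scaffold, so the k
cysteines are fixed as single-residue anchor columns and the k+1
pre-/inter-/post-cysteine regions are aligned independently, each by
deterministic progressive profile alignment (BLOSUM62, affine gaps,
guide order from k-mer distances with id tie-breaks).  Anchor columns
are therefore gap-free and cysteine-only by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ick_domains import _B62, _B62_INDEX
from .seq_io import SeqRecord

GAP = "-"

#: Clustal conservation groups (residue sets).
STRONG_GROUPS = ["STA", "NEQK", "NHQK", "NDEQ", "QHRK", "MILV", "MILF",
                 "HY", "FYW"]
WEAK_GROUPS = ["CSA", "ATV", "SAG", "STNK", "STPA", "SGND", "SNDEQK",
               "NDEQHK", "NEQHRK", "FVLIM", "HFY"]


@dataclass(frozen=True)
class AnchorSet:
    """Domain records sharing one cysteine count, with anchor offsets."""

    sequences: tuple[SeqRecord, ...]
    anchor_map: dict[str, tuple[int, ...]]  # id -> 1-based cys positions
    k: int


@dataclass(frozen=True)
class RegionalAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]            # gapped rows, equal width
    anchor_columns: tuple[int, ...]  # 0-based column indices
    region_blocks: tuple[tuple[int, int], ...]  # half-open column ranges

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]


def anchor_cysteines(domains: Sequence[SeqRecord],
                     on_deviant: str = "error",
                     ) -> AnchorSet | tuple[AnchorSet, list[tuple[str, str]]]:
    """Locate the shared cysteine anchors of a domain family.

    All domains must have the same cysteine count (the modal count).
    With ``on_deviant="error"`` a mixed family raises, listing the
    offenders; with ``"reject"`` the deviants are returned alongside the
    AnchorSet as (id, reason) pairs.
    """
    if not domains:
        raise ValueError("empty domain set")
    counts = {d.id: len(d.cysteine_positions()) for d in domains}
    vals = sorted(counts.values())
    modal = max(set(vals), key=lambda v: (vals.count(v), -v))
    offenders = [(d.id, f"cysteine count {counts[d.id]} != {modal}")
                 for d in domains if counts[d.id] != modal]
    if offenders and on_deviant == "error":
        raise ValueError(
            "mixed cysteine counts: " + "; ".join(f"{i} ({r})"
                                                  for i, r in offenders))
    kept = tuple(d for d in domains if counts[d.id] == modal)
    aset = AnchorSet(
        sequences=kept,
        anchor_map={d.id: tuple(d.cysteine_positions()) for d in kept},
        k=modal,
    )
    if on_deviant == "reject":
        return aset, offenders
    return aset


# -- progressive profile alignment of one region ---------------------------


def _kmer_profile(s: str, k: int = 2) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(s) - k + 1):
        w = s[i:i + k]
        out[w] = out.get(w, 0) + 1
    return out


def _kmer_distance(a: str, b: str, k: int = 2) -> float:
    """1 − cosine similarity of k-mer count vectors (1.0 if either empty)."""
    pa, pb = _kmer_profile(a, k), _kmer_profile(b, k)
    if not pa or not pb:
        return 1.0
    num = sum(v * pb.get(w, 0) for w, v in pa.items())
    den = (sum(v * v for v in pa.values()) ** 0.5
           * sum(v * v for v in pb.values()) ** 0.5)
    return 1.0 - num / den if den else 1.0


def _guide_order(ids: Sequence[str], seqs: dict[str, str]) -> list[str]:
    """Greedy join order: closest pair first, then nearest remaining.

    Ties broken by id lexicographic order for determinism.
    """
    ids = sorted(ids)
    if len(ids) <= 2:
        return list(ids)
    d = {(a, b): _kmer_distance(seqs[a], seqs[b])
         for i, a in enumerate(ids) for b in ids[i + 1:]}
    first = min(d, key=lambda p: (d[p], p))
    order = list(first)
    remaining = [i for i in ids if i not in order]
    while remaining:
        def avg_d(x: str) -> float:
            return sum(d.get((min(x, o), max(x, o)), 0.0)
                       for o in order) / len(order)
        nxt = min(remaining, key=lambda x: (avg_d(x), x))
        order.append(nxt)
        remaining.remove(nxt)
    return order


def _col_score(col: str, res: str) -> float:
    """Mean BLOSUM62 score of a residue against a profile column."""
    scores = [_B62[_B62_INDEX[c], _B62_INDEX[res]] for c in col if c != GAP]
    return float(np.mean(scores)) if scores else 0.0


def _align_seq_to_profile(profile: list[str], seq: str,
                          gap_open: float, gap_extend: float,
                          ) -> tuple[list[str], str]:
    """Global affine alignment of one sequence to a profile."""
    ncol = len(profile[0]) if profile else 0
    cols = ["".join(r[j] for r in profile) for j in range(ncol)]
    m, n = ncol, len(seq)
    NEG = float("-inf")
    M = np.full((m + 1, n + 1), NEG)
    Ix = np.full((m + 1, n + 1), NEG)  # gap in seq (consume profile col)
    Iy = np.full((m + 1, n + 1), NEG)  # gap in profile (consume residue)
    M[0, 0] = 0.0
    for i in range(1, m + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, n + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = _col_score(cols[i - 1], seq[j - 1])
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                              Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_extend)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_extend)
    # traceback
    i, j = m, n
    state = max(("M", "Ix", "Iy"),
                key=lambda st: {"M": M, "Ix": Ix, "Iy": Iy}[st][m, n])
    new_profile = [""] * len(profile)
    new_row = ""
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            for r_i, r in enumerate(profile):
                new_profile[r_i] = r[i - 1] + new_profile[r_i]
            new_row = seq[j - 1] + new_row
            s = _col_score(cols[i - 1], seq[j - 1])
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
                if np.isclose(prev, mat[i, j]):
                    state = st
                    break
        elif state == "Ix" or j == 0:
            for r_i, r in enumerate(profile):
                new_profile[r_i] = r[i - 1] + new_profile[r_i]
            new_row = GAP + new_row
            if i > 1 and not np.isclose(Ix[i, j], Ix[i - 1, j] - gap_extend):
                state = "M"
            elif i == 1:
                state = "M"
            i -= 1
        else:  # Iy or i == 0
            for r_i in range(len(profile)):
                new_profile[r_i] = GAP + new_profile[r_i]
            new_row = seq[j - 1] + new_row
            if j > 1 and not np.isclose(Iy[i, j], Iy[i, j - 1] - gap_extend):
                state = "M"
            elif j == 1:
                state = "M"
            j -= 1
    return new_profile, new_row


def align_region(seqs: dict[str, str], order: Sequence[str],
                 gap_open: float = 11.0, gap_extend: float = 1.0,
                 ) -> dict[str, str]:
    """Progressively align one region's substrings; returns gapped rows."""
    maxlen = max((len(s) for s in seqs.values()), default=0)
    if maxlen <= 1:
        # degenerate region: copy verbatim, pad the empties
        return {i: s + GAP * (maxlen - len(s)) for i, s in seqs.items()}
    nonempty = [i for i in order if seqs[i]]
    empty = [i for i in order if not seqs[i]]
    if not nonempty:
        return {i: "" for i in seqs}
    profile = [seqs[nonempty[0]]]
    prof_ids = [nonempty[0]]
    for sid in nonempty[1:]:
        profile, row = _align_seq_to_profile(profile, seqs[sid],
                                             gap_open, gap_extend)
        profile.append(row)
        prof_ids.append(sid)
    width = len(profile[0])
    out = dict(zip(prof_ids, profile))
    for sid in empty:
        out[sid] = GAP * width
    return out


def align_regions(anchors: AnchorSet, gap_open: float = 11.0,
                  gap_extend: float = 1.0) -> RegionalAlignment:
    """Anchor the k cysteines and align the k+1 regions independently."""
    seqs = {r.id: r.residues for r in anchors.sequences}
    ids = sorted(seqs)
    k = anchors.k
    order = _guide_order(ids, seqs)
    # region r of sequence s: substring between anchor r and anchor r+1
    region_rows: list[dict[str, str]] = []
    for r in range(k + 1):
        sub = {}
        for sid in ids:
            cys = anchors.anchor_map[sid]
            lo = 0 if r == 0 else cys[r - 1]          # 0-based exclusive
            hi = len(seqs[sid]) if r == k else cys[r] - 1
            sub[sid] = seqs[sid][lo:hi]
        region_rows.append(align_region(sub, order, gap_open, gap_extend))
    # stitch: region 0, C, region 1, C, ..., region k
    rows = {sid: "" for sid in ids}
    anchor_columns: list[int] = []
    region_blocks: list[tuple[int, int]] = []
    col = 0
    for r in range(k + 1):
        width = len(next(iter(region_rows[r].values()))) \
            if region_rows[r] else 0
        region_blocks.append((col, col + width))
        for sid in ids:
            rows[sid] += region_rows[r][sid]
        col += width
        if r < k:
            anchor_columns.append(col)
            for sid in ids:
                rows[sid] += "C"
            col += 1
    return RegionalAlignment(
        ids=tuple(ids),
        rows=tuple(rows[sid] for sid in ids),
        anchor_columns=tuple(anchor_columns),
        region_blocks=tuple(region_blocks),
    )


def conservation_line(aln: RegionalAlignment) -> str:
    """Clustal-style conservation symbols, one per alignment column.

    '*' — a single residue type with no gaps; ':' — all residues within
    one strong group; '.' — one weak group; ' ' otherwise.  A gap
    anywhere in the column disqualifies every symbol except ' '.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    out = []
    for j in range(aln.width):
        col = {r[j] for r in aln.rows}
        if GAP in col:
            out.append(" ")
        elif len(col) == 1:
            out.append("*")
        elif any(col <= set(g) for g in STRONG_GROUPS):
            out.append(":")
        elif any(col <= set(g) for g in WEAK_GROUPS):
            out.append(".")
        else:
            out.append(" ")
    return "".join(out)


def to_clustal(aln: RegionalAlignment, block: int = 60) -> str:
    """Clustal-format text with the conservation line below each block."""
    cons = conservation_line(aln)
    name_w = max(len(i) for i in aln.ids) + 2
    lines = ["CLUSTAL-style regional alignment", ""]
    for start in range(0, aln.width, block):
        for sid, row in zip(aln.ids, aln.rows):
            lines.append(sid.ljust(name_w) + row[start:start + block])
        lines.append(" " * name_w + cons[start:start + block])
        lines.append("")
    return "\n".join(lines)
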