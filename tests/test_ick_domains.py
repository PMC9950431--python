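"""Cysteine-scaffold scanning, domain splitting, connectivity, repeats."""

import re

import numpy as np
import pytest

from knotminer.ick_domains import (DEFAULT_3DS, DEFAULT_4DS, DomainHit,
                                   IckPattern, QcRules, _self_align_once,
                                   blosum62_score, detect_internal_repeats,
                                   predict_connectivity, qc_filter, scan_ick,
                                   split_domains)
from knotminer.seq_io import SeqRecord
from knotminer.synthetic_data import NON_CYS, make_scaffold

AAS = "ACDEFGHIKLMNPQRSTVWY"


# -- scanning ---------------------------------------------------------------

def test_xt3a_scaffold_yields_two_3ds_domains(xt3a, xt3a_hits):
    assert [(h.start, h.end) for h in xt3a_hits] == [(14, 45), (50, 80)]
    assert xt3a_hits[0].cys_positions == (14, 21, 28, 29, 34, 45)
    assert xt3a_hits[1].cys_positions == (50, 57, 64, 65, 70, 80)
    assert all(h.ds_class == "3DS" for h in xt3a_hits)


def test_cysteine_free_sequence_has_no_hits():
    rec = SeqRecord(id="nocys", residues="ADEFGHIKLMNPQRSTVWY" * 10)
    assert scan_ick(rec) == []


def _regex_candidates(seq: str, pat: IckPattern) -> set:
    """Positions (1-based) where a scaffold window starts, via regex."""
    body = "C" + "".join(f"[^C]{{{lo},{hi}}}C" for lo, hi in pat.loop_bounds)
    return {m.start() + 1 for m in re.finditer(f"(?=({body}))", seq)}


def _oracle_scan(rec: SeqRecord, pat: IckPattern):
    """Exhaustive regex window detection + leftmost-first greedy."""
    cys = rec.cysteine_positions()
    starts = _regex_candidates(rec.residues, pat)
    hits = []
    i = 0
    while i < len(cys):
        if cys[i] in starts and i + pat.n_cys <= len(cys):
            window = tuple(cys[i:i + pat.n_cys])
            hits.append((window[0], window[-1], window))
            i += pat.n_cys
        else:
            i += 1
    return hits


@pytest.mark.parametrize("pattern", [DEFAULT_3DS, DEFAULT_4DS],
                         ids=["3DS", "4DS"])
def test_scan_matches_exhaustive_window_oracle(pattern):
    rng = np.random.default_rng(101)
    for _ in range(150):
        n = int(rng.integers(30, 300))
        residues = "".join(
            rng.choice(list(AAS), n,
                       p=[0.12 if a == "C" else 0.88 / 19 for a in AAS]))
        rec = SeqRecord(id="fuzz", residues=residues, source="synthetic")
        got = [(h.start, h.end, h.cys_positions) for h in scan_ick(rec,
                                                                   pattern)]
        assert got == _oracle_scan(rec, pattern)


def test_hits_never_overlap_on_implanted_scaffolds():
    rng = np.random.default_rng(55)
    for _ in range(50):
        recs = []
        for k in range(3):
            r, _ = make_scaffold(DEFAULT_3DS, rng, (0, 10), (0, 10),
                                 record_id=f"s{k}")
            recs.append(r.residues)
        rec = SeqRecord(id="multi", residues="".join(recs), source="synthetic")
        hits = scan_ick(rec)
        for a, b in zip(hits, hits[1:]):
            assert a.end < b.start


# -- splitting and linkers --------------------------------------------------

def test_xt3a_split_gives_two_domains_and_linker_of_four(xt3a, xt3a_hits):
    domains, linkers = split_domains(xt3a, xt3a_hits)
    assert [d.id for d in domains] == ["Xt3a-scaffold|D1", "Xt3a-scaffold|D2"]
    assert domains[0].residues == xt3a.residues[13:45]
    assert len(linkers) == 1 and linkers[0].length == 4


def test_single_hit_yields_one_record_no_linker(xt3a, xt3a_hits):
    domains, linkers = split_domains(xt3a, xt3a_hits[:1])
    assert len(domains) == 1 and linkers == []


def test_overlapping_hits_rejected(xt3a, xt3a_hits):
    bad = DomainHit(parent_id=xt3a.id, start=34, end=65,
                    cys_positions=(34, 45, 50, 57, 64, 65), ds_class="3DS")
    with pytest.raises(ValueError, match="overlap"):
        split_domains(xt3a, [xt3a_hits[0], bad])


def test_linker_lengths_equal_construction_gaps():
    rng = np.random.default_rng(77)
    for _ in range(20):
        parts, gaps = [], []
        pos = 0
        doms = []
        for k in range(3):
            r, _ = make_scaffold(DEFAULT_3DS, rng, (0, 0), (0, 0),
                                 record_id=f"d{k}")
            if k:
                g = int(rng.integers(0, 15))
                gaps.append(g)
                parts.append("".join(rng.choice(list(NON_CYS), g)))
                pos += g
            parts.append(r.residues)
            doms.append((pos + 1, pos + len(r)))
            pos += len(r)
        rec = SeqRecord(id="tri", residues="".join(parts), source="synthetic")
        hits = scan_ick(rec)
        assert len(hits) == 3
        _, linkers = split_domains(rec, hits)
        assert [ln.length for ln in linkers] == gaps
        # tails + domains + linkers tile the parent exactly
        total = sum(h.end - h.start + 1 for h in hits) \
            + sum(ln.length for ln in linkers) \
            + (hits[0].start - 1) + (len(rec) - hits[-1].end)
        assert total == len(rec)


# -- connectivity -----------------------------------------------------------

def test_xt3a_connectivity_matches_knot_rule(xt3a_hits):
    d1 = {(p.pos_a, p.pos_b) for p in predict_connectivity(xt3a_hits[0])}
    d2 = {(p.pos_a, p.pos_b) for p in predict_connectivity(xt3a_hits[1])}
    assert d1 == {(14, 29), (21, 34), (28, 45)}
    assert d2 == {(50, 65), (57, 70), (64, 80)}


def test_connectivity_is_a_perfect_matching():
    rng = np.random.default_rng(9)
    for pat in (DEFAULT_3DS, DEFAULT_4DS):
        rec, _ = make_scaffold(pat, rng, record_id="p")
        (hit,) = scan_ick(rec, pat)
        pairs = predict_connectivity(hit)
        used = [p for pair in pairs for p in (pair.pos_a, pair.pos_b)]
        assert sorted(used) == sorted(hit.cys_positions)


def test_wrong_cysteine_count_raises():
    hit = DomainHit(parent_id="x", start=1, end=20,
                    cys_positions=(1, 5, 9, 13, 20), ds_class="3DS")
    with pytest.raises(ValueError, match="5"):
        predict_connectivity(hit)


# -- internal repeats -------------------------------------------------------

def test_exact_duplication_is_called_at_100_identity():
    rng = np.random.default_rng(21)
    u = "".join(rng.choice(list(NON_CYS), 40))
    rec = SeqRecord(id="dup", residues=u + u, source="synthetic")
    (call,) = detect_internal_repeats(rec)
    assert call.span_a == (1, 40) and call.span_b == (41, 80)
    assert call.identity == 100.0


def test_iid_sequence_yields_no_call_at_60_identity():
    rng = np.random.default_rng(2024)
    rec = SeqRecord(id="iid", residues="".join(rng.choice(list(AAS), 100)),
                    source="synthetic")
    assert detect_internal_repeats(rec, min_identity=60.0,
                                   min_unit_len=20) == []


def test_repeat_detection_is_reversal_symmetric():
    rng = np.random.default_rng(31)
    u = "".join(rng.choice(list(NON_CYS), 35))
    rec = SeqRecord(id="f", residues=u + u, source="synthetic")
    rev = SeqRecord(id="r", residues=rec.residues[::-1], source="synthetic")
    (cf,) = detect_internal_repeats(rec)
    (cr,) = detect_internal_repeats(rev)
    n = len(rec)
    mirror = lambda span: (n - span[1] + 1, n - span[0] + 1)
    assert cr.score == cf.score and cr.identity == cf.identity
    assert {cr.span_a, cr.span_b} == {mirror(cf.span_a), mirror(cf.span_b)}


def _oracle_best_score(residues: str, band: int,
                       gap_open: float = 11.0, gap_extend: float = 1.0):
    """Score-only Smith-Waterman with the |i-j| < band region excluded."""
    n = len(residues)
    best = 0.0
    H = [[0.0] * (n + 1) for _ in range(n + 1)]
    E = [[float("-inf")] * (n + 1) for _ in range(n + 1)]
    F = [[float("-inf")] * (n + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(i + band, n + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = blosum62_score(residues[i - 1], residues[j - 1])
            H[i][j] = max(0.0, s + max(H[i - 1][j - 1], E[i - 1][j - 1],
                                       F[i - 1][j - 1]))
            best = max(best, H[i][j])
    return best


def test_repeat_score_matches_bruteforce_oracle_on_duplications():
    rng = np.random.default_rng(303)
    for _ in range(25):
        unit = "".join(rng.choice(list(NON_CYS), int(rng.integers(22, 45))))
        # mutate the second copy at 10-40% of sites
        copy = list(unit)
        k = int(rng.integers(2, max(3, len(unit) // 3)))
        for pos in rng.choice(len(unit), size=k, replace=False):
            copy[pos] = str(rng.choice(list(NON_CYS)))
        residues = unit + "".join(copy)
        rec = SeqRecord(id="sim", residues=residues, source="synthetic")
        calls = detect_internal_repeats(rec, min_identity=0.0,
                                        min_unit_len=20, max_rounds=1)
        oracle = _oracle_best_score(residues, band=20)
        assert calls and calls[0].score == oracle


# -- qc filtering -----------------------------------------------------------

def test_long_loop_removed():
    cys = (1, 5, 9, 50, 55, 60)
    residues = "".join("C" if (i + 1) in cys else "A" for i in range(60))
    rec = SeqRecord(id="ll", residues=residues)
    hit = DomainHit(parent_id="ll", start=1, end=60, cys_positions=cys,
                    ds_class="3DS")
    kept, decisions = qc_filter([rec], {"ll": [hit]},
                                QcRules(max_loop=25))
    assert kept == [] and decisions[0].reason == "LONG_LOOP"


def test_missing_cysteines_removed():
    rec = SeqRecord(id="mc", residues="ACACACACAC" + "A" * 20)
    kept, decisions = qc_filter([rec], {}, QcRules(required_cys=6))
    assert kept == [] and decisions[0].reason == "MISSING_CYS"


def test_xt3a_kept_under_default_rules(xt3a, xt3a_hits):
    kept, decisions = qc_filter([xt3a], {xt3a.id: xt3a_hits})
    assert kept == [xt3a] and decisions[0].reason == "OK"


def test_long_nterm_removed(xt3a):
    shifted = SeqRecord(id="shift", residues="A" * 70 + xt3a.residues)
    hits = scan_ick(shifted)
    kept, decisions = qc_filter([shifted], {"shift": hits})
    assert kept == [] and decisions[0].reason == "LONG_NTERM"
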