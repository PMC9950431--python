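"""Synthetic toxin families with ground-truth manifests.

Generates the data regime the pipeline is designed for: ICK families
with an absolutely conserved cysteine scaffold and variable loops,
tandem (double-knot) duplications with domain-selective divergence, and
non-ICK decoy secreted peptides — everything seeded and accompanied by
a machine-checkable truth manifest, so every downstream stage can be
tested for recovery without external downloads.

The mutation process mirrors the Poisson amino-acid model used for
likelihood computation (uniform exchange over 20 states), so parameter
recovery is a fair test: on a branch of length ``t`` a site of relative
rate ``r`` redraws its residue with probability ``1 - e^{-(20/19) r t}``
(a redraw picks uniformly among the 20 residues, so the expected
fraction of *observed* changes is ``(19/20)(1 - e^{-(20/19) r t})``).
Cysteine scaffold positions never mutate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from skbio import TreeNode

from .evolution import PhyloTree, _AA, N_STATES
from .ick_domains import DEFAULT_3DS, IckPattern, scan_ick
from .seq_io import SeqRecord

#: the 19 non-cysteine residues used for loop backgrounds
NON_CYS = "".join(c for c in _AA if c != "C")

#: Xt3a cysteine scaffold: 82 residues, cysteines at the twelve positions
#: determined by the disulfide connectivity of the solved structure.
XT3A_LENGTH = 82
XT3A_CYS_POSITIONS = (14, 21, 28, 29, 34, 45, 50, 57, 64, 65, 70, 80)
XT3A_CONNECTIVITY = ((14, 29), (21, 34), (28, 45),
                     (50, 65), (57, 70), (64, 80))


def xt3a_scaffold(seed: int = 7) -> SeqRecord:
    """The 82-residue double-ICK fixture scaffold.

    Cysteines sit at the twelve structurally determined positions; the
    remaining residues are a fixed seeded draw from the non-cysteine
    background (the published primary sequence is not reproduced — only
    the cysteine architecture matters to the pipeline).
    """
    rng = np.random.default_rng(seed)
    residues = list(rng.choice(list(NON_CYS), size=XT3A_LENGTH))
    for p in XT3A_CYS_POSITIONS:
        residues[p - 1] = "C"
    return SeqRecord(id="Xt3a-scaffold", residues="".join(residues),
                     description="double-ICK fixture scaffold",
                     source="fixture")


@dataclass
class SimConfig:
    """Knobs of the synthetic study conditions."""

    seed: int
    n_families: int = 3
    family_size: int = 12
    scaffold: IckPattern = field(default_factory=lambda: DEFAULT_3DS)
    n_tail: tuple[int, int] = (0, 12)       # uniform range, residues
    c_tail: tuple[int, int] = (0, 8)
    branch_length: tuple[float, float] = (0.02, 0.25)
    slow_fraction: float = 0.5              # fraction of slow sites
    slow_rate: float = 0.3
    fast_rate: float = 1.7
    n_tandems: int = 5
    linker_length: tuple[int, int] = (2, 10)
    tandem_divergence: tuple[float, float] = (0.1, 0.3)  # per-domain
    n_decoys: int = 200
    decoy_length: tuple[int, int] = (40, 200)
    decoy_cys_freq: float = 0.03
    max_rejection_attempts: int = 200


@dataclass
class TruthRecord:
    record_id: str
    family: str | None = None
    domain_intervals: list[tuple[int, int]] = field(default_factory=list)
    cys_positions: list[int] = field(default_factory=list)
    is_tandem: bool = False
    linker_length: int | None = None
    is_decoy: bool = False


@dataclass
class TruthManifest:
    records: dict[str, TruthRecord] = field(default_factory=dict)
    trees: dict[str, str] = field(default_factory=dict)      # family -> newick
    site_rates: dict[str, list[float]] = field(default_factory=dict)

    def add(self, rec: TruthRecord) -> None:
        if rec.record_id in self.records:
            raise ValueError(f"duplicate truth record {rec.record_id}")
        self.records[rec.record_id] = rec

    def verify(self, records: Sequence[SeqRecord]) -> None:
        """Check every manifest claim against the emitted records."""
        by_id = {r.id: r for r in records}
        for rid, truth in self.records.items():
            rec = by_id.get(rid)
            if rec is None:
                raise AssertionError(f"manifest record {rid} not emitted")
            for p in truth.cys_positions:
                if rec.residues[p - 1] != "C":
                    raise AssertionError(
                        f"{rid}: claimed cysteine at {p} is "
                        f"{rec.residues[p - 1]}")
            for s, e in truth.domain_intervals:
                if not (1 <= s <= e <= len(rec)):
                    raise AssertionError(f"{rid}: interval {s}-{e} outside")
                if rec.residues[s - 1] != "C" or rec.residues[e - 1] != "C":
                    raise AssertionError(
                        f"{rid}: domain {s}-{e} not cysteine-bounded")

    def to_json(self) -> str:
        return json.dumps({
            "records": {k: asdict(v) for k, v in self.records.items()},
            "trees": self.trees,
            "site_rates": self.site_rates,
        }, indent=1, sort_keys=True)


def _random_background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NON_CYS), size=n)) if n else ""


def make_scaffold(pattern: IckPattern, rng: np.random.Generator,
                  n_tail: tuple[int, int] = (0, 0),
                  c_tail: tuple[int, int] = (0, 0),
                  record_id: str = "scaffold") -> tuple[SeqRecord, TruthRecord]:
    """One random ICK sequence satisfying a cysteine pattern."""
    for lo, hi in pattern.loop_bounds:
        if lo > hi:
            raise ValueError("infeasible loop bounds")
    loops = [int(rng.integers(lo, hi + 1)) for lo, hi in pattern.loop_bounds]
    nt = int(rng.integers(n_tail[0], n_tail[1] + 1))
    ct = int(rng.integers(c_tail[0], c_tail[1] + 1))
    parts = [_random_background(rng, nt)]
    cys_positions = []
    pos = nt
    for i in range(pattern.n_cys):
        parts.append("C")
        pos += 1
        cys_positions.append(pos)
        if i < pattern.n_cys - 1:
            parts.append(_random_background(rng, loops[i]))
            pos += loops[i]
    parts.append(_random_background(rng, ct))
    residues = "".join(parts)
    rec = SeqRecord(id=record_id, residues=residues, source="synthetic")
    truth = TruthRecord(record_id=record_id,
                        domain_intervals=[(cys_positions[0],
                                           cys_positions[-1])],
                        cys_positions=cys_positions)
    return rec, truth


def mutate(residues: str, t: float, site_rates: Sequence[float],
           rng: np.random.Generator, frozen: Sequence[int] = (),
           alphabet: str = NON_CYS) -> str:
    """Evolve a sequence along one branch under the Poisson model.

    ``frozen`` lists 1-based positions that never change (the cysteine
    scaffold).  A site redraws uniformly over ``alphabet`` with
    probability ``1 - exp(-(20/19) * rate * t)``.  The default alphabet
    excludes cysteine so mutation never blurs the scaffold signal; pass
    the full 20-letter alphabet for a model-exact 20-state process.
    """
    frozen_set = set(frozen)
    out = list(residues)
    lam = (N_STATES / (N_STATES - 1.0)) * np.asarray(site_rates) * t
    p_redraw = 1.0 - np.exp(-lam)
    draws = rng.random(len(residues))
    new_res = rng.choice(list(alphabet), size=len(residues))
    for i in range(len(residues)):
        if (i + 1) in frozen_set:
            continue
        if draws[i] < p_redraw[i]:
            out[i] = new_res[i]
    return "".join(out)


def random_tree(ids: Sequence[str], rng: np.random.Generator,
                branch_length: tuple[float, float] = (0.02, 0.25),
                ) -> PhyloTree:
    """A random bifurcating tree over ``ids`` with uniform branch lengths."""
    nodes = [TreeNode(name=i) for i in ids]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]  # pop higher index first
        nodes.pop(j)
        nodes.pop(i)
        for child in (a, b):
            child.length = float(rng.uniform(*branch_length))
        parent = TreeNode()
        parent.extend([a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return PhyloTree(root=root)


def evolve_family(ancestor: SeqRecord, tree: PhyloTree,
                  site_rates: Sequence[float], rng: np.random.Generator,
                  frozen: Sequence[int] = (), family: str = "fam",
                  ) -> tuple[list[SeqRecord], TruthManifest]:
    """Evolve an ancestral sequence down a tree; leaves become records."""
    rates = np.asarray(site_rates, dtype=float)
    if rates.size != len(ancestor):
        raise ValueError("site_rates length must match the ancestor")
    manifest = TruthManifest()
    manifest.trees[family] = tree.newick
    manifest.site_rates[family] = [float(r) for r in rates]
    cys = [p for p in ancestor.cysteine_positions()]
    frozen = list(frozen) if frozen else cys
    seqs: dict[int, str] = {id(tree.root): ancestor.residues}
    records: list[SeqRecord] = []
    for node in tree.root.preorder(include_self=False):
        parent_seq = seqs[id(node.parent)]
        child_seq = mutate(parent_seq, node.length or 0.0, rates, rng,
                           frozen=frozen)
        seqs[id(node)] = child_seq
        if node.is_tip():
            rid = f"{family}|{node.name}"
            records.append(SeqRecord(id=rid, residues=child_seq,
                                     description=f"member of {family}",
                                     source="synthetic"))
            manifest.add(TruthRecord(
                record_id=rid, family=family,
                domain_intervals=[(cys[0], cys[-1])] if cys else [],
                cys_positions=frozen,
            ))
    return records, manifest


def make_tandem(ancestor: SeqRecord, cfg: SimConfig,
                rng: np.random.Generator, record_id: str = "tandem",
                ) -> tuple[SeqRecord, TruthManifest]:
    """A double-knot record: tail + domain copy 1 + linker + copy 2 + tail.

    Each copy diverges independently from the ancestor domain by its own
    branch length from ``cfg.tandem_divergence``, emulating
    domain-selective divergence (copy 2 faster by default).
    """
    cys = ancestor.cysteine_positions()
    if not cys:
        raise ValueError("tandem ancestor must contain cysteines")
    dom = ancestor.residues[cys[0] - 1:cys[-1]]
    dom_cys = [p - cys[0] + 1 for p in cys]
    uniform = np.ones(len(dom))
    d1, d2 = cfg.tandem_divergence
    copy1 = mutate(dom, d1, uniform, rng, frozen=dom_cys)
    copy2 = mutate(dom, d2, uniform, rng, frozen=dom_cys)
    linker_len = int(rng.integers(cfg.linker_length[0],
                                  cfg.linker_length[1] + 1))
    nt = int(rng.integers(cfg.n_tail[0], cfg.n_tail[1] + 1))
    ct = int(rng.integers(cfg.c_tail[0], cfg.c_tail[1] + 1))
    ntail = _random_background(rng, nt)
    ctail = _random_background(rng, ct)
    linker = _random_background(rng, linker_len)
    residues = ntail + copy1 + linker + copy2 + ctail
    off1 = nt
    off2 = nt + len(dom) + linker_len
    cys_all = [off1 + p for p in dom_cys] + [off2 + p for p in dom_cys]
    rec = SeqRecord(id=record_id, residues=residues,
                    description="synthetic double-knot", source="synthetic")
    manifest = TruthManifest()
    manifest.add(TruthRecord(
        record_id=record_id,
        domain_intervals=[(off1 + dom_cys[0], off1 + dom_cys[-1]),
                          (off2 + dom_cys[0], off2 + dom_cys[-1])],
        cys_positions=cys_all,
        is_tandem=True,
        linker_length=linker_len,
    ))
    return rec, manifest


def make_decoys(cfg: SimConfig, rng: np.random.Generator,
                pattern: IckPattern | None = None) -> list[SeqRecord]:
    """Non-ICK background peptides, guaranteed not to match the pattern.

    Residues are drawn i.i.d. with cysteines at ``decoy_cys_freq``;
    candidates matching the ICK pattern are rejected and redrawn.
    """
    pattern = pattern or cfg.scaffold
    probs = np.full(20, (1.0 - cfg.decoy_cys_freq) / 19.0)
    probs[_AA.index("C")] = cfg.decoy_cys_freq
    out: list[SeqRecord] = []
    for i in range(cfg.n_decoys):
        for attempt in range(cfg.max_rejection_attempts):
            length = int(rng.integers(cfg.decoy_length[0],
                                      cfg.decoy_length[1] + 1))
            residues = "".join(rng.choice(list(_AA), size=length, p=probs))
            rec = SeqRecord(id=f"decoy{i + 1:04d}", residues=residues,
                            description="non-ICK decoy", source="synthetic")
            if not scan_ick(rec, pattern):
                out.append(rec)
                break
        else:
            raise RuntimeError(
                f"decoy rejection failed after "
                f"{cfg.max_rejection_attempts} attempts")
    return out


def make_benchmark(cfg: SimConfig,
                   ) -> tuple[list[SeqRecord], TruthManifest]:
    """The default study-condition benchmark: families + tandems + decoys."""
    rng = np.random.default_rng(cfg.seed)
    records: list[SeqRecord] = []
    manifest = TruthManifest()
    for f in range(cfg.n_families):
        anc, _ = make_scaffold(cfg.scaffold, rng, cfg.n_tail, cfg.c_tail,
                               record_id=f"fam{f + 1}-anc")
        n_slow = int(round(cfg.slow_fraction * len(anc)))
        rates = np.full(len(anc), cfg.fast_rate)
        rates[:n_slow] = cfg.slow_rate
        tree = random_tree([f"m{m + 1:02d}" for m in range(cfg.family_size)],
                           rng, cfg.branch_length)
        recs, man = evolve_family(anc, tree, rates, rng,
                                  family=f"fam{f + 1}")
        records.extend(recs)
        for r in man.records.values():
            manifest.add(r)
        manifest.trees.update(man.trees)
        manifest.site_rates.update(man.site_rates)
    for t in range(cfg.n_tandems):
        anc, _ = make_scaffold(cfg.scaffold, rng, (0, 0), (0, 0),
                               record_id=f"tandem{t + 1}-anc")
        rec, man = make_tandem(anc, cfg, rng, record_id=f"tandem{t + 1:02d}")
        records.append(rec)
        for r in man.records.values():
            manifest.add(r)
    for rec in make_decoys(cfg, rng):
        records.append(rec)
        manifest.add(TruthRecord(record_id=rec.id, is_decoy=True))
    manifest.verify(records)
    return records, manifest
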