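"""End-to-end orchestration: mine → classify → split → cluster → align
→ tree/rates → sequence space, with a reproducible run manifest.

Every stage writes its artifact under the run directory; the manifest
records config hash, per-artifact sha256 checksums and per-stage record
counts, so two runs with the same config and seed can be compared
checksum-for-checksum.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .curation import greedy_cluster, representatives
from .evolution import bootstrap_support, site_rates
from .ick_domains import (DEFAULT_3DS, DEFAULT_4DS, DomainHit, QcRules,
                          detect_internal_repeats, predict_connectivity,
                          qc_filter, scan_ick, split_domains)
from .regional_msa import (align_regions, anchor_cysteines,
                           conservation_line, to_clustal)
from .seq_io import read_fasta, translate_orfs, write_fasta
from .seqspace import featurize, nearest_neighbors, pca_project
from .synthetic_data import SimConfig, make_benchmark

_PATTERNS = {"3DS": DEFAULT_3DS, "4DS": DEFAULT_4DS}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    out_dir: str = "knotminer-run"
    seed: int = 0
    input_fasta: str | None = None      # protein FASTA; None -> simulate
    input_nucleotide: bool = False
    min_orf_aa: int = 40
    patterns: tuple[str, ...] = ("3DS",)
    simulate: bool = False
    max_loop: int = 25
    max_nterm: int = 60
    repeat_min_identity: float = 40.0
    repeat_min_unit_len: int = 20
    repeat_max_rounds: int = 3
    cluster_threshold: float = 0.99
    bootstrap_reps: int = 1000
    collapse_below: float = 50.0
    rate_categories: int = 4
    pca_components: int = 3
    neighbor_k: int = 10
    neighbor_query: str | None = None
    detect_repeats: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        for p in self.patterns:
            if p not in _PATTERNS:
                raise ValueError(f"unknown pattern class {p!r}")
        if self.input_fasta is None and not self.simulate:
            raise ValueError("either input_fasta or simulate must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "patterns" in raw:
            raw = dict(raw, patterns=tuple(raw["patterns"]))
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # analysis identity, not artifact location
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    counts: dict = field(default_factory=dict)
    removals: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    stages: list = field(default_factory=list)
    failure: str | None = None


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(path: Path, header: Sequence[str],
               rows: Sequence[Sequence[Any]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute every enabled stage; returns the manifest (also on disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__,
                           config_hash=cfg.config_hash(), seed=cfg.seed)
    artifacts: list[Path] = []

    def stage(name: str):
        manifest.stages.append(name)
        manifest.timings[name] = time.time()
        return name

    def done(name: str) -> None:
        manifest.timings[name] = round(time.time() - manifest.timings[name], 4)

    try:
        # -- input ---------------------------------------------------------
        stage("input")
        if cfg.simulate:
            sim_cfg = SimConfig(seed=cfg.seed, **cfg.sim)
            records, truth = make_benchmark(sim_cfg)
            (out / "truth.json").write_text(truth.to_json())
            artifacts.append(out / "truth.json")
        elif cfg.input_nucleotide:
            nucs = read_fasta(cfg.input_fasta, alphabet="nucleotide")
            records = [orf for nuc in nucs
                       for orf in translate_orfs(nuc, cfg.min_orf_aa)]
        else:
            records = read_fasta(cfg.input_fasta)
        write_fasta(records, out / "input.faa")
        artifacts.append(out / "input.faa")
        manifest.counts["input_records"] = len(records)
        done("input")

        # -- scan ----------------------------------------------------------
        stage("scan")
        patterns = [_PATTERNS[p] for p in cfg.patterns]
        hits_by_id: dict[str, list[DomainHit]] = {
            r.id: scan_ick(r, patterns) for r in records}
        n_hits = sum(len(v) for v in hits_by_id.values())
        _write_tsv(out / "domains.tsv",
                   ["parent_id", "start", "end", "ds_class", "cys_positions"],
                   [(h.parent_id, h.start, h.end, h.ds_class,
                     ";".join(map(str, h.cys_positions)))
                    for hits in hits_by_id.values() for h in hits])
        artifacts.append(out / "domains.tsv")
        manifest.counts["domain_hits"] = n_hits
        manifest.counts["records_with_hits"] = sum(
            1 for v in hits_by_id.values() if v)
        done("scan")

        # -- qc ------------------------------------------------------------
        stage("qc")
        rules = QcRules(max_loop=cfg.max_loop, max_nterm=cfg.max_nterm)
        with_hits = [r for r in records if hits_by_id[r.id]]
        kept, decisions = qc_filter(with_hits, hits_by_id, rules)
        manifest.removals = [
            {"record_id": d.record_id, "reason": d.reason}
            for d in decisions if d.reason != "OK"]
        _write_tsv(out / "qc.tsv", ["record_id", "reason"],
                   [(d.record_id, d.reason) for d in decisions])
        artifacts.append(out / "qc.tsv")
        manifest.counts["qc_kept"] = len(kept)
        manifest.counts["qc_removed"] = len(with_hits) - len(kept)
        done("qc")

        # -- repeats -------------------------------------------------------
        if cfg.detect_repeats:
            stage("repeats")
            repeat_rows = []
            for r in kept:
                if len(hits_by_id[r.id]) < 2:
                    continue
                for call in detect_internal_repeats(
                        r, min_identity=cfg.repeat_min_identity,
                        min_unit_len=cfg.repeat_min_unit_len,
                        max_rounds=cfg.repeat_max_rounds):
                    repeat_rows.append((
                        call.parent_id, call.span_a[0], call.span_a[1],
                        call.span_b[0], call.span_b[1],
                        f"{call.identity:.1f}", f"{call.score:g}"))
            _write_tsv(out / "repeats.tsv",
                       ["parent_id", "a_start", "a_end", "b_start", "b_end",
                        "identity", "score"], repeat_rows)
            artifacts.append(out / "repeats.tsv")
            manifest.counts["repeat_calls"] = len(repeat_rows)
            done("repeats")

        # -- split ---------------------------------------------------------
        stage("split")
        domain_records = []
        linker_rows = []
        connectivity_rows = []
        for r in kept:
            doms, linkers = split_domains(r, hits_by_id[r.id])
            domain_records.extend(doms)
            for ln in linkers:
                linker_rows.append((ln.upstream_id, ln.downstream_id,
                                    ln.length))
            for h in hits_by_id[r.id]:
                for pair in predict_connectivity(h):
                    connectivity_rows.append(
                        (r.id, pair.rank, pair.pos_a, pair.pos_b))
        write_fasta(domain_records, out / "domains.faa")
        _write_tsv(out / "linkers.tsv",
                   ["upstream", "downstream", "length"], linker_rows)
        _write_tsv(out / "connectivity.tsv",
                   ["parent_id", "rank", "pos_a", "pos_b"],
                   connectivity_rows)
        artifacts += [out / "domains.faa", out / "linkers.tsv",
                      out / "connectivity.tsv"]
        manifest.counts["domain_records"] = len(domain_records)
        manifest.counts["linkers"] = len(linker_rows)
        done("split")

        # -- cluster -------------------------------------------------------
        stage("cluster")
        clusters = greedy_cluster(domain_records, cfg.cluster_threshold)
        reps = representatives(domain_records, clusters)
        _write_tsv(out / "clusters.tsv",
                   ["representative", "member"],
                   [(c.representative, m) for c in clusters
                    for m in c.members])
        write_fasta(reps, out / "representatives.faa")
        artifacts += [out / "clusters.tsv", out / "representatives.faa"]
        manifest.counts["clusters"] = len(clusters)
        done("cluster")

        # -- align / tree / rates / seqspace ------------------------------
        aln = None
        by_class: dict[str, list] = {}
        hit_class = {}
        for hits in hits_by_id.values():
            for idx, h in enumerate(sorted(hits, key=lambda x: x.start),
                                    start=1):
                hit_class[f"{h.parent_id}|D{idx}"] = h.ds_class
        for rec in reps:
            by_class.setdefault(hit_class.get(rec.id, "3DS"), []).append(rec)
        best_class = max(by_class, key=lambda c: len(by_class[c]),
                         default=None) if by_class else None
        if best_class and len(by_class[best_class]) >= 2:
            stage("align")
            aset = anchor_cysteines(by_class[best_class])
            aln = align_regions(aset)
            (out / "alignment.clustal").write_text(to_clustal(aln))
            artifacts.append(out / "alignment.clustal")
            manifest.counts["aligned_sequences"] = len(aln)
            manifest.counts["alignment_width"] = aln.width
            done("align")
        if aln is not None and len(aln) >= 3:
            stage("tree")
            tree = bootstrap_support(aln, n_reps=cfg.bootstrap_reps,
                                     seed=cfg.seed,
                                     collapse_below=cfg.collapse_below)
            (out / "tree.nwk").write_text(tree.newick + "\n")
            artifacts.append(out / "tree.nwk")
            done("tree")

            stage("rates")
            profile = site_rates(aln, tree,
                                 n_categories=cfg.rate_categories)
            _write_tsv(out / "site_rates.tsv",
                       ["column", "rate", "scored"],
                       [(j + 1,
                         "NA" if not profile.scored[j]
                         else f"{profile.rates[j]:.6f}",
                         int(profile.scored[j]))
                        for j in range(aln.width)])
            artifacts.append(out / "site_rates.tsv")
            manifest.counts["scored_columns"] = int(profile.scored.sum())
            done("rates")

            stage("seqspace")
            fm = featurize(aln)
            pca = pca_project(fm, cfg.pca_components)
            query = cfg.neighbor_query or pca.ids[0]
            report_nn = nearest_neighbors(pca, query, k=cfg.neighbor_k)
            _write_tsv(out / "pca_scores.tsv",
                       ["id"] + [f"PC{i + 1}"
                                 for i in range(pca.scores.shape[1])],
                       [(pca.ids[i],
                         *(f"{v:.6f}" for v in pca.scores[i]))
                        for i in range(len(pca.ids))])
            _write_tsv(out / "neighbors.tsv", ["query", "rank", "id",
                                               "distance"],
                       [(report_nn.query, r + 1, nid, f"{d:.6f}")
                        for r, (nid, d) in enumerate(report_nn.neighbors)])
            (out / "pca_manifest.json").write_text(json.dumps({
                "explained_variance_ratio":
                    [float(v) for v in pca.explained_variance_ratio],
                "n_dropped_columns": len(pca.dropped_columns),
            }, indent=1))
            artifacts += [out / "pca_scores.tsv", out / "neighbors.tsv",
                          out / "pca_manifest.json"]
            done("seqspace")
    except Exception as exc:  # record the failure, then re-raise
        manifest.failure = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(
            json.dumps(asdict(manifest), indent=1, sort_keys=True))
        raise
    for p in artifacts:
        manifest.checksums[p.name] = _sha256(p)
    (out / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=1, sort_keys=True))
    return manifest


def report(manifest: RunManifest, out_dir: str | Path) -> str:
    """Human-readable run summary from the manifest and artifacts."""
    out = Path(out_dir)
    lines = [f"knotminer {manifest.version} run "
             f"(config {manifest.config_hash}, seed {manifest.seed})",
             ""]
    for key in sorted(manifest.counts):
        lines.append(f"  {key}: {manifest.counts[key]}")
    if manifest.removals:
        lines.append("  removed records:")
        for r in manifest.removals:
            lines.append(f"    {r['record_id']}: {r['reason']}")
    tree_file = out / "tree.nwk"
    if tree_file.exists():
        lines += ["", "tree:", "  " + tree_file.read_text().strip()]
    nn_file = out / "neighbors.tsv"
    if nn_file.exists():
        lines += ["", "nearest neighbours:"]
        lines += ["  " + ln for ln in
                  nn_file.read_text().strip().splitlines()]
    if manifest.failure:
        lines += ["", f"FAILED: {manifest.failure}"]
    return "\n".join(lines) + "\n"
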