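"""End-to-end orchestration: correlate, rank families, intersect, network, candidates.

A run is described by a single declarative YAML config (all keys mirrored
by CLI flags); outputs are a correlation table, per-guide family rankings,
the Venn region table, the network in SIF and GraphML form, the candidate
report, and a JSON run manifest with input checksums and stage counts.
Identical inputs and config produce identical output files (the manifest's
timestamp is the one deliberately non-reproducible field; it is excluded
from determinism comparisons).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import yaml

from guidecoex._version import __version__
from guidecoex.correlation import ThresholdSpec, correlate_guides, filter_by_threshold
from guidecoex.families import rank_families, shared_top_families, write_rankings
from guidecoex.io import (
    ExpressionMatrix,
    read_expression_matrix,
    read_family_table,
    read_guide_list,
)
from guidecoex.network import (
    ALL_FAMILIES,
    build_network,
    count_edge_signs,
    export_graphml,
    export_sif,
    select_negative_candidates,
    write_candidates,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_config"]

logger = logging.getLogger("guidecoex")

#: Guides covered by the supplementary family-ranking/Venn analysis of the
#: original study (the other four guides are retained for the network).
PAPER_VENN_GUIDES = ["OsGI", "Ghd7", "OsMADS14", "Hd3a"]

_KNOWN_KEYS = {
    "matrix",
    "guides",
    "families",
    "out_dir",
    "family_threshold",
    "network_threshold",
    "top_k",
    "network_family",
    "min_negative_partners",
    "venn_guides",
    "log_transform",
}
_REQUIRED_KEYS = {"matrix", "guides", "families", "out_dir"}


@dataclass
class PipelineConfig:
    matrix: str
    guides: str
    families: str
    out_dir: str
    family_threshold: ThresholdSpec = ThresholdSpec(0.8)
    network_threshold: ThresholdSpec = ThresholdSpec(0.6)
    top_k: int = 5
    network_family: str = "G2-like"
    min_negative_partners: int = 2
    venn_guides: str = "all"  # "all" or "paper"
    log_transform: bool = False

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.min_negative_partners < 1:
            raise ValueError("min_negative_partners must be >= 1")
        if self.venn_guides not in ("all", "paper"):
            raise ValueError("venn_guides must be 'all' or 'paper'")


@dataclass
class RunManifest:
    """Config echo, input checksums and per-stage counts for one run."""

    config: dict
    input_checksums: dict[str, str]
    counts: dict = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(asdict(self), indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def _parse_threshold(value, default: ThresholdSpec) -> ThresholdSpec:
    if value is None:
        return default
    if isinstance(value, (int, float)):
        return ThresholdSpec(float(value), default.mode, default.strict)
    if isinstance(value, dict):
        unknown = set(value) - {"tau", "mode", "strict"}
        if unknown:
            raise ValueError(f"unknown threshold key: {sorted(unknown)[0]!r}")
        return ThresholdSpec(
            float(value.get("tau", default.tau)),
            str(value.get("mode", default.mode)),
            bool(value.get("strict", default.strict)),
        )
    raise ValueError(f"cannot parse threshold from {value!r}")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config file, apply defaults, reject unknown keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping of key: value pairs")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key: {sorted(unknown)[0]!r}")
    missing = _REQUIRED_KEYS - set(raw)
    if missing:
        raise ValueError(f"missing required config key: {sorted(missing)[0]!r}")
    return PipelineConfig(
        matrix=str(raw["matrix"]),
        guides=str(raw["guides"]),
        families=str(raw["families"]),
        out_dir=str(raw["out_dir"]),
        family_threshold=_parse_threshold(raw.get("family_threshold"), ThresholdSpec(0.8)),
        network_threshold=_parse_threshold(raw.get("network_threshold"), ThresholdSpec(0.6)),
        top_k=int(raw.get("top_k", 5)),
        network_family=str(raw.get("network_family", "G2-like")),
        min_negative_partners=int(raw.get("min_negative_partners", 2)),
        venn_guides=str(raw.get("venn_guides", "all")),
        log_transform=bool(raw.get("log_transform", False)),
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_echo(config: PipelineConfig) -> dict:
    echo = asdict(config)
    echo["family_threshold"] = asdict(config.family_threshold)
    echo["network_threshold"] = asdict(config.network_threshold)
    return echo


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage and write all outputs to ``config.out_dir``.

    Stages are computed before anything is written; a failure during the
    write phase removes the files already written so no partial output
    directory survives.
    """
    out_dir = Path(config.out_dir)

    def stage(name: str):
        logger.info("stage: %s", name)

    stage("read inputs")
    try:
        matrix = read_expression_matrix(config.matrix)
        guides = read_guide_list(config.guides)
        annotation = read_family_table(config.families)
    except Exception as exc:
        raise RuntimeError(f"[read inputs] {exc}") from exc

    if config.log_transform:
        matrix = ExpressionMatrix(np.log2(matrix.data + 1.0))

    stage("correlate")
    try:
        table = correlate_guides(matrix, guides)
    except Exception as exc:
        raise RuntimeError(f"[correlate] {exc}") from exc

    stage("rank families")
    try:
        rankings = []
        passing_per_guide = {}
        for sym, gid in guides.entries:
            passing = filter_by_threshold(table, config.family_threshold, gid)
            passing_per_guide[gid] = passing
            rankings.append(
                rank_families(
                    passing,
                    annotation,
                    top_k=config.top_k,
                    guide_id=sym,
                    threshold=config.family_threshold,
                )
            )
    except Exception as exc:
        raise RuntimeError(f"[rank families] {exc}") from exc

    stage("venn")
    try:
        if config.venn_guides == "paper":
            venn_rankings = [rk for rk in rankings if rk.guide_id in PAPER_VENN_GUIDES]
            if not venn_rankings:
                raise ValueError(
                    "venn_guides='paper' but none of "
                    f"{PAPER_VENN_GUIDES} found among guide symbols"
                )
        else:
            venn_rankings = rankings
        shared = shared_top_families(venn_rankings)
    except Exception as exc:
        raise RuntimeError(f"[venn] {exc}") from exc

    stage("network")
    try:
        net = build_network(
            table, annotation, family=config.network_family, spec=config.network_threshold
        )
        signs = count_edge_signs(net)
    except Exception as exc:
        raise RuntimeError(f"[network] {exc}") from exc

    stage("candidates")
    try:
        candidates = select_negative_candidates(net, config.min_negative_partners)
    except Exception as exc:
        raise RuntimeError(f"[candidates] {exc}") from exc

    manifest = RunManifest(
        config=_config_echo(config),
        input_checksums={
            "matrix": _sha256(Path(config.matrix)),
            "guides": _sha256(Path(config.guides)),
            "families": _sha256(Path(config.families)),
        },
        counts={
            "genes_read": len(matrix.gene_ids),
            "samples": matrix.n_samples,
            "guides": len(guides),
            "zero_variance_dropped": len(table.zero_variance_genes),
            "tfs_passing_family_threshold": {
                guides.symbol_of(gid): sum(1 for g in passing if g in annotation)
                for gid, passing in passing_per_guide.items()
            },
            "families_ranked": {rk.guide_id: len(rk.ranked) for rk in rankings},
            "shared_top_families": sorted(shared.intersection),
            "network_nodes": len(net.guide_ids) + len(net.tf_ids),
            "network_tf_nodes": len(net.tf_ids),
            "network_edges": net.n_edges,
            "tf_sign_counts": signs.counts,
            "candidates": len(candidates),
        },
        timestamp=datetime.now(timezone.utc).isoformat(),
    )

    stage("write outputs")
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def _w(name: str, writer) -> None:
            p = out_dir / name
            writer(p)
            written.append(p)

        _w("correlations.tsv", table.write)
        _w("family_rankings.tsv", lambda p: write_rankings(rankings, p))
        _w(
            "venn.tsv",
            lambda p: shared.to_frame().to_csv(p, sep="\t", index=False, lineterminator="\n"),
        )
        _w("network.sif", lambda p: export_sif(net, p))
        _w("network.graphml", lambda p: export_graphml(net, p))
        _w("candidates.tsv", lambda p: write_candidates(candidates, p))
        _w("manifest.json", manifest.write)
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"[write outputs] {exc}") from exc
    return manifest
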