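"""End-to-end orchestration with config files and reproducible run manifests.

Two pipelines compose the library stages:

* phospho:  read sites -> median centring -> protein-abundance correction ->
  motif annotation -> filter cascade [-> network clustering of the
  significant hits].
* fdapa:    read traces -> correct -> double-exponential fits
  [-> condition comparison].

Each run directory receives every intermediate table plus ``manifest.json``
recording the config, seed, package version and SHA-256 checksums of the
inputs, so a manifest alone suffices to reproduce the run.  Reruns with the
same config and inputs produce byte-identical outputs; no stage mutates its
input files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .errors import ConfigurationError
from .motifs import BUILTIN_MOTIFS, annotate_motifs
from . import fdapa as fd
from . import network as net
from . import silac

logger = logging.getLogger(__name__)

__all__ = ["PhosphoConfig", "FdapaConfig", "RunConfig", "load_config",
           "run_phospho_pipeline", "run_fdapa_pipeline"]


@dataclass
class PhosphoConfig:
    sites: str | None = None
    motifs: list[str] = field(default_factory=lambda: list(BUILTIN_MOTIFS))
    fold_threshold: float = 1.0
    p_threshold: float = 0.1
    mitotic_list: str | None = None
    edges: str | None = None
    penalty: float = 2.0
    min_size: int = 3
    min_density: float = 0.3
    overlap_merge: float = 0.8


@dataclass
class FdapaConfig:
    traces: str | None = None
    bleach_mode: str = "auto"
    bleach_constant: float | None = None
    constrain_sum: bool = False
    n_starts: int = 20
    r2_min: float = 0.8
    compare_by: str = "condition"
    statistic: str = "t_half_slow"


@dataclass
class RunConfig:
    """Validated run configuration (paths, thresholds, seed, output dir)."""

    out_dir: str = "run"
    seed: int = 0
    phospho: PhosphoConfig = field(default_factory=PhosphoConfig)
    fdapa: FdapaConfig = field(default_factory=FdapaConfig)

    def validate(self, require: str | None = None) -> None:
        if not 0.0 < self.phospho.p_threshold <= 1.0:
            raise ConfigurationError("p_threshold must be in (0, 1]")
        if self.phospho.min_size < 1:
            raise ConfigurationError("min_size must be >= 1")
        unknown = set(self.phospho.motifs) - set(BUILTIN_MOTIFS)
        if unknown:
            raise ConfigurationError(f"unknown motifs: {sorted(unknown)}")
        paths = {
            "phospho.sites": self.phospho.sites,
            "phospho.mitotic_list": self.phospho.mitotic_list,
            "phospho.edges": self.phospho.edges,
            "fdapa.traces": self.fdapa.traces,
        }
        for key, p in paths.items():
            if require and not key.startswith(require):
                continue
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{key}: input path does not exist: {p}")
        if require == "phospho" and self.phospho.sites is None:
            raise ConfigurationError("phospho.sites is required")
        if require == "fdapa" and self.fdapa.traces is None:
            raise ConfigurationError("fdapa.traces is required")


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(
        out_dir=raw.get("out_dir", "run"),
        seed=int(raw.get("seed", 0)),
        phospho=PhosphoConfig(**raw.get("phospho", {})),
        fdapa=FdapaConfig(**raw.get("fdapa", {})),
    )
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, config: RunConfig, inputs: dict[str, str], outputs: list[str]) -> None:
    manifest = {
        "tool": "phosphoflux",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "input_checksums_sha256": {k: _sha256(v) for k, v in inputs.items() if v},
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def run_phospho_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Run normalize -> annotate -> cascade [-> cluster]; returns run dir."""
    config.validate(require="phospho")
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pc = config.phospho

    sites = silac.read_site_table(pc.sites)
    logger.info("phospho: %d site rows read", len(sites))
    sites = silac.median_center(sites)
    sites = silac.correct_protein_abundance(sites)
    silac.write_site_table(sites, out / "normalized_sites.tsv")

    rules = [BUILTIN_MOTIFS[m] for m in pc.motifs]
    annotated = annotate_motifs(sites, rules)
    silac.write_site_table(annotated, out / "annotated_sites.tsv")

    mitotic = None
    if pc.mitotic_list:
        mitotic = [
            line.strip() for line in Path(pc.mitotic_list).read_text().splitlines() if line.strip()
        ]
    result = silac.apply_cascade(
        annotated,
        motif_rules=rules,
        fold_threshold=pc.fold_threshold,
        p_threshold=pc.p_threshold,
        mitotic_list=mitotic,
    )
    for name, counts in result.counts.items():
        logger.info("phospho cascade %s: %s", name, counts)
    silac.write_cascade_report(result, out / "cascade_report.yaml")
    outputs = ["normalized_sites.tsv", "annotated_sites.tsv", "cascade_report.yaml"]
    for (motif, tier), table in result.tier_tables.items():
        fname = f"tier_{motif}_{tier}.tsv"
        silac.write_site_table(table, out / fname)
        outputs.append(fname)

    if pc.edges:
        graph = net.read_edge_list(pc.edges)
        # cluster within the subnetwork induced by significant hits
        hits = {
            str(p).upper()
            for (motif, tier), table in result.tier_tables.items()
            if tier == "sig"
            for p in table["protein_id"]
        }
        sub = graph.subgraph([n for n in graph.nodes if n in hits]) if hits else graph
        clusters = net.find_clusters(
            sub if sub.number_of_nodes() else graph,
            penalty=pc.penalty,
            min_size=pc.min_size,
            min_density=pc.min_density,
            overlap_merge=pc.overlap_merge,
        )
        net.write_clusters(clusters, out / "clusters.tsv", out / "clusters.graphml", graph)
        outputs += ["clusters.tsv", "clusters.graphml"]

    inputs = {"sites": pc.sites, "mitotic_list": pc.mitotic_list, "edges": pc.edges}
    _write_manifest(out, config, inputs, outputs)
    return out


def run_fdapa_pipeline(config: RunConfig, out_dir=None) -> Path:
    """Run correct -> fit [-> compare]; returns run dir."""
    config.validate(require="fdapa")
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fc = config.fdapa

    traces = fd.read_traces(fc.traces)
    if not traces:
        raise ConfigurationError(f"no traces found in {fc.traces}")
    logger.info("fdapa: %d traces read", len(traces))
    fits = fd.fit_traces(
        traces,
        bleach_mode=fc.bleach_mode,
        bleach_constant=fc.bleach_constant,
        constrain_sum=fc.constrain_sum,
        n_starts=fc.n_starts,
        seed=config.seed,
    )
    fits.to_csv(out / "fits.tsv", sep="\t", index=False)
    outputs = ["fits.tsv"]

    groups = sorted(fits[fc.compare_by].astype(str).unique())
    if len(groups) == 2:
        comp = fd.compare_turnover(
            fits, groups[0], groups[1], by=fc.compare_by,
            statistic=fc.statistic, r2_min=fc.r2_min,
        )
        report = {
            "statistic": comp.statistic,
            "group_a": comp.group_a,
            "group_b": comp.group_b,
            "n_a": len(comp.values_a),
            "n_b": len(comp.values_b),
            "mean_a": comp.mean_a,
            "mean_b": comp.mean_b,
            "sem_a": comp.sem_a,
            "sem_b": comp.sem_b,
            "t_statistic": comp.t_statistic,
            "p_value": comp.p_value,
            "excluded_cells": comp.excluded_cells,
        }
        (out / "comparison.json").write_text(json.dumps(report, indent=2) + "\n")
        outputs.append("comparison.json")
        logger.info(
            "fdapa compare %s: %s=%.1f vs %s=%.1f, p=%.3g",
            comp.statistic, comp.group_a, comp.mean_a, comp.group_b, comp.mean_b, comp.p_value,
        )

    _write_manifest(out, config, {"traces": fc.traces}, outputs)
    return out
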