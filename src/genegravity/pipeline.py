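"""End-to-end orchestration: network -> CePIN -> propagation -> gravity ->
set statistics, with a manifest recording parameters and input checksums."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import coexpr, gravity, netio, propagation as propagate, setstats


@dataclass
class RunConfig:
    network_path: str
    expression_path: str
    mutations_path: str
    metadata_path: str | None = None
    geneset_paths: dict[str, str] = field(default_factory=dict)
    exclusions_path: str | None = None
    universe: int = 20_462
    alpha: float = 0.7
    tol: float = 1e-6
    max_iter: int = 10_000
    sample_quantile: float = 0.20
    sample_fraction: float = 0.20
    normalize_by_length: bool = False
    log2_transform: bool = False
    top_n: int = 100
    output_dir: str = "results"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha {self.alpha} outside [0, 1]")
        if not 0 < self.sample_quantile < 1:
            raise ValueError("sample_quantile must be in (0, 1)")
        if not 0 < self.sample_fraction <= 1:
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        for label, path in self._input_paths().items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"{label} path does not exist: {path}")

    def _input_paths(self) -> dict[str, str]:
        paths = {
            "network": self.network_path,
            "expression": self.expression_path,
            "mutations": self.mutations_path,
        }
        if self.metadata_path:
            paths["metadata"] = self.metadata_path
        if self.exclusions_path:
            paths["exclusions"] = self.exclusions_path
        for name, p in self.geneset_paths.items():
            paths[f"geneset_{name}"] = p
        return paths

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _checksum(path: str) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_study(config: RunConfig) -> dict:
    """Execute all stages and write the result bundle to disk.

    Stage failures abort with the stage name and the underlying cause.
    Returns a summary dict (also written as manifest.yaml) with per-stage
    record counts for dropped-gene accounting.
    """
    config.validate()
    os.makedirs(config.output_dir, exist_ok=True)
    log: dict = {"stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # annotate with the failing stage
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return wrap

    network = stage("netio")(lambda: netio.read_edge_tsv(config.network_path, header=True))
    log["stages"]["netio"] = {
        "nodes": network.n_nodes,
        "edges": network.n_edges,
        "self_loops_dropped": network.n_self_loops_dropped,
        "duplicates_dropped": network.n_duplicates_dropped,
    }

    metadata = None
    if config.metadata_path:
        metadata = stage("metadata")(lambda: netio.read_metadata_tsv(config.metadata_path))

    matrix = stage("expression")(lambda: coexpr.read_expression_tsv(config.expression_path))
    filtered, expressed = stage("filter")(
        lambda: coexpr.filter_expression(matrix, config.sample_quantile, config.sample_fraction)
    )
    log["stages"]["filter"] = {
        "genes_in": int(matrix.shape[0]),
        "genes_expressed": len(expressed),
        "samples": int(matrix.shape[1]),
    }
    cepin = stage("cepin")(
        lambda: coexpr.build_cepin(
            network, filtered, transform="log2" if config.log2_transform else "none"
        )
    )
    log["stages"]["cepin"] = {
        "edges": cepin.n_edges,
        "undefined_pcc_dropped": cepin.n_undefined_dropped,
    }

    mutations = stage("mutations")(lambda: propagate.read_mutations_tsv(config.mutations_path))
    n_excluded = 0
    if config.exclusions_path:
        excluded = setstats.read_sample_list(config.exclusions_path)
        mutations, n_excluded = setstats.exclude_samples(mutations, excluded)
    m0 = stage("m0")(
        lambda: propagate.build_m0(
            mutations,
            network,
            normalize_by_length=config.normalize_by_length,
            metadata=metadata,
        )
    )
    log["stages"]["m0"] = {
        "records_used": m0.n_records_used,
        "non_nonsynonymous_dropped": m0.n_records_nonsyn_dropped,
        "genes_dropped": m0.n_genes_dropped,
        "samples_excluded": n_excluded,
    }
    prop = stage("propagate")(
        lambda: propagate.propagate(
            network,
            m0,
            propagate.PropagationConfig(alpha=config.alpha, tol=config.tol, max_iter=config.max_iter),
        )
    )
    log["stages"]["propagate"] = {"iterations": prop.iterations, "residual": prop.residual}

    table = stage("gravity")(lambda: gravity.pairwise_gravity(cepin, prop))
    scores = stage("aveg")(
        lambda: gravity.aveg_scores(table, metadata=metadata, degrees=network.degrees)
    )

    catalog = None
    results: list[setstats.TestResult] = []
    if config.geneset_paths:
        catalog = setstats.load_catalog(config.geneset_paths, universe=config.universe)
        results = stage("setstats")(lambda: run_set_statistics(table, scores, catalog, config.top_n))

    out = lambda name: os.path.join(config.output_dir, name)
    coexpr.write_cepin_tsv(cepin, out("cepin.tsv"))
    propagate.write_propagated_tsv(m0, prop, out("propagated.tsv"))
    gravity.write_gravity_tsv(table, out("gravity.tsv"))
    gravity.write_scores_tsv(scores, out("gene_scores.tsv"))
    if results:
        setstats.write_results_tsv(results, out("set_tests.tsv"))

    manifest = {
        "parameters": asdict(config),
        "inputs": {label: _checksum(path) for label, path in config._input_paths().items()},
        "log": log,
    }
    with open(out("manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def run_set_statistics(
    gravity_table: pd.DataFrame,
    scores: pd.DataFrame,
    catalog: setstats.GeneSetCatalog,
    top_n: int = 100,
) -> list[setstats.TestResult]:
    """The standard per-catalog comparison battery, one BH family per
    comparison kind (set-pair G contrast, top-n enrichment, X-vs-autosome)."""
    from . import gravity as gravity_mod

    pair_tests = []
    for name in catalog.names():
        set_pairs, non_set_pairs = gravity_mod.classify_pairs(gravity_table, catalog[name])
        if len(set_pairs) < 2 or len(non_set_pairs) < 2:
            continue
        pair_tests.append(
            setstats.wilcoxon_rank_sum(
                set_pairs["g_score"], non_set_pairs["g_score"], name=f"set_pairs_{name}"
            )
        )
    results = setstats.adjust_family(pair_tests, family="set_pairs")

    top_tests = [
        setstats.topn_enrichment(scores, catalog[name], n=min(top_n, len(scores)), name=f"top{top_n}_{name}")
        for name in catalog.names()
    ]
    results += setstats.adjust_family(top_tests, family=f"top{top_n}_enrichment")

    if "chromosome" in scores.columns:
        x_tests = []
        for name in catalog.names():
            try:
                x_tests.append(
                    setstats.x_vs_autosomes(scores, catalog[name], name=f"x_vs_autosomes_{name}")
                )
            except ValueError:
                continue
        results += setstats.adjust_family(x_tests, family="x_vs_autosomes")
    return results
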