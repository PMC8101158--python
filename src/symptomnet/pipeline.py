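"""End-to-end pipeline orchestration with reproducible per-stage seeding."""
from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from ._utils import child_seed
from .ggm import GGMConfig, estimate_network
from .io import (read_cohort, write_centrality, write_cohort, write_communities,
                 write_network, write_stability, write_true_network)
from .netanalysis import (bootstrap_communities, centrality_stability, centrality_table,
                          edge_accuracy_bootstrap, severity_centrality_correlation,
                          walktrap_communities)
from .nct import centrality_difference_test, nct_test
from .prognosis import ENRConfig, prognosis_analysis
from .preprocess import reduce_cohort, screen_items
from .synthetic import (CohortSpec, default_cohort, default_network, generate_cohort)

log = logging.getLogger("symptomnet")


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; loadable from YAML or JSON."""

    output_dir: str = "results/pipeline"
    cohort_csv: str | None = None       # if None, a synthetic cohort is simulated
    cohort_sidecar: str | None = None
    seed: int = 0
    # stage toggles
    simulate: bool = True
    preprocess: bool = True
    network: bool = True
    centrality: bool = True
    nct: bool = False
    prognosis: bool = True
    # scale knobs
    n_subjects: int = 2000
    n_nodes: int = 20
    bootstrap_B: int = 100
    nct_iterations: int = 1000
    shapley_reps: int = 500
    ggm: dict = field(default_factory=dict)
    enr: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> preprocess -> network -> centrality -> [nct] ->
    prognosis, writing every artifact plus a provenance manifest.

    Stage failures halt the run; partial outputs and the manifest (with the
    failure recorded) are persisted.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    results: dict = {"manifest": manifest}

    def _finish(stage: str, error: Exception | None = None):
        manifest["stages"][stage] = "failed" if error else "ok"
        if error is not None:
            manifest["error"] = f"{stage}: {error}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    ggm_cfg = GGMConfig(**config.ggm)
    try:
        if config.cohort_csv is not None:
            cohort = read_cohort(config.cohort_csv, config.cohort_sidecar)
            net_spec = None
        elif config.simulate:
            net_spec = default_network(n_nodes=config.n_nodes)
            cohort_spec = default_cohort(
                n_subjects=config.n_subjects, n_nodes=config.n_nodes,
                seed=child_seed(config.seed, "simulate"))
            cohort = generate_cohort(net_spec, cohort_spec)
            write_cohort(cohort, out / "cohort.csv", out / "cohort.json")
            write_true_network(net_spec, out / "true_network.tsv", out / "true_labels.json")
        else:
            raise ValueError("no cohort: provide cohort_csv or enable simulate")
        results["cohort"] = cohort
        _finish("input")
    except Exception as exc:  # noqa: BLE001
        _finish("input", exc)
        raise

    if config.preprocess:
        try:
            screen = screen_items(cohort)
            (out / "screen_report.json").write_text(json.dumps({
                "flagged": screen.flagged,
                "skewness": screen.skewness.tolist(),
            }, indent=2))
            cohort, overlap = reduce_cohort(cohort)
            (out / "overlap_report.json").write_text(json.dumps({
                "pairs": [list(p) for p in overlap.pairs],
                "decisions": {f"{i},{j}": d for (i, j), d in overlap.decisions.items()},
                "fraction_different": {f"{i},{j}": v
                                       for (i, j), v in overlap.fraction_different.items()},
            }, indent=2))
            write_cohort(cohort, out / "cohort_reduced.csv", out / "cohort_reduced.json")
            results["screen"] = screen
            results["overlap"] = overlap
            _finish("preprocess")
        except Exception as exc:  # noqa: BLE001
            _finish("preprocess", exc)
            raise

    net = None
    if config.network:
        try:
            net = estimate_network(cohort, ggm_cfg, correct_covariates=True)
            write_network(net, out / "network.tsv", out / "network_provenance.json",
                          {"seed": config.seed, "config_hash": config.config_hash()})
            results["network"] = net
            _finish("network")
        except Exception as exc:  # noqa: BLE001
            _finish("network", exc)
            raise

    if config.centrality and net is not None:
        try:
            partition = bootstrap_communities(
                cohort, ggm_cfg, B=config.bootstrap_B,
                seed=child_seed(config.seed, "communities"))
            table = centrality_table(net, partition.assignment)
            write_communities(partition, net.nodes, out / "communities.tsv",
                              out / "communities_summary.json")
            write_centrality(table, out / "centrality.csv")
            stab = edge_accuracy_bootstrap(
                cohort, ggm_cfg, B=max(config.bootstrap_B, 2),
                seed=child_seed(config.seed, "edges"))
            cs = centrality_stability(
                cohort, ggm_cfg, B=max(config.bootstrap_B // 2, 10),
                seed=child_seed(config.seed, "cs"))
            stab.drop_proportions = cs.drop_proportions
            stab.correlation_quantiles = cs.correlation_quantiles
            stab.cs_coefficient = cs.cs_coefficient
            write_stability(stab, out / "stability.json")
            sev = severity_centrality_correlation(cohort, table)
            (out / "severity_centrality.json").write_text(
                json.dumps(sev, indent=2, default=float))
            results.update(partition=partition, centrality=table, stability=stab)
            _finish("centrality")
        except Exception as exc:  # noqa: BLE001
            _finish("centrality", exc)
            raise

    if config.nct:
        try:
            if cohort.group is None:
                raise ValueError("nct stage requires group labels")
            groups = np.unique(cohort.group)
            if len(groups) != 2:
                raise ValueError(f"nct stage needs exactly 2 groups, got {len(groups)}")
            g1 = cohort.subset(np.flatnonzero(cohort.group == groups[0]))
            g2 = cohort.subset(np.flatnonzero(cohort.group == groups[1]))
            res = nct_test(g1, g2, ggm_cfg, iterations=config.nct_iterations,
                           seed=child_seed(config.seed, "nct"))
            cdt = centrality_difference_test(
                g1, g2, "EI", ggm_cfg, iterations=config.nct_iterations,
                seed=child_seed(config.seed, "nct-centrality"))
            (out / "nct.json").write_text(json.dumps({
                "groups": [str(g) for g in groups],
                "global_strength": [res.strength1, res.strength2],
                "p_strength": res.p_strength,
                "p_structure": res.p_structure,
                "posthoc_warranted": res.posthoc_warranted,
                "iterations": res.iterations,
                "centrality_pvals_holm": cdt["pvals_holm"].tolist(),
            }, indent=2, default=float))
            results["nct"] = res
            _finish("nct")
        except Exception as exc:  # noqa: BLE001
            _finish("nct", exc)
            raise
    elif cohort.group is None:
        log.info("no group labels: NCT stage skipped")

    if config.prognosis:
        try:
            enr_cfg = ENRConfig(seed=child_seed(config.seed, "prognosis"), **config.enr)
            report = prognosis_analysis(cohort, enr_cfg, mc_reps=config.shapley_reps)
            from .prognosis import compare_models
            comp = compare_models(report)
            (out / "prognosis.json").write_text(json.dumps({
                "alpha": report.item_model.alpha,
                "lambda": report.item_model.lam,
                "comparison": comp,
                "shapley_mc_reps": report.shapley_mc_reps,
            }, indent=2, default=float))
            import pandas as pd
            pd.DataFrame({
                "feature": report.item_model.feature_names,
                "coef": report.item_model.coef,
                "shapley_mean_abs": report.shapley_mean_abs,
                "shapley_mean_signed": report.shapley_mean_signed,
            }).to_csv(out / "prognosis_importance.csv", index=False)
            results["prognosis"] = report
            _finish("prognosis")
        except Exception as exc:  # noqa: BLE001
            _finish("prognosis", exc)
            raise

    return results
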