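"""Reading and writing cohorts and analysis artifacts (CSV/TSV/JSON)."""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ggm import GGMNetwork
from .netanalysis import CentralityTable, CommunityPartition, StabilityReport
from .synthetic import NetworkSpec, SymptomCohort, planted_weights


def write_cohort(cohort: SymptomCohort, csv_path: str | Path,
                 sidecar_path: str | Path | None = None) -> None:
    """One row per subject: items, duration covariates, outcome, optional
    group/study labels; a JSON sidecar records item ranges."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(cohort.items, columns=cohort.item_names)
    for k, name in enumerate(cohort.covariate_names):
        df[name] = cohort.covariates[:, k]
    df["outcome"] = cohort.outcome
    if cohort.group is not None:
        df["group"] = cohort.group
    if cohort.study is not None:
        df["study"] = cohort.study
    df.to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    meta = {
        "item_names": cohort.item_names,
        "item_ranges": [list(r) for r in cohort.item_ranges],
        "covariate_names": cohort.covariate_names,
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=2))


def read_cohort(csv_path: str | Path, sidecar_path: str | Path | None = None
                ) -> SymptomCohort:
    """Read and validate a cohort CSV + JSON sidecar.

    Missing cells and ordinal values outside the declared range are rejected
    with row/column coordinates.
    """
    csv_path = Path(csv_path)
    if sidecar_path is None:
        sidecar_path = csv_path.with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text())
    df = pd.read_csv(csv_path)
    item_names = meta["item_names"]
    cov_names = meta.get("covariate_names", [])
    numeric_cols = item_names + cov_names + ["outcome"]
    for col in numeric_cols:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
        na = df[col].isna()
        if na.any():
            row = int(np.flatnonzero(na.values)[0])
            raise ValueError(f"missing value at row {row}, column '{col}'")
    ranges = [tuple(r) for r in meta["item_ranges"]]
    items = df[item_names].to_numpy(dtype=float)
    for k, (lo, hi) in enumerate(ranges):
        bad = (items[:, k] < lo) | (items[:, k] > hi)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"value {items[row, k]} at row {row}, column '{item_names[k]}' "
                f"outside declared range [{lo},{hi}]"
            )
    cov = df[cov_names].to_numpy(dtype=float) if cov_names else np.zeros((len(df), 0))
    cohort = SymptomCohort(
        items=items,
        item_names=list(item_names),
        item_ranges=ranges,
        covariates=cov,
        outcome=df["outcome"].to_numpy(dtype=float),
        group=df["group"].to_numpy() if "group" in df.columns else None,
        study=df["study"].to_numpy() if "study" in df.columns else None,
        covariate_names=list(cov_names),
    )
    cohort.validate()
    return cohort


def write_network(net: GGMNetwork, tsv_path: str | Path,
                  provenance_path: str | Path | None = None,
                  provenance: dict | None = None) -> None:
    """Edge-list TSV (node_i, node_j, partial_correlation) + JSON provenance."""
    rows = net.edge_list()
    pd.DataFrame(rows, columns=["node_i", "node_j", "partial_correlation"]).to_csv(
        tsv_path, sep="\t", index=False)
    if provenance_path is not None:
        block = {
            "estimator": net.estimator,
            "gamma": net.gamma,
            "n": net.n,
            "nodes": net.nodes,
            "covariates_corrected": net.covariates_corrected,
            "ebic": net.ebic,
        }
        block.update(provenance or {})
        Path(provenance_path).write_text(json.dumps(block, indent=2, default=float))


def read_network(tsv_path: str | Path, nodes: list[str] | None = None) -> GGMNetwork:
    df = pd.read_csv(tsv_path, sep="\t")
    if nodes is None:
        nodes = sorted(set(df["node_i"]) | set(df["node_j"]))
    idx = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for _, r in df.iterrows():
        i, j = idx[r["node_i"]], idx[r["node_j"]]
        W[i, j] = W[j, i] = r["partial_correlation"]
    return GGMNetwork(nodes=list(nodes), weights=W, n=0, estimator="from-file", gamma=np.nan)


def write_true_network(spec: NetworkSpec, tsv_path: str | Path,
                       labels_path: str | Path | None = None) -> None:
    """Ground-truth edge list + community labels for a synthetic network."""
    P = planted_weights(spec)
    rows = []
    p = spec.n_nodes
    for i in range(p):
        for j in range(i + 1, p):
            if P[i, j] != 0:
                rows.append((f"item{i:02d}", f"item{j:02d}", float(P[i, j])))
    pd.DataFrame(rows, columns=["node_i", "node_j", "weight"]).to_csv(
        tsv_path, sep="\t", index=False)
    if labels_path is not None:
        Path(labels_path).write_text(json.dumps({
            "community_labels": spec.community_labels.tolist(),
        }, indent=2))


def write_centrality(table: CentralityTable, csv_path: str | Path) -> None:
    df = pd.DataFrame({
        "node": table.nodes,
        "ei": table.ei, "bridge_ei": table.bridge_ei,
        "pc": table.pc, "pr": table.pr, "pcpr": table.pcpr,
    })
    for name, z in table.z.items():
        df[f"z_{name}"] = z
    df.to_csv(csv_path, index=False)


def write_communities(partition: CommunityPartition, nodes: list[str],
                      tsv_path: str | Path, summary_path: str | Path | None = None) -> None:
    df = pd.DataFrame({"node": nodes, "community": partition.assignment})
    if partition.item_stability is not None:
        df["stability"] = partition.item_stability
    df.to_csv(tsv_path, sep="\t", index=False)
    if summary_path is not None:
        Path(summary_path).write_text(json.dumps({
            "n_communities": int(partition.n_communities),
            "count_median": partition.count_median,
            "count_sd": partition.count_sd,
            "count_ci": list(partition.count_ci) if partition.count_ci else None,
            "n_failed": partition.n_failed,
        }, indent=2, default=float))


def write_stability(report: StabilityReport, json_path: str | Path) -> None:
    Path(json_path).write_text(json.dumps({
        "n_boot": report.n_boot,
        "edge_estimates": report.edge_estimates.tolist(),
        "edge_ci_lower": report.edge_ci_lower.tolist(),
        "edge_ci_upper": report.edge_ci_upper.tolist(),
        "drop_proportions": None if report.drop_proportions is None
        else report.drop_proportions.tolist(),
        "correlation_quantiles": None if report.correlation_quantiles is None
        else report.correlation_quantiles.tolist(),
        "cs_coefficient": report.cs_coefficient,
    }, indent=2, default=float))
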