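"""Predicted-vs-measured comparison, network export and the pipeline driver.

The comparison pairs each directional predicted interaction strength with
the measured one for the same (recipient, influencer) pair and reports the
Pearson correlation, by default over the significant measured interactions
only.  Interaction matrices export as directed graphs (influencer ->
recipient, edge weight = mean interaction strength) in GraphML and SIF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .crossfeed import classify_crossfeeding, filter_background, call_production
from .depletion import gated_fold_changes, utilization_profiles
from .growth import MISMatrix, fit_growth_table, mis_matrix
from .interaction import PISMatrix, competitive_rank, predicted_interactions
from .io import write_matrix
from .metrics import metrics_table
from .simulate import (
    NoiseModel,
    generate_truth,
    simulate_monocultures,
    simulate_sequential,
)


@dataclass
class ComparisonResult:
    r: float
    pvalue: float
    n_pairs: int
    pairs: pd.DataFrame  # recipient, influencer, predicted, measured, significant
    per_recipient: pd.DataFrame
    n_undefined_excluded: int


def correlate_predicted_measured(
    pis: PISMatrix, mis: MISMatrix, significant_only: bool = True
) -> ComparisonResult:
    """Pearson correlation of predicted vs. measured interaction strengths.

    Pairs are matched exactly by (recipient, influencer); recipients with an
    undefined predicted row are excluded and counted.
    """
    rows = []
    n_undefined = 0
    shared_rec = [r for r in mis.values.index if r in pis.values.index]
    shared_inf = [i for i in mis.values.columns if i in pis.values.columns]
    for r in shared_rec:
        if r in pis.undefined_recipients:
            n_undefined += mis.values.loc[r, shared_inf].notna().sum()
            continue
        for i in shared_inf:
            if r == i:
                continue
            pred = pis.values.loc[r, i]
            meas = mis.values.loc[r, i]
            if pd.isna(pred) or pd.isna(meas):
                continue
            rows.append(
                {
                    "recipient": r, "influencer": i,
                    "predicted": float(pred), "measured": float(meas),
                    "significant": bool(mis.significant.loc[r, i]),
                }
            )
    pairs = pd.DataFrame(rows)
    if significant_only and not pairs.empty:
        pairs = pairs[pairs["significant"]].reset_index(drop=True)
    if len(pairs) < 3:
        raise ValueError("fewer than 3 paired interaction strengths")
    if pairs["measured"].nunique() == 1 or pairs["predicted"].nunique() == 1:
        raise ValueError("zero-variance vector; correlation undefined")
    res = stats.pearsonr(pairs["predicted"], pairs["measured"])

    per_rec = []
    for r, grp in pairs.groupby("recipient"):
        if len(grp) >= 3 and grp["measured"].nunique() > 1 and grp["predicted"].nunique() > 1:
            rr = stats.pearsonr(grp["predicted"], grp["measured"])
            per_rec.append({"recipient": r, "r": rr.statistic,
                            "pvalue": rr.pvalue, "n": len(grp)})
    per_recipient = pd.DataFrame(per_rec)
    return ComparisonResult(
        float(res.statistic), float(res.pvalue), len(pairs), pairs,
        per_recipient, int(n_undefined),
    )


def interaction_graph(mis: MISMatrix) -> nx.DiGraph:
    """Directed graph: influencer -> recipient, weight = interaction strength."""
    if mis.values.notna().sum().sum() == 0:
        raise ValueError("empty interaction matrix")
    g = nx.DiGraph()
    for iso in sorted(set(mis.values.index) | set(mis.values.columns)):
        g.add_node(iso)
    for r in mis.values.index:
        for i in mis.values.columns:
            v = mis.values.loc[r, i]
            if pd.isna(v):
                continue
            g.add_edge(
                i, r,
                weight=float(v),
                significant=bool(mis.significant.loc[r, i]),
            )
    return g


def export_network(mis: MISMatrix, path: str | Path, fmt: str = "graphml") -> None:
    """Write the interaction network as GraphML or SIF (Cytoscape dialects)."""
    g = interaction_graph(mis)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path, named_key_ids=True, edge_id_from_attribute=None)
    elif fmt == "sif":
        lines = [
            f"{u}\tinfluences\t{v}" for u, v in sorted(g.edges())
        ]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def pis_heatmap(pis: PISMatrix, path: str | Path) -> None:
    """Clustered heatmap of predicted interaction strengths (presentation)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .interaction import cluster_order

    order = cluster_order(pis)
    M = pis.values.loc[order, order]
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M.to_numpy(), cmap="Blues_r", vmin=-1, vmax=0)
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(order)), order, fontsize=7)
    ax.set_xlabel("influencer")
    ax.set_ylabel("recipient")
    fig.colorbar(im, label="predicted interaction strength")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(
    outdir: str | Path,
    seed: int = 42,
    n_isolates: int = 8,
    n_metabolites: int = 60,
    cv: float = 0.1,
    n_secreted_per_isolate: int = 6,
    alpha: float = 0.05,
    figures: bool = False,
) -> dict:
    """Run every stage on a seeded synthetic experiment and write a bundle.

    Stages: simulate -> gated fold changes -> profiles -> metrics ->
    predicted interactions and ranks -> growth fits and measured
    interactions -> untargeted filtering, production and cross-feeding ->
    predicted-vs-measured comparison -> network export.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    def stage(name: str):
        log.append(name)

    stage("simulate")
    truth = generate_truth(
        n_isolates=n_isolates, n_metabolites=n_metabolites, seed=seed,
        n_secreted_per_isolate=n_secreted_per_isolate,
    )
    noise = NoiseModel(cv=cv, seed=seed)
    mono = simulate_monocultures(truth, noise)
    seq = simulate_sequential(mono, noise)

    stage("foldchange")
    fcm = gated_fold_changes(mono.targeted_table(), mono.metadata, alpha=alpha)
    write_matrix(fcm.fc, outdir / "fold_changes.csv")
    write_matrix(fcm.pvalues, outdir / "fold_change_pvalues.csv")

    stage("profiles")
    profiles = utilization_profiles(fcm)
    write_matrix(profiles, outdir / "utilization_profiles.csv")

    stage("metrics")
    mtab = metrics_table(profiles)
    write_matrix(mtab, outdir / "substrate_metrics.csv")

    stage("predict")
    pis = predicted_interactions(profiles)
    write_matrix(pis.values, outdir / "pis_matrix.csv")
    ranks = competitive_rank(pis)
    write_matrix(ranks, outdir / "competitive_ranks.csv")

    stage("growth")
    params = fit_growth_table(mono.growth)
    params.to_csv(outdir / "growth_params.csv", index=False, lineterminator="\n")
    mis_od = mis_matrix(seq.growth, alpha=alpha, metric="final_od")
    write_matrix(mis_od.values, outdir / "mis_final_od.csv")
    write_matrix(mis_od.pvalues, outdir / "mis_final_od_pvalues.csv")
    mis_resp = mis_matrix(seq.growth, alpha=alpha, metric="cumulative_respiration")
    write_matrix(mis_resp.values, outdir / "mis_respiration.csv")
    write_matrix(mis_resp.pvalues, outdir / "mis_respiration_pvalues.csv")

    stage("crossfeed")
    retained = filter_background(seq.peaks, seq.metadata, alpha=alpha)
    produced = call_production(mono.peaks, mono.metadata, alpha=alpha,
                               retained=[f for f in retained
                                         if f in mono.peaks.analyte_ids])
    produced.drop(columns="produced").to_csv(
        outdir / "production_calls.csv", lineterminator="\n"
    )
    xf = classify_crossfeeding(seq.peaks, seq.metadata, alpha=alpha,
                               retained=retained)
    xf.calls.to_csv(outdir / "crossfeed_calls.csv", index=False, lineterminator="\n")
    xf.summary.to_csv(outdir / "crossfeed_summary.csv", lineterminator="\n")

    stage("report")
    comparison = {}
    for name, mism in (("final_od", mis_od), ("respiration", mis_resp)):
        cmp_res = correlate_predicted_measured(pis, mism, significant_only=True)
        cmp_res.pairs.to_csv(
            outdir / f"comparison_pairs_{name}.csv", index=False, lineterminator="\n"
        )
        comparison[name] = {"r": cmp_res.r, "pvalue": cmp_res.pvalue,
                            "n_pairs": cmp_res.n_pairs}
    export_network(mis_od, outdir / "mis_network.graphml", fmt="graphml")
    export_network(mis_od, outdir / "mis_network.sif", fmt="sif")
    if figures:
        pis_heatmap(pis, outdir / "pis_heatmap.png")

    provenance = {
        "version": __version__,
        "seed": seed,
        "alpha": alpha,
        "n_isolates": n_isolates,
        "n_metabolites": n_metabolites,
        "cv": cv,
        "n_secreted_per_isolate": n_secreted_per_isolate,
        "stages": log,
        "comparison": comparison,
        "n_retained_features": len(retained),
    }
    (outdir / "run.json").write_text(json.dumps(provenance, indent=2) + "\n")
    return provenance
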