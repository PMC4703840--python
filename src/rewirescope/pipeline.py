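"""End-to-end orchestration: simulate -> DE -> scores -> structure -> inference -> evaluation.

``run_pipeline`` executes every stage on a simulated rewiring study, logging
parameters and seeds, and writes machine-readable TSV/JSON summaries plus a
short human-readable report. Stage sizes are configurable; the default
configuration runs the full study design for simulation, DE and structure
stages, and a reduced gene panel for network inference (the NRR sweep over
all regulator x gene pairs at full transcriptome scale is a cluster-sized
computation, not a laptop one).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, io, netinfer, scores, simulate, structure
from .datatypes import GeneSet
from .evaluate import enrichment_of_sets

__all__ = ["default_config", "run_pipeline", "load_config"]

log = logging.getLogger("rewirescope")

STAGES = ("simulate", "de", "scores", "structure", "infer", "evaluate")


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "simulate": {"n_genes": 3891, "n_constructs": 85},
        "de": {"shrink": True, "fdr": 0.05, "fold_change": 1.2},
        "scores": {"top_k": 10},
        "structure": {
            "isa_seeds": 100,
            "cluster_max_genes": 400,
            "pca_axis": "constructs",
        },
        "infer": {
            "n_genes": 36,
            "n_regulators": 6,
            "n_samples": 200,
            "q_set": [1, 3, 5],
            "n_subsets": 50,
            "alpha": 0.05,
            "precision": 30.0,
        },
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config(int(user.get("seed", 0)))
    for key, val in user.items():
        if isinstance(val, dict) and key in cfg:
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _stage(name):
    log.info("stage %s: starting", name)
    return time.monotonic()


def _done(name, t0):
    log.info("stage %s: done in %.1fs", name, time.monotonic() - t0)


def run_pipeline(config: dict, out_dir, force: bool = False) -> dict:
    """Run all stages, write outputs under ``out_dir``, return the summary dict.

    Deterministic given ``config['seed']``: re-running with the same config
    reproduces identical tables. Refuses to overwrite an existing summary
    unless ``force``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary_path = out / "summary.json"
    if summary_path.exists() and not force:
        raise FileExistsError(f"{summary_path} exists; pass force=True to overwrite")
    seed = int(config.get("seed", 0))
    summary: dict = {"seed": seed, "stages": {}}

    # -- simulate -----------------------------------------------------------
    t0 = _stage("simulate")
    sim_cfg = config["simulate"]
    network, designs, params, truth_info = simulate.default_study(
        seed=seed, n_genes=sim_cfg["n_genes"], n_constructs=sim_cfg["n_constructs"]
    )
    matrix, true_fc, true_deg = simulate.simulate_rewired_experiment(network, designs, params)
    io.write_expression(matrix, out / "replicates")
    io.write_design(designs, out / "design.tsv")
    io.write_network(network, out / "network.tsv")
    summary["stages"]["simulate"] = {
        "genes": int(true_fc.shape[0]),
        "constructs": int(true_fc.shape[1]),
        "network_edges": len(network),
        "regulators": len(network.regulators),
        "true_deg_total": int(true_deg.to_numpy().sum()),
    }
    _done("simulate", t0)

    # -- differential expression -------------------------------------------
    t0 = _stage("de")
    de_cfg = config["de"]
    if not matrix.control_columns():
        raise RuntimeError("de stage: matrix has no control samples")
    fc_cols, sizes = {}, {}
    for c in matrix.constructs():
        res = diffexpr.de_analysis(
            matrix, c, shrink=de_cfg["shrink"], fdr=de_cfg["fdr"], fold_change=de_cfg["fold_change"]
        )
        fc_cols[c] = res.table["log2fc"]
        sizes[c] = res.perturbation_size
    fc = pd.DataFrame(fc_cols)
    sizes = pd.Series(sizes, name="perturbation_size")
    io.write_matrix(fc, out / "log2fc.tsv")
    sizes.to_frame().to_csv(out / "perturbation_sizes.tsv", sep="\t", index_label="construct")
    orf_constructs = [d for d in designs if d.orf is not None]
    r_deg, _, p_deg = diffexpr.association_with_design(
        [sizes[d.construct] for d in orf_constructs],
        [d.orf_out_degree for d in orf_constructs],
    )
    summary["stages"]["de"] = {
        "max_perturbation": int(sizes.max()),
        "median_perturbation": float(sizes.median()),
        "out_degree_association_R": round(r_deg, 4),
        "out_degree_association_p": float(p_deg),
    }
    _done("de", t0)

    # -- state scores -------------------------------------------------------
    t0 = _stage("scores")
    ribo = truth_info["ribosomal"]
    geneset = GeneSet("ribosomal", members=ribo.members, excluded=ribo.drivers)
    score = scores.geneset_score(fc, geneset)
    candidates = set(fc.index) - set(ribo.members)
    ranking = scores.rank_regulators(fc, score, candidates=candidates)
    ranking.head(50).to_csv(out / "ribosomal_regulators.tsv", sep="\t")
    score.to_frame().to_csv(out / "ribosomal_score.tsv", sep="\t", index_label="construct")
    drivers = list(truth_info["ribosomal_drivers"])
    r2 = scores.variance_explained(score, fc.loc[drivers].T)
    summary["stages"]["scores"] = {
        "top_regulator": str(ranking.index[0]),
        "top_regulator_R": round(float(ranking["R"].iloc[0]), 4),
        "driver_best_rank": int(ranking.loc[drivers, "rank"].min()),
        "driver_worst_rank": int(ranking.loc[drivers, "rank"].max()),
        "drivers_variance_explained": round(float(r2), 4),
    }
    _done("scores", t0)

    # -- structure ----------------------------------------------------------
    t0 = _stage("structure")
    st_cfg = config["structure"]
    retained = structure.display_filter(fc, true_deg.reindex(columns=fc.columns))
    # cluster a variance-capped gene subset; full-matrix UPGMA is quadratic
    sub = fc.loc[retained]
    if len(sub) > st_cfg["cluster_max_genes"]:
        top = sub.var(axis=1).nlargest(st_cfg["cluster_max_genes"]).index
        sub = sub.loc[top]
    sub = sub.loc[(sub != 0).any(axis=1)]
    dend = structure.upgma(structure.uncentred_distance_matrix(sub.to_numpy()), labels=list(sub.index))
    (out / "genes_dendrogram.nwk").write_text(dend.to_newick() + "\n")
    pre = structure.isa_gene_prefilter(fc)
    bics = structure.isa_biclusters(pre, n_seeds=st_cfg["isa_seeds"], seed=seed)
    with open(out / "biclusters.tsv", "w") as fh:
        fh.write("bicluster\tn_genes\tn_constructs\tgenes\tconstructs\n")
        for k, b in enumerate(bics):
            fh.write(
                f"bc{k:02d}\t{len(b.genes)}\t{len(b.constructs)}\t"
                f"{','.join(map(str, b.genes))}\t{','.join(map(str, b.constructs))}\n"
            )
    pca = structure.pca_kaiser(fc, variables_axis=st_cfg["pca_axis"])
    pd.DataFrame({"eigenvalue": pca.eigenvalues}).to_csv(
        out / "pca_eigenvalues.tsv", sep="\t", index_label="component"
    )
    summary["stages"]["structure"] = {
        "display_filter_genes": int(len(retained)),
        "biclusters": len(bics),
        "pca_retained": pca.retained,
        "pca_cumulative_variance": round(pca.cumulative_variance, 4),
    }
    _done("structure", t0)

    # -- network inference --------------------------------------------------
    t0 = _stage("infer")
    inf_cfg = config["infer"]
    from .datatypes import GgmSpec

    rng = np.random.default_rng(seed + 7)
    p, n_reg = inf_cfg["n_genes"], inf_cfg["n_regulators"]
    gold = simulate.simulate_gold_network(
        p, n_reg, exponent=1.5, max_degree=max(3, p // 5), seed=seed + 11,
        genes=[f"y{i:03d}" for i in range(p)],
    )
    gnames = [f"y{i:03d}" for i in range(p)]
    gidx = {g: i for i, g in enumerate(gnames)}
    spec = GgmSpec(
        p=p,
        edges=tuple((gidx[r], gidx[t]) for r, t, _, _ in gold.edges),
        magnitude=0.35,
        n=inf_cfg["n_samples"],
    )
    samples = simulate.simulate_ggm(spec, seed=seed + 13)
    reg_idx = sorted(gidx[r] for r in gold.regulators)
    pairs = [(i, j) for i in reg_idx for j in range(p) if j != i]
    nrr = netinfer.average_nrr(
        samples,
        pairs,
        q_set=inf_cfg["q_set"],
        n_subsets=inf_cfg["n_subsets"],
        alpha=inf_cfg["alpha"],
        seed=seed + 17,
        variables=gnames,
    )
    nrr.table.to_csv(out / "nrr_table.tsv", sep="\t")
    curve = netinfer.precision_recall(nrr, gold)
    curve.points.to_csv(out / "pr_curve.tsv", sep="\t", index=False)
    try:
        net = netinfer.network_at_precision(curve, nrr, inf_cfg["precision"])
        with open(out / "inferred_network.sif", "w") as fh:
            for r, t in net.edges:
                fh.write(f"{r}\tassoc\t{t}\n")
        net_summary = {
            "nodes": len(net.nodes),
            "edges": len(net.edges),
            "modules": net.n_modules,
        }
    except ValueError:
        net = None
        net_summary = {"nodes": 0, "edges": 0, "modules": 0, "note": "precision not reached"}
    summary["stages"]["infer"] = {
        "gold_edges": len(gold),
        "final_recall": round(float(curve.points["recall"].iloc[-1]), 2),
        **net_summary,
    }
    _done("infer", t0)

    # -- evaluation ---------------------------------------------------------
    t0 = _stage("evaluate")
    if net is not None and net.edges:
        # enrichment of the top regulator's predicted targets in its true ones
        top_reg = net.edges[0][0]
        predicted = {t for r, t in net.edges if r == top_reg}
        reported = {t for t, _, _ in gold.targets_of(top_reg)}
        enr = enrichment_of_sets(gnames, reported, predicted)
        eval_summary = {
            "enrichment_regulator": str(top_reg),
            "enrichment_overlap": enr.overlap,
            "enrichment_p": float(enr.p),
        }
    else:
        eval_summary = {"note": "no inferred network to evaluate"}
    summary["stages"]["evaluate"] = eval_summary
    _done("evaluate", t0)

    assert set(summary["stages"]) == set(STAGES)
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    _write_report(out / "report.md", summary)
    return summary


def _write_report(path: Path, summary: dict) -> None:
    lines = ["# rewirescope pipeline report", "", f"Seed: {summary['seed']}", ""]
    for stage in STAGES:
        lines.append(f"## {stage}")
        for k, v in summary["stages"][stage].items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
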