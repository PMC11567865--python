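"""End-to-end pipeline orchestration and reporting.

``run_pipeline`` sequences the stages — simulate (or load), preprocess,
estimate the joint multilayer network and the synaptic-only network,
topology, signed modules, balance census, group comparison, and the
network-informed regressions — writing every stage's artifacts plus a run
manifest with configuration, seeds and file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import pandas as pd

from . import balance as balance_mod
from . import communities, compare, models, simulate, topology
from .core import (
    LAYERS,
    read_node_meta,
    write_edge_csv,
    write_graphml,
    write_node_meta,
)
from .ggm import estimate_network
from .preprocess import log2_median_center, nonparanormal_transform

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": {"enabled": True},
    "preprocess": {"log2_center": False, "merge_r_threshold": 0.8},
    "estimate": {"gamma": 0.5, "n_lambda": 100, "lambda_min_ratio": 0.01, "tol": 1e-6},
    "communities": {"n_spins": 25, "n_restarts": 20, "gamma_pos": 1.0, "gamma_neg": 1.0},
    "topology": {"powerlaw_n_boot": 500},
    "compare": {"enabled": True, "n_perm": 100, "alpha": 0.05, "n_lambda": 15,
                "lambda_min_ratio": 0.01, "tol": 1e-4},
    "moderate": {"enabled": True},
}


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | None, out_dir: str | Path) -> Path:
    """Execute all stages; returns the artifact directory.

    The configuration is a nested dict (typically loaded from YAML); any
    stage error aborts with the stage name, and the manifest records the
    stages completed so far.
    """
    cfg = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict[str, Any] = {
        "config": cfg,
        "seed": seed,
        "version": __import__("peptinet").__version__,
        "stages": [],
        "warnings": [],
        "outputs": {},
    }
    stage = "init"
    try:
        # ------------------------------------------------ data
        stage = "simulate" if cfg["simulate"].get("enabled", False) else "load"
        t0 = time.time()
        if cfg["simulate"].get("enabled", False):
            sim_cfg = simulate.SyntheticConfig(seed=seed, **{
                k: v for k, v in cfg["simulate"].items() if k not in ("enabled",)
            })
            high, low, truth = simulate.generate_study(sim_cfg)
            node_meta = truth.node_meta
            X_high, X_low = high.X, low.X
            cov = pd.concat(
                [high.covariates.assign(group="high"), low.covariates.assign(group="low")],
                ignore_index=True,
            )
            X_all = pd.concat([X_high, X_low], ignore_index=True)
            X_all.to_csv(out / "data_matrix.csv", index=False)
            cov.to_csv(out / "covariates.csv", index=False)
            write_node_meta(node_meta, str(out / "node_meta.tsv"))
            truth_json = {
                "modules": truth.modules,
                "hub_nodes": truth.hub_nodes,
                "group_unique_edges": [list(e) for e in truth.group_unique_edges],
                "seed": truth.seed,
            }
            (out / "truth.json").write_text(json.dumps(truth_json, indent=1))
        else:
            paths = cfg["input"]
            X_all = pd.read_csv(paths["data"], na_values=["", "NA"])
            cov = pd.read_csv(paths["covariates"])
            node_meta = read_node_meta(paths["node_meta"])
            if cfg["preprocess"].get("log2_center", False):
                X_all = log2_median_center(X_all)
            grp = cov["group"] if "group" in cov else None
            if grp is None:
                highs, lows = compare.median_split(cov["activity_counts"])
                grp = pd.Series("low", index=cov.index)
                grp.loc[highs] = "high"
                cov = cov.assign(group=grp)
            X_high = X_all[cov["group"].to_numpy() == "high"].reset_index(drop=True)
            X_low = X_all[cov["group"].to_numpy() == "low"].reset_index(drop=True)
            truth = None
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # ------------------------------------------------ preprocess + estimate
        stage = "estimate"
        t0 = time.time()
        est = cfg["estimate"]
        X_npn = nonparanormal_transform(X_all)
        net, fit = estimate_network(
            X_npn, node_meta, gamma=est["gamma"], n_lambda=est["n_lambda"],
            lambda_min_ratio=est["lambda_min_ratio"], tol=est["tol"], layout_seed=seed + 42,
        )
        write_graphml(net, str(out / "multilayer_network.graphml"))
        write_edge_csv(net, str(out / "multilayer_edges.csv"))
        fit.path_summary().to_csv(out / "ggm_path.csv", index=False)

        syn_ids = [m.node_id for m in node_meta if m.layer == LAYERS[0]]
        syn_meta = [m for m in node_meta if m.layer == LAYERS[0]]
        syn_net, _ = estimate_network(
            X_npn[syn_ids], syn_meta, gamma=est["gamma"], n_lambda=est["n_lambda"],
            lambda_min_ratio=est["lambda_min_ratio"], tol=est["tol"], layout_seed=seed + 43,
        )
        write_graphml(syn_net, str(out / "synaptic_network.graphml"))
        write_edge_csv(syn_net, str(out / "synaptic_edges.csv"))
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # ------------------------------------------------ topology
        stage = "topology"
        t0 = time.time()
        cent = topology.centrality_table(net)
        cent.to_csv(out / "centrality.csv", index=False)
        topo = topology.topology_summary(
            net, n_boot=cfg["topology"]["powerlaw_n_boot"], seed=seed
        )
        (out / "topology.json").write_text(json.dumps(topo, indent=1))
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # ------------------------------------------------ communities (synaptic only)
        stage = "communities"
        t0 = time.time()
        com = cfg["communities"]
        part = communities.spinglass_partition(
            syn_net, n_spins=com["n_spins"], n_restarts=com["n_restarts"],
            gamma_pos=com["gamma_pos"], gamma_neg=com["gamma_neg"], seed=seed,
        )
        communities.apply_partition(syn_net, part)
        for m in node_meta:
            if m.node_id in part.assignment:
                m.module_id = part.assignment[m.node_id]
        pd.DataFrame(
            {"node_id": list(part.assignment), "module_id": list(part.assignment.values())}
        ).to_csv(out / "partition.csv", index=False)
        (out / "communities.json").write_text(json.dumps({
            "K": part.K, "modularity_signed": part.modularity,
            "modularity_positive": part.modularity_positive,
            "transitivity": part.transitivity, "hamiltonian": part.hamiltonian,
            "seed": part.seed, "n_restarts": part.n_restarts,
        }, indent=1))
        # module composition (annotation cross-tabs) and expected-influence ANOVA
        comps = []
        for attr in ("cell_type", "localization", "function_tag"):
            tab = communities.module_composition(syn_net.network, attr)
            long = tab.reset_index().melt(id_vars="module", var_name="value",
                                          value_name="count")
            long.insert(1, "attribute", attr)
            comps.append(long[long["count"] > 0])
        pd.concat(comps, ignore_index=True).to_csv(out / "module_composition.csv",
                                                   index=False)
        ei = topology.expected_influence(net)
        syn_pos = [k for k, m in enumerate(node_meta) if m.layer == LAYERS[0]]
        anova = {}
        for label, groups in (
            ("module", [part.assignment[node_meta[k].node_id] for k in syn_pos]),
            ("function", [node_meta[k].function_tag or "other" for k in syn_pos]),
        ):
            try:
                F, pval, means = communities.module_attribute_anova(
                    ei[syn_pos], pd.Series(groups).to_numpy()
                )
                anova[label] = {"F": F, "p": pval,
                                "means": {str(k): v for k, v in means.items()}}
            except ValueError as exc:
                manifest["warnings"].append(f"expected-influence ANOVA ({label}): {exc}")
        (out / "influence_anova.json").write_text(json.dumps(anova, indent=1))
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # ------------------------------------------------ balance
        stage = "balance"
        t0 = time.time()
        bal = balance_mod.global_balance(net)
        (out / "balance.json").write_text(json.dumps(balance_mod.balance_report(bal), indent=1))
        manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # ------------------------------------------------ group comparison
        stage = "compare"
        if cfg["compare"].get("enabled", True):
            t0 = time.time()
            cmp_cfg = cfg["compare"]
            result = compare.nct(
                X_high, X_low, node_meta,
                n_perm=cmp_cfg["n_perm"], alpha=cmp_cfg["alpha"],
                gamma=est["gamma"], seed=seed + 1,
                n_lambda=cmp_cfg["n_lambda"],
                lambda_min_ratio=cmp_cfg["lambda_min_ratio"], tol=cmp_cfg["tol"],
            )
            (out / "comparison.json").write_text(json.dumps(result.to_json(), indent=1))
            result.edges.to_csv(out / "comparison_edges.csv", index=False)
            result.centrality.to_csv(out / "comparison_centrality.csv", index=False)
            manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

        # ------------------------------------------------ informed models
        stage = "moderate"
        if cfg["moderate"].get("enabled", True) and "cognition_z" in cov:
            t0 = time.time()
            assignment = part.assignment
            scores = pd.DataFrame({
                f"module_{m}": models.module_score(X_npn, assignment, m)
                for m in range(1, part.K + 1)
            })
            assoc = models.module_cognition_association(
                scores, cov["cognition_z"],
                cov[["age_at_death", "sex", "education"]],
            )
            assoc.to_csv(out / "module_cognition.csv")
            # three-way moderation on the designated p-tau nodes
            ptau1 = cfg.get("moderate", {}).get("ptau1", "pp_01")
            ptau2 = cfg.get("moderate", {}).get("ptau2", "pp_02")
            mod_id = int(cfg.get("moderate", {}).get("module", 2))
            if ptau1 in X_npn.columns and ptau2 in X_npn.columns and mod_id <= part.K:
                syn_scores = models.module_score(
                    X_npn[syn_ids], {k: v for k, v in assignment.items()}, mod_id
                )
                fit_mod = models.threeway_moderation(
                    cov["tangle_density"], X_npn[ptau1], X_npn[ptau2],
                    syn_scores, cov["activity_counts"],
                )
                fit_mod.table.to_csv(out / "moderation.csv")
            manifest["stages"].append({"stage": stage, "seconds": round(time.time() - t0, 2)})

    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def render_report(artifact_dir: str | Path) -> Path:
    """Render plots and a markdown report from a completed artifact directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    art = Path(artifact_dir)
    required = ["multilayer_network.graphml", "centrality.csv", "manifest.json"]
    for name in required:
        if not (art / name).exists():
            raise FileNotFoundError(f"artifact {name!r} missing from {art}")

    lines = ["# Network analysis report", ""]

    layer_colors = {
        "synaptic_peptide": "white", "ppi_complex": "lightgray",
        "pathological_peptide": "yellowgreen", "cellular_pathology": "teal",
    }
    for gname, fname in (("multilayer", "multilayer_network.graphml"),
                         ("synaptic", "synaptic_network.graphml")):
        if not (art / fname).exists():
            continue
        G = nx.read_graphml(art / fname)
        pos = {
            n: (float(d.get("x", 0)), float(d.get("y", 0))) for n, d in G.nodes(data=True)
        }
        if all(v == (0, 0) for v in pos.values()):
            pos = nx.spring_layout(G, seed=1)
        fig, ax = plt.subplots(figsize=(7, 7))
        ecol = ["tab:blue" if G.edges[e]["weight"] > 0 else "tab:red" for e in G.edges]
        ew = [4 * abs(G.edges[e]["weight"]) for e in G.edges]
        ncol = [layer_colors.get(G.nodes[n].get("layer", ""), "orange") for n in G]
        nx.draw_networkx(G, pos, ax=ax, node_color=ncol, edge_color=ecol, width=ew,
                         node_size=90, font_size=4, edgecolors="black")
        ax.set_axis_off()
        fig.savefig(art / f"network_{gname}.png", dpi=150, bbox_inches="tight")
        plt.close(fig)
        lines += [f"![{gname} network](network_{gname}.png)", ""]

    cent = pd.read_csv(art / "centrality.csv")
    fig, axes = plt.subplots(1, 4, figsize=(10, max(4, len(cent) * 0.12)), sharey=True)
    for ax, col in zip(axes, ["strength_z", "closeness_z", "betweenness_z",
                              "expected_influence_z"]):
        ax.plot(cent[col], range(len(cent)), "o-", ms=2, lw=0.5)
        ax.set_title(col.replace("_z", ""), fontsize=8)
        ax.axvline(0, color="gray", lw=0.5)
    axes[0].set_yticks(range(len(cent)))
    axes[0].set_yticklabels(cent["node_id"], fontsize=3)
    fig.savefig(art / "centrality_z.png", dpi=150, bbox_inches="tight")
    plt.close(fig)
    lines += ["![centrality z-scores](centrality_z.png)", ""]

    hubs = cent.loc[cent["hub"], "node_id"].tolist()
    lines += [f"Hub nodes (betweenness > mean + 2 SD): {', '.join(hubs) or 'none'}", ""]

    if (art / "communities.json").exists():
        cj = json.loads((art / "communities.json").read_text())
        lines += [
            f"Synaptic modules: K = {cj['K']}, signed modularity Q = "
            f"{cj['modularity_signed']:.3f}, transitivity = {cj['transitivity']:.3f}", "",
        ]
    if (art / "balance.json").exists():
        bj = json.loads((art / "balance.json").read_text())
        frac = bj["balance_fraction"]
        lines += [
            f"Structural balance: {bj['n_balanced']} / {bj['n_triangles']} triangles "
            f"balanced ({frac:.3f})" if frac is not None else
            "Structural balance: no closed triangles", "",
        ]
    if (art / "comparison.json").exists():
        comp = json.loads((art / "comparison.json").read_text())
        gc = comp["global_connectivity"]
        lines += [
            "## Group comparison",
            f"Global connectivity: high {gc['group_a']:.3f} vs low {gc['group_b']:.3f} "
            f"(p = {gc['p_value']:.3f})",
            "",
        ]
        sig = ["{}-{}".format(e["i"], e["j"]) for e in comp["edges"] if e.get("reject")]
        lines += ["Edges differing after Holm correction: " + (", ".join(sig) or "none"), ""]
    else:
        lines += ["## Group comparison", "not run", ""]

    if (art / "module_cognition.csv").exists():
        lines += ["## Module-cognition associations", "",
                  pd.read_csv(art / "module_cognition.csv").to_string(index=False), ""]
    if (art / "moderation.csv").exists():
        lines += ["## Three-way moderation", "",
                  pd.read_csv(art / "moderation.csv").to_string(index=False), ""]

    report = art / "report.md"
    report.write_text("\n".join(lines))
    return report
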