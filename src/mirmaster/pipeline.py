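"""End-to-end orchestration: DE per stage -> stage filter -> MI network ->
database filter -> master-regulator calls -> oncogenic activity -> survival.

Every stage writes its table under the output directory, and the whole run
is a pure function of (inputs, config, seed): a single global seed is fanned
out into per-stage substreams via ``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .de import bh_adjust, nb_differential_expression, size_factors, vst_like_transform
from .dbfilter import filter_by_databases, read_edge_set
from .io import read_counts, read_metadata, write_table
from .mmr import build_regulons, call_master_regulators, gene_signature, score_regulons
from .network import bootstrap_consensus, node_degree
from .oncogenic import oa_table
from .stage import STAGES, filter_consistent_upregulated, stage_correlation_table
from .survival import cox_regression, kaplan_meier, logrank_test, median_dichotomize
from .synthetic import (CohortConfig, generate_cohort, generate_target_databases,
                        write_cohort)

__all__ = ["default_config", "run_pipeline", "PipelineError"]

_STAGE_NAMES = ("simulate", "de", "stage_filter", "network", "db_filter",
                "mmr", "oa", "survival")


class PipelineError(RuntimeError):
    """Stage failure carrying the stage name for machine-readable status."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def default_config() -> dict:
    return {
        "seed": 7,
        "thresholds": {
            "de_fdr": 0.05,
            "de_lfc": 0.5,
            "corr_p": 0.05,
            "mmr_fdr": 0.05,
            "logrank_alpha": 0.05,
        },
        "network": {
            "n_boot": 100,
            "mi_p": 1e-4,
            "dpi_tolerance": 0.0,
            "consensus_alpha": 0.05,
            "mi_null": 1000,
            "min_regulon_size": 10,
        },
        "mmr": {"n_null": 1000},
        "db_filter": True,
    }


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {name: int(c.generate_state(1)[0]) for name, c in zip(_STAGE_NAMES, children)}


def _load_inputs(cfg: dict, outdir: Path, seeds: dict):
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        db_spec = sim.pop("databases", None)
        sim.setdefault("seed", seeds["simulate"])
        for key in ("planted_mmr_ids", "planted_edges", "driver_roles", "stage_probs"):
            if key in sim:
                sim[key] = tuple(tuple(x) if isinstance(x, (list, tuple)) else x
                                 for x in sim[key]) if key != "stage_probs" else tuple(sim[key])
        config = CohortConfig(**sim)
        mirna, mrna, meta, truth = generate_cohort(config)
        dbs = []
        if db_spec:
            dbs = generate_target_databases(
                truth,
                n_dbs=int(db_spec.get("n_dbs", 3)),
                recall=float(db_spec.get("recall", 0.8)),
                precision=float(db_spec.get("precision", 0.5)),
                seed=seeds["simulate"] + 1,
            )
        write_cohort(outdir / "inputs", mirna, mrna, meta, truth, databases=dbs)
        roles = truth.driver_roles
        return mirna, mrna, meta, dbs, roles
    inputs = cfg.get("inputs")
    if not inputs:
        raise PipelineError("simulate", "config needs a 'simulate' or 'inputs' block")
    mirna = read_counts(inputs["mirna_counts"])
    mrna = read_counts(inputs["mrna_counts"])
    meta = read_metadata(inputs["metadata"])
    dbs = [read_edge_set(p, name=Path(p).stem) for p in inputs.get("databases", [])]
    roles = {}
    if "driver_annotation" in inputs:
        ann = pd.read_csv(inputs["driver_annotation"], sep="\t")
        roles = dict(zip(ann["gene"], ann["role"]))
    return mirna, mrna, meta, dbs, roles


def run_pipeline(config: dict, outdir) -> dict:
    """Execute all stages; returns a results bundle of DataFrames/lists."""
    cfg = _merge(default_config(), config)
    if "seed" not in config and "seed" not in cfg:
        raise PipelineError("simulate", "config must set a seed")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(int(cfg["seed"]))
    thr = cfg["thresholds"]
    net_cfg = cfg["network"]

    mirna, mrna, meta, dbs, roles = _load_inputs(cfg, out, seeds)

    meta_idx = meta.set_index("sample_id")
    cond = meta_idx.loc[mirna.columns, "condition"]
    is_tumor = (cond == "tumor").to_numpy()
    stage_lab = meta_idx.loc[mirna.columns, "stage"].astype(str)

    # --- per-stage miRNA DE against all normals -------------------------
    stage_de = {}
    try:
        for st in STAGES:
            cols = (~is_tumor) | (stage_lab.str.upper().str.rstrip("ABC") == st).to_numpy()
            sub = mirna.loc[:, cols]
            g = is_tumor[cols].astype(int)
            tab = nb_differential_expression(sub, g)
            stage_de[st] = tab
            write_table(tab, out / f"de_mirna_stage_{st}.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("de", str(exc)) from exc

    # --- stage filter ---------------------------------------------------
    try:
        mir_vst = vst_like_transform(mirna, size_factors(mirna))
        corr = stage_correlation_table(mir_vst, meta)
        ids, audit = filter_consistent_upregulated(
            stage_de, corr, fdr_cutoff=thr["de_fdr"], lfc_cutoff=thr["de_lfc"],
            corr_p_cutoff=thr["corr_p"],
        )
        write_table(audit, out / "stage_filter.tsv")
        write_table(pd.DataFrame({"mirna": ids}), out / "consistent_mirnas.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("stage_filter", str(exc)) from exc

    # --- mRNA DE (signature + OA directionality) ------------------------
    try:
        de_mrna = nb_differential_expression(mrna, is_tumor.astype(int))
        write_table(de_mrna, out / "de_mrna.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("de", str(exc)) from exc

    # --- network on tumor samples ---------------------------------------
    try:
        de_genes = de_mrna.loc[de_mrna["padj"] <= thr["de_fdr"], "feature"]
        tumor_cols = list(mirna.columns[is_tumor])
        mrna_vst = vst_like_transform(mrna, size_factors(mrna))
        net_mirna = mir_vst.loc[ids, tumor_cols] if ids else mir_vst.loc[[], tumor_cols]
        net_mrna = mrna_vst.loc[sorted(de_genes), tumor_cols]
        if net_mirna.empty or net_mrna.empty:
            network = pd.DataFrame(columns=["mirna", "gene", "mi", "support",
                                            "direction_sign"])
        else:
            network = bootstrap_consensus(
                net_mirna, net_mrna,
                n_boot=int(net_cfg["n_boot"]),
                mi_p=float(net_cfg["mi_p"]),
                tolerance=float(net_cfg["dpi_tolerance"]),
                consensus_alpha=float(net_cfg["consensus_alpha"]),
                n_null=int(net_cfg["mi_null"]),
                seed=seeds["network"],
            )
        write_table(network, out / "network.tsv")
        mir_deg, gene_deg = node_degree(network)
        write_table(mir_deg.reset_index(), out / "degree_mirna.tsv")
        write_table(gene_deg.reset_index(), out / "degree_gene.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("network", str(exc)) from exc

    # --- database filter -------------------------------------------------
    try:
        if cfg.get("db_filter", True) and dbs:
            network = filter_by_databases(network, dbs)
        else:
            network = filter_by_databases(network, [], allow_empty=True)
        write_table(network, out / "network_filtered.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("db_filter", str(exc)) from exc

    # --- master regulators ----------------------------------------------
    try:
        regulons = build_regulons(network, min_size=int(net_cfg["min_regulon_size"]))
        signature = gene_signature(de_mrna)
        calls = score_regulons(regulons, signature,
                               n_null=int(cfg["mmr"]["n_null"]), seed=seeds["mmr"])
        mmr_ids = call_master_regulators(calls, fdr_cutoff=thr["mmr_fdr"])
        write_table(calls, out / "mmr_calls.tsv")
        write_table(pd.DataFrame({"mirna": mmr_ids}), out / "mmr_ids.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("mmr", str(exc)) from exc

    # --- oncogenic activity ----------------------------------------------
    try:
        lfc = dict(zip(de_mrna["feature"], de_mrna["log2FoldChange"]))
        mmr_regulons = [r for r in regulons if r.mirna in set(mmr_ids)]
        oa = oa_table(mmr_regulons, roles, lfc)
        write_table(oa, out / "oncogenic_activity.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("oa", str(exc)) from exc

    # --- survival ---------------------------------------------------------
    try:
        surv = _survival_stage(mir_vst, meta, mmr_ids, thr["logrank_alpha"])
        write_table(surv, out / "survival.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("survival", str(exc)) from exc

    manifest = {
        "version": __version__,
        "seed": int(cfg["seed"]),
        "stage_seeds": seeds,
        "thresholds": thr,
        "network": net_cfg,
        "n_consistent_mirnas": len(ids),
        "n_network_edges": int(len(network)),
        "n_mmr": len(mmr_ids),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return {
        "stage_de": stage_de,
        "consistent_mirnas": ids,
        "de_mrna": de_mrna,
        "network": network,
        "mmr_calls": calls,
        "mmr_ids": mmr_ids,
        "oa": oa,
        "survival": surv,
        "manifest": manifest,
    }


def _survival_stage(mir_vst: pd.DataFrame, meta: pd.DataFrame, mirnas,
                    logrank_alpha: float) -> pd.DataFrame:
    """Median split + log-rank + uni/multivariate Cox per candidate miRNA."""
    from .stage import stage_to_ordinal

    meta_idx = meta.set_index("sample_id")
    tumors = meta_idx[meta_idx["condition"] == "tumor"]
    tumors = tumors[np.isfinite(tumors["time"].astype(float))
                    & np.isfinite(tumors["event"].astype(float))]
    rows = []
    for mid in mirnas:
        if mid not in mir_vst.index:
            continue
        expr = mir_vst.loc[mid, tumors.index]
        try:
            groups = median_dichotomize(expr)
        except ValueError:
            continue
        t = tumors["time"].astype(float).to_numpy()
        e = tumors["event"].astype(int).to_numpy()
        chi2, p = logrank_test(t, e, groups.to_numpy())
        df = pd.DataFrame(
            {
                "time": t,
                "event": e,
                "high_expression": (groups == "high").astype(int).to_numpy(),
                "age_ge_58": (tumors["age"].astype(float) >= 58).astype(int).to_numpy(),
                "stage_ord": [stage_to_ordinal(s) for s in tumors["stage"]],
                "er_positive": (tumors["er_status"] == "positive").astype(int).to_numpy(),
                "pr_positive": (tumors["pr_status"] == "positive").astype(int).to_numpy(),
            }
        )
        covs = ["high_expression", "age_ge_58", "stage_ord", "er_positive",
                "pr_positive"]
        try:
            uni = cox_regression(df, ["high_expression"], mode="univariate")
            multi = cox_regression(df, covs, mode="multivariate")
        except ValueError:
            continue
        for tab in (uni, multi):
            for _, r in tab.iterrows():
                rows.append(
                    (mid, r["covariate"], r["mode"], r["HR"], r["CI_low"],
                     r["CI_high"], r["p"], chi2, p, p <= logrank_alpha)
                )
    return pd.DataFrame(
        rows,
        columns=["mirna", "covariate", "mode", "HR", "CI_low", "CI_high", "p",
                 "logrank_chi2", "logrank_p", "logrank_significant"],
    )
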