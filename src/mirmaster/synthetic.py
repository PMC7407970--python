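"""Synthetic cohort generator with serialized ground truth.

Counts are negative-binomial with a mean/size parameterization: for a mean
``mu`` and configured ``dispersion`` ``a``, draws use size ``1/a`` so that
``Var = mu + a * mu**2``.  Planted miRNAs get a tumor log2-mean increment of
``stage_trend * stage`` (stage coded 1-4), which makes them upregulated in
tumors and monotone in stage.  Each planted edge shifts its target gene's
tumor log2-mean by ``sign * effect_size * z``, where ``z`` is the
regulator's observed log2 expression standardized across the whole cohort
(so upregulated regulators push their targets directionally, and the
within-tumor variation creates mutual information).  Survival times are
exponential with log-hazard ``survival_beta * mean(z over planted
regulators)`` for tumors.

Everything is a deterministic function of the config, including its seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "EdgeSet",
    "generate_cohort",
    "generate_target_databases",
    "generate_driver_annotation",
    "mmr_benchmark_config",
    "write_cohort",
]

ROLES = ("oncogene", "tsg", "dual", "none")
_STAGE_LABELS = {1: "I", 2: "II", 3: "III", 4: "IV"}
_BASELINE_HAZARD = np.log(2.0) / 60.0  # median survival 60 time units


@dataclass(frozen=True)
class CohortConfig:
    n_tumor: int
    n_normal: int
    n_mirna: int
    n_mrna: int
    stage_probs: tuple = (0.25, 0.25, 0.25, 0.25)
    planted_mmr_ids: tuple = ()
    # (mirna, gene, sign in {-1,+1}, effect_size) per edge
    planted_edges: tuple = ()
    mirna_base_mean: float = 500.0
    mrna_base_mean: float = 500.0
    dispersion: float = 0.1
    stage_trend: float = 0.0
    # baseline tumor log2 shift for planted miRNAs, on top of the stage
    # trend; lets the tumor/normal separation dominate the within-tumor
    # spread of the regulator z-score
    tumor_lfc: float = 0.0
    libsize_lognormal_sd: float = 0.2
    survival_beta: float = 0.0
    censor_rate: float = 0.3
    seed: int = 0
    # gene -> role; genes absent default to "none" (plumbing for the
    # oncogenic-activity stage; roles never feed back into expression)
    driver_roles: tuple = ()

    def mirna_ids(self):
        return [f"mir-{i:03d}" for i in range(1, self.n_mirna + 1)]

    def gene_ids(self):
        return [f"gene-{i:04d}" for i in range(1, self.n_mrna + 1)]

    def validate(self):
        for name in ("n_tumor", "n_normal", "n_mirna", "n_mrna"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        probs = np.asarray(self.stage_probs, dtype=float)
        if probs.shape != (4,) or np.any(probs < 0) or abs(probs.sum() - 1) > 1e-9:
            raise ValueError("stage_probs must be a 4-vector summing to 1")
        if self.mirna_base_mean <= 0 or self.mrna_base_mean <= 0:
            raise ValueError("base means must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.libsize_lognormal_sd < 0:
            raise ValueError("libsize_lognormal_sd must be >= 0")
        if not 0 <= self.censor_rate <= 1:
            raise ValueError("censor_rate must be in [0, 1]")
        mirnas = set(self.mirna_ids())
        genes = set(self.gene_ids())
        if not set(self.planted_mmr_ids) <= mirnas:
            raise ValueError("planted_mmr_ids reference undeclared miRNAs")
        for m, g, sign, eff in self.planted_edges:
            if m not in mirnas or g not in genes:
                raise ValueError(f"planted edge ({m}, {g}) references undeclared features")
            if sign not in (-1, 1):
                raise ValueError("edge sign must be -1 or +1")
        for g, role in self.driver_roles:
            if g not in genes:
                raise ValueError(f"driver role for undeclared gene {g}")
            if role not in ROLES:
                raise ValueError(f"unknown driver role {role!r}")


@dataclass
class GroundTruth:
    planted_mmr_ids: list
    planted_edges: list
    driver_roles: dict
    true_log2fc: dict
    mirna_ids: list
    gene_ids: list

    def to_json(self, path):
        payload = dataclasses.asdict(self)
        payload["planted_edges"] = [list(e) for e in payload["planted_edges"]]
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path):
        payload = json.loads(Path(path).read_text())
        payload["planted_edges"] = [tuple(e) for e in payload["planted_edges"]]
        return cls(**payload)


@dataclass(frozen=True)
class EdgeSet:
    name: str
    pairs: frozenset  # of (mirna, gene)


def _nb_draw(rng, mean, dispersion):
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def generate_cohort(config: CohortConfig):
    """Simulate (mirna_counts, mrna_counts, metadata, truth) for one cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_t, n_n = config.n_tumor, config.n_normal
    n_samples = n_t + n_n
    sample_ids = [f"T{i:04d}" for i in range(1, n_t + 1)] + [
        f"N{i:04d}" for i in range(1, n_n + 1)
    ]
    is_tumor = np.r_[np.ones(n_t, bool), np.zeros(n_n, bool)]

    stages = np.zeros(n_samples, dtype=int)
    stages[:n_t] = rng.choice([1, 2, 3, 4], size=n_t, p=np.asarray(config.stage_probs))

    lib = np.exp(rng.normal(0.0, config.libsize_lognormal_sd, n_samples))

    mirna_ids = config.mirna_ids()
    gene_ids = config.gene_ids()
    mir_index = {m: i for i, m in enumerate(mirna_ids)}
    gene_index = {g: j for j, g in enumerate(gene_ids)}
    planted = set(config.planted_mmr_ids)

    # miRNA counts
    log2_mu_mir = np.full((config.n_mirna, n_samples), np.log2(config.mirna_base_mean))
    for m in planted:
        log2_mu_mir[mir_index[m], :n_t] += (
            config.tumor_lfc + config.stage_trend * stages[:n_t]
        )
    mu_mir = np.exp2(log2_mu_mir) * lib[None, :]
    mirna_counts = _nb_draw(rng, mu_mir, config.dispersion)

    # regulator z-scores from observed, library-corrected log2 expression
    expr = np.log2(1.0 + mirna_counts / lib[None, :])
    sd = expr.std(axis=1)
    sd[sd == 0] = 1.0
    z = (expr - expr.mean(axis=1)[:, None]) / sd[:, None]

    # mRNA counts
    log2_mu_gene = np.full((config.n_mrna, n_samples), np.log2(config.mrna_base_mean))
    for m, gname, sign, eff in config.planted_edges:
        log2_mu_gene[gene_index[gname], :n_t] += sign * eff * z[mir_index[m], :n_t]
    mu_gene = np.exp2(log2_mu_gene) * lib[None, :]
    mrna_counts = _nb_draw(rng, mu_gene, config.dispersion)

    # survival: exponential PH on the mean planted-regulator z-score
    if planted:
        zbar = z[[mir_index[m] for m in sorted(planted)], :n_t].mean(axis=0)
    else:
        zbar = np.zeros(n_t)
    hazard = _BASELINE_HAZARD * np.exp(config.survival_beta * zbar)
    death = rng.exponential(1.0 / hazard)
    censored = rng.random(n_t) < config.censor_rate
    time = np.where(censored, death * rng.random(n_t), death)
    event = (~censored).astype(int)

    age = np.clip(np.round(rng.normal(58, 10, n_samples)), 25, 90).astype(int)
    er = np.where(rng.random(n_samples) < 0.7, "positive", "negative")
    pr = np.where(rng.random(n_samples) < 0.6, "positive", "negative")

    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "condition": np.where(is_tumor, "tumor", "normal"),
            "stage": [
                _STAGE_LABELS[s] if t else "NA" for s, t in zip(stages, is_tumor)
            ],
            "time": np.r_[np.round(time, 4), np.full(n_n, np.nan)],
            "event": np.r_[event.astype(float), np.full(n_n, np.nan)],
            "age": age,
            "er_status": er,
            "pr_status": pr,
        }
    )

    roles = dict(config.driver_roles)
    truth = GroundTruth(
        planted_mmr_ids=sorted(planted),
        planted_edges=[tuple(e) for e in config.planted_edges],
        driver_roles={g: roles.get(g, "none") for g in gene_ids},
        true_log2fc=_true_lfc(config, stages[:n_t], z, mir_index, gene_index, n_t),
        mirna_ids=mirna_ids,
        gene_ids=gene_ids,
    )
    mirna_df = pd.DataFrame(mirna_counts, index=mirna_ids, columns=sample_ids)
    mrna_df = pd.DataFrame(mrna_counts, index=gene_ids, columns=sample_ids)
    return mirna_df, mrna_df, metadata, truth


def _true_lfc(config, tumor_stages, z, mir_index, gene_index, n_t):
    """Expected tumor-vs-normal log2 shift per feature (generative scale)."""
    out = {}
    for m in config.mirna_ids():
        if m in set(config.planted_mmr_ids):
            out[m] = float(config.tumor_lfc + config.stage_trend * tumor_stages.mean())
        else:
            out[m] = 0.0
    shift = {g: 0.0 for g in config.gene_ids()}
    for m, g, sign, eff in config.planted_edges:
        shift[g] += float(sign * eff * z[mir_index[m], :n_t].mean())
    out.update(shift)
    return out


def generate_target_databases(truth: GroundTruth, n_dbs: int, recall: float,
                              precision: float, seed: int):
    """Mock target databases: true edges at a recall, decoys at a precision.

    Each database keeps every true edge independently with probability
    ``recall`` and adds uniformly drawn decoy (non-true) pairs so that the
    expected precision equals ``precision``.
    """
    if not (0 < recall <= 1 and 0 < precision <= 1):
        raise ValueError("recall and precision must be in (0, 1]")
    if n_dbs < 1:
        raise ValueError("n_dbs must be >= 1")
    true_edges = sorted((m, g) for m, g, _, _ in truth.planted_edges)
    if not true_edges and precision < 1:
        raise ValueError("cannot set precision < 1 with no true edges (no decoy ratio)")
    rng = np.random.default_rng(seed)
    true_set = set(true_edges)
    non_true = [
        (m, g)
        for m in truth.mirna_ids
        for g in truth.gene_ids
        if (m, g) not in true_set
    ]
    dbs = []
    for d in range(n_dbs):
        keep = [e for e in true_edges if rng.random() < recall]
        k = len(keep)
        n_decoy = int(round(k * (1 - precision) / precision))
        if n_decoy > len(non_true):
            raise ValueError("not enough non-true pairs for requested precision")
        decoy_idx = rng.choice(len(non_true), size=n_decoy, replace=False)
        pairs = frozenset(keep) | frozenset(non_true[i] for i in decoy_idx)
        dbs.append(EdgeSet(name=f"mockdb{d + 1}", pairs=pairs))
    return dbs


def generate_driver_annotation(genes, frac_onc: float, frac_tsg: float,
                               frac_dual: float, seed: int) -> dict:
    """Random role assignment: round(frac * n) genes per role, rest "none".

    Counts use round-half-up on ``frac * n``; genes are shuffled by the seed
    and roles dealt in the order oncogene, tsg, dual.
    """
    fracs = (frac_onc, frac_tsg, frac_dual)
    if any(f < 0 for f in fracs):
        raise ValueError("fractions must be >= 0")
    if sum(fracs) > 1 + 1e-12:
        raise ValueError("fractions must sum to <= 1")
    genes = list(genes)
    n = len(genes)
    counts = [int(np.floor(f * n + 0.5)) for f in fracs]
    while sum(counts) > n:  # rounding overflow guard
        counts[int(np.argmax(counts))] -= 1
    order = list(np.random.default_rng(seed).permutation(n))
    roles = {g: "none" for g in genes}
    pos = 0
    for role, c in zip(("oncogene", "tsg", "dual"), counts):
        for i in order[pos:pos + c]:
            roles[genes[i]] = role
        pos += c
    return roles


def mmr_benchmark_config(seed: int) -> CohortConfig:
    """The planted-regulator benchmark cohort.

    10 miRNAs, 5 of them planted master regulators, each repressing a
    disjoint block of 20 of 200 genes with effect size 1.5; 300 tumors and
    100 normals.  Targets of the first three regulators are annotated as
    tumor suppressors (so repression should classify "oncogenic"), targets
    of the last two as oncogenes ("suppressor").
    """
    n_mirna, n_mrna = 10, 200
    planted = tuple(f"mir-{i:03d}" for i in range(1, 6))
    edges = []
    roles = []
    for k, m in enumerate(planted):
        targets = [f"gene-{j:04d}" for j in range(20 * k + 1, 20 * k + 21)]
        for g in targets:
            edges.append((m, g, -1, 1.5))
            roles.append((g, "tsg" if k < 3 else "oncogene"))
    return CohortConfig(
        n_tumor=300,
        n_normal=100,
        n_mirna=n_mirna,
        n_mrna=n_mrna,
        planted_mmr_ids=planted,
        planted_edges=tuple(edges),
        stage_trend=0.25,
        tumor_lfc=2.0,
        survival_beta=0.8,
        seed=seed,
        driver_roles=tuple(roles),
    )


def write_cohort(outdir, mirna_counts, mrna_counts, metadata, truth,
                 databases=(), annotation=None):
    """Serialize a cohort in the pipeline's TSV dialect."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mirna_counts.rename_axis("feature").to_csv(out / "mirna_counts.tsv", sep="\t")
    mrna_counts.rename_axis("feature").to_csv(out / "mrna_counts.tsv", sep="\t")
    metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth.to_json(out / "truth.json")
    for db in databases:
        pd.DataFrame(sorted(db.pairs), columns=["mirna", "gene"]).to_csv(
            out / f"db_{db.name}.tsv", sep="\t", index=False
        )
    roles = annotation if annotation is not None else truth.driver_roles
    pd.DataFrame(sorted(roles.items()), columns=["gene", "role"]).to_csv(
        out / "driver_annotation.tsv", sep="\t", index=False
    )
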