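import numpy as np
import pytest

from mirmaster.de import (nb_differential_expression, size_factors,
                          vst_like_transform)
from mirmaster.mmr import (build_regulons, call_master_regulators,
                           gene_signature, score_regulons)
from mirmaster.network import bootstrap_consensus
from mirmaster.oncogenic import oa_table
from mirmaster.synthetic import generate_cohort, mmr_benchmark_config

_BENCH_CACHE = {}


def _run_benchmark(seed: int) -> dict:
    """Planted-regulator benchmark: cohort -> DE -> network -> MMR -> OA."""
    cfg = mmr_benchmark_config(seed=seed)
    mirna, mrna, meta, truth = generate_cohort(cfg)
    is_tumor = (
        meta.set_index("sample_id").loc[mirna.columns, "condition"] == "tumor"
    ).to_numpy()
    de_mrna = nb_differential_expression(mrna, is_tumor.astype(int))
    mir_vst = vst_like_transform(mirna, size_factors(mirna))
    mrna_vst = vst_like_transform(mrna, size_factors(mrna))
    tumor_cols = mirna.columns[is_tumor]
    network = bootstrap_consensus(
        mir_vst[tumor_cols], mrna_vst[tumor_cols], n_boot=20, seed=1000 + seed
    )
    regulons = build_regulons(network, min_size=3)
    signature = gene_signature(de_mrna)
    calls = score_regulons(regulons, signature, n_null=1000, seed=2000 + seed)
    called = call_master_regulators(calls, fdr_cutoff=0.05)
    lfc = dict(zip(de_mrna["feature"], de_mrna["log2FoldChange"]))
    oa = oa_table([r for r in regulons if r.mirna in set(called)],
                  truth.driver_roles, lfc)
    return {
        "config": cfg,
        "truth": truth,
        "meta": meta,
        "mir_vst": mir_vst,
        "de_mrna": de_mrna,
        "network": network,
        "regulons": regulons,
        "calls": calls,
        "called": called,
        "oa": oa,
    }


@pytest.fixture(scope="session")
def benchmark_run():
    """Factory fixture: benchmark results per seed, cached for the session."""

    def run(seed: int) -> dict:
        if seed not in _BENCH_CACHE:
            _BENCH_CACHE[seed] = _run_benchmark(seed)
        return _BENCH_CACHE[seed]

    return run


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
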