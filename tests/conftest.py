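"""Shared fixtures: cached simulation runs used by several test modules."""

from dataclasses import replace

import numpy as np
import pytest

import herniaqtl as hq
from _utils import analysis_subset


@pytest.fixture(scope="session")
def small_sim():
    """One small but complete four-generation simulation."""
    design = replace(
        hq.desk_design(seed=7), n_f2=120, n_f3_ordinary=60, n_f3_designed=80,
        n_variants=400,
    )
    return hq.simulate_population(design)


@pytest.fixture(scope="session")
def enriched_run():
    """One desk-scale enriched run with the full analysis stack precomputed."""
    result = hq.simulate_population(hq.desk_design(seed=0))
    gt, y, pheno = analysis_subset(result)
    gwas = hq.MixedModelGWAS().fit(gt, y)
    fst = hq.FstScan().fit(gt, np.where(y == 1, "affected", "unaffected"))
    return {
        "result": result,
        "genotypes": gt,
        "y": y,
        "pheno": pheno,
        "gwas": gwas,
        "fst": fst,
        "causal_pos": result.design.causal_position,
    }


def _recovery_one(seed):
    result = hq.simulate_population(hq.desk_design(seed=seed))
    causal_pos = result.design.causal_position
    chrom = str(result.design.causal_chrom)
    gt, y, _ = analysis_subset(result)

    gwas = hq.MixedModelGWAS().fit(gt, y)
    r = gwas.results_
    top = r.loc[r["p_wald"].idxmin()]
    gwas_hit = abs(top["pos"] - causal_pos) <= 2e6

    fst = hq.FstScan().fit(gt, np.where(y == 1, "affected", "unaffected"))
    topf = fst.records_.loc[fst.records_["fst"].idxmax()]
    fst_hit = abs(topf["pos"] - causal_pos) <= 2e6

    ld = hq.LDLAScan().fit(gt, y, G=gwas.K_)
    ldla_hit = ld.interval_.contains(causal_pos)

    pos = gt.variants["pos"].to_numpy()
    ci = int(np.argmin(np.abs(pos - causal_pos)))
    _, still = hq.conditional_scan(gt, y, None, gwas.K_, ci)

    # trace the planted founder haplotype string over +-1 Mb
    interval = (chrom, causal_pos - 1_000_000, causal_pos + 1_000_000)
    founder_id, hap = result.design.founder_q_carriers[0]
    full = result.genotypes
    fi = full.sample_index([founder_id])[0]
    cols = full.variant_range(*interval)
    q_string = tuple(full.haplotypes[fi, hap, cols])
    trace = hq.trace_to_founders(result.pedigree, full, q_string, interval)
    reached = [p for p in trace.paths if p[-1].startswith("F0")]
    to_planted = [p for p in reached if p[-1] == founder_id]

    return {
        "gwas_hit": bool(gwas_hit),
        "fst_hit": bool(fst_hit),
        "ldla_hit": bool(ldla_hit),
        "conditional_cleared": not still,
        "trace_planted": len(to_planted),
        "trace_total": len(reached),
        "incidence": result.truth.incidence,
    }


@pytest.fixture(scope="session")
def recovery_runs():
    """Twenty desk-scale replicates of the full mapping stack."""
    return [_recovery_one(seed) for seed in range(20)]
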