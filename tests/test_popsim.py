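"""Simulator: founder model, meiosis, gene dropping, phenotypes, chip thinning."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import herniaqtl as hq
from herniaqtl.fstscan import fst_per_snp, multilocus_fst
from herniaqtl.popsim import DesignError, SimDesign, simulate_founders


def test_design_validation_errors():
    with pytest.raises(DesignError):
        SimDesign(n_f2=0).validate()
    with pytest.raises(DesignError):
        SimDesign(breed_divergence=1.5).validate()
    with pytest.raises(DesignError):
        SimDesign(causal_position=10**12).validate()
    with pytest.raises(DesignError):
        SimDesign(penetrance_carrier=0.1, penetrance_noncarrier=0.5).validate()


def test_founder_q_allele_forced():
    design = SimDesign(
        n_variants=200, chrom_length_bp=5_000_000, causal_position=2_500_000, seed=3
    )
    gt, ped, causal_idx = simulate_founders(design)
    col = gt.haplotypes[:, :, causal_idx]
    assert col.sum() == 1  # exactly one founder chromosome carries Q
    fi = gt.sample_index(["F0_S1"])[0]
    assert col[fi, 0] == 1
    assert int(gt.variants["pos"].iloc[causal_idx]) == 2_500_000


def test_low_divergence_collapses_breed_frequencies():
    base = dict(
        n_f0_sires=15, n_f0_dams=15, n_variants=400, chrom_length_bp=5_000_000,
        causal_position=2_500_000, seed=5,
    )
    labels = ["A"] * 15 + ["B"] * 15
    fsts = {}
    for div in (0.02, 0.3):
        gt, _, _ = simulate_founders(SimDesign(breed_divergence=div, **base))
        rec = fst_per_snp(gt, labels)
        fsts[div] = multilocus_fst(rec)
    assert fsts[0.02] < 0.08  # near-collapse of the Beta to its mean
    assert fsts[0.02] < fsts[0.3]


def test_divergence_recovered_by_fst_oracle():
    """Balding-Nichols divergence 0.3 is recovered by the multi-locus
    Fst combination across breeds (20 haplotypes per breed, 500 variants)."""
    design = SimDesign(
        n_f0_sires=10, n_f0_dams=10, breed_divergence=0.3, n_variants=500,
        chrom_length_bp=10_000_000, causal_position=5_000_000, seed=42,
    )
    gt, _, _ = simulate_founders(design)
    rec = fst_per_snp(gt, ["A"] * 10 + ["B"] * 10)
    assert abs(multilocus_fst(rec) - 0.3) <= 0.1


def test_meiosis_zero_map_returns_whole_parental_haplotype():
    rng = np.random.default_rng(0)
    variants = pd.DataFrame(
        {"chrom": "1", "pos": [100, 200, 300], "id": list("abc"), "ref": "A", "alt": "C"}
    )
    haps = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
    for _ in range(20):
        g = hq.meiosis(haps, variants, 0.0, rng)
        assert np.array_equal(g, haps[0]) or np.array_equal(g, haps[1])


def test_meiosis_poisson_crossover_mean():
    """A 1-Morgan chromosome yields a mean crossover count of 1 per gamete."""
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.linspace(1, 100_000_000, 200).astype(int),
            "id": [f"v{i}" for i in range(200)],
            "ref": "A",
            "alt": "C",
        }
    )
    haps = np.zeros((2, 200), dtype=np.int8)
    haps[1] = 1
    rng = np.random.default_rng(0)
    total = sum(
        hq.meiosis(haps, variants, 1.0, rng, return_crossovers=True)[1]
        for _ in range(10_000)
    )
    assert abs(total / 10_000 - 1.0) <= 0.05


def test_mendelian_consistency_everywhere(small_sim):
    """Every offspring allele matches one of the transmitting parent's."""
    gt = small_sim.genotypes
    ped = small_sim.pedigree.set_index("id")
    idx = {s: i for i, s in enumerate(gt.samples)}
    h = gt.haplotypes
    for child, row in ped.iterrows():
        if row["sire"] is None:
            continue
        for hap_i, parent in ((0, row["sire"]), (1, row["dam"])):
            par = h[idx[parent]]
            kid = h[idx[child], hap_i]
            assert np.all((kid == par[0]) | (kid == par[1]))


def test_q_copies_match_transmission_audit(small_sim):
    """Recorded Q copies equal the causal-site dosage, and every carrier
    chromosome chains back to the planted founder through carrier parents."""
    gt = small_sim.genotypes
    causal = small_sim.truth.causal_index
    dosage = gt.haplotypes[:, :, causal].sum(axis=1)
    assert np.array_equal(
        dosage, small_sim.truth.q_copies.loc[list(gt.samples)].to_numpy()
    )
    ped = small_sim.pedigree.set_index("id")
    idx = {s: i for i, s in enumerate(gt.samples)}
    carriers = {s for s in gt.samples if dosage[idx[s]] >= 1}
    founder_id, _ = small_sim.design.founder_q_carriers[0]
    for s in carriers:
        walker = s
        for _ in range(10):
            sire, dam = ped.at[walker, "sire"], ped.at[walker, "dam"]
            if sire is None:
                assert walker == founder_id
                break
            parents = [p for p in (sire, dam) if dosage[idx[p]] >= 1]
            assert parents, f"carrier {s} has no carrier parent at {walker}"
            walker = parents[0]


def test_no_full_sib_matings_in_f2_and_ordinary_f3(small_sim):
    ped = small_sim.pedigree.set_index("id")
    for gen in ("F2", "F3-ordinary"):
        for _, row in ped[ped["generation"] == gen].iterrows():
            ps, pd_ = ped.at[row["sire"], "sire"], ped.at[row["sire"], "dam"]
            ms, md = ped.at[row["dam"], "sire"], ped.at[row["dam"], "dam"]
            assert not (ps == ms and pd_ == md)


def test_phenotypes_deterministic_penetrance_limits(small_sim):
    ped = small_sim.pedigree
    q = small_sim.truth.q_copies
    rng = np.random.default_rng(0)
    scored = hq.assign_phenotypes(ped, q, 1.0, 0.0, rng)
    males = scored[(scored["sex"] == "M") & (scored["status"] != "unscored")]
    carrier = q.loc[males["id"]].to_numpy() >= 1
    assert np.array_equal(males["status"].to_numpy() == "affected", carrier)
    assert (scored.loc[scored["sex"] == "F", "status"] == "unscored").all()


def test_phenotype_incidence_within_binomial_band(small_sim):
    """Realized incidence sits in the binomial 95% band around the
    expectation from the realized carrier count."""
    from scipy.stats import binom

    ped = small_sim.pedigree
    q = small_sim.truth.q_copies
    f1, f0 = 0.5, 0.01
    rng = np.random.default_rng(123)
    scored = hq.assign_phenotypes(ped, q, f1, f0, rng)
    males = scored[
        (scored["sex"] == "M") & (scored["generation"] == "F3-designed")
    ]
    carrier = q.loc[males["id"]].to_numpy() >= 1
    n = len(males)
    expect_p = (carrier.sum() * f1 + (~carrier).sum() * f0) / n
    k = int((males["status"] == "affected").sum())
    lo, hi = binom.ppf([0.025, 0.975], n, expect_p)
    assert lo <= k <= hi


def test_null_penetrance_supported():
    """f1 = f0 is a legal (null) design."""
    d = replace(hq.desk_design(seed=4), penetrance_carrier=0.2,
                penetrance_noncarrier=0.2, n_f2=80, n_f3_ordinary=20,
                n_f3_designed=30, n_variants=200)
    res = hq.simulate_population(d)
    assert (res.pedigree["generation"] == "F3-designed").sum() == 30


def test_designed_f3_fails_without_affected_f2():
    d = replace(hq.desk_design(seed=4), penetrance_carrier=1e-12,
                penetrance_noncarrier=0.0, n_f2=50, n_f3_ordinary=5,
                n_f3_designed=5, n_variants=100)
    with pytest.raises(DesignError, match="affected"):
        hq.simulate_population(d)


def test_thin_to_chip_identity_and_subset():
    rng = np.random.default_rng(1)
    from _utils import random_panel

    gt = random_panel(rng, n=5, L=100)
    chip, idx = hq.thin_to_chip(gt, 100, rng)
    assert np.array_equal(chip.haplotypes, gt.haplotypes)
    chip, idx = hq.thin_to_chip(gt, 20, rng)
    assert chip.n_variants == 20
    pos_full = gt.variants["pos"].to_numpy()
    pos_chip = chip.variants["pos"].to_numpy()
    assert np.all(np.isin(pos_chip, pos_full))
    assert np.all(np.diff(pos_chip) > 0)
    with pytest.raises(ValueError):
        hq.thin_to_chip(gt, 1, rng)


def test_thin_to_chip_gap_ratio():
    """500 chip variants out of 10,000: chip spacing ~20x the full spacing."""
    rng = np.random.default_rng(2)
    pos = (np.arange(10_000) + 1) * 10_000  # even sequence-density grid
    haps = np.zeros((2, 2, 10_000), dtype=np.int8)
    from _utils import make_panel

    gt = make_panel(haps, positions=pos)
    chip, _ = hq.thin_to_chip(gt, 500, rng)
    gap_full = np.median(np.diff(pos))
    gap_chip = np.median(np.diff(chip.variants["pos"].to_numpy()))
    assert 0.75 * 20 <= gap_chip / gap_full <= 1.25 * 20


def test_thin_to_chip_causal_membership():
    rng = np.random.default_rng(3)
    from _utils import random_panel

    gt = random_panel(rng, n=4, L=200)
    chip, idx = hq.thin_to_chip(gt, 20, rng, causal_index=101, include_causal=True)
    assert 101 in idx
    chip, idx = hq.thin_to_chip(gt, 20, rng, causal_index=101, include_causal=False)
    assert 101 not in idx and len(idx) == 20


def test_single_seed_determinism(tmp_path):
    design = replace(hq.desk_design(seed=11), n_f2=40, n_f3_ordinary=10,
                     n_f3_designed=10, n_variants=120)
    out = []
    for run in range(2):
        res = hq.simulate_population(design)
        p = tmp_path / f"run{run}.vcf"
        hq.write_vcf(res.genotypes, p)
        out.append(p.read_bytes())
    assert out[0] == out[1]
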