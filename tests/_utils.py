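"""Helpers shared across test modules."""

import numpy as np
import pandas as pd

import herniaqtl as hq


def make_panel(haplotypes, samples=None, positions=None, chrom="1", phased=True):
    """PhasedGenotypes from an (n, 2, L) allele array with default metadata."""
    haplotypes = np.asarray(haplotypes, dtype=np.int8)
    n, _, L = haplotypes.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n)]
    if positions is None:
        positions = (np.arange(L) + 1) * 1000
    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "id": [f"v{j}" for j in range(L)],
            "ref": "A",
            "alt": "C",
        }
    )
    return hq.PhasedGenotypes(variants, haplotypes, samples, phased=phased)


def random_panel(rng, n=20, L=50, freq_low=0.1, freq_high=0.9):
    freqs = rng.uniform(freq_low, freq_high, L)
    haps = (rng.random((n, 2, L)) < freqs).astype(np.int8)
    return make_panel(haps)


def analysis_subset(result):
    """Designed-F3 males with QC-filtered genotypes (the study's GWAS frame)."""
    ped = result.pedigree
    pheno = hq.phenotype_table(ped[ped["generation"] == "F3-designed"])
    gt = result.genotypes.subset_samples(list(pheno["id"]))
    gt, _ = hq.qc_filter(gt)
    return gt, pheno["y"].to_numpy(), pheno
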