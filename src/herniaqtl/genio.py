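"""Genotype/pedigree/phenotype containers, file formats, and QC filters.

Coordinates are 1-based inclusive everywhere (VCF convention); ``COORD_BASE``
documents this single choice. Genotypes are biallelic; the missing-allele
sentinel ``MISSING`` (-1) is distinct from any allele code and maps to ``./.``
in VCF and ``0 0`` in ped files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

#: All genomic coordinates in this package are 1-based inclusive.
COORD_BASE = 1

#: Sentinel for a missing allele, distinct from allele codes 0/1.
MISSING = -1

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]
PEDIGREE_COLUMNS = ["id", "sire", "dam", "sex", "generation", "batch", "status"]

AFFECTED, UNAFFECTED, UNSCORED = "affected", "unaffected", "unscored"


class EmptyPanelError(ValueError):
    """All variants (or all individuals) were removed from a panel."""


class FormatError(ValueError):
    """A genotype file violated its format contract."""


class PhasedGenotypes:
    """Biallelic genotype panel with two haplotypes per individual.

    Parameters
    ----------
    variants : pandas.DataFrame
        Columns ``chrom, pos, id, ref, alt``; positions 1-based and strictly
        increasing within each chromosome.
    haplotypes : ndarray of int8, shape (n_samples, 2, n_variants)
        Allele codes 0 (ref) / 1 (alt) / ``MISSING``.
    samples : sequence of str
    phased : bool
        False when the two allele rows carry no phase information (e.g. read
        from an unphased VCF or a ped file). Phase-requiring stages must check
        this flag.
    """

    def __init__(self, variants, haplotypes, samples, phased=True):
        variants = pd.DataFrame(variants).reset_index(drop=True)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in variants.columns]
        if missing_cols:
            raise ValueError(f"variant table lacks columns {missing_cols}")
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        if haplotypes.ndim != 3 or haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n_samples, 2, n_variants)")
        if haplotypes.shape[2] != len(variants):
            raise ValueError("haplotype length != number of variants")
        if haplotypes.shape[0] != len(samples):
            raise ValueError("haplotype rows != number of samples")
        for chrom, sub in variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise FormatError(f"positions not strictly increasing on {chrom}")
        self.variants = variants
        self.haplotypes = haplotypes
        self.samples = list(samples)
        self.phased = bool(phased)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[2]

    def copy(self) -> "PhasedGenotypes":
        return PhasedGenotypes(
            self.variants.copy(), self.haplotypes.copy(), list(self.samples), self.phased
        )

    def sample_index(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in panel") from exc

    # -- derived matrices ------------------------------------------------
    def genotype_missing(self) -> np.ndarray:
        """Boolean (n_samples, n_variants); True where either allele missing."""
        return np.any(self.haplotypes == MISSING, axis=1)

    def dosages(self, impute_mean: bool = False) -> np.ndarray:
        """Alt-allele dosage matrix (n_samples, n_variants), NaN for missing.

        With ``impute_mean`` missing entries are replaced by twice the
        observed alt-allele frequency (the centered-GRM convention).
        """
        d = self.haplotypes.sum(axis=1).astype(float)
        miss = self.genotype_missing()
        d[miss] = np.nan
        if impute_mean:
            freq = allele_freq(self)["freq"].to_numpy()
            fill = 2.0 * np.where(np.isnan(freq), 0.0, freq)
            idx = np.where(miss)
            d[idx] = fill[idx[1]]
        return d

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, ids_or_index) -> "PhasedGenotypes":
        idx = np.asarray(ids_or_index)
        if idx.dtype.kind not in "iub":
            idx = self.sample_index(idx)
        elif idx.dtype.kind == "b":
            idx = np.flatnonzero(idx)
        return PhasedGenotypes(
            self.variants,
            self.haplotypes[idx],
            [self.samples[i] for i in idx],
            self.phased,
        )

    def subset_variants(self, index) -> "PhasedGenotypes":
        idx = np.asarray(index)
        if idx.dtype.kind == "b":
            idx = np.flatnonzero(idx)
        return PhasedGenotypes(
            self.variants.iloc[idx],
            self.haplotypes[:, :, idx],
            self.samples,
            self.phased,
        )

    def variant_range(self, chrom, start_bp, end_bp) -> np.ndarray:
        """Indices of variants on ``chrom`` with start_bp <= pos <= end_bp."""
        v = self.variants
        mask = (v["chrom"] == chrom) & (v["pos"] >= start_bp) & (v["pos"] <= end_bp)
        return np.flatnonzero(mask.to_numpy())

    def intersect_variants(self, other):
        """Restrict two panels to their shared (chrom, pos) variant set.

        The harmonization step needed before cross-panel haplotype matching
        when generations were genotyped on chips of different density.
        """
        key_self = list(zip(self.variants["chrom"], self.variants["pos"]))
        key_other = set(zip(other.variants["chrom"], other.variants["pos"]))
        keep_self = [i for i, k in enumerate(key_self) if k in key_other]
        kept = set(key_self[i] for i in keep_self)
        keep_other = [
            i
            for i, k in enumerate(zip(other.variants["chrom"], other.variants["pos"]))
            if k in kept
        ]
        return self.subset_variants(np.array(keep_self, int)), other.subset_variants(
            np.array(keep_other, int)
        )

    def merge_samples(self, other) -> "PhasedGenotypes":
        """Stack two panels over identical variant grids."""
        if not self.variants[["chrom", "pos"]].equals(other.variants[["chrom", "pos"]]):
            raise ValueError("variant grids differ; intersect_variants first")
        return PhasedGenotypes(
            self.variants,
            np.concatenate([self.haplotypes, other.haplotypes], axis=0),
            self.samples + other.samples,
            self.phased and other.phased,
        )


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_freq(genotypes: PhasedGenotypes, subset=None) -> pd.DataFrame:
    """Per-variant alt-allele frequency and MAF from observed alleles only.

    Returns a DataFrame with ``freq`` (alt alleles / non-missing alleles),
    ``maf``, ``n_called`` (non-missing allele count). Variants with every
    allele missing get NaN frequency and are flagged in ``all_missing``.
    """
    gt = genotypes if subset is None else genotypes.subset_samples(subset)
    if gt.n_samples == 0:
        raise ValueError("subset is empty")
    h = gt.haplotypes
    called = h != MISSING
    n_called = called.sum(axis=(0, 1))
    alt = np.where(called, h, 0).sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / np.maximum(n_called, 1), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame(
        {
            "freq": freq,
            "maf": maf,
            "n_called": n_called,
            "all_missing": n_called == 0,
        },
        index=gt.variants.index,
    )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QcReport:
    """Exact bookkeeping of one qc_filter pass."""

    n_variants_before: int
    n_variants_after: int
    n_samples_before: int
    n_samples_after: int
    removed_no_position: int = 0
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_indiv_missing: int = 0

    def __post_init__(self):
        assert self.n_variants_before == (
            self.n_variants_after
            + self.removed_no_position
            + self.removed_call_rate
            + self.removed_maf
        )
        assert self.n_samples_before == self.n_samples_after + self.removed_indiv_missing


def qc_filter(
    genotypes: PhasedGenotypes,
    maf_min: float = 0.01,
    variant_call_rate_min: float = 0.90,
    indiv_missing_max: float = 0.10,
):
    """Apply the chip QC rules: drop individuals with more than
    ``indiv_missing_max`` missing genotypes first, then drop variants with an
    unspecified position, call rate below ``variant_call_rate_min``, or MAF
    below ``maf_min`` — variant statistics recomputed on the retained
    individuals (PLINK's conventional order).

    Returns ``(filtered_panel, QcReport)``; raises :class:`EmptyPanelError`
    if nothing survives on either axis.
    """
    for t in (maf_min, variant_call_rate_min, indiv_missing_max):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    n_var0, n_samp0 = genotypes.n_variants, genotypes.n_samples

    miss = genotypes.genotype_missing()
    indiv_rate = miss.mean(axis=1) if n_var0 else np.zeros(n_samp0)
    keep_samp = indiv_rate <= indiv_missing_max
    removed_indiv = int((~keep_samp).sum())
    for i in np.flatnonzero(~keep_samp):
        log.debug(
            "removing individual %s: missingness %.3f > %.3f",
            genotypes.samples[i], indiv_rate[i], indiv_missing_max,
        )
    if not keep_samp.any():
        raise EmptyPanelError("all individuals removed by missingness filter")
    gt = genotypes.subset_samples(keep_samp)

    pos_ok = gt.variants["pos"].to_numpy() > 0
    removed_pos = int((~pos_ok).sum())

    freq = allele_freq(gt)
    call_rate = freq["n_called"].to_numpy() / (2 * gt.n_samples)
    cr_ok = call_rate >= variant_call_rate_min
    removed_cr = int((pos_ok & ~cr_ok).sum())

    maf = freq["maf"].to_numpy()
    maf_ok = ~np.isnan(maf) & (maf >= maf_min)
    removed_maf = int((pos_ok & cr_ok & ~maf_ok).sum())

    keep_var = pos_ok & cr_ok & maf_ok
    if log.isEnabledFor(logging.DEBUG):
        for j in np.flatnonzero(~keep_var):
            reason = (
                "no position" if not pos_ok[j]
                else f"call rate {call_rate[j]:.3f}" if not cr_ok[j]
                else f"MAF {maf[j]:.4f}"
            )
            log.debug("removing variant %s: %s", gt.variants["id"].iloc[j], reason)
    if not keep_var.any():
        raise EmptyPanelError("all variants removed by QC")
    gt = gt.subset_variants(keep_var)

    report = QcReport(
        n_variants_before=n_var0,
        n_variants_after=gt.n_variants,
        n_samples_before=n_samp0,
        n_samples_after=gt.n_samples,
        removed_no_position=removed_pos,
        removed_call_rate=removed_cr,
        removed_maf=removed_maf,
        removed_indiv_missing=removed_indiv,
    )
    return gt, report


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

def phenotype_table(pedigree: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Binary phenotype table (id, y, sex, batch) from scored pedigree rows.

    Only individuals with a scored affection status enter; ``y`` is 1 for
    affected, 0 for unaffected. When ``samples`` is given, every phenotyped id
    must exist in it and rows are ordered to match.
    """
    ped = pedigree[pedigree["status"].isin([AFFECTED, UNAFFECTED])]
    tab = pd.DataFrame(
        {
            "id": ped["id"].to_numpy(),
            "y": (ped["status"] == AFFECTED).astype(int).to_numpy(),
            "sex": ped["sex"].to_numpy(),
            "batch": ped["batch"].to_numpy(),
        }
    )
    if samples is not None:
        order = {s: i for i, s in enumerate(samples)}
        unknown = [i for i in tab["id"] if i not in order]
        if unknown:
            raise ValueError(f"phenotyped ids missing from genotype panel: {unknown[:5]}")
        tab = tab.sort_values("id", key=lambda c: c.map(order)).reset_index(drop=True)
    return tab


def validate_pedigree(pedigree: pd.DataFrame) -> None:
    """Structural audit: parents exist with the right sex, founders have no
    parents, the graph is acyclic, and only males carry a scored status."""
    ped = pedigree.set_index("id")
    sex = ped["sex"].to_dict()
    for col in ("sire", "dam"):
        want = "M" if col == "sire" else "F"
        for child, parent in ped[col].items():
            if parent is None or (isinstance(parent, float) and np.isnan(parent)):
                continue
            if parent not in ped.index:
                raise ValueError(f"{col} {parent!r} of {child!r} not in pedigree")
            if sex[parent] != want:
                raise ValueError(f"{col} {parent!r} has sex {sex[parent]!r}")
    scored = ped[ped["status"].isin([AFFECTED, UNAFFECTED])]
    if (scored["sex"] != "M").any():
        raise ValueError("trait is scored in males only")
    # acyclicity via generation-free topological walk
    order: dict = {}

    def depth(i, seen):
        if i in order:
            return order[i]
        if i in seen:
            raise ValueError(f"pedigree cycle involving {i!r}")
        seen.add(i)
        d = 0
        for p in (ped.at[i, "sire"], ped.at[i, "dam"]):
            if p is not None and not (isinstance(p, float) and np.isnan(p)) and p in ped.index:
                d = max(d, depth(p, seen) + 1)
        order[i] = d
        return d

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, len(ped) + 100))
    try:
        for i in ped.index:
            depth(i, set())
    finally:
        sys.setrecursionlimit(old)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(genotypes: PhasedGenotypes, path) -> None:
    """Write a minimal GT-only VCF; ``|`` separator when phased, ``/`` else."""
    sep = "|" if genotypes.phased else "/"
    v = genotypes.variants
    contigs = v.groupby("chrom", sort=False)["pos"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=herniaqtl\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={int(length) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        haps = genotypes.haplotypes
        for j in range(genotypes.n_variants):
            row = v.iloc[j]
            calls = []
            for i in range(genotypes.n_samples):
                a, b = haps[i, 0, j], haps[i, 1, j]
                sa = "." if a == MISSING else str(int(a))
                sb = "." if b == MISSING else str(int(b))
                calls.append(f"{sa}{sep}{sb}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> PhasedGenotypes:
    """Read a biallelic VCF via cyvcf2.

    Unphased records are accepted; the panel's ``phased`` flag drops to False
    as soon as any non-missing call lacks phase, so phase-requiring stages can
    reject the panel.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, haps = [], []
    phased = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} (biallelic panels only)"
            )
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "id": rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}",
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        col = np.full((len(samples), 2), MISSING, dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            a, b, ph = g[0], g[1], bool(g[2])
            col[i, 0] = MISSING if a < 0 else a
            col[i, 1] = MISSING if b < 0 else b
            if (a >= 0 or b >= 0) and not ph:
                phased = False
        haps.append(col)
    if not rows:
        raise EmptyPanelError(f"no variant records in {path}")
    variants = pd.DataFrame(rows)
    hap = np.stack(haps, axis=2)  # (n, 2, L)
    return PhasedGenotypes(variants, hap, samples, phased=phased)


# ---------------------------------------------------------------------------
# PLINK-style ped/map
# ---------------------------------------------------------------------------

def write_ped_map(genotypes: PhasedGenotypes, prefix, pedigree: pd.DataFrame = None):
    """Write ``prefix.ped`` / ``prefix.map`` with literal ref/alt allele codes.

    Family/parent/sex/phenotype columns come from ``pedigree`` when supplied,
    else placeholders. The ped format is unphased by convention.
    """
    v = genotypes.variants
    with open(f"{prefix}.map", "w") as fh:
        for _, row in v.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{int(row['pos'])}\n")
    ped_info = None
    if pedigree is not None:
        ped_info = pedigree.set_index("id")
    ref = v["ref"].to_numpy()
    alt = v["alt"].to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for i, s in enumerate(genotypes.samples):
            if ped_info is not None and s in ped_info.index:
                row = ped_info.loc[s]
                sire = row["sire"] if pd.notna(row["sire"]) else "0"
                dam = row["dam"] if pd.notna(row["dam"]) else "0"
                sex = "1" if row["sex"] == "M" else "2"
                status = {AFFECTED: "2", UNAFFECTED: "1"}.get(row["status"], "0")
            else:
                sire = dam = "0"
                sex = "0"
                status = "0"
            fields = ["FAM1", s, str(sire), str(dam), sex, status]
            h = genotypes.haplotypes[i]
            for j in range(genotypes.n_variants):
                a, b = h[0, j], h[1, j]
                fields.append("0" if a == MISSING else (ref[j] if a == 0 else alt[j]))
                fields.append("0" if b == MISSING else (ref[j] if b == 0 else alt[j]))
            fh.write(" ".join(fields) + "\n")


def read_ped_map(prefix, ref_alt: pd.DataFrame = None) -> PhasedGenotypes:
    """Read ``prefix.ped`` / ``prefix.map``; the result is flagged unphased.

    ``ref_alt`` (a variant table with ``ref``/``alt`` columns) pins the allele
    coding; without it the lexicographically smaller observed allele is taken
    as ref ('N' for the unobserved allele of a monomorphic variant).
    """
    variants = pd.read_csv(
        f"{prefix}.map", sep=r"\s+", header=None, names=["chrom", "id", "cm", "pos"]
    )
    n_var = len(variants)
    samples, rows = [], []
    with open(f"{prefix}.ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_var:
                raise FormatError(f"{prefix}.ped line {ln}: expected {6 + 2 * n_var} fields")
            samples.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows).reshape(len(samples), n_var, 2)
    if ref_alt is not None:
        ref = np.asarray(ref_alt["ref"], dtype=object)
        alt = np.asarray(ref_alt["alt"], dtype=object)
    else:
        ref = np.empty(n_var, dtype=object)
        alt = np.empty(n_var, dtype=object)
        for j in range(n_var):
            seen = sorted(set(alleles[:, j, :].ravel()) - {"0"})
            ref[j] = seen[0] if seen else "N"
            alt[j] = seen[1] if len(seen) > 1 else "N"
    hap = np.full((len(samples), 2, n_var), MISSING, dtype=np.int8)
    for j in range(n_var):
        for k in range(2):
            col = alleles[:, j, k]
            hap[col == ref[j], k, j] = 0
            hap[col == alt[j], k, j] = 1
            bad = ~np.isin(col, ["0", ref[j], alt[j]])
            if bad.any():
                raise FormatError(
                    f"{prefix}.ped: unexpected allele {col[bad][0]!r} at variant "
                    f"{variants['id'].iloc[j]!r} (line {int(np.flatnonzero(bad)[0]) + 1})"
                )
    table = pd.DataFrame(
        {
            "chrom": variants["chrom"].astype(str),
            "pos": variants["pos"].astype(int),
            "id": variants["id"].astype(str),
            "ref": ref,
            "alt": alt,
        }
    )
    return PhasedGenotypes(table, hap, samples, phased=False)


# ---------------------------------------------------------------------------
# pedigree / truth tables
# ---------------------------------------------------------------------------

def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype={"id": str}, na_values=["NA"])
    for col in ("sire", "dam"):
        ped[col] = ped[col].where(pd.notna(ped[col]), None)
    return ped[PEDIGREE_COLUMNS]
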