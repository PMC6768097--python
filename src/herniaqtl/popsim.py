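"""Gene-dropping simulator of a four-generation pig resource population.

The simulated design mirrors a White Duroc x Erhualian intercross: a handful
of F0 boars from one breed and sows from the other, an F1, a large F2 bred in
batches while avoiding full-sib matings, and two F3 cohorts — an ordinary
random-mated one and a "designed" one whose matings involve unaffected full-
or half-sibs of affected F2 males, enriching the frequency of a planted
susceptibility haplotype (Q) and with it the incidence of the binary,
male-only trait.

Founder haplotypes are drawn under the Balding–Nichols model: each variant
gets an ancestral frequency uniform on [0.05, 0.95] and each breed a
Beta-distributed frequency whose spread is governed by an Fst-like divergence
parameter. Disease risk is a dominant single-locus incomplete-penetrance
model: males carrying at least one Q copy are affected with probability
``penetrance_carrier`` (f1), non-carriers with ``penetrance_noncarrier`` (f0).
Females are generated for mating but never scored.

Transmission is Mendelian gene dropping with a Haldane (no-interference)
crossover process at a fixed 1 cM/Mb map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genio import (
    AFFECTED,
    PEDIGREE_COLUMNS,
    UNAFFECTED,
    UNSCORED,
    PhasedGenotypes,
)


class DesignError(ValueError):
    """The requested population cannot be constructed (e.g. no affected F2)."""


@dataclass(frozen=True)
class SimDesign:
    """Parameters of one simulated resource population.

    Defaults follow the published design: 2 F0 sires x 17 dams, 9 F1 boars and
    59 sows, 1,912 F2 in 6 batches, 661 ordinary and 851 designed F3.
    """

    n_f0_sires: int = 2
    n_f0_dams: int = 17
    n_f1_males: int = 9
    n_f1_females: int = 59
    n_f2: int = 1912
    n_f3_ordinary: int = 661
    n_f3_designed: int = 851
    n_chromosomes: int = 1
    chrom_length_bp: int = 140_000_000
    n_variants: int = 2000
    breed_divergence: float = 0.3
    causal_chrom: int = 1
    causal_position: int = 70_000_000
    penetrance_carrier: float = 0.5
    penetrance_noncarrier: float = 0.005
    founder_q_carriers: tuple = (("F0_S1", 0),)
    map_cM_per_Mb: float = 1.0
    n_batches: int = 6
    #: restrict designed-F3 qualifying relatives: 'any', 'full', or 'half'
    designed_sib_type: str = "any"
    #: extra same-breed individuals outside the pedigree (generation "REF"),
    #: emulating a diverse sequenced reference panel unrelated to the cross
    n_reference_per_breed: int = 0
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_f0_sires,
            self.n_f0_dams,
            self.n_f1_males,
            self.n_f1_females,
            self.n_f2,
            self.n_f3_ordinary,
            self.n_f3_designed,
            self.n_chromosomes,
            self.n_variants,
            self.n_batches,
        )
        if any(c < 1 for c in counts):
            raise DesignError("all design counts must be >= 1")
        if not 0.0 < self.breed_divergence < 1.0:
            raise DesignError("breed_divergence must lie in (0, 1)")
        f0, f1 = self.penetrance_noncarrier, self.penetrance_carrier
        if not 0.0 <= f0 < f1 <= 1.0 and not (0.0 <= f0 == f1 <= 1.0):
            if not (0.0 <= f0 <= f1 <= 1.0):
                raise DesignError("penetrances must satisfy 0 <= f0 <= f1 <= 1")
        if not (1 <= self.causal_chrom <= self.n_chromosomes):
            raise DesignError("causal_chrom outside the simulated genome")
        if not (1 <= self.causal_position <= self.chrom_length_bp):
            raise DesignError("causal_position outside the chromosome")
        if self.designed_sib_type not in ("any", "full", "half"):
            raise DesignError("designed_sib_type must be 'any', 'full' or 'half'")


def desk_design(seed: int = 0) -> SimDesign:
    """Workstation-scale study design used throughout evaluation.

    One SSC8-like 140-Mb chromosome with 2,000 variants, 2 sires x 8 dams,
    300 F2, 200 ordinary F3 and 520 designed F3 (~250 designed-F3 males),
    causal locus at 70 Mb, penetrances f1=0.5 / f0=0.01.
    """
    return SimDesign(
        n_f0_dams=8,
        n_f1_males=8,
        n_f1_females=24,
        n_f2=300,
        n_f3_ordinary=200,
        n_f3_designed=520,
        penetrance_carrier=0.5,
        penetrance_noncarrier=0.01,
        seed=seed,
    )


@dataclass
class TruthRecord:
    """Ground truth carried alongside a simulated population."""

    causal_index: int
    q_founder_haplotypes: tuple
    q_copies: pd.Series  # per-individual 0/1/2
    incidence: dict  # generation label -> realized incidence among scored males


@dataclass
class SimResult:
    design: SimDesign
    genotypes: PhasedGenotypes
    pedigree: pd.DataFrame
    truth: TruthRecord


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def _variant_grid(design: SimDesign, rng: np.random.Generator) -> pd.DataFrame:
    per_chrom = np.full(design.n_chromosomes, design.n_variants // design.n_chromosomes)
    per_chrom[: design.n_variants % design.n_chromosomes] += 1
    rows = []
    for c in range(1, design.n_chromosomes + 1):
        n = int(per_chrom[c - 1])
        pos = np.array([], dtype=np.int64)
        while len(pos) < n:  # rejection-free enough: collisions are negligible
            draw = rng.integers(1, design.chrom_length_bp + 1, size=2 * n)
            pos = np.unique(np.concatenate([pos, draw]))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        if c == design.causal_chrom:
            # plant the causal site exactly at its design coordinate
            j = int(np.argmin(np.abs(pos - design.causal_position)))
            pos[j] = design.causal_position
            pos = np.sort(np.unique(pos))
            while len(pos) < n:  # repair collisions from the replacement
                extra = rng.integers(1, design.chrom_length_bp + 1, size=n)
                pos = np.sort(np.unique(np.concatenate([pos, extra])))[:n]
                if design.causal_position not in pos:
                    pos[-1] = design.causal_position
                    pos = np.sort(pos)
        rows.append(
            pd.DataFrame(
                {
                    "chrom": str(c),
                    "pos": pos.astype(np.int64),
                    "id": [f"snp_{c}_{p}" for p in pos],
                    "ref": "A",
                    "alt": "C",
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_founders(design: SimDesign, rng: np.random.Generator = None):
    """Draw F0 haplotypes under Balding–Nichols breed divergence.

    Sires come from breed 1 (Duroc-like), dams from breed 2 (Erhualian-like).
    The designated ``founder_q_carriers`` haplotypes are forced to carry the
    alt (Q) allele at the causal variant; every other founder haplotype is
    forced to the ref allele, so the causal alt allele marks the planted
    haplotype uniquely.
    """
    design.validate()
    if rng is None:
        rng = np.random.default_rng(design.seed)
    variants = _variant_grid(design, rng)
    L = len(variants)
    p_anc = rng.uniform(0.05, 0.95, size=L)
    F = design.breed_divergence
    shape = (1.0 - F) / F
    breed_p = np.stack(
        [rng.beta(p_anc * shape, (1.0 - p_anc) * shape) for _ in range(2)]
    )

    sires = [f"F0_S{i + 1}" for i in range(design.n_f0_sires)]
    dams = [f"F0_D{i + 1}" for i in range(design.n_f0_dams)]
    nref = design.n_reference_per_breed
    refs = [f"REF_A{i + 1}" for i in range(nref)] + [f"REF_B{i + 1}" for i in range(nref)]
    samples = sires + dams + refs
    breed_of = np.array([0] * len(sires) + [1] * len(dams) + [0] * nref + [1] * nref)
    hap = (
        rng.random((len(samples), 2, L)) < breed_p[breed_of][:, None, :]
    ).astype(np.int8)

    causal_idx = int(
        np.flatnonzero(
            (variants["chrom"] == str(design.causal_chrom))
            & (variants["pos"] == design.causal_position)
        )[0]
    )
    hap[:, :, causal_idx] = 0
    index = {s: i for i, s in enumerate(samples)}
    for fid, h in design.founder_q_carriers:
        if fid not in index:
            raise DesignError(f"founder_q_carriers names unknown founder {fid!r}")
        hap[index[fid], h, causal_idx] = 1

    genotypes = PhasedGenotypes(variants, hap, samples, phased=True)
    pedigree = pd.DataFrame(
        {
            "id": samples,
            "sire": None,
            "dam": None,
            "sex": ["M"] * len(sires) + ["F"] * (len(dams) + len(refs)),
            "generation": ["F0"] * (len(sires) + len(dams)) + ["REF"] * len(refs),
            "batch": "-",
            "status": UNSCORED,
        }
    )[PEDIGREE_COLUMNS]
    return genotypes, pedigree, causal_idx


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def _chrom_layout(variants: pd.DataFrame, map_cM_per_Mb: float):
    """Per-chromosome (index array, positions, map length in Morgans)."""
    layout = []
    for _, sub in variants.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        span_bp = pos[-1] - pos[0] if len(pos) > 1 else 0
        layout.append((idx, pos, span_bp * map_cM_per_Mb / 100.0 / 1e6))
    return layout


def meiosis(
    parent_haps: np.ndarray,
    variants: pd.DataFrame,
    map_cM_per_Mb: float,
    rng: np.random.Generator,
    return_crossovers: bool = False,
    _layout=None,
):
    """One gamete from a parent's two phased haplotypes.

    Crossover counts are Poisson with mean equal to the chromosome map length
    in Morgans (Haldane, no interference); breakpoint positions are uniform.
    Every gamete allele equals one of the two parental alleles at that site.
    """
    gamete = np.empty(parent_haps.shape[1], dtype=np.int8)
    total_xo = 0
    layout = _layout if _layout is not None else _chrom_layout(variants, map_cM_per_Mb)
    for idx, pos, morgans in layout:
        k = rng.poisson(morgans) if morgans > 0 else 0
        total_xo += k
        start = int(rng.integers(0, 2))
        if k == 0:
            gamete[idx] = parent_haps[start, idx]
            continue
        breaks = np.sort(rng.uniform(pos[0], pos[-1], size=k))
        which = (start + np.searchsorted(breaks, pos, side="right")) % 2
        gamete[idx] = parent_haps[which, idx]
    if return_crossovers:
        return gamete, total_xo
    return gamete


# ---------------------------------------------------------------------------
# phenotype assignment
# ---------------------------------------------------------------------------

def assign_phenotypes(
    pedigree: pd.DataFrame,
    q_copies: pd.Series,
    f1: float,
    f0: float,
    rng: np.random.Generator,
    generations=("F2", "F3-ordinary", "F3-designed"),
) -> pd.DataFrame:
    """Score males in the given generations under the dominant penetrance
    model: affected with probability ``f1`` if Q copies >= 1, else ``f0``.
    Females remain unscored."""
    if not (0.0 <= f0 <= 1.0 and 0.0 <= f1 <= 1.0):
        raise ValueError("penetrances must lie in [0, 1]")
    ped = pedigree.copy()
    mask = (ped["sex"] == "M") & ped["generation"].isin(generations)
    ids = ped.loc[mask, "id"]
    carrier = q_copies.loc[ids].to_numpy() >= 1
    prob = np.where(carrier, f1, f0)
    affected = rng.random(len(ids)) < prob
    ped.loc[mask, "status"] = np.where(affected, AFFECTED, UNAFFECTED)
    return ped


# ---------------------------------------------------------------------------
# generations
# ---------------------------------------------------------------------------

def _full_sibs(ped_lookup, a, b) -> bool:
    sa, da = ped_lookup[a]
    sb, db = ped_lookup[b]
    return sa is not None and sa == sb and da is not None and da == db


def _shares_parent(ped_lookup, a, b) -> bool:
    sa, da = ped_lookup[a]
    sb, db = ped_lookup[b]
    return (sa is not None and sa == sb) or (da is not None and da == db)


def build_generations(
    design: SimDesign,
    founders: PhasedGenotypes,
    founder_ped: pd.DataFrame,
    causal_idx: int,
    rng: np.random.Generator,
) -> SimResult:
    """Gene-drop F1, F2 and both F3 cohorts from the founders.

    F2 parents are non-full-sib F1 pairs; F2 batch labels cycle round-robin
    over ``n_batches``. F2 males are phenotyped before F3 construction so the
    designed cohort can be mated from unaffected full- or half-sibs of
    affected F2 males (partner drawn at random). Raises :class:`DesignError`
    when no affected F2 male exists — callers may raise penetrance or reseed.
    """
    design.validate()
    variants = founders.variants
    L = founders.n_variants
    rows = [founder_ped]
    hap_blocks = [founders.haplotypes]
    samples = list(founders.samples)
    index = {s: i for i, s in enumerate(samples)}

    layout = _chrom_layout(variants, design.map_cM_per_Mb)

    def drop_child(cid, sire, dam, sex, generation, batch):
        child = np.empty((1, 2, L), dtype=np.int8)
        child[0, 0] = meiosis(
            all_haps[index[sire]], variants, design.map_cM_per_Mb, rng, _layout=layout
        )
        child[0, 1] = meiosis(
            all_haps[index[dam]], variants, design.map_cM_per_Mb, rng, _layout=layout
        )
        return child, {
            "id": cid,
            "sire": sire,
            "dam": dam,
            "sex": sex,
            "generation": generation,
            "batch": batch,
            "status": UNSCORED,
        }

    def grow(block, new_rows):
        nonlocal all_haps
        hap_blocks.append(block)
        all_haps = np.concatenate(hap_blocks, axis=0)
        hap_blocks[:] = [all_haps]
        for r in new_rows:
            index[r["id"]] = len(samples)
            samples.append(r["id"])
        rows.append(pd.DataFrame(new_rows))

    all_haps = founders.haplotypes

    # ---- F1 ----
    f0 = founder_ped[founder_ped["generation"] == "F0"]
    sires = f0.loc[f0["sex"] == "M", "id"].tolist()
    dams = f0.loc[f0["sex"] == "F", "id"].tolist()
    f1_rows, f1_block = [], []
    n_f1 = design.n_f1_males + design.n_f1_females
    for i in range(n_f1):
        sex = "M" if i < design.n_f1_males else "F"
        s = sires[int(rng.integers(len(sires)))]
        d = dams[int(rng.integers(len(dams)))]
        block, row = drop_child(f"F1_{i + 1}", s, d, sex, "F1", "-")
        f1_block.append(block)
        f1_rows.append(row)
    grow(np.concatenate(f1_block), f1_rows)

    ped_lookup = {
        r["id"]: (r["sire"], r["dam"]) for df in rows for r in df.to_dict("records")
    }

    # ---- F2 ----
    f1_males = [r["id"] for r in f1_rows if r["sex"] == "M"]
    f1_females = [r["id"] for r in f1_rows if r["sex"] == "F"]
    if design.n_f2 and not (f1_males and f1_females):
        raise DesignError("need F1 of both sexes to breed F2")
    f2_rows, f2_block = [], []
    for i in range(design.n_f2):
        for _ in range(1000):
            s = f1_males[int(rng.integers(len(f1_males)))]
            d = f1_females[int(rng.integers(len(f1_females)))]
            if not _full_sibs(ped_lookup, s, d):
                break
        else:
            raise DesignError("could not find a non-full-sib F1 pair")
        sex = "M" if rng.random() < 0.5 else "F"
        batch = f"b{i % design.n_batches + 1}"
        block, row = drop_child(f"F2_{i + 1}", s, d, sex, "F2", batch)
        f2_block.append(block)
        f2_rows.append(row)
        ped_lookup[row["id"]] = (s, d)
    grow(np.concatenate(f2_block), f2_rows)

    pedigree = pd.concat(rows, ignore_index=True)[PEDIGREE_COLUMNS]
    q_copies = pd.Series(
        all_haps[:, :, causal_idx].sum(axis=1), index=pd.Index(samples, name="id")
    )
    pedigree = assign_phenotypes(
        pedigree,
        q_copies,
        design.penetrance_carrier,
        design.penetrance_noncarrier,
        rng,
        generations=("F2",),
    )
    status = pedigree.set_index("id")["status"]

    # ---- F3 ordinary ----
    f2_males = [r["id"] for r in f2_rows if r["sex"] == "M"]
    f2_females = [r["id"] for r in f2_rows if r["sex"] == "F"]
    if design.n_f3_ordinary and not (f2_males and f2_females):
        raise DesignError("need F2 of both sexes to breed F3")
    f3o_rows, f3o_block = [], []
    for i in range(design.n_f3_ordinary):
        for _ in range(1000):
            s = f2_males[int(rng.integers(len(f2_males)))]
            d = f2_females[int(rng.integers(len(f2_females)))]
            if not _full_sibs(ped_lookup, s, d):
                break
        else:
            raise DesignError("could not find a non-full-sib F2 pair")
        sex = "M" if rng.random() < 0.5 else "F"
        block, row = drop_child(f"F3O_{i + 1}", s, d, sex, "F3-ordinary", "-")
        f3o_block.append(block)
        f3o_rows.append(row)

    # ---- F3 designed ----
    affected_f2 = [
        r["id"] for r in f2_rows if r["sex"] == "M" and status[r["id"]] == AFFECTED
    ]
    if design.n_f3_designed and not affected_f2:
        raise DesignError(
            "no affected F2 male: the designed F3 cohort cannot be constructed "
            "(raise penetrance or reseed)"
        )

    def qualifies(cand, case) -> bool:
        if cand == case or status[cand] == AFFECTED:
            return False
        full = _full_sibs(ped_lookup, cand, case)
        shared = _shares_parent(ped_lookup, cand, case)
        if design.designed_sib_type == "full":
            return full
        if design.designed_sib_type == "half":
            return shared and not full
        return shared

    # per-affected sib pools: the designed matings deliberately pair relatives
    # of affected males, so each parent is drawn by first picking an affected
    # male, then one of HIS unaffected sibs. With sib_type 'any', full sibs
    # (the affected male's own litter, the strongest expected enrichment) are
    # preferred and half sibs are the fallback.
    def pool_for(case):
        pool = sorted(c["id"] for c in f2_rows if qualifies(c["id"], case))
        if design.designed_sib_type == "any":
            full = [c for c in pool if _full_sibs(ped_lookup, c, case)]
            if full:
                return full
        return pool

    sib_pool = {case: pool_for(case) for case in affected_f2}
    cases_with_sibs = [c for c in affected_f2 if sib_pool[c]]
    if design.n_f3_designed and not cases_with_sibs:
        raise DesignError("no unaffected sib of an affected F2 male qualifies")
    sex_of = {r["id"]: r["sex"] for r in f2_rows}

    def draw_designed_parent():
        case = cases_with_sibs[int(rng.integers(len(cases_with_sibs)))]
        pool = sib_pool[case]
        return pool[int(rng.integers(len(pool)))]

    f3d_rows, f3d_block = [], []
    for i in range(design.n_f3_designed):
        q = draw_designed_parent()
        # second parent: another affected male's sib of the opposite sex,
        # falling back to a random F2 partner when none turns up
        p = None
        for _ in range(200):
            cand = draw_designed_parent()
            if cand != q and sex_of[cand] != sex_of[q]:
                p = cand
                break
        if p is None:
            partners = f2_females if sex_of[q] == "M" else f2_males
            for _ in range(1000):
                cand = partners[int(rng.integers(len(partners)))]
                if cand != q:
                    p = cand
                    break
        s, d = (q, p) if sex_of[q] == "M" else (p, q)
        sex = "M" if rng.random() < 0.5 else "F"
        block, row = drop_child(f"F3D_{i + 1}", s, d, sex, "F3-designed", "-")
        f3d_block.append(block)
        f3d_rows.append(row)

    grow(np.concatenate(f3o_block + f3d_block), f3o_rows + f3d_rows)
    pedigree = pd.concat(
        [pedigree, pd.DataFrame(f3o_rows + f3d_rows)], ignore_index=True
    )[PEDIGREE_COLUMNS]

    q_copies = pd.Series(
        all_haps[:, :, causal_idx].sum(axis=1), index=pd.Index(samples, name="id")
    )
    pedigree = assign_phenotypes(
        pedigree,
        q_copies,
        design.penetrance_carrier,
        design.penetrance_noncarrier,
        rng,
        generations=("F3-ordinary", "F3-designed"),
    )

    incidence = {}
    for gen in ("F2", "F3-ordinary", "F3-designed"):
        scored = pedigree[
            (pedigree["generation"] == gen) & (pedigree["sex"] == "M")
        ]["status"]
        n = (scored != UNSCORED).sum()
        incidence[gen] = float((scored == AFFECTED).sum() / n) if n else float("nan")

    genotypes = PhasedGenotypes(variants, all_haps, samples, phased=True)
    truth = TruthRecord(
        causal_index=causal_idx,
        q_founder_haplotypes=tuple(design.founder_q_carriers),
        q_copies=q_copies,
        incidence=incidence,
    )
    return SimResult(design, genotypes, pedigree, truth)


def simulate_population(design: SimDesign) -> SimResult:
    """Run the full simulation from a single seed (founders -> F3)."""
    rng = np.random.default_rng(design.seed)
    founders, founder_ped, causal_idx = simulate_founders(design, rng)
    return build_generations(design, founders, founder_ped, causal_idx, rng)


# ---------------------------------------------------------------------------
# chip thinning
# ---------------------------------------------------------------------------

def thin_to_chip(
    genotypes: PhasedGenotypes,
    n_chip_variants: int,
    rng: np.random.Generator,
    causal_index: int = None,
    include_causal: bool = True,
):
    """Thin a sequence-density panel to an evenly-spaced-with-jitter chip.

    Returns ``(chip_panel, chip_indices)``; the full panel is left untouched
    as the sequence reference. ``include_causal`` controls whether the causal
    variant is forced onto / off the chip.
    """
    L = genotypes.n_variants
    if n_chip_variants < 2:
        raise ValueError("a chip needs at least 2 variants")
    if n_chip_variants > L:
        raise ValueError("n_chip_variants exceeds panel size")
    base = np.linspace(0, L - 1, n_chip_variants)
    spacing = (L - 1) / max(n_chip_variants - 1, 1)
    jitter = rng.uniform(-0.4, 0.4, size=n_chip_variants) * spacing
    idx = np.clip(np.round(base + jitter).astype(int), 0, L - 1)
    idx = np.unique(idx)
    # repair duplicates from rounding so the chip keeps its size
    missing = n_chip_variants - len(idx)
    if missing > 0:
        pool = np.setdiff1d(np.arange(L), idx)
        idx = np.sort(np.concatenate([idx, pool[:missing]]))
    if causal_index is not None:
        if include_causal and causal_index not in idx:
            drop = int(np.argmin(np.abs(idx - causal_index)))
            idx[drop] = causal_index
            idx = np.sort(idx)
        elif not include_causal and causal_index in idx:
            pool = np.setdiff1d(np.arange(L), idx)
            idx = np.sort(np.append(idx[idx != causal_index], pool[:1]))
    return genotypes.subset_variants(idx), idx


# ---------------------------------------------------------------------------
# truth re-derivation oracle support
# ---------------------------------------------------------------------------

def recompute_q_copies(result: SimResult) -> pd.Series:
    """Q copy number read off the transmitted haplotypes.

    Because the causal alt allele exists only on the planted founder
    haplotype(s), a chromosome carries Q exactly when its causal-site allele
    is 1; IBS at that site equals IBD with the planted haplotype. A full
    transmission audit (every carrier chromosome chains to the planted
    founder through carrier parents) complements this check.
    """
    gt = result.genotypes
    causal = result.truth.causal_index
    copies = gt.haplotypes[:, :, causal].sum(axis=1)
    return pd.Series(copies, index=pd.Index(gt.samples, name="id"))
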