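"""Shared susceptibility haplotypes: discovery, carrier classification,
founder tracing, and the carrier enrichment chi-square test.

Sharing is exact identity-by-state over the target interval — an affected
individual carries a candidate haplotype when either of its chromosomes
matches the candidate allele string exactly (a mismatch budget exists but
defaults to 0, as no tolerance is defensible a priori). Candidate strings are
traced up the pedigree by the same exact-match rule: a carrier chromosome is
attributed to whichever parent also carries the string, down to the founders;
a step where no parent matches marks the string as created by recombination
inside the interval (untraceable from there).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .genio import AFFECTED, UNAFFECTED, PhasedGenotypes


class ZeroMarginError(ValueError):
    """A contingency-table margin is zero; the statistic is undefined."""


@dataclass
class HaplotypeCandidate:
    alleles: tuple  # allele string over the interval
    carrier_count: int  # affected individuals carrying it
    carriers: list  # their ids


def _interval_columns(genotypes: PhasedGenotypes, interval) -> np.ndarray:
    chrom, start_bp, end_bp = interval
    cols = genotypes.variant_range(str(chrom), start_bp, end_bp)
    if len(cols) == 0:
        raise ValueError(f"interval {chrom}:{start_bp}-{end_bp} spans no variants")
    return cols


def find_shared_haplotypes(
    genotypes: PhasedGenotypes,
    affected_ids,
    interval,
    min_share_fraction: float = 0.8,
) -> list:
    """Distinct haplotype strings over ``interval`` carried by at least
    ``min_share_fraction`` of the affected individuals.

    Returns :class:`HaplotypeCandidate` objects ordered by carrier count
    (descending), ties broken lexicographically by allele string; the result
    is invariant to the order of ``affected_ids``.
    """
    if not genotypes.phased:
        raise ValueError("haplotype sharing requires phased input")
    if not 0.0 < min_share_fraction <= 1.0:
        raise ValueError("min_share_fraction must lie in (0, 1]")
    cols = _interval_columns(genotypes, interval)
    affected_ids = sorted(set(affected_ids))
    idx = genotypes.sample_index(affected_ids)
    carriers: dict = {}
    for sid, i in zip(affected_ids, idx):
        strings = {tuple(genotypes.haplotypes[i, c, cols]) for c in range(2)}
        for s in strings:
            carriers.setdefault(s, set()).add(sid)
    n = len(affected_ids)
    out = [
        HaplotypeCandidate(alleles=s, carrier_count=len(ids), carriers=sorted(ids))
        for s, ids in carriers.items()
        if len(ids) / n >= min_share_fraction
    ]
    out.sort(key=lambda c: (-c.carrier_count, c.alleles))
    return out


def classify_carriers(
    genotypes: PhasedGenotypes, candidates, interval, mismatch_budget: int = 0
) -> pd.DataFrame:
    """Copies of each candidate per individual plus an any-candidate flag.

    A chromosome matches a candidate when its allele string over the interval
    differs in at most ``mismatch_budget`` positions (default exact).
    """
    if not candidates:
        raise ValueError("no candidate haplotypes given")
    cols = _interval_columns(genotypes, interval)
    seqs = genotypes.haplotypes[:, :, cols]
    out = pd.DataFrame({"id": genotypes.samples})
    any_copies = np.zeros(genotypes.n_samples, dtype=int)
    for k, cand in enumerate(candidates):
        target = np.asarray(
            cand.alleles if isinstance(cand, HaplotypeCandidate) else cand, dtype=np.int8
        )
        mismatches = (seqs != target[None, None, :]).sum(axis=2)
        copies = (mismatches <= mismatch_budget).sum(axis=1)
        out[f"copies_Q{k + 1}"] = copies
        any_copies = np.maximum(any_copies, copies)
    out["carrier"] = any_copies > 0
    return out


@dataclass
class TraceResult:
    candidate: tuple
    founders: set  # founder ids the string was traced to
    paths: list  # each path: list of ids, carrier -> founder
    untraceable: list  # (id, reason) pairs
    ambiguous: list = field(default_factory=list)  # ids where both parents matched


def trace_to_founders(
    pedigree: pd.DataFrame,
    genotypes: PhasedGenotypes,
    candidate,
    interval,
) -> TraceResult:
    """Attribute a candidate haplotype to founder chromosomes by walking the
    pedigree upward with exact identity-by-state matching.

    Every reported path is parent-linked in the pedigree. Carriers where both
    parents match are flagged ambiguous and both branches are followed;
    carriers where neither parent matches are reported untraceable
    (recombination inside the interval).
    """
    cols = _interval_columns(genotypes, interval)
    target = np.asarray(
        candidate.alleles if isinstance(candidate, HaplotypeCandidate) else candidate,
        dtype=np.int8,
    )
    sample_idx = {s: i for i, s in enumerate(genotypes.samples)}

    def matches(ind) -> bool:
        if ind not in sample_idx:
            return False
        seq = genotypes.haplotypes[sample_idx[ind], :, cols].T  # (2, len(cols))
        return bool(np.any(np.all(seq == target[None, :], axis=1)))

    ped = pedigree.set_index("id")
    founders, paths, untraceable, ambiguous = set(), [], [], []

    def walk(ind, path):
        sire = ped.at[ind, "sire"] if ind in ped.index else None
        dam = ped.at[ind, "dam"] if ind in ped.index else None
        is_founder = (sire is None or (isinstance(sire, float) and np.isnan(sire))) and (
            dam is None or (isinstance(dam, float) and np.isnan(dam))
        )
        if is_founder:
            founders.add(ind)
            paths.append(path)
            return
        hits = [p for p in (sire, dam) if p is not None and matches(p)]
        if not hits:
            untraceable.append((ind, "no parent matches (interval recombination)"))
            paths.append(path)
            return
        if len(hits) == 2:
            ambiguous.append(ind)
        for p in hits:
            walk(p, path + [p])

    carrier_table = classify_carriers(genotypes, [target], interval)
    ped_ids = set(ped.index)
    for sid in carrier_table.loc[carrier_table["carrier"], "id"]:
        if sid not in ped_ids:
            raise ValueError(f"carrier {sid!r} absent from pedigree")
        walk(sid, [sid])
    return TraceResult(
        candidate=tuple(target),
        founders=founders,
        paths=paths,
        untraceable=untraceable,
        ambiguous=ambiguous,
    )


def carrier_contingency_test(
    n_affected_carriers: int,
    n_affected: int,
    n_unaffected_carriers: int,
    n_unaffected: int,
):
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    affected/unaffected x carrier/non-carrier table.

    The continuity correction is deliberately off: the plain Pearson statistic
    reproduces published worked examples from their printed counts, while the
    Yates-corrected p differs by orders of magnitude.

    Returns ``(statistic, df, p)``; raises :class:`ZeroMarginError` when a
    margin is empty.
    """
    if n_affected <= 0 or n_unaffected <= 0:
        raise ValueError("both phenotype groups must be non-empty")
    if not (0 <= n_affected_carriers <= n_affected):
        raise ValueError("affected carriers outside [0, n_affected]")
    if not (0 <= n_unaffected_carriers <= n_unaffected):
        raise ValueError("unaffected carriers outside [0, n_unaffected]")
    table = np.array(
        [
            [n_affected_carriers, n_affected - n_affected_carriers],
            [n_unaffected_carriers, n_unaffected - n_unaffected_carriers],
        ],
        dtype=float,
    )
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ZeroMarginError("a margin of the 2x2 table is zero")
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def shared_haplotype_report(
    genotypes: PhasedGenotypes,
    pedigree: pd.DataFrame,
    interval,
    min_share_fraction: float = 0.8,
) -> pd.DataFrame:
    """End-to-end report: discover candidates among affected individuals,
    classify carriers genome-wide, trace to founders, and test enrichment."""
    ped = pedigree.set_index("id")
    scored = [
        s
        for s in genotypes.samples
        if s in ped.index and ped.at[s, "status"] in (AFFECTED, UNAFFECTED)
    ]
    affected = [s for s in scored if ped.at[s, "status"] == AFFECTED]
    unaffected = [s for s in scored if s not in set(affected)]
    candidates = find_shared_haplotypes(
        genotypes, affected, interval, min_share_fraction
    )
    rows = []
    if not candidates:
        return pd.DataFrame(rows)
    carrier_tab = classify_carriers(genotypes, candidates, interval).set_index("id")
    for k, cand in enumerate(candidates):
        col = f"copies_Q{k + 1}"
        aff_car = int((carrier_tab.loc[affected, col] > 0).sum())
        una_car = int((carrier_tab.loc[unaffected, col] > 0).sum())
        trace = trace_to_founders(pedigree, genotypes, cand, interval)
        stat, dof, p = carrier_contingency_test(
            aff_car, len(affected), una_car, len(unaffected)
        )
        rows.append(
            {
                "candidate": f"Q{k + 1}",
                "haplotype": "".join(map(str, cand.alleles)),
                "n_affected_carriers": aff_car,
                "n_affected": len(affected),
                "n_unaffected_carriers": una_car,
                "n_unaffected": len(unaffected),
                "founders": ",".join(sorted(trace.founders)),
                "chi2": stat,
                "df": dof,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
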