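"""Marker and genotype quality control.

Two screens run before any association fit, mirroring the usual PLINK/MERLIN
preprocessing of family GWAS data:

* an exact Hardy-Weinberg equilibrium test on unrelated founders, removing
  markers with p below a threshold (default 1e-4).  The exact conditional
  test sums the probabilities of all heterozygote counts no more probable
  than the observed one, given the allele counts; unlike the chi-square test
  it is not anticonservative for rare variants.
* a deterministic Mendelian-consistency screen on trios: wherever no phase
  assignment of transmitted alleles is compatible with Mendelian
  inheritance, all three genotypes at that marker are set missing (never
  altered to another value).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .transmission import mendel_consistent_mask

__all__ = ["QCReport", "hwe_exact_pvalue", "filter_hwe", "mendel_screen",
           "founder_records", "genotype_counts"]


@dataclass
class QCReport:
    """What the QC screens removed or zeroed."""

    markers_removed_hwe: list = field(default_factory=list)  # (id, p-value)
    genotypes_zeroed_mendel: list = field(default_factory=list)  # (trio, marker)
    n_genotypes_zeroed: int = 0
    founders_used: int = 0


def _log_het_prob(n_het, n_rare, n_total):
    """Log probability of ``n_het`` heterozygotes conditional on ``n_rare``
    copies of the rarer allele among ``n_total`` diploid genotypes."""
    n_common = 2 * n_total - n_rare
    hom_r = (n_rare - n_het) // 2
    hom_c = n_total - n_het - hom_r
    return (n_het * np.log(2.0)
            + gammaln(n_total + 1)
            - gammaln(hom_r + 1) - gammaln(n_het + 1) - gammaln(hom_c + 1)
            + gammaln(n_rare + 1) + gammaln(n_common + 1)
            - gammaln(2 * n_total + 1))


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities that do not exceed the observed count's
    probability.  Symmetric in the two homozygote counts; monomorphic
    markers give p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no data: all genotype counts are zero")
    n_rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[hets <= n]
    hets = hets[(n_rare - hets) // 2 + hets <= n]
    logp = _log_het_prob(hets, n_rare, n)
    logp -= np.logaddexp.reduce(logp)  # normalize (guards rounding)
    p_obs = logp[hets == n_Aa][0]
    return float(min(1.0, np.exp(np.logaddexp.reduce(logp[logp <= p_obs + 1e-12]))))


def founder_records(records):
    """Subjects with no parents listed in the dataset (unrelated founders)."""
    missing = {"0", "", None}
    return [r for r in records
            if r.father_id in missing and r.mother_id in missing]


def genotype_counts(records, panel):
    """Per-marker (n_target_hom, n_het, n_other_hom) genotype counts."""
    M = len(panel.marker_ids)
    counts = np.zeros((M, 3), int)
    for r in records:
        for j, gt in enumerate(r.genotypes):
            if gt is None:
                continue
            c = sum(1 for a in gt if a == panel.target_allele[j])
            counts[j, 2 - c] += 1
    return counts


def filter_hwe(panel, founders, alpha: float = 1e-4):
    """Remove markers failing the exact HWE test among founders.

    Returns the filtered panel (order preserved) and a QCReport.
    """
    if not founders:
        raise ValueError("empty founder set: cannot test HWE")
    counts = genotype_counts(founders, panel)
    removed = []
    keep = []
    for j, mid in enumerate(panel.marker_ids):
        n_AA, n_Aa, n_aa = counts[j]
        if n_AA + n_Aa + n_aa == 0:
            keep.append(j)
            continue
        p = hwe_exact_pvalue(n_AA, n_Aa, n_aa)
        if p < alpha:
            removed.append((mid, p))
        else:
            keep.append(j)
    report = QCReport(markers_removed_hwe=removed, founders_used=len(founders))
    return panel.subset(keep), report


def mendel_screen(trios, panel):
    """Zero Mendelian-inconsistent trio genotypes.

    For every (trio, marker) where no transmitted-allele assignment is
    Mendelian-compatible, the father, mother and child genotypes at that
    marker are all set missing.  Returns new trios and a QCReport; the screen
    is total (it never fails).
    """
    out = []
    zeroed = []
    for t in trios:
        ok = mendel_consistent_mask(t.father_counts, t.mother_counts,
                                    t.child_counts)
        if ok.all():
            out.append(t)
            continue
        bad = np.flatnonzero(~ok)
        fc, mc, cc = (t.father_counts.copy(), t.mother_counts.copy(),
                      t.child_counts.copy())
        fc[bad] = mc[bad] = cc[bad] = -1
        out.append(dataclasses.replace(t, father_counts=fc, mother_counts=mc,
                                       child_counts=cc))
        zeroed.extend((t.offspring_id, panel.marker_ids[j]) for j in bad)
    report = QCReport(genotypes_zeroed_mendel=zeroed,
                      n_genotypes_zeroed=len(zeroed))
    return out, report
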