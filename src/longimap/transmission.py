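"""Resolve transmitted/nontransmitted parental alleles in trios and build
the preferential-transmission statistic matrix Z.

For each trio and biallelic marker there are at most four phase assignments
(which paternal and which maternal allele was transmitted).  A parental side
is *resolvable* when every Mendelian-compatible assignment agrees on that
parent's transmitted allele; a homozygous parent is always resolvable.  The
classic ambiguous case -- father, mother and child all heterozygous -- is
unresolvable on both sides and the statistic is recorded as missing.

Per resolvable side the statistic is, with H the target allele and h the
nontarget allele:

* affected offspring:   +1 if H transmitted over h, -1 if h over H, else 0;
* unaffected offspring: the sign-reversed coding (-1 if H over h).

Z is the sum of the paternal and maternal side statistics; when only one
side is resolvable Z carries that side alone and the entry's multiplicity
is 1 instead of 2 (the expectation model then uses m*mu instead of 2*mu).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "TransmissionCall",
    "MendelianInconsistencyError",
    "resolve_transmission",
    "transmission_statistics",
    "ZMatrix",
    "build_z_matrix",
    "z_rows_from_counts",
    "nontransmitted_counts",
]


class MendelianInconsistencyError(ValueError):
    """Raised when a trio genotype admits no Mendelian phase assignment."""


@dataclass
class TransmissionCall:
    """Resolved transmitted/nontransmitted alleles for one trio at one marker."""

    paternal_transmitted: Optional[str] = None
    paternal_nontransmitted: Optional[str] = None
    paternal_resolvable: bool = False
    maternal_transmitted: Optional[str] = None
    maternal_nontransmitted: Optional[str] = None
    maternal_resolvable: bool = False


def _candidates(father_gt, mother_gt, child_gt):
    """All Mendelian-compatible (paternal, maternal) transmitted-allele pairs.

    A missing parent is a wildcard; a missing child genotype constrains
    nothing (any parental assignment is compatible).
    """
    f_alleles = list(father_gt) if father_gt is not None else None
    m_alleles = list(mother_gt) if mother_gt is not None else None
    child = Counter(child_gt) if child_gt is not None else None

    wild = object()
    f_opts = f_alleles if f_alleles is not None else [wild]
    m_opts = m_alleles if m_alleles is not None else [wild]
    out = []
    for x, y in itertools.product(f_opts, m_opts):
        if child is None:
            out.append((x, y))
            continue
        pair = Counter()
        free = 0
        for a in (x, y):
            if a is wild:
                free += 1
            else:
                pair[a] += 1
        if all(pair[a] <= child[a] for a in pair) and \
                sum(child.values()) - sum(pair.values()) == free:
            out.append((x, y))
    return out, wild


def resolve_transmission(father_gt, mother_gt, child_gt) -> TransmissionCall:
    """Resolve which parental alleles were transmitted to the offspring.

    Genotypes are unordered allele pairs (2-sequences of allele codes) or
    ``None`` when missing.  Raises :class:`MendelianInconsistencyError` if no
    phase assignment is compatible (such genotypes should have been zeroed by
    the QC screen beforehand).
    """
    cands, wild = _candidates(father_gt, mother_gt, child_gt)
    if not cands:
        raise MendelianInconsistencyError(
            f"no Mendelian phase assignment for trio "
            f"father={father_gt} mother={mother_gt} child={child_gt}"
        )
    call = TransmissionCall()
    f_trans = {x for x, _ in cands}
    if father_gt is not None and len(f_trans) == 1 and wild not in f_trans:
        t = next(iter(f_trans))
        rest = list(father_gt)
        rest.remove(t)
        call.paternal_transmitted = t
        call.paternal_nontransmitted = rest[0]
        call.paternal_resolvable = True
    m_trans = {y for _, y in cands}
    if mother_gt is not None and len(m_trans) == 1 and wild not in m_trans:
        t = next(iter(m_trans))
        rest = list(mother_gt)
        rest.remove(t)
        call.maternal_transmitted = t
        call.maternal_nontransmitted = rest[0]
        call.maternal_resolvable = True
    return call


def _side_stat(transmitted, nontransmitted, affected: bool, target: str) -> int:
    if transmitted == nontransmitted:
        return 0
    s = 1 if transmitted == target else -1
    return s if affected else -s


def transmission_statistics(call: TransmissionCall, affected: bool,
                            target_allele: str):
    """Per-side preferential-transmission statistics (paternal, maternal).

    Unresolvable sides yield ``None`` (missing), never an imputed value.
    """
    pat = mat = None
    if call.paternal_resolvable:
        pat = _side_stat(call.paternal_transmitted, call.paternal_nontransmitted,
                         affected, target_allele)
    if call.maternal_resolvable:
        mat = _side_stat(call.maternal_transmitted, call.maternal_nontransmitted,
                         affected, target_allele)
    return pat, mat


# ---------------------------------------------------------------------------
# Vectorized path: genotypes coded as target-allele counts (0, 1, 2; -1 missing)
# ---------------------------------------------------------------------------

def _gt_from_count(c):
    if c < 0:
        return None
    return ("H",) * c + ("h",) * (2 - c)


def _build_tables():
    """Lookup tables over all (father, mother, child) count-coded configs.

    Index order is (f+1, m+1, c+1) for counts in {-1, 0, 1, 2}.  Entries:
    valid flag (Mendelian-consistent), per-side resolvable flags, per-side
    signed statistic for the *affected* coding (s=+1 when H transmitted over
    h), and per-side indicator that the nontransmitted allele is h.
    """
    shp = (4, 4, 4)
    valid = np.zeros(shp, bool)
    res_p = np.zeros(shp, bool)
    res_m = np.zeros(shp, bool)
    s_p = np.zeros(shp, np.int8)
    s_m = np.zeros(shp, np.int8)
    nth_p = np.zeros(shp, bool)
    nth_m = np.zeros(shp, bool)
    for f, m, c in itertools.product((-1, 0, 1, 2), repeat=3):
        try:
            call = resolve_transmission(_gt_from_count(f), _gt_from_count(m),
                                        _gt_from_count(c))
        except MendelianInconsistencyError:
            continue
        i = (f + 1, m + 1, c + 1)
        valid[i] = True
        if call.paternal_resolvable:
            res_p[i] = True
            s_p[i] = _side_stat(call.paternal_transmitted,
                                call.paternal_nontransmitted, True, "H")
            nth_p[i] = call.paternal_nontransmitted == "h"
        if call.maternal_resolvable:
            res_m[i] = True
            s_m[i] = _side_stat(call.maternal_transmitted,
                                call.maternal_nontransmitted, True, "H")
            nth_m[i] = call.maternal_nontransmitted == "h"
    return valid, res_p, res_m, s_p, s_m, nth_p, nth_m

(_VALID, _RES_P, _RES_M, _S_P, _S_M, _NTH_P, _NTH_M) = _build_tables()


def _idx(fc, mc, cc):
    return (np.asarray(fc, int) + 1, np.asarray(mc, int) + 1,
            np.asarray(cc, int) + 1)


def mendel_consistent_mask(fc, mc, cc) -> np.ndarray:
    """Elementwise Mendelian-consistency for count-coded trio genotypes."""
    return _VALID[_idx(fc, mc, cc)]


def z_rows_from_counts(fc, mc, cc):
    """Vectorized trio resolution on count-coded genotype arrays.

    Parameters
    ----------
    fc, mc, cc : (n, M) int arrays of target-allele counts (-1 = missing).

    Returns
    -------
    s : (n, M) int8 -- summed signed statistic in the affected coding
        (negate for unaffected rows);
    m : (n, M) uint8 -- number of resolvable parental sides (0 = missing entry).

    Raises on Mendelian-inconsistent entries: screen with qc.mendel_screen
    first.
    """
    i = _idx(fc, mc, cc)
    bad = ~_VALID[i]
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise MendelianInconsistencyError(
            f"Mendelian-inconsistent genotypes at trio row {r}, marker {c}; "
            "run the QC screen first"
        )
    s = _S_P[i] + _S_M[i]
    m = _RES_P[i].astype(np.uint8) + _RES_M[i].astype(np.uint8)
    return s, m


@dataclass
class ZMatrix:
    """Stacked preferential-transmission statistics.

    One row per (offspring, visit) with a non-excluded analysis status;
    columns are the gene's markers.  ``z`` holds Z1 entries on affected rows
    and Z2 entries on unaffected rows (never mixed); ``m`` is the per-entry
    count of resolvable parental sides (0 marks a missing entry, for which
    ``z`` is NaN).
    """

    z: np.ndarray                 # (R, M) float, NaN where m == 0
    m: np.ndarray                 # (R, M) uint8 in {0, 1, 2}
    affected: np.ndarray          # (R,) bool
    family: np.ndarray            # (R,) int
    visit: np.ndarray             # (R,) int
    offspring: list = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return self.z.shape[0]

    @property
    def n_markers(self) -> int:
        return self.z.shape[1]

    def rows(self, affected: bool) -> "ZMatrix":
        sel = self.affected == affected
        return ZMatrix(self.z[sel], self.m[sel], self.affected[sel],
                       self.family[sel], self.visit[sel],
                       [o for o, k in zip(self.offspring, sel) if k])


def _trio_count_arrays(trios, panel):
    n, M = len(trios), len(panel.marker_ids)
    fc = np.full((n, M), -1, np.int8)
    mc = np.full((n, M), -1, np.int8)
    cc = np.full((n, M), -1, np.int8)
    for i, t in enumerate(trios):
        fc[i] = t.father_counts
        mc[i] = t.mother_counts
        cc[i] = t.child_counts
    return fc, mc, cc


def build_z_matrix(trios, panel, assignments) -> ZMatrix:
    """Build the Z matrix for a set of trios under a phenotype scheme.

    Parameters
    ----------
    trios : sequence of TrioObservation.
    panel : MarkerPanel (defines marker order and target alleles; trio
        genotype counts are already oriented to the panel's target alleles).
    assignments : mapping offspring_id -> PhenotypeAssignment giving the
        per-visit analysis status (affected / unaffected / excluded).
    """
    fc, mc, cc = _trio_count_arrays(trios, panel)
    s, mult = z_rows_from_counts(fc, mc, cc)

    rows_z, rows_m, aff, fam, vis, off = [], [], [], [], [], []
    for i, trio in enumerate(trios):
        asg = assignments.get(trio.offspring_id)
        if asg is None:
            continue
        for l, status in enumerate(asg.statuses):
            if status is None:
                continue
            sign = 1 if status == 1 else -1
            rows_z.append(sign * s[i].astype(float))
            rows_m.append(mult[i])
            aff.append(status == 1)
            fam.append(trio.family_index)
            vis.append(l + 1)
            off.append(trio.offspring_id)
    if rows_z:
        z = np.vstack(rows_z)
        m = np.vstack(rows_m)
    else:
        z = np.empty((0, len(panel.marker_ids)))
        m = np.empty((0, len(panel.marker_ids)), np.uint8)
    z[m == 0] = np.nan
    return ZMatrix(z, m, np.array(aff, bool), np.array(fam, int),
                   np.array(vis, int), off)


def nontransmitted_counts(trios, panel):
    """Per-marker tallies used by the pi estimator.

    Returns (nontransmitted h count, resolvable nontransmitted count,
    h count among all parental alleles, all parental allele count).
    """
    fc, mc, cc = _trio_count_arrays(trios, panel)
    i = _idx(fc, mc, cc)
    res_p, res_m = _RES_P[i], _RES_M[i]
    nt_h = (res_p & _NTH_P[i]).sum(axis=0) + (res_m & _NTH_M[i]).sum(axis=0)
    nt_tot = res_p.sum(axis=0) + res_m.sum(axis=0)
    all_h = np.zeros(fc.shape[1])
    all_tot = np.zeros(fc.shape[1])
    for arr in (fc, mc):
        obs = arr >= 0
        all_h += np.where(obs, 2 - arr, 0).sum(axis=0)
        all_tot += 2 * obs.sum(axis=0)
    return nt_h.astype(float), nt_tot.astype(float), all_h, all_tot
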