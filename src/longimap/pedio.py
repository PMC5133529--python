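"""Read/write PLINK PED/MAP text files and assemble nuclear-family trios.

Coordinates are genetic-map positions in cM throughout (the MAP file's bp
column is carried as metadata only).  The missing allele code is "0".

The target allele H(t) per marker -- the allele whose preferential
transmission is tracked -- is assigned by a configurable rule: ``"minor"``
(minor allele among founders; the default, reproducible convention) or an
explicit per-marker mapping.  The sign of the fitted genetic effect is
interpretable only relative to this choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "MarkerPanel",
    "PedigreeRecord",
    "TrioObservation",
    "read_ped_map",
    "write_ped_map",
    "read_visits",
    "read_gene_table",
    "extract_trios",
    "write_gene_results",
    "records_to_counts",
]

MISSING_ALLELE = "0"
MISSING_PARENT = "0"


@dataclass
class MarkerPanel:
    """Ordered biallelic markers with cM positions and target alleles."""

    marker_ids: List[str]
    positions_cm: np.ndarray
    alleles: List[Tuple[str, str]]
    target_allele: List[str]
    chrom: List[str] = field(default_factory=list)
    positions_bp: List[int] = field(default_factory=list)

    def __post_init__(self):
        self.positions_cm = np.asarray(self.positions_cm, float)
        if np.any(np.diff(self.positions_cm) < 0):
            raise ValueError("marker positions must be sorted ascending")
        for mid, al, tg in zip(self.marker_ids, self.alleles, self.target_allele):
            if len(set(al)) != 2:
                raise ValueError(f"marker {mid} is not biallelic: alleles {al}")
            if tg not in al:
                raise ValueError(f"target allele {tg} not among alleles of {mid}")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def nontarget_allele(self, j: int) -> str:
        a, b = self.alleles[j]
        return b if self.target_allele[j] == a else a

    def subset(self, idx: Sequence[int]) -> "MarkerPanel":
        idx = list(idx)
        return MarkerPanel(
            [self.marker_ids[j] for j in idx],
            self.positions_cm[idx],
            [self.alleles[j] for j in idx],
            [self.target_allele[j] for j in idx],
            [self.chrom[j] for j in idx] if self.chrom else [],
            [self.positions_bp[j] for j in idx] if self.positions_bp else [],
        )

    def marker_index(self) -> Dict[str, int]:
        return {m: j for j, m in enumerate(self.marker_ids)}


@dataclass
class PedigreeRecord:
    """One PED row: identifiers plus per-marker unordered allele pairs."""

    family_id: str
    subject_id: str
    father_id: str
    mother_id: str
    sex: str
    genotypes: List[Optional[Tuple[str, str]]]


@dataclass
class TrioObservation:
    """One offspring with both parents, genotype counts oriented to the
    panel's target alleles (-1 = missing), and per-visit affection status."""

    family_id: str
    family_index: int
    offspring_id: str
    father_id: str
    mother_id: str
    father_counts: np.ndarray
    mother_counts: np.ndarray
    child_counts: np.ndarray
    status_by_visit: Tuple[Optional[int], ...]


def _parse_map(map_path):
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) != 4:
                raise ValueError(f"{map_path}:{ln}: MAP rows need 4 columns, "
                                 f"got {len(f)}")
            rows.append((f[0], f[1], float(f[2]), int(f[3])))
    return rows


def read_ped_map(ped_path, map_path, target_rule: Union[str, Dict[str, str]] = "minor"):
    """Read a PLINK PED/MAP pair.

    Markers are ordered by cM position (re-sorted with a warning if the MAP
    file is unsorted).  ``target_rule`` is ``"minor"`` or a mapping
    marker_id -> target allele.

    Returns (MarkerPanel, list of PedigreeRecord).
    """
    map_rows = _parse_map(map_path)
    order = sorted(range(len(map_rows)), key=lambda i: map_rows[i][2])
    if order != list(range(len(map_rows))):
        warnings.warn(f"{map_path}: markers not sorted by position; re-sorting")
    map_rows = [map_rows[i] for i in order]
    M = len(map_rows)

    records = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) != 6 + 2 * M:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * M} fields "
                    f"(6 + 2x{M} markers), got {len(f)}")
            raw = f[6:]
            genotypes = []
            for j in range(M):
                a, b = raw[2 * order[j]], raw[2 * order[j] + 1]
                if MISSING_ALLELE in (a, b):
                    genotypes.append(None)
                else:
                    genotypes.append((a, b))
            records.append(PedigreeRecord(f[0], f[1], f[2], f[3], f[4], genotypes))

    # observed alleles and founder allele counts per marker
    from .qc import founder_records
    founders = founder_records(records) or records
    alleles: List[Tuple[str, str]] = []
    targets: List[str] = []
    for j, (chrom, mid, cm, bp) in enumerate(map_rows):
        seen: Dict[str, int] = {}
        for r in records:
            gt = r.genotypes[j]
            if gt:
                for a in gt:
                    seen.setdefault(a, 0)
        for r in founders:
            gt = r.genotypes[j]
            if gt:
                for a in gt:
                    seen[a] = seen.get(a, 0) + 1
        if len(seen) != 2:
            raise ValueError(f"marker {mid} is not biallelic: observed alleles "
                             f"{sorted(seen)}")
        pair = tuple(sorted(seen))
        alleles.append(pair)
        if isinstance(target_rule, dict):
            tgt = target_rule[mid]
        elif target_rule == "minor":
            # minor allele among founders; deterministic tie-break on code
            tgt = min(pair, key=lambda a: (seen[a], a))
        else:
            raise ValueError(f"unknown target rule {target_rule!r}")
        targets.append(tgt)

    panel = MarkerPanel(
        [r[1] for r in map_rows],
        np.array([r[2] for r in map_rows]),
        alleles,
        targets,
        [r[0] for r in map_rows],
        [r[3] for r in map_rows],
    )
    return panel, records


def write_ped_map(panel: MarkerPanel, records, ped_path, map_path) -> None:
    """Write records back to a PED/MAP pair (round-trip inverse of
    :func:`read_ped_map` for sorted input)."""
    with open(map_path, "w") as fh:
        for j, mid in enumerate(panel.marker_ids):
            chrom = panel.chrom[j] if panel.chrom else "1"
            bp = panel.positions_bp[j] if panel.positions_bp else j + 1
            fh.write(f"{chrom}\t{mid}\t{panel.positions_cm[j]:.10g}\t{bp}\n")
    with open(ped_path, "w") as fh:
        for r in records:
            fields = [r.family_id, r.subject_id, r.father_id, r.mother_id,
                      r.sex, "0"]
            for gt in r.genotypes:
                fields.extend(gt if gt else (MISSING_ALLELE, MISSING_ALLELE))
            fh.write(" ".join(fields) + "\n")


def read_visits(path) -> pd.DataFrame:
    """Read the longitudinal phenotype table.

    Tab-separated, one row per subject x visit, columns
    (subject_id, visit, status) with status in {0, 1} or a missing marker
    ("NA", "-9", "", "."). Duplicate (subject, visit) pairs are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=None,
                     names=["subject_id", "visit", "status"],
                     comment="#", skip_blank_lines=True)
    if df.iloc[0].tolist() == ["subject_id", "visit", "status"]:
        df = df.iloc[1:].reset_index(drop=True)
    dup = df.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        pair = df.loc[dup.idxmax(), ["subject_id", "visit"]].tolist()
        raise ValueError(f"duplicate (subject, visit) pair: {pair}")
    missing_codes = {"NA", "-9", "", ".", "nan"}

    def _status(s):
        s = str(s).strip()
        if s in missing_codes:
            return None
        if s not in {"0", "1"}:
            raise ValueError(f"invalid status {s!r}; expected 0, 1 or missing")
        return int(s)

    df["visit"] = df["visit"].astype(int)
    status = df["status"].map(_status).astype(object)
    df["status"] = status.where(pd.notna(status), None)
    return df


def visits_to_status_table(df: pd.DataFrame) -> Dict[str, Tuple[Optional[int], ...]]:
    """Pivot the visit table into {subject: per-visit status tuple}."""
    L = int(df["visit"].max())
    table: Dict[str, list] = {}
    for sid, visit, status in df.itertuples(index=False):
        table.setdefault(sid, [None] * L)[visit - 1] = status
    return {sid: tuple(v) for sid, v in table.items()}


def read_gene_table(path) -> pd.DataFrame:
    """Gene annotation table: tab-separated (gene, chrom, start_cM, end_cM)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#",
                     names=["gene", "chrom", "start_cm", "end_cm"])
    if df.iloc[0]["gene"].lower() == "gene":
        df = df.iloc[1:].reset_index(drop=True)
    df["start_cm"] = df["start_cm"].astype(float)
    df["end_cm"] = df["end_cm"].astype(float)
    return df


def _counts(gt, target) -> int:
    if gt is None:
        return -1
    return sum(1 for a in gt if a == target)


def records_to_counts(record: Optional[PedigreeRecord], panel: MarkerPanel) -> np.ndarray:
    M = panel.n_markers
    if record is None:
        return np.full(M, -1, np.int8)
    return np.array([_counts(record.genotypes[j], panel.target_allele[j])
                     for j in range(M)], np.int8)


def extract_trios(records, phenotypes, panel: MarkerPanel):
    """Assemble one TrioObservation per offspring with both parents identified.

    ``phenotypes`` maps subject_id -> per-visit status tuple.  Families are
    validated to be nuclear (a single parental pair); larger pedigrees must
    be split upstream before they reach this package.  Offspring with no
    phenotype at any visit are excluded and counted.

    Returns (trios, n_families, n_excluded_no_phenotype).
    """
    by_family: Dict[str, list] = {}
    for r in records:
        by_family.setdefault(r.family_id, []).append(r)

    trios: List[TrioObservation] = []
    n_excluded = 0
    family_index = 0
    for fam_id, members in by_family.items():
        ids = {r.subject_id: r for r in members}
        for r in members:
            if r.subject_id in (r.father_id, r.mother_id):
                raise ValueError(f"subject {r.subject_id} listed as own "
                                 f"ancestor in family {fam_id}")
        offspring = [r for r in members
                     if r.father_id != MISSING_PARENT or r.mother_id != MISSING_PARENT]
        pairs = {(r.father_id, r.mother_id) for r in offspring}
        if len(pairs) > 1:
            raise ValueError(
                f"family {fam_id} is not nuclear ({len(pairs)} parental "
                "pairs); split extended pedigrees into nuclear families "
                "before analysis (pedigree splitting is outside this "
                "package's scope)")
        if not offspring:
            continue
        family_index += 1
        father_id, mother_id = next(iter(pairs))
        fc = records_to_counts(ids.get(father_id), panel)
        mc = records_to_counts(ids.get(mother_id), panel)
        for child in offspring:
            statuses = phenotypes.get(child.subject_id)
            if statuses is None or all(s is None for s in statuses):
                n_excluded += 1
                continue
            trios.append(TrioObservation(
                fam_id, family_index, child.subject_id, father_id, mother_id,
                fc, mc, records_to_counts(child, panel), tuple(statuses)))
    return trios, family_index, n_excluded


def write_gene_results(fits, path) -> None:
    """Write per-gene fit results as a tab-separated report.

    Columns: gene, tau_hat, se_tau, C_hat, se_C, p_value, n_trios, converged.
    Non-converged fits get empty SE and p-value fields.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to write")
    with open(path, "w") as fh:
        fh.write("gene\ttau_hat\tse_tau\tC_hat\tse_C\tp_value\tn_trios\tconverged\n")
        for f in fits:
            def fmt(x, ok=True):
                return "" if (x is None or not ok or not np.isfinite(x)) else f"{x:.10g}"
            ok = bool(f.converged)
            fh.write("\t".join([
                f.gene,
                fmt(f.params.tau), fmt(f.se_tau, ok),
                fmt(f.params.c_eff), fmt(f.se_c, ok),
                fmt(f.p_value_c, ok),
                str(f.n_trios_affected + f.n_trios_unaffected),
                "true" if ok else "false",
            ]) + "\n")
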