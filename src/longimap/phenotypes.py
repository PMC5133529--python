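"""The four analysis phenotypes built from per-visit binary status.

A longitudinal binary trait observed at L visits (status 0/1, possibly
missing) is collapsed into one of four analysis phenotypes:

* **ever** -- affected if affected at any visit; requires at least two
  non-missing visits (subjects with fewer measurements are excluded so the
  eligible set is comparable with the progression phenotype).
* **progression** -- the incident-case construction: subjects affected at
  their first non-missing visit (prevalent cases) are excluded; the rest
  are affected if they convert at any later visit.
* **baseline** -- status at the first non-missing visit (L = 1).
* **longitudinal** -- all per-visit statuses carried through (missing visits
  excluded for that visit only).

Statuses in a :class:`PhenotypeAssignment` are 1 (affected), 0 (unaffected)
or ``None`` (excluded at that analysis time point).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

__all__ = [
    "SCHEMES",
    "PhenotypeAssignment",
    "derive_ever",
    "derive_progression",
    "derive_baseline",
    "derive_longitudinal",
    "derive",
    "derive_all",
    "summarize",
    "affected_percentage",
    "longitudinal_average_percentage",
]

SCHEMES = ("ever", "progression", "baseline", "longitudinal")


@dataclass
class PhenotypeAssignment:
    """Per-visit analysis statuses for one subject under one scheme."""

    subject_id: str
    scheme: str
    statuses: Tuple[Optional[int], ...]

    @property
    def eligible(self) -> bool:
        return any(s is not None for s in self.statuses)


def _observed(status_by_visit):
    return [(l, s) for l, s in enumerate(status_by_visit) if s is not None]


def derive_ever(status_by_visit, subject_id: str = "") -> PhenotypeAssignment:
    obs = _observed(status_by_visit)
    if len(obs) < 2:
        return PhenotypeAssignment(subject_id, "ever", (None,))
    status = 1 if any(s == 1 for _, s in obs) else 0
    return PhenotypeAssignment(subject_id, "ever", (status,))


def derive_progression(status_by_visit, subject_id: str = "") -> PhenotypeAssignment:
    obs = _observed(status_by_visit)
    if len(obs) < 2 or obs[0][1] == 1:  # too few measurements, or prevalent
        return PhenotypeAssignment(subject_id, "progression", (None,))
    status = 1 if any(s == 1 for _, s in obs[1:]) else 0
    return PhenotypeAssignment(subject_id, "progression", (status,))


def derive_baseline(status_by_visit, subject_id: str = "") -> PhenotypeAssignment:
    obs = _observed(status_by_visit)
    if not obs:
        return PhenotypeAssignment(subject_id, "baseline", (None,))
    return PhenotypeAssignment(subject_id, "baseline", (obs[0][1],))


def derive_longitudinal(status_by_visit, subject_id: str = "") -> PhenotypeAssignment:
    return PhenotypeAssignment(subject_id, "longitudinal",
                               tuple(status_by_visit))


_DERIVERS = {
    "ever": derive_ever,
    "progression": derive_progression,
    "baseline": derive_baseline,
    "longitudinal": derive_longitudinal,
}


def derive(scheme: str, status_by_visit, subject_id: str = "") -> PhenotypeAssignment:
    try:
        fn = _DERIVERS[scheme]
    except KeyError:
        raise ValueError(f"unknown phenotype scheme {scheme!r}; "
                         f"choose one of {SCHEMES}") from None
    return fn(status_by_visit, subject_id)


def derive_all(scheme: str, status_table) -> dict:
    """Derive assignments for every subject in a {subject: statuses} mapping."""
    return {sid: derive(scheme, statuses, sid)
            for sid, statuses in status_table.items()}


def summarize(assignments) -> dict:
    """Per-visit counts of affected / unaffected / excluded subjects."""
    L = max((len(a.statuses) for a in assignments.values()), default=0)
    aff = [0] * L
    unaff = [0] * L
    excl = [0] * L
    for a in assignments.values():
        for l in range(L):
            s = a.statuses[l] if l < len(a.statuses) else None
            if s == 1:
                aff[l] += 1
            elif s == 0:
                unaff[l] += 1
            else:
                excl[l] += 1
    return {"affected": aff, "unaffected": unaff, "excluded": excl,
            "total": [a + u for a, u in zip(aff, unaff)]}


def affected_percentage(n_affected: float, n_total: float) -> float:
    """Affected offspring as a percentage of all offspring."""
    if n_total <= 0:
        raise ValueError("no offspring")
    return 100.0 * n_affected / n_total


def longitudinal_average_percentage(affected_by_visit: Sequence[float],
                                    total_by_visit: Sequence[float]) -> float:
    """Average longitudinal affected percentage across visits.

    Computed as (mean affected count) / (mean total count), i.e. the
    affected fraction of the average per-visit sample.
    """
    if len(affected_by_visit) != len(total_by_visit) or not affected_by_visit:
        raise ValueError("need equal-length, nonempty per-visit counts")
    mean_aff = sum(affected_by_visit) / len(affected_by_visit)
    mean_tot = sum(total_by_visit) / len(total_by_visit)
    return affected_percentage(mean_aff, mean_tot)
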