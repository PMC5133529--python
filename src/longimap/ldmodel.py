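"""Parametric expectation model for multipoint preferential transmission.

The method models the expected preferential-transmission statistic at a
marker located ``t_j`` cM as a function of the unobserved disease-locus
position ``tau``::

    mu1(t_j) = (1 - 2*theta) * C  * (1 - theta)**N * pi_j   (affected trios)
    mu2(t_j) = (1 - 2*theta) * C* * (1 - theta)**N * pi_j   (unaffected trios)

where ``theta`` is the recombination fraction between ``t_j`` and ``tau``
(obtained from the map distance through a map function), ``N`` is the number
of generations since the disease variant arose (it controls how fast the
marker-disease association decays with distance), ``C`` and ``C*`` are the
genetic-effect parameters -- the expected transmission distortion at the
disease locus itself for affected and unaffected offspring -- and ``pi_j``
is the probability of the nontarget marker allele on a non-disease
haplotype, estimated from nontransmitted parental alleles.

All positions are genetic-map coordinates in centimorgans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "recomb_fraction",
    "mu1",
    "mu2",
    "dmu_ddelta",
    "estimate_pi",
    "estimate_pi_from_counts",
]


@dataclass
class ModelParams:
    """Model parameter vector delta = (tau, N, C, C*).

    tau : disease-locus position in cM, constrained to the scanned region.
    n_gen : generations since initiation of the disease variant (>= 1);
        a decay-rate nuisance parameter, treated as continuous.
    c_eff : genetic effect for affected trios, in [-1, 1].
    c_star : genetic effect for unaffected trios, in [-1, 1].
    """

    tau: float
    n_gen: float
    c_eff: float
    c_star: float

    def as_array(self) -> np.ndarray:
        return np.array([self.tau, self.n_gen, self.c_eff, self.c_star], float)

    @classmethod
    def from_array(cls, a) -> "ModelParams":
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))

    def validate(self) -> None:
        if not self.n_gen >= 0:
            raise ValueError("n_gen must be nonnegative")
        if abs(self.c_eff) > 1 + 1e-12 or abs(self.c_star) > 1 + 1e-12:
            raise ValueError("|C| and |C*| must not exceed 1")


def recomb_fraction(t_j, tau, map_function: str = "haldane"):
    """Recombination fraction between map positions ``t_j`` and ``tau`` (cM).

    Haldane (default, no interference): theta = (1 - exp(-2d/100)) / 2.
    Kosambi: theta = tanh(2d/100) / 2.
    Both map zero distance to 0 and saturate at 0.5.
    """
    d = np.abs(np.asarray(t_j, float) - tau)
    if map_function == "haldane":
        return 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    if map_function == "kosambi":
        return 0.5 * np.tanh(2.0 * d / 100.0)
    raise ValueError(f"unknown map function: {map_function!r}")


def _dtheta_dtau(t_j, tau, map_function: str = "haldane"):
    """d(theta)/d(tau); one-sided at t_j == tau (sign(0) treated as 0)."""
    diff = tau - np.asarray(t_j, float)
    d = np.abs(diff)
    if map_function == "haldane":
        return np.sign(diff) * np.exp(-2.0 * d / 100.0) / 100.0
    if map_function == "kosambi":
        return np.sign(diff) / (100.0 * np.cosh(2.0 * d / 100.0) ** 2)
    raise ValueError(f"unknown map function: {map_function!r}")


def _decay(theta, n_gen):
    # (1 - 2 theta) (1 - theta)^N, computed in log space for large N
    one_m = 1.0 - theta
    return (1.0 - 2.0 * theta) * np.exp(n_gen * np.log(one_m))


def mu1(params: ModelParams, pi_j, t_j, map_function: str = "haldane"):
    """Expected transmission statistic for one parental side, affected trio."""
    theta = recomb_fraction(t_j, params.tau, map_function)
    return _decay(theta, params.n_gen) * params.c_eff * np.asarray(pi_j, float)


def mu2(params: ModelParams, pi_j, t_j, map_function: str = "haldane"):
    """Expected transmission statistic for one parental side, unaffected trio."""
    theta = recomb_fraction(t_j, params.tau, map_function)
    return _decay(theta, params.n_gen) * params.c_star * np.asarray(pi_j, float)


def dmu_ddelta(params: ModelParams, pi_j, t_j, which: int,
               map_function: str = "haldane") -> np.ndarray:
    """Partial derivatives of mu wrt delta = (tau, N, C, C*).

    Parameters
    ----------
    which : 1 for mu1 (affected, effect C), 2 for mu2 (unaffected, effect C*).

    Returns
    -------
    (4, M) array of (d mu/d tau, d mu/d N, d mu/d C, d mu/d C*) for each
    marker position in ``t_j``.  The derivative wrt tau is one-sided when
    tau coincides with a marker position.
    """
    t = np.atleast_1d(np.asarray(t_j, float))
    pi = np.broadcast_to(np.asarray(pi_j, float), t.shape)
    theta = recomb_fraction(t, params.tau, map_function)
    dtheta = _dtheta_dtau(t, params.tau, map_function)
    coef = params.c_eff if which == 1 else params.c_star
    one_m = 1.0 - theta
    pow_n = np.exp(params.n_gen * np.log(one_m))
    g = (1.0 - 2.0 * theta) * pow_n * pi          # mu = coef * g
    mu = coef * g

    # d/d tau: product rule over (1-2theta) and (1-theta)^N
    pow_nm1 = np.exp(np.clip(params.n_gen - 1.0, 0.0, None) * np.log(one_m))
    if params.n_gen < 1.0:  # exact for any N >= 0
        pow_nm1 = pow_n / one_m
    dmu_dtau = coef * pi * (
        -2.0 * dtheta * pow_n
        + (1.0 - 2.0 * theta) * params.n_gen * pow_nm1 * (-dtheta)
    )
    dmu_dn = mu * np.log(one_m)

    out = np.zeros((4, t.size))
    out[0] = dmu_dtau
    out[1] = dmu_dn
    out[2 if which == 1 else 3] = g
    return out


def estimate_pi_from_counts(nontrans_h: np.ndarray, nontrans_total: np.ndarray,
                            fallback_h_freq: np.ndarray) -> np.ndarray:
    """Per-marker frequency of the nontarget allele among nontransmitted
    parental alleles; markers with no resolvable nontransmitted allele fall
    back to the nontarget frequency among all parental alleles."""
    nontrans_h = np.asarray(nontrans_h, float)
    total = np.asarray(nontrans_total, float)
    fallback = np.asarray(fallback_h_freq, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(total > 0, nontrans_h / np.maximum(total, 1.0), fallback)
    return np.clip(pi, 0.0, 1.0)


def estimate_pi(trios, panel) -> np.ndarray:
    """Estimate pi_j (nontarget-allele frequency on non-disease haplotypes)
    from the nontransmitted parental alleles of a set of trios.

    Pooled over all trios and both parental sides; each resolvable side
    contributes its one nontransmitted allele per marker.
    """
    from .transmission import nontransmitted_counts

    nt_h, nt_tot, all_h, all_tot = nontransmitted_counts(trios, panel)
    with np.errstate(invalid="ignore", divide="ignore"):
        fallback = np.where(all_tot > 0, all_h / np.maximum(all_tot, 1.0), 0.5)
    return estimate_pi_from_counts(nt_h, nt_tot, fallback)
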