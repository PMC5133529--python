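"""Synthetic nuclear-family data with the structure the mapping model assumes.

The generator plants a diallelic disease locus at a known map position
``tau`` and lets marker-disease association decay as (1 - theta)^N:

* a single founder haplotype carries the disease allele together with the
  target allele at every flanking marker (complete initial LD);
* for ``n_gen`` generations every disease-carrying haplotype recombines
  against a random background haplotype (independent per-interval
  crossovers, Haldane), keeping the recombinant that retains the disease
  allele;
* parents draw haplotypes from this pool with the disease-allele frequency,
  offspring receive one recombined haplotype per parent (one more Haldane
  meiosis), and the disease-locus column is withheld from the marker panel;
* the longitudinal binary phenotype is an absorbing incidence process:
  first-visit status from the penetrance of the offspring's disease
  genotype, later visits convert unaffected -> affected with a
  genotype-dependent hazard, and affected subjects stay affected -- the
  monotone structure that makes the ever/progression phenotypes meaningful.

Because the method's plug-in pi-hat treats nontransmitted parental alleles
as a proxy for non-disease haplotypes, the default disease variant is rare
(frequency 0.05); the effect size is controlled exactly by solving the
heterozygote penetrance so that the transmission distortion at the disease
locus, E[Y_T(tau) | affected], equals the requested C.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .ldmodel import recomb_fraction
from .pedio import MarkerPanel, PedigreeRecord, TrioObservation

__all__ = [
    "SimConfig",
    "SimDataset",
    "implied_transmission_effect",
    "penetrance_for_effect",
    "simulate_haplotype_pool",
    "simulate_families",
    "simulate_dataset",
    "make_fixture",
    "FIXTURES",
    "recovery_config",
    "null_config",
    "longitudinal_config",
]


def implied_transmission_effect(disease_freq: float, penetrances) -> Tuple[float, float, float]:
    """Exact (C, C*, prevalence) implied by a penetrance model.

    Enumerates parental disease-locus alleles and transmissions; C is the
    expected preferential-transmission statistic at the disease locus for an
    affected offspring (equal for both parental sides by symmetry), C* its
    unaffected-offspring counterpart.
    """
    p = disease_freq
    f = np.asarray(penetrances, float)
    num_c = num_cs = den_c = den_cs = 0.0
    for a1, a2, b1, b2 in itertools.product((0, 1), repeat=4):
        w_alleles = (p if a1 else 1 - p) * (p if a2 else 1 - p) \
            * (p if b1 else 1 - p) * (p if b2 else 1 - p)
        for ti, tj in itertools.product((0, 1), repeat=2):
            w = w_alleles * 0.25
            dp = (a1, a2)[ti]
            dm = (b1, b2)[tj]
            g = dp + dm
            y_t = dp - (a1, a2)[1 - ti]  # paternal side
            num_c += w * f[g] * y_t
            den_c += w * f[g]
            num_cs += w * (1 - f[g]) * (-y_t)
            den_cs += w * (1 - f[g])
    return num_c / den_c, num_cs / den_cs, den_c


def penetrance_for_effect(c_target: float, disease_freq: float,
                          f0: float = 0.0, f2: float = 1.0) -> float:
    """Heterozygote penetrance f1 such that the implied C equals c_target.

    C decreases monotonically in f1 between the recessive (f1 = f0) and
    dominant (f1 = f2) endpoints; c_target must lie in that range.
    """
    def gap(f1):
        return implied_transmission_effect(disease_freq, (f0, f1, f2))[0] - c_target

    lo, hi = gap(f0), gap(f2)
    if not (min(lo, hi) <= 0 <= max(lo, hi)):
        raise ValueError(
            f"C = {c_target} not reachable for p = {disease_freq}, "
            f"f0 = {f0}, f2 = {f2} (range [{min(lo, hi) + c_target:.3f}, "
            f"{max(lo, hi) + c_target:.3f}])")
    return brentq(gap, f0, f2, xtol=1e-12)


@dataclass
class SimConfig:
    """Study-design parameters for one simulated gene region.

    Defaults describe the calibration setting used throughout the test
    suite: a 20-marker, 2-cM gene region; a rare (p = 0.05) disease variant
    that arose N = 50 generations ago at mid-region; penetrances chosen so
    the transmission distortion at the locus is exactly C = 0.6; one visit.
    """

    n_families: int = 600
    offspring_per_family: int = 1
    n_markers: int = 20
    span_cm: float = 2.0
    tau_cm: Optional[float] = None          # None -> mid-region
    n_gen: float = 50.0
    disease_freq: float = 0.05
    penetrances: Optional[Tuple[float, float, float]] = None  # None -> solve f1 for c_target
    c_target: float = 0.6
    visits: int = 1
    hazards: Tuple[float, float, float] = (0.0, 0.0, 0.0)  # per-visit conversion by genotype
    dropout: float = 0.0                    # absorbing per-visit missingness after visit 1
    marker_freq: float = 0.2                # background target-allele frequency
    pool_size: int = 1500
    ascertain_affected: Optional[int] = None    # collect fixed class sizes
    ascertain_unaffected: Optional[int] = None

    def __post_init__(self):
        if self.penetrances is None:
            f1 = penetrance_for_effect(self.c_target, self.disease_freq)
            self.penetrances = (0.0, f1, 1.0)
        f = self.penetrances
        if not (0 <= f[0] <= f[1] <= f[2] <= 1):
            raise ValueError("penetrances must lie in [0,1], nondecreasing in "
                             "disease-allele count")
        if self.ascertain_affected is not None and self.offspring_per_family != 1:
            raise ValueError("ascertainment is supported for one offspring "
                             "per family")

    @property
    def positions(self) -> np.ndarray:
        return np.linspace(0.0, self.span_cm, self.n_markers)

    @property
    def tau(self) -> float:
        return self.span_cm / 2.0 if self.tau_cm is None else self.tau_cm


def recovery_config(**kw) -> SimConfig:
    """The parameter-recovery setting (ascertained 600 + 600 trios)."""
    kw.setdefault("ascertain_affected", 600)
    kw.setdefault("ascertain_unaffected", 600)
    return SimConfig(**kw)


def null_config(**kw) -> SimConfig:
    """No genetic effect: flat penetrances, C = 0."""
    kw.setdefault("penetrances", (0.25, 0.25, 0.25))
    kw.setdefault("n_markers", 10)
    kw.setdefault("ascertain_affected", 200)
    kw.setdefault("ascertain_unaffected", 200)
    return SimConfig(**kw)


def longitudinal_config(**kw) -> SimConfig:
    """Four-visit absorbing-incidence setting with a commoner variant.

    Baseline prevalence near 10% rising toward ~25-30% by visit 4, with the
    genotype acting on the per-visit conversion hazard as strongly as on
    the baseline penetrance (a stationary genetic effect): repeated visits
    then genuinely accumulate association information, which is the regime
    the longitudinal-vs-baseline efficiency comparison addresses.
    """
    kw.setdefault("disease_freq", 0.1)
    kw.setdefault("penetrances", (0.02, 0.5, 0.95))
    kw.setdefault("visits", 4)
    kw.setdefault("hazards", (0.04, 0.6, 0.95))
    kw.setdefault("n_families", 800)
    return SimConfig(**kw)


# ---------------------------------------------------------------------------
# Haplotype machinery.  Haplotypes are 0/1 target-allele indicator vectors
# over the loci sequence = markers with the disease locus inserted at tau.
# ---------------------------------------------------------------------------

def _loci(config: SimConfig) -> Tuple[np.ndarray, int]:
    pos = config.positions
    ti = int(np.searchsorted(pos, config.tau))
    return np.insert(pos, ti, config.tau), ti


def _interval_thetas(loci: np.ndarray) -> np.ndarray:
    """One-meiosis recombination fraction per inter-locus interval (Haldane)."""
    return recomb_fraction(np.diff(loci), 0.0, "haldane")


def _anchored_recombine(anchor: np.ndarray, other: np.ndarray,
                        thetas: np.ndarray, ti: int,
                        rng: np.random.Generator) -> np.ndarray:
    """One meiosis per row, conditional on the anchor haplotype donating the
    allele at locus index ``ti``.  Crossovers are independent Bernoulli per
    interval (Haldane, no interference)."""
    n, L = anchor.shape
    sw = rng.random((n, L - 1)) < thetas
    par = np.zeros((n, L), np.int8)
    if ti < L - 1:
        par[:, ti + 1:] = np.cumsum(sw[:, ti:], axis=1) % 2
    if ti > 0:
        par[:, :ti] = np.cumsum(sw[:, :ti][:, ::-1], axis=1)[:, ::-1] % 2
    return np.where(par == 0, anchor, other)


def simulate_haplotype_pool(config: SimConfig,
                            rng: np.random.Generator) -> np.ndarray:
    """Evolve the disease-haplotype pool for ``n_gen`` generations.

    Returns a (pool_size, n_markers + 1) 0/1 array over the loci sequence
    (disease-locus column included, always 1).  The founder haplotype
    carries the target allele at every marker; each generation every pool
    haplotype recombines against a fresh background haplotype drawn at the
    background marker frequency in linkage equilibrium.
    """
    loci, ti = _loci(config)
    thetas = _interval_thetas(loci)
    K, L = config.pool_size, loci.size
    pool = np.ones((K, L), np.int8)
    for _ in range(int(round(config.n_gen))):
        bg = (rng.random((K, L)) < config.marker_freq).astype(np.int8)
        bg[:, ti] = 0
        pool = _anchored_recombine(pool, bg, thetas, ti, rng)
    return pool


@dataclass
class SimDataset:
    """In-memory simulated trios: genotype counts over markers, per-visit
    statuses, and the generating truth."""

    config: SimConfig
    positions: np.ndarray
    father_counts: np.ndarray      # (n, M) int8
    mother_counts: np.ndarray
    child_counts: np.ndarray
    statuses: np.ndarray           # (n, L) float, NaN = missing visit
    family_index: np.ndarray       # (n,) int, 1-based
    disease_genotype: np.ndarray   # (n,) offspring disease-allele count
    truth: Dict = field(default_factory=dict)

    @property
    def n_trios(self) -> int:
        return self.child_counts.shape[0]

    def panel(self) -> MarkerPanel:
        M = self.positions.size
        return MarkerPanel(
            [f"snp{j + 1}" for j in range(M)], self.positions.copy(),
            [("A", "G")] * M, ["A"] * M, ["1"] * M,
            [int(1e6 * (1 + p)) for p in self.positions])

    def _offspring_ids(self):
        seen: Dict[int, int] = {}
        ids = []
        for fam in self.family_index:
            k = seen.get(int(fam), 0) + 1
            seen[int(fam)] = k
            ids.append(f"F{fam}_c{k}")
        return ids

    def status_table(self) -> Dict[str, Tuple[Optional[int], ...]]:
        out = {}
        for i, oid in enumerate(self._offspring_ids()):
            out[oid] = tuple(None if np.isnan(s) else int(s)
                             for s in self.statuses[i])
        return out

    def to_trios(self):
        trios = []
        for i, oid in enumerate(self._offspring_ids()):
            fam = int(self.family_index[i])
            trios.append(TrioObservation(
                f"F{fam}", fam, oid, f"F{fam}_f", f"F{fam}_m",
                self.father_counts[i], self.mother_counts[i],
                self.child_counts[i],
                tuple(None if np.isnan(s) else int(s)
                      for s in self.statuses[i])))
        return trios

    def analyze(self, scheme: str = "baseline", map_function: str = "haldane",
                gene: str = "SIM"):
        """Run the full mapping fit on this dataset under one phenotype
        scheme (pi estimation, Z construction, estimating-equation solve,
        sandwich inference).  Returns a GeneFit."""
        from .estimator import fit_gene
        from .ldmodel import estimate_pi
        from .phenotypes import derive_all
        from .transmission import build_z_matrix

        trios = self.to_trios()
        panel = self.panel()
        pi = estimate_pi(trios, panel)
        zmat = build_z_matrix(trios, panel,
                              derive_all(scheme, self.status_table()))
        return fit_gene(zmat, panel.positions_cm, pi, gene=gene,
                        map_function=map_function)

    # ---- file output -----------------------------------------------------

    def _records(self):
        def gt(c):
            if c < 0:
                return None
            return ("A",) * int(c) + ("G",) * int(2 - c)

        recs = []
        done_parents = set()
        for i, oid in enumerate(self._offspring_ids()):
            fam = f"F{self.family_index[i]}"
            if fam not in done_parents:
                done_parents.add(fam)
                recs.append(PedigreeRecord(fam, f"{fam}_f", "0", "0", "1",
                                           [gt(c) for c in self.father_counts[i]]))
                recs.append(PedigreeRecord(fam, f"{fam}_m", "0", "0", "2",
                                           [gt(c) for c in self.mother_counts[i]]))
            recs.append(PedigreeRecord(fam, oid, f"{fam}_f", f"{fam}_m", "0",
                                       [gt(c) for c in self.child_counts[i]]))
        return recs

    def write(self, out_dir, prefix: str = "sim") -> Dict[str, Path]:
        """Write PED/MAP + visit TSV + gene table + truth JSON."""
        from .pedio import write_ped_map

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {k: out / f"{prefix}{ext}" for k, ext in
                 [("ped", ".ped"), ("map", ".map"), ("visits", ".visits.tsv"),
                  ("genes", ".genes.tsv"), ("truth", ".truth.json")]}
        write_ped_map(self.panel(), self._records(), paths["ped"], paths["map"])
        with open(paths["visits"], "w") as fh:
            for sid, statuses in self.status_table().items():
                for l, s in enumerate(statuses, 1):
                    fh.write(f"{sid}\t{l}\t{'NA' if s is None else s}\n")
        with open(paths["genes"], "w") as fh:
            lo, hi = self.positions[0], self.positions[-1]
            mid = 0.5 * (lo + hi)
            fh.write(f"GENE1\t1\t{lo:.10g}\t{hi:.10g}\n")
            fh.write(f"GENE1L\t1\t{lo:.10g}\t{mid:.10g}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1)
        return paths


def _visit_statuses(g: np.ndarray, config: SimConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Absorbing incidence process: (n, L) status array with NaN dropout."""
    n, L = g.size, config.visits
    f = np.asarray(config.penetrances, float)
    hz = np.asarray(config.hazards, float)
    st = np.zeros((n, L))
    st[:, 0] = rng.random(n) < f[g]
    for l in range(1, L):
        convert = rng.random(n) < hz[g]
        st[:, l] = np.maximum(st[:, l - 1], convert)
    if config.dropout > 0 and L > 1:
        gone = np.zeros(n, bool)
        for l in range(1, L):
            gone |= rng.random(n) < config.dropout
            st[gone, l] = np.nan
    return st


def simulate_families(config: SimConfig, pool: np.ndarray,
                      rng: np.random.Generator) -> SimDataset:
    """Draw trios from the haplotype pool.

    Parent haplotypes are disease-pool rows with probability
    ``disease_freq`` and background haplotypes otherwise; offspring receive
    one recombined haplotype per parent.  Genotypes at the disease locus
    determine the phenotype process; the disease-locus column is withheld
    from the genotype output and stored in the truth record.

    With ascertainment configured, the phenotype process runs first on
    disease-locus genotypes alone and marker haplotypes are generated only
    for the sampled trios (marker content is independent of affection given
    the disease-locus alleles and donor haplotypes, so this is exact).
    """
    loci, ti = _loci(config)
    thetas = _interval_thetas(loci)
    opf = config.offspring_per_family
    p = config.disease_freq

    asc = config.ascertain_affected is not None or config.ascertain_unaffected is not None
    n_fam = config.n_families
    if asc:
        want_a = config.ascertain_affected or 0
        want_u = config.ascertain_unaffected or 0
        _, _, prev = implied_transmission_effect(p, config.penetrances)
        n_raw = int(max(want_a / max(prev, 1e-6), want_u / max(1 - prev, 1e-6))
                    * 1.4 + 500)
    else:
        n_raw = n_fam

    # stage 1: disease-locus alleles, transmissions, phenotype process
    par_dis = rng.random((n_raw, 4)) < p        # father h1,h2, mother h1,h2
    n_off = n_raw * opf
    donor_f = rng.integers(0, 2, n_off)
    donor_m = rng.integers(0, 2, n_off)
    fam_of_off = np.repeat(np.arange(n_raw), opf)
    dp = par_dis[fam_of_off, donor_f].astype(int)
    dm = par_dis[fam_of_off, 2 + donor_m].astype(int)
    g = dp + dm
    st = _visit_statuses(g, config, rng)

    if asc:
        ever_aff = np.nansum(st, axis=1) > 0
        aff_idx = np.flatnonzero(ever_aff)[:want_a]
        unaff_idx = np.flatnonzero(~ever_aff)[:want_u]
        if aff_idx.size < want_a or unaff_idx.size < want_u:
            raise RuntimeError("ascertainment shortfall; increase n_raw factor")
        sel = np.sort(np.concatenate([aff_idx, unaff_idx]))
    else:
        sel = np.arange(n_off)

    fam_sel = fam_of_off[sel]
    uniq_fam, fam_pos = np.unique(fam_sel, return_inverse=True)
    nf = uniq_fam.size

    # stage 2: parent haplotypes over all loci for the selected families
    haps = np.empty((nf, 4, loci.size), np.int8)
    dis_flags = par_dis[uniq_fam]
    n_dis = int(dis_flags.sum())
    pool_rows = pool[rng.integers(0, pool.shape[0], n_dis)]
    bg = (rng.random((nf, 4, loci.size)) < config.marker_freq).astype(np.int8)
    bg[:, :, ti] = 0
    haps[:] = bg
    haps[dis_flags] = pool_rows

    # stage 3: offspring meioses anchored on the known donor haplotypes
    k = sel.size
    f1 = haps[fam_pos, donor_f[sel]]
    f2 = haps[fam_pos, 1 - donor_f[sel]]
    m1 = haps[fam_pos, 2 + donor_m[sel]]
    m2 = haps[fam_pos, 2 + (1 - donor_m[sel])]
    pat = _anchored_recombine(f1, f2, thetas, ti, rng)
    mat = _anchored_recombine(m1, m2, thetas, ti, rng)

    marker_cols = np.delete(np.arange(loci.size), ti)
    father_counts = (haps[fam_pos, 0] + haps[fam_pos, 1])[:, marker_cols]
    mother_counts = (haps[fam_pos, 2] + haps[fam_pos, 3])[:, marker_cols]
    child_counts = (pat + mat)[:, marker_cols]

    c_eff, c_star, prev = implied_transmission_effect(p, config.penetrances)
    truth = {
        "tau_cm": config.tau, "n_gen": config.n_gen,
        "c_eff": c_eff, "c_star": c_star, "prevalence_visit1": prev,
        "disease_freq": p, "penetrances": list(config.penetrances),
        "marker_freq": config.marker_freq,
        "target_alleles": {f"snp{j + 1}": "A"
                           for j in range(config.n_markers)},
        "disease_locus_withheld": True,
    }
    return SimDataset(
        config, config.positions,
        father_counts.astype(np.int8), mother_counts.astype(np.int8),
        child_counts.astype(np.int8), st[sel],
        fam_pos + 1, g[sel], truth)


def simulate_dataset(config: SimConfig, seed_or_rng) -> SimDataset:
    """Pool + families in one call."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    pool = simulate_haplotype_pool(config, rng)
    return simulate_families(config, pool, rng)


FIXTURES = {
    "tiny-null": (lambda: null_config(ascertain_affected=60,
                                      ascertain_unaffected=60,
                                      n_markers=8), 20240001),
    "tiny-signal": (lambda: recovery_config(ascertain_affected=150,
                                            ascertain_unaffected=150,
                                            n_markers=10), 20240002),
    "longitudinal-demo": (lambda: longitudinal_config(n_families=300,
                                                      dropout=0.05), 20240003),
}


def make_fixture(name: str, out_dir=None, seed: Optional[int] = None):
    """Deterministic bundled datasets for demos and smoke tests.

    Returns the SimDataset; with ``out_dir`` also writes PED/MAP, visit TSV,
    gene table and truth JSON.
    """
    try:
        cfg_fn, default_seed = FIXTURES[name]
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; "
                         f"choices: {sorted(FIXTURES)}") from None
    sim = simulate_dataset(cfg_fn(), seed if seed is not None else default_seed)
    if out_dir is not None:
        sim.write(out_dir, prefix=name.replace("-", "_"))
    return sim
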