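"""Predicted genetic parameters of a biparental cross from marker effects.

Given two inbred parents, a genetic map and per-trait additive marker
effects, this module predicts the progeny family mean, genetic variance,
superior progeny mean and between-trait genetic correlation for fully
inbred (F-infinity) recombinant progeny.

The variance/covariance predictions rest on the expected disequilibrium
between parental-origin indicators in selfed RILs,
``D(c) = (1 - 2c) / (1 + 2c)``, with pairwise recombination fractions
obtained from map distances through Haldane's function. Two independent
oracles are provided: an exact exhaustive enumeration of the multilocus
RIL genotype distribution (small segregating sets) and a Monte-Carlo
progeny simulator built on :mod:`crossgain.simnam` machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gmap import GeneticMap, haldane_c
from .simnam import FIXATION_ROUNDS, _self_batch

__all__ = [
    "CrossSpec",
    "CrossPrediction",
    "recombination_fraction",
    "expected_ld_ril",
    "selection_intensity",
    "predict_cross_mean",
    "predict_cross_variance",
    "predict_cross_covariance",
    "predict_superior_progeny",
    "predict_correlated_response",
    "predict_crosses",
    "simulate_cross_oracle",
    "enumerate_cross_oracle",
]


def recombination_fraction(gmap: GeneticMap, i, j) -> float:
    """Recombination fraction between two mapped markers (0.5 across chromosomes)."""
    return gmap.recomb_fraction(i, j)


def expected_ld_ril(c, generations=None):
    """Expected origin-indicator correlation in selfed RILs at F-infinity.

    D = (1 - 2c) / (1 + 2c). Finite-generation populations are handled by
    the Monte-Carlo oracle, not by this closed form.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any((c_arr < 0) | (c_arr > 0.5)):
        raise ValueError("recombination fraction must be in [0, 0.5]")
    if generations is not None and np.isfinite(generations):
        raise ValueError(
            "closed form is for fully inbred lines; use simulate_cross_oracle "
            "for finite selfing generations"
        )
    return (1.0 - 2.0 * c_arr) / (1.0 + 2.0 * c_arr)


def selection_intensity(p: float) -> float:
    """Standardized selection differential k_p = phi(z_p) / p."""
    if not 0.0 < p < 1.0:
        raise ValueError("selection proportion must be in (0, 1)")
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


@dataclass
class CrossSpec:
    """Phase structure of an inbred x inbred cross on the marker panel.

    ``seg`` flags loci where the parents carry different homozygous
    alleles; ``d = (z1 - z2)/2`` gives the phase sign (+1/-1) there.
    """

    parent1_id: str
    parent2_id: str
    z1: np.ndarray
    z2: np.ndarray
    seg: np.ndarray = field(init=False)
    d: np.ndarray = field(init=False)
    valid: np.ndarray = field(init=False)
    n_dropped: int = field(init=False, default=0)

    def __post_init__(self):
        z1 = np.asarray(self.z1, dtype=float)
        z2 = np.asarray(self.z2, dtype=float)
        if z1.shape != z2.shape or z1.ndim != 1:
            raise ValueError("parent dosage vectors must be equal-length 1-D")
        hom1 = np.isin(z1, (-1.0, 1.0))
        hom2 = np.isin(z2, (-1.0, 1.0))
        self.valid = hom1 & hom2
        self.n_dropped = int(np.sum(~self.valid))
        self.z1, self.z2 = z1, z2
        self.seg = self.valid & (z1 != z2)
        self.d = np.where(self.seg, (z1 - z2) / 2.0, 0.0)

    @classmethod
    def from_parents(cls, parent1_id, z1, parent2_id, z2,
                     strict: bool = True) -> "CrossSpec":
        spec = cls(parent1_id, parent2_id, z1, z2)
        if strict and spec.n_dropped:
            raise ValueError(
                f"cross {parent1_id} x {parent2_id}: {spec.n_dropped} "
                "heterozygous/missing parental loci (use strict=False to drop)"
            )
        return spec

    @property
    def n_segregating(self) -> int:
        return int(self.seg.sum())


def _effect_vector(effects):
    """Accept a MarkerEffects-like object or a bare array; return (intercept, u)."""
    if hasattr(effects, "effects"):
        return float(getattr(effects, "intercept", 0.0)), np.asarray(effects.effects, float)
    return 0.0, np.asarray(effects, float)


def predict_cross_mean(cross: CrossSpec, effects) -> float:
    """Predicted family mean: intercept + sum of mid-parent dosage x effect."""
    mu0, u = _effect_vector(effects)
    if u.size != cross.z1.size:
        raise ValueError("effects length does not match marker panel")
    mid = np.where(cross.valid, (cross.z1 + cross.z2) / 2.0, 0.0)
    return float(mu0 + mid @ u)


def _seg_blocks(cross: CrossSpec, gmap: GeneticMap):
    """Segregating column indices grouped by chromosome."""
    if cross.z1.size != gmap.n_markers:
        raise ValueError("cross marker panel does not match map")
    out = []
    for sl in gmap.chromosome_slices():
        idx = np.nonzero(cross.seg[sl])[0] + sl.start
        if idx.size:
            out.append(idx)
    return out


def _ld_matrix(gmap: GeneticMap, idx: np.ndarray) -> np.ndarray:
    return expected_ld_ril(gmap.recomb_matrix(idx))


def predict_cross_variance(cross: CrossSpec, effects, gmap: GeneticMap) -> float:
    """Predicted genetic variance among F-infinity progeny of the cross.

    sigma^2 = sum_{i,j in S} u_i u_j d_i d_j D(c_ij); computed per
    chromosome since D vanishes at c = 0.5. Tiny negative values from
    floating-point cancellation are clipped at 0.
    """
    _, u = _effect_vector(effects)
    if u.size != cross.z1.size:
        raise ValueError("effects length does not match marker panel")
    total = 0.0
    for idx in _seg_blocks(cross, gmap):
        a = u[idx] * cross.d[idx]
        total += float(a @ _ld_matrix(gmap, idx) @ a)
    if total < -1e-10:
        raise FloatingPointError(f"analytic variance {total} below tolerance")
    return max(total, 0.0)


def predict_cross_covariance(cross: CrossSpec, effects_t1, effects_t2,
                             gmap: GeneticMap):
    """Predicted genetic covariance and correlation between two traits.

    Returns ``(cov, r_g)``; ``r_g`` is NaN when either trait's predicted
    variance is zero (correlation undefined, flagged rather than 0).
    """
    _, u1 = _effect_vector(effects_t1)
    _, u2 = _effect_vector(effects_t2)
    if u1.size != u2.size or u1.size != cross.z1.size:
        raise ValueError("effect vectors must share the cross's marker panel")
    cov = 0.0
    v1 = 0.0
    v2 = 0.0
    for idx in _seg_blocks(cross, gmap):
        D = _ld_matrix(gmap, idx)
        a1 = u1[idx] * cross.d[idx]
        a2 = u2[idx] * cross.d[idx]
        cov += float(a1 @ D @ a2)
        v1 += float(a1 @ D @ a1)
        v2 += float(a2 @ D @ a2)
    v1, v2 = max(v1, 0.0), max(v2, 0.0)
    if v1 == 0.0 or v2 == 0.0:
        return cov, float("nan")
    r = cov / np.sqrt(v1 * v2)
    if abs(r) > 1.0 + 1e-8:
        raise FloatingPointError(f"|r_g| = {abs(r)} exceeds 1 beyond tolerance")
    return cov, float(np.clip(r, -1.0, 1.0))


def predict_superior_progeny(mu: float, var_g: float, p: float,
                             direction: str = "high") -> float:
    """mu_sp = mu +/- k_p * sigma_g depending on the favourable direction."""
    if var_g < 0:
        raise ValueError("genetic variance must be >= 0")
    if direction not in ("high", "low"):
        raise ValueError(f"unknown direction {direction!r} (use 'high'/'low')")
    k = selection_intensity(p)
    offset = k * np.sqrt(var_g)
    return float(mu + offset if direction == "high" else mu - offset)


def predict_correlated_response(mu2: float, sd_g2: float, r_g: float,
                                p: float) -> float:
    """Correlated progeny mean on a secondary trait: mu2 + k_p * r_g * sigma_g2."""
    if not np.isfinite(r_g) or abs(r_g) > 1.0 + 1e-8:
        raise ValueError("r_g must be finite with |r_g| <= 1")
    if sd_g2 < 0:
        raise ValueError("sd_g2 must be >= 0")
    return float(mu2 + selection_intensity(p) * r_g * sd_g2)


@dataclass
class CrossPrediction:
    """Per-cross predicted parameters for all traits and trait pairs."""

    parent1_id: str
    parent2_id: str
    trait_names: tuple
    mu: np.ndarray          # per trait
    var_g: np.ndarray       # per trait
    musp: np.ndarray        # per trait
    cov_g: np.ndarray       # trait x trait (diagonal = var_g)
    r_g: np.ndarray         # trait x trait, NaN where undefined
    p: float = 0.10
    directions: tuple = ()
    n_segregating: int = 0


def predict_crosses(crosses, effects_by_trait: dict, gmap: GeneticMap,
                    p: float = 0.10, directions: dict | None = None,
                    strict: bool = True) -> list[CrossPrediction]:
    """Analytic predictions for a list of (id1, z1, id2, z2) parent tuples."""
    traits = list(effects_by_trait)
    directions = directions or {}
    out = []
    for (id1, z1, id2, z2) in crosses:
        cross = CrossSpec.from_parents(id1, z1, id2, z2, strict=strict)
        t = len(traits)
        mu = np.zeros(t)
        var = np.zeros(t)
        musp = np.zeros(t)
        cov = np.zeros((t, t))
        rg = np.eye(t)
        dirs = tuple(directions.get(tr, "high") for tr in traits)
        for i, tr in enumerate(traits):
            mu[i] = predict_cross_mean(cross, effects_by_trait[tr])
            var[i] = predict_cross_variance(cross, effects_by_trait[tr], gmap)
            musp[i] = predict_superior_progeny(mu[i], var[i], p, dirs[i])
            cov[i, i] = var[i]
        for i in range(t):
            for j in range(i + 1, t):
                c_ij, r_ij = predict_cross_covariance(
                    cross, effects_by_trait[traits[i]],
                    effects_by_trait[traits[j]], gmap)
                cov[i, j] = cov[j, i] = c_ij
                rg[i, j] = rg[j, i] = r_ij
        out.append(CrossPrediction(id1, id2, tuple(traits), mu, var, musp,
                                   cov, rg, p, dirs, cross.n_segregating))
    return out


def predictions_to_frames(preds: list[CrossPrediction]):
    """Flatten predictions into (per-trait, per-trait-pair) data frames."""
    rows, prows = [], []
    for pr in preds:
        for i, tr in enumerate(pr.trait_names):
            rows.append((pr.parent1_id, pr.parent2_id, tr, pr.mu[i],
                         pr.var_g[i], pr.musp[i]))
        for i in range(len(pr.trait_names)):
            for j in range(i + 1, len(pr.trait_names)):
                prows.append((pr.parent1_id, pr.parent2_id, pr.trait_names[i],
                              pr.trait_names[j], pr.cov_g[i, j], pr.r_g[i, j]))
    per_trait = pd.DataFrame(
        rows, columns=["parent1", "parent2", "trait", "mu_hat", "var_hat",
                       "musp_hat"])
    per_pair = pd.DataFrame(
        prows, columns=["parent1", "parent2", "trait1", "trait2", "cov_hat",
                        "rg_hat"])
    return per_trait, per_pair


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def _reduced_switch_p(gmap: GeneticMap, idx: np.ndarray) -> np.ndarray:
    """Switch probabilities between consecutive segregating loci.

    Haldane recombination is additive in map distance, so skipping the
    non-segregating markers in between is exact.
    """
    pos = gmap.position[idx]
    chrom = gmap.chromosome[idx]
    p = np.empty(idx.size)
    p[0] = 0.5
    if idx.size > 1:
        d = np.diff(pos)
        same = np.diff(chrom) == 0
        p[1:] = np.where(same, haldane_c(np.maximum(d, 0.0)), 0.5)
    return p


def simulate_cross_oracle(cross: CrossSpec, effects_list, gmap: GeneticMap,
                          n_progeny: int, selfing_generations,
                          rng: np.random.Generator,
                          fixation_rounds: int = FIXATION_ROUNDS):
    """Monte-Carlo progeny moments for a cross under one or more traits.

    Simulates ``n_progeny`` RIL lineages over the segregating loci only
    (fixed loci contribute a constant) and scores them with each trait's
    effects. Returns ``(mean, var, corr)`` with per-trait arrays and the
    empirical trait-by-trait correlation matrix.
    """
    if n_progeny < 2:
        raise ValueError("n_progeny must be >= 2")
    if not isinstance(effects_list, (list, tuple)):
        effects_list = [effects_list]
    intercepts, us = zip(*(_effect_vector(e) for e in effects_list))
    for u in us:
        if u.size != cross.z1.size:
            raise ValueError("effects length does not match marker panel")
    fixed_mask = cross.valid & ~cross.seg
    const = np.array(
        [mu0 + float(cross.z1[fixed_mask] @ u[fixed_mask])
         for mu0, u in zip(intercepts, us)]
    )
    idx = np.nonzero(cross.seg)[0]
    t = len(us)
    if idx.size == 0:
        mean = const.copy()
        return mean, np.zeros(t), np.full((t, t), np.nan)

    switch_p = _reduced_switch_p(gmap, idx)
    a1 = ((cross.z1[idx] + 1) // 2).astype(np.uint8)
    a2 = ((cross.z2[idx] + 1) // 2).astype(np.uint8)
    H1 = np.repeat(a1[None, :], n_progeny, axis=0)
    H2 = np.repeat(a2[None, :], n_progeny, axis=0)
    if selfing_generations is None or np.isinf(selfing_generations):
        gens, fix = fixation_rounds, True
    else:
        gens, fix = int(selfing_generations), False
    H1, H2 = _self_batch(H1, H2, switch_p, gens, rng, fix=fix)
    dos = H1.astype(np.int8) + H2.astype(np.int8) - 1
    U = np.column_stack([u[idx] for u in us])
    vals = dos @ U + const[None, :]
    mean = vals.mean(axis=0)
    var = vals.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals, rowvar=False)
    corr = np.atleast_2d(corr)
    return mean, var, corr


def _gamete_kernel(n_loci: int, switch_p: np.ndarray) -> np.ndarray:
    """Exact gamete distribution per diplotype state.

    Returns G with G[s, h] = P(gamete haplotype h | diplotype s) where a
    diplotype state ``s = h1 * 2^L + h2`` encodes its two haplotypes as
    allele bitmasks (bit k = allele at locus k). The parental-origin chain
    along the loci is Markov (no interference), with switch probabilities
    ``switch_p`` and a fair start.
    """
    L = n_loci
    nh = 1 << L
    h1 = np.arange(nh * nh) >> L
    h2 = np.arange(nh * nh) & (nh - 1)
    G = np.zeros((nh * nh, nh))
    for w in range(nh):
        # probability of origin chain w (bit k = take h2 at locus k)
        pw = 1.0
        prev = None
        for k in range(L):
            bit = (w >> k) & 1
            if prev is None:
                pw *= 0.5
            else:
                pw *= switch_p[k] if bit != prev else 1.0 - switch_p[k]
            prev = bit
        gam = (h1 & ~w) | (h2 & w)
        np.add.at(G, (np.arange(nh * nh), gam), pw)
    return G


def _exact_ril_distribution(a1: np.ndarray, a2: np.ndarray,
                            switch_p: np.ndarray,
                            tol: float = 1e-14) -> np.ndarray:
    """Exact F-infinity RIL haplotype distribution for one linkage group.

    Iterates the selfing Markov chain on diplotype states until the
    heterozygous (transient) mass drops below ``tol``; the absorbing
    states (h, h) give the multilocus fixation probabilities.
    """
    L = a1.size
    nh = 1 << L
    G = _gamete_kernel(L, switch_p)
    start1 = int(sum(int(b) << k for k, b in enumerate(a1)))
    start2 = int(sum(int(b) << k for k, b in enumerate(a2)))
    pi = np.zeros(nh * nh)
    pi[start1 * nh + start2] = 1.0
    diag = np.arange(nh) * nh + np.arange(nh)
    for _ in range(4000):
        het_mass = 1.0 - pi[diag].sum()
        if het_mass < tol:
            break
        M = G.T @ (pi[:, None] * G)
        pi = M.reshape(-1)
    return pi[diag] / pi[diag].sum()


def enumerate_cross_oracle(cross: CrossSpec, effects_list, gmap: GeneticMap,
                           max_loci_per_chrom: int = 8):
    """Exhaustive probability-weighted enumeration of F-infinity progeny.

    Computes exact multilocus RIL genotype probabilities per chromosome
    (chromosomes segregate independently) and from them the exact progeny
    mean, variance and trait-pair covariance. Independent of the analytic
    pairwise-disequilibrium formulas; limited to small segregating sets
    (``max_loci_per_chrom`` linked loci).
    """
    if not isinstance(effects_list, (list, tuple)):
        effects_list = [effects_list]
    intercepts, us = zip(*(_effect_vector(e) for e in effects_list))
    fixed_mask = cross.valid & ~cross.seg
    t = len(us)
    mean = np.array(
        [mu0 + float(cross.z1[fixed_mask] @ u[fixed_mask])
         for mu0, u in zip(intercepts, us)]
    )
    cov = np.zeros((t, t))
    for idx in _seg_blocks(cross, gmap):
        if idx.size > max_loci_per_chrom:
            raise ValueError(
                f"{idx.size} segregating loci on one chromosome exceeds the "
                f"enumeration limit of {max_loci_per_chrom}"
            )
        switch_p = _reduced_switch_p(gmap, idx)
        a1 = ((cross.z1[idx] + 1) // 2).astype(np.uint8)
        a2 = ((cross.z2[idx] + 1) // 2).astype(np.uint8)
        q = _exact_ril_distribution(a1, a2, switch_p)
        nh = q.size
        bits = ((np.arange(nh)[:, None] >> np.arange(idx.size)[None, :]) & 1)
        dos = 2 * bits - 1  # haplotype allele -> homozygous dosage
        vals = dos @ np.column_stack([u[idx] for u in us])  # nh x t
        m = q @ vals
        mean += m
        centred = vals - m[None, :]
        cov += (centred * q[:, None]).T @ centred
    return mean, cov
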