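"""Synthetic nested-association-mapping (NAM) populations with known truth.

A hub parent is crossed to a panel of founders; each biparental family is
taken through one F1 meiosis and a configurable number of selfing rounds
by single-seed descent to produce recombinant inbred lines (RILs).
Crossovers follow the Haldane no-interference model, so the stochastic
simulator is a valid oracle for the analytic cross-parameter equations in
:mod:`crossgain.crosspred`.

Trait genetic architectures are additive: a random subset of markers acts
as causal loci with pleiotropic effects drawn from a multivariate normal,
which induces between-trait genetic correlations through shared loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .gmap import GeneticMap

__all__ = [
    "HaplotypePair",
    "TraitArchitecture",
    "SimConfig",
    "SimTruth",
    "NamDataset",
    "make_gamete",
    "simulate_family",
    "assign_qtl_effects",
    "genetic_values",
    "simulate_phenotypes",
    "true_family_params",
    "simulate_nam",
]

#: selfing rounds used to stand in for complete inbreeding (residual
#: heterozygosity 2^-25 per locus, far below any tolerance used here)
FIXATION_ROUNDS = 25


@dataclass
class HaplotypePair:
    """Two allele vectors (0/1) over the map; inbred lines have h1 == h2."""

    h1: np.ndarray
    h2: np.ndarray

    def __post_init__(self):
        self.h1 = np.asarray(self.h1, dtype=np.uint8)
        self.h2 = np.asarray(self.h2, dtype=np.uint8)
        if self.h1.shape != self.h2.shape or self.h1.ndim != 1:
            raise ValueError("haplotypes must be equal-length 1-D vectors")
        if not (np.isin(self.h1, (0, 1)).all() and np.isin(self.h2, (0, 1)).all()):
            raise ValueError("alleles must be 0/1")

    @property
    def n_markers(self) -> int:
        return self.h1.size

    @property
    def is_inbred(self) -> bool:
        return bool(np.array_equal(self.h1, self.h2))

    @classmethod
    def inbred(cls, alleles) -> "HaplotypePair":
        a = np.asarray(alleles, dtype=np.uint8)
        return cls(a, a.copy())

    def dosage(self) -> np.ndarray:
        """Genotype coded -1/0/+1 (allele count minus 1)."""
        return self.h1.astype(np.int8) + self.h2.astype(np.int8) - 1


def _batch_gametes(H1: np.ndarray, H2: np.ndarray, switch_p: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of (H1, H2) under Haldane recombination.

    ``switch_p[k]`` is the probability that the parental origin changes
    between marker k-1 and k; the first marker of each chromosome carries
    0.5 so a fresh fair phase is drawn there, which also makes a single
    cumulative parity sweep across chromosome boundaries exact.
    """
    switches = rng.random(H1.shape) < switch_p
    origin = np.cumsum(switches, axis=1) & 1  # parity: 0 -> h1, 1 -> h2
    return np.where(origin == 0, H1, H2)


def make_gamete(parent: HaplotypePair, gmap: GeneticMap,
                rng: np.random.Generator) -> np.ndarray:
    """Simulate one recombinant haplotype from ``parent``."""
    if parent.n_markers != gmap.n_markers:
        raise ValueError(
            f"haplotype length {parent.n_markers} != map size {gmap.n_markers}"
        )
    return _batch_gametes(
        parent.h1[None, :], parent.h2[None, :], gmap.interval_recomb(), rng
    )[0]


def _self_batch(H1, H2, switch_p, generations, rng, fix=False):
    """Advance a batch of individuals through selfing by single-seed descent."""
    for _ in range(generations):
        new1 = _batch_gametes(H1, H2, switch_p, rng)
        new2 = _batch_gametes(H1, H2, switch_p, rng)
        H1, H2 = new1, new2
    if fix:
        # collapse residual heterozygosity; h1 is a fair pick by symmetry
        H2 = H1
    return H1, H2


def simulate_family(p1: HaplotypePair, p2: HaplotypePair, n_ril: int,
                    selfing_generations, gmap: GeneticMap,
                    rng: np.random.Generator, strict: bool = True,
                    line_prefix: str = "ril") -> GenotypeMatrix:
    """Derive ``n_ril`` RILs from the cross p1 x p2.

    Each RIL is an independent lineage: one F1 meiosis pair followed by
    ``selfing_generations`` selfing rounds (``None`` means complete
    inbreeding, implemented as :data:`FIXATION_ROUNDS` rounds followed by
    collapsing any residual heterozygosity).
    """
    if n_ril < 1:
        raise ValueError("n_ril must be >= 1")
    for tag, p in (("parent1", p1), ("parent2", p2)):
        if p.n_markers != gmap.n_markers:
            raise ValueError(f"{tag} haplotype length does not match map")
        if strict and not p.is_inbred:
            raise ValueError(f"{tag} is heterozygous; inbred parents required")
    switch_p = gmap.interval_recomb()
    f1_h1 = np.repeat(p1.h1[None, :], n_ril, axis=0)
    f1_h2 = np.repeat(p2.h1[None, :], n_ril, axis=0)
    if selfing_generations is None or np.isinf(selfing_generations):
        gens, fix = FIXATION_ROUNDS, True
    else:
        gens, fix = int(selfing_generations), False
        if gens < 0:
            raise ValueError("selfing_generations must be >= 0")
    # the F1 -> F2 meiosis is the first selfing round applied to the F1 pair
    H1, H2 = _self_batch(f1_h1, f1_h2, switch_p, gens, rng, fix=fix)
    dosages = H1.astype(np.int8) + H2.astype(np.int8) - 1
    ids = np.array([f"{line_prefix}{k + 1:04d}" for k in range(n_ril)], object)
    return GenotypeMatrix(ids, gmap.marker_id, dosages.astype(float))


@dataclass
class TraitArchitecture:
    """Additive multi-trait QTL architecture over map columns."""

    qtl_indices: np.ndarray          # columns of the genotype matrix
    effect_matrix: np.ndarray        # n_qtl x n_traits, per allele substitution
    effect_covariance: np.ndarray    # n_traits x n_traits
    trait_names: tuple = ()

    def __post_init__(self):
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        self.effect_matrix = np.atleast_2d(np.asarray(self.effect_matrix, float))
        self.effect_covariance = np.atleast_2d(
            np.asarray(self.effect_covariance, float)
        )
        if self.effect_matrix.shape[0] != self.qtl_indices.size:
            raise ValueError("effect_matrix rows must match qtl_indices")
        t = self.effect_matrix.shape[1]
        if self.effect_covariance.shape != (t, t):
            raise ValueError("effect_covariance shape does not match trait count")
        if not self.trait_names:
            self.trait_names = tuple(f"trait{i + 1}" for i in range(t))

    @property
    def n_traits(self) -> int:
        return self.effect_matrix.shape[1]

    def effects_full(self, n_markers: int) -> np.ndarray:
        """Marker-length effect matrix (zeros at non-QTL columns)."""
        out = np.zeros((n_markers, self.n_traits))
        out[self.qtl_indices] = self.effect_matrix
        return out


def assign_qtl_effects(gmap: GeneticMap, n_qtl: int, effect_covariance,
                       rng: np.random.Generator,
                       trait_names=()) -> TraitArchitecture:
    """Draw QTL positions without replacement and pleiotropic effects.

    Effects per QTL are iid multivariate normal with the supplied
    trait-by-trait covariance, so the expected across-QTL correlation of
    effect vectors equals the corresponding correlation of the covariance.
    """
    cov = np.atleast_2d(np.asarray(effect_covariance, float))
    if not np.allclose(cov, cov.T):
        raise ValueError("effect covariance must be symmetric")
    if np.min(np.linalg.eigvalsh(cov)) < -1e-10 * max(1.0, np.abs(cov).max()):
        raise ValueError("effect covariance must be positive semi-definite")
    if n_qtl > gmap.n_markers:
        raise ValueError("n_qtl exceeds number of markers")
    idx = np.sort(rng.choice(gmap.n_markers, size=n_qtl, replace=False))
    # svd method handles singular (perfectly correlated) covariances
    effects = rng.multivariate_normal(
        np.zeros(cov.shape[0]), cov, size=n_qtl, method="svd"
    )
    return TraitArchitecture(idx, effects, cov, tuple(trait_names))


@dataclass
class SimConfig:
    """Knobs for the synthetic NAM generator; all randomness flows from rng_seed."""

    n_founders: int = 5
    n_families: int = 5
    ril_per_family: int = 100
    selfing_generations: int | None = None  # None = fully inbred (F-infinity)
    n_chromosomes: int = 5
    markers_per_chromosome: int = 20
    chromosome_length_cM: float = 100.0
    n_qtl: int = 40
    heritability: tuple = (0.7,)          # plot-level h2 per trait
    n_environments: int = 3
    env_variance: float = 1.0
    effect_correlations: tuple = ()       # upper-triangle trait correlations
    effect_scale: tuple = ()              # per-trait effect sd (default 1)
    intercepts: tuple = ()                # per-trait intercept (default 0)
    trait_names: tuple = ()
    with_checks: bool = False
    set_size: int = 35
    set_effect_sd: float = 0.0
    selection_proportion: float = 0.10
    directions: tuple = ()                # "high"/"low" per trait, default high
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("n_founders", "n_families", "ril_per_family",
                     "n_chromosomes", "markers_per_chromosome", "n_qtl",
                     "n_environments"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_families > self.n_founders:
            raise ValueError("n_families cannot exceed n_founders")
        self.heritability = tuple(float(h) for h in np.atleast_1d(self.heritability))
        for h in self.heritability:
            if not 0.0 < h <= 1.0:
                raise ValueError("heritability must be in (0, 1]")
        t = self.n_traits
        if not self.trait_names:
            self.trait_names = tuple(f"trait{i + 1}" for i in range(t))
        if not self.intercepts:
            self.intercepts = (0.0,) * t
        if not self.effect_scale:
            self.effect_scale = (1.0,) * t
        if not self.directions:
            self.directions = ("high",) * t
        if len(self.directions) != t or len(self.intercepts) != t:
            raise ValueError("per-trait settings must match trait count")

    @property
    def n_traits(self) -> int:
        return len(self.heritability)

    def effect_covariance(self) -> np.ndarray:
        t = self.n_traits
        corr = np.eye(t)
        vals = list(self.effect_correlations)
        k = 0
        for i in range(t):
            for j in range(i + 1, t):
                r = vals[k] if k < len(vals) else 0.0
                corr[i, j] = corr[j, i] = r
                k += 1
        s = np.asarray(self.effect_scale, float)
        return corr * np.outer(s, s)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown simulation config keys: {sorted(extra)}")
        d = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def genetic_values(genotypes: GenotypeMatrix, arch: TraitArchitecture,
                   intercepts=None) -> np.ndarray:
    """True genetic value per line per trait (additive, dosage * effect)."""
    Z = genotypes.dosages[:, arch.qtl_indices]
    if np.isnan(Z).any():
        raise ValueError("missing dosages at QTL columns")
    g = Z @ arch.effect_matrix
    if intercepts is not None:
        g = g + np.asarray(intercepts, float)[None, :]
    return g


@dataclass
class SimTruth:
    """Per-family true parameters computed from simulated genetic values."""

    families: list
    trait_names: tuple
    mean: np.ndarray        # F x T
    variance: np.ndarray    # F x T
    musp: np.ndarray        # F x T
    rg: np.ndarray          # F x T x T
    arch: TraitArchitecture = field(repr=False, default=None)

    def to_dict(self) -> dict:
        out = {}
        for f, fam in enumerate(self.families):
            out[str(fam)] = {
                "mean": dict(zip(self.trait_names, self.mean[f].tolist())),
                "variance": dict(zip(self.trait_names, self.variance[f].tolist())),
                "musp": dict(zip(self.trait_names, self.musp[f].tolist())),
                "rg": {
                    f"{a}:{b}": float(self.rg[f, i, j])
                    for i, a in enumerate(self.trait_names)
                    for j, b in enumerate(self.trait_names)
                    if i < j
                },
            }
        return out


def _n_selected(p: float, n: int) -> int:
    return max(1, int(round(p * n)))


def true_family_params(genotypes: GenotypeMatrix, families, arch: TraitArchitecture,
                       p: float = 0.10, directions=None,
                       intercepts=None) -> SimTruth:
    """Exact family parameters from the simulated lines' genetic values.

    Superior-progeny mean is the mean of the best ``p`` fraction of lines,
    direction-aware; correlations use the pooled within-family Pearson
    correlation of genetic values.
    """
    fams = np.asarray(families, dtype=object)
    if fams.size != genotypes.n_lines:
        raise ValueError("families must align with genotype rows")
    t = arch.n_traits
    directions = tuple(directions) if directions else ("high",) * t
    g = genetic_values(genotypes, arch, intercepts)
    fam_list = list(pd.unique(fams))
    F = len(fam_list)
    mean = np.zeros((F, t))
    var = np.zeros((F, t))
    musp = np.zeros((F, t))
    rg = np.full((F, t, t), np.nan)
    for f, fam in enumerate(fam_list):
        gf = g[fams == fam]
        n = gf.shape[0]
        if n < 2:
            raise ValueError(f"family {fam!r} has fewer than 2 lines")
        mean[f] = gf.mean(axis=0)
        var[f] = gf.var(axis=0, ddof=1)
        nsel = _n_selected(p, n)
        for j in range(t):
            srt = np.sort(gf[:, j])
            musp[f, j] = srt[-nsel:].mean() if directions[j] == "high" else srt[:nsel].mean()
        sd = np.sqrt(var[f])
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.cov(gf, rowvar=False, ddof=1)
            c = np.atleast_2d(c)
            rg[f] = c / np.outer(sd, sd)
        np.fill_diagonal(rg[f], 1.0)
        rg[f][np.outer(sd == 0, np.ones(t, bool)) | np.outer(np.ones(t, bool), sd == 0)] = np.nan
        np.fill_diagonal(rg[f], 1.0)
    return SimTruth(fam_list, arch.trait_names, mean, var, musp, rg, arch)


def simulate_phenotypes(genotypes: GenotypeMatrix, families,
                        arch: TraitArchitecture, config: SimConfig,
                        rng: np.random.Generator,
                        parents: GenotypeMatrix | None = None,
                        pedigree: pd.DataFrame | None = None) -> pd.DataFrame:
    """Multi-environment plot phenotypes in long format.

    Plot value = intercept + genetic value + environment effect (+ set
    effect) + residual. Residual variance per trait is calibrated against
    the realized variance of genetic values so the plot-level heritability
    matches the config exactly for the drawn population.
    """
    fams = np.asarray(families, dtype=object)
    g = genetic_values(genotypes, arch, config.intercepts)
    t = arch.n_traits
    var_g = g.var(axis=0, ddof=1)
    h2 = np.asarray(config.heritability, float)
    sd_eps = np.sqrt(var_g * (1.0 - h2) / h2)

    env_ids = [f"env{j + 1}" for j in range(config.n_environments)]
    env_eff = rng.normal(0.0, np.sqrt(config.env_variance),
                         size=(config.n_environments, t))

    # set assignment within family (one set per family unless checks on)
    set_of_line = {}
    records = []  # (line_id, family_id, set_id, is_check, gvalue row)
    fam_order = list(pd.unique(fams))
    parent_g = None
    if parents is not None:
        parent_g = genetic_values(parents, arch, config.intercepts)
    for fam in fam_order:
        lines = genotypes.line_ids[fams == fam]
        gl = g[fams == fam]
        if config.with_checks:
            n_sets = max(1, int(np.ceil(len(lines) / config.set_size)))
        else:
            n_sets = 1
        for k, (lid, gv) in enumerate(zip(lines, gl)):
            sid = f"{fam}_s{(k % n_sets) + 1}"
            records.append((lid, fam, sid, 0, gv))
            set_of_line[lid] = sid
        if config.with_checks and parents is not None and pedigree is not None:
            row = pedigree.loc[pedigree["family_id"] == fam]
            if not row.empty:
                for parent in (row.iloc[0]["parent1"], row.iloc[0]["parent2"]):
                    if parents.has_line(parent):
                        pg = parent_g[list(parents.line_ids).index(parent)]
                        for s in range(n_sets):
                            records.append((parent, fam, f"{fam}_s{s + 1}", 1, pg))

    set_ids = sorted({r[2] for r in records})
    set_eff = {}
    for sid in set_ids:
        set_eff[sid] = (rng.normal(0.0, config.set_effect_sd, size=t)
                        if config.set_effect_sd > 0 else np.zeros(t))

    rows = []
    for j, env in enumerate(env_ids):
        for (lid, fam, sid, is_check, gv) in records:
            eps = rng.normal(0.0, sd_eps)
            vals = gv + env_eff[j] + set_eff[sid] + eps
            for ti, trait in enumerate(config.trait_names):
                rows.append((lid, fam, env, sid, is_check, trait, vals[ti]))
    return pd.DataFrame(
        rows,
        columns=["line_id", "family_id", "env_id", "set_id", "is_check",
                 "trait", "value"],
    )


@dataclass
class NamDataset:
    """Bundle of everything one synthetic NAM run produces."""

    config: SimConfig
    gmap: GeneticMap
    genotypes: GenotypeMatrix      # RILs only
    parents: GenotypeMatrix        # hub + founders
    families: np.ndarray           # family id per RIL row
    pedigree: pd.DataFrame         # family_id, parent1, parent2
    phenotypes: pd.DataFrame
    arch: TraitArchitecture
    truth: SimTruth


def simulate_nam(config: SimConfig, rng: np.random.Generator | None = None) -> NamDataset:
    """Generate a complete hub-parent NAM dataset from a config and seed."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    gmap = GeneticMap.uniform(config.n_chromosomes, config.markers_per_chromosome,
                              config.chromosome_length_cM)
    m = gmap.n_markers

    hub = HaplotypePair.inbred(rng.integers(0, 2, size=m))
    founders = [HaplotypePair.inbred(rng.integers(0, 2, size=m))
                for _ in range(config.n_founders)]
    parent_ids = ["HUB"] + [f"P{i + 1:02d}" for i in range(config.n_founders)]
    parent_dos = np.vstack([hub.dosage()] + [f.dosage() for f in founders]).astype(float)
    parents = GenotypeMatrix(np.array(parent_ids, object), gmap.marker_id, parent_dos)

    arch = assign_qtl_effects(gmap, config.n_qtl, config.effect_covariance(),
                              rng, config.trait_names)

    fam_ids, ped_rows, blocks, fam_col = [], [], [], []
    for f in range(config.n_families):
        fam = f"fam{f + 1:02d}"
        fam_ids.append(fam)
        ped_rows.append((fam, "HUB", f"P{f + 1:02d}"))
        ril = simulate_family(hub, founders[f], config.ril_per_family,
                              config.selfing_generations, gmap, rng,
                              line_prefix=f"{fam}_r")
        blocks.append(ril.dosages)
        fam_col.extend([fam] * config.ril_per_family)
    line_ids = np.concatenate(
        [[f"{fam}_r{k + 1:04d}" for k in range(config.ril_per_family)]
         for fam in fam_ids]
    ).astype(object)
    genotypes = GenotypeMatrix(line_ids, gmap.marker_id, np.vstack(blocks))
    families = np.asarray(fam_col, dtype=object)
    pedigree = pd.DataFrame(ped_rows, columns=["family_id", "parent1", "parent2"])

    phenos = simulate_phenotypes(genotypes, families, arch, config, rng,
                                 parents=parents, pedigree=pedigree)
    truth = true_family_params(genotypes, families, arch,
                               p=config.selection_proportion,
                               directions=config.directions,
                               intercepts=config.intercepts)
    return NamDataset(config, gmap, genotypes, parents, families, pedigree,
                      phenos, arch, truth)
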