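"""Leave-one-family-out cross-validation and predictive-ability summaries.

For each validation family, marker effects are re-estimated on all lines
outside the family, the family's parameters are predicted from its two
parents, and predictions are compared with observed (phenotype-based)
estimates via Pearson correlation, with bootstrap confidence intervals and
a relative bias statistic for the genetic variance.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crosspred import predict_crosses
from .genotypes import GenotypeMatrix
from .gmap import GeneticMap
from .rrblup import RRBlupSolver

log = logging.getLogger(__name__)

__all__ = [
    "lofo_splits",
    "run_crossval",
    "predictive_ability",
    "bootstrap_ci",
    "variance_bias",
    "summarize_crossval",
]


def lofo_splits(pedigree: pd.DataFrame, families: pd.Series | dict,
                available_lines) -> list[tuple[str, list]]:
    """Leave-one-family-out splits: (held-out family, training line ids).

    ``families`` maps line_id -> family_id; ``available_lines`` limits the
    pool (e.g. lines with both genotypes and BLUEs). Families whose parents
    are listed in the pedigree but lack genotypes are the caller's concern;
    here every family in the pedigree yields one split.
    """
    fam_of = dict(families) if not isinstance(families, pd.Series) \
        else families.to_dict()
    pool = [l for l in available_lines if l in fam_of]
    fams = list(pedigree["family_id"])
    if len(fams) != len(set(fams)):
        raise ValueError("duplicate families in pedigree")
    if len(fams) < 2:
        raise ValueError("need >= 2 families for leave-one-family-out")
    splits = []
    for fam in fams:
        train = [l for l in pool if fam_of[l] != fam]
        held = {l for l in pool if fam_of[l] == fam}
        if set(train) & held:
            raise AssertionError("leakage: training set intersects held-out family")
        splits.append((fam, train))
    return splits


@dataclass
class CrossValConfig:
    p: float = 0.10
    directions: dict = None
    strict_parents: bool = True

    def __post_init__(self):
        if self.directions is None:
            self.directions = {}


def run_crossval(gmap: GeneticMap, genotypes: GenotypeMatrix,
                 parents: GenotypeMatrix, pedigree: pd.DataFrame,
                 families, blues: pd.DataFrame, observed_traits: pd.DataFrame,
                 observed_pairs: pd.DataFrame, traits=None,
                 config: CrossValConfig | None = None) -> pd.DataFrame:
    """Predicted-vs-observed table per (family, parameter, trait/pair).

    ``observed_traits``/``observed_pairs`` come from
    :func:`crossgain.remlvc.estimate_family_params` computed once on the
    full data — they are validation targets, not per-split quantities.
    Returns long format: family, parameter, trait, trait2, predicted,
    observed.
    """
    config = config or CrossValConfig()
    if traits is None:
        traits = list(pd.unique(blues["trait"]))
    fam_of = pd.Series(np.asarray(families, object),
                       index=genotypes.line_ids).to_dict()
    blues_by_trait = {
        t: blues[blues["trait"] == t].set_index("line_id")["blue"]
        for t in traits
    }
    available = [l for l in genotypes.line_ids
                 if all(l in blues_by_trait[t].index for t in traits)]
    splits = lofo_splits(pedigree, fam_of, available)
    obs_t = observed_traits.set_index(["family", "trait"])
    obs_p = observed_pairs.set_index(["family", "trait1", "trait2"])

    rows = []
    for fam, train in splits:
        ped_row = pedigree.loc[pedigree["family_id"] == fam].iloc[0]
        p1, p2 = ped_row["parent1"], ped_row["parent2"]
        if not (parents.has_line(p1) and parents.has_line(p2)):
            log.warning("family %s skipped: parent genotypes missing", fam)
            continue
        solver = RRBlupSolver(genotypes.subset(train))
        effects = {}
        failed = False
        for t in traits:
            y = blues_by_trait[t].reindex(train).to_numpy(float)
            try:
                effects[t] = solver.fit(y, trait=t)
            except Exception as exc:  # propagate as a dropped family
                log.warning("family %s trait %s: RR-BLUP failed (%s)", fam, t, exc)
                failed = True
        if failed:
            continue
        pred = predict_crosses(
            [(p1, parents.row(p1), p2, parents.row(p2))], effects, gmap,
            p=config.p, directions=config.directions,
            strict=config.strict_parents)[0]
        for i, t in enumerate(traits):
            for param, val in (("mu", pred.mu[i]), ("varG", pred.var_g[i]),
                               ("musp", pred.musp[i])):
                key = (fam, t)
                obs = np.nan
                if key in obs_t.index:
                    col = {"mu": "mu", "varG": "varG", "musp": "musp"}[param]
                    obs = float(obs_t.loc[key, col])
                rows.append((fam, param, t, "", val, obs))
        for i in range(len(traits)):
            for j in range(i + 1, len(traits)):
                key = (fam, traits[i], traits[j])
                obs = float(obs_p.loc[key, "rG"]) if key in obs_p.index else np.nan
                rows.append((fam, "rG", traits[i], traits[j],
                             pred.r_g[i, j], obs))
    return pd.DataFrame(rows, columns=["family", "parameter", "trait",
                                       "trait2", "predicted", "observed"])


def predictive_ability(pred, obs) -> float:
    """Pearson correlation over families; incomplete pairs dropped listwise."""
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    ok = np.isfinite(pred) & np.isfinite(obs)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete (predicted, observed) pairs")
    p, o = pred[ok], obs[ok]
    if np.std(p) == 0 or np.std(o) == 0:
        log.warning("zero variance in predictions or observations")
        return float("nan")
    return float(np.corrcoef(p, o)[0, 1])


def bootstrap_ci(pred, obs, B: int = 10000,
                 rng: np.random.Generator | None = None,
                 level: float = 0.95):
    """Bootstrap CI for the predictive ability by resampling family pairs.

    Replicates resample whole (predicted, observed) pairs with
    replacement; the interval is formed from the order statistics of the
    sorted replicate correlations (the 250th and 9750th of 10,000 for a
    95% interval). Returns ``(lo, hi, significant)`` where significance
    means the interval excludes 0. Degenerate replicates (zero variance)
    are skipped and logged.
    """
    if B < 100:
        raise ValueError("B < 100 makes the order-statistic bounds meaningless")
    rng = rng or np.random.default_rng()
    pred = np.asarray(pred, float)
    obs = np.asarray(obs, float)
    ok = np.isfinite(pred) & np.isfinite(obs)
    p, o = pred[ok], obs[ok]
    n = p.size
    if n < 3:
        raise ValueError("need >= 3 complete pairs")
    idx = rng.integers(0, n, size=(B, n))
    bp = p[idx]
    bo = o[idx]
    bp = bp - bp.mean(axis=1, keepdims=True)
    bo = bo - bo.mean(axis=1, keepdims=True)
    num = np.sum(bp * bo, axis=1)
    den = np.sqrt(np.sum(bp ** 2, axis=1) * np.sum(bo ** 2, axis=1))
    good = den > 0
    n_bad = int(B - good.sum())
    if n_bad:
        log.info("%d degenerate bootstrap replicates skipped", n_bad)
    r = np.sort(num[good] / den[good])
    nb = r.size
    alpha = 1.0 - level
    lo_i = max(int(round(alpha / 2 * B)) - 1, 0)
    hi_i = min(int(round((1 - alpha / 2) * B)) - 1, nb - 1)
    lo_i = min(lo_i, nb - 1)
    lo, hi = float(r[lo_i]), float(r[hi_i])
    significant = bool(lo > 0.0 or hi < 0.0)
    return lo, hi, significant


def variance_bias(pred_vars, obs_vars) -> float:
    """Relative bias of predicted genetic variances, in percent.

    100 * (mean(pred) - mean(obs)) / mean(obs); negative means predictions
    sit on a lower scale than the observations.
    """
    pred = np.asarray(pred_vars, float)
    obs = np.asarray(obs_vars, float)
    ok = np.isfinite(pred) & np.isfinite(obs)
    if ok.sum() < 1:
        raise ValueError("need at least one family with both values")
    mo = obs[ok].mean()
    if mo == 0:
        raise ValueError("mean observed variance is zero")
    return float(100.0 * (pred[ok].mean() - mo) / mo)


def summarize_crossval(results: pd.DataFrame, B: int = 10000,
                       seed: int = 0) -> pd.DataFrame:
    """Predictive ability + bootstrap CI per parameter and trait (pair).

    Bootstrap seeds are derived per (parameter, trait) so the summary is
    reproducible regardless of evaluation order.
    """
    rows = []
    for (param, trait, trait2), grp in results.groupby(
            ["parameter", "trait", "trait2"], sort=True):
        pred = grp["predicted"].to_numpy(float)
        obs = grp["observed"].to_numpy(float)
        ok = np.isfinite(pred) & np.isfinite(obs)
        n = int(ok.sum())
        if n < 3:
            log.warning("skipping %s/%s%s: only %d complete pairs",
                        param, trait, f"/{trait2}" if trait2 else "", n)
            continue
        r = predictive_ability(pred, obs)
        tag = zlib.crc32(f"{param}|{trait}|{trait2}".encode())
        sub_rng = np.random.default_rng(np.random.SeedSequence([seed, tag]))
        lo, hi, sig = bootstrap_ci(pred, obs, B=B, rng=sub_rng)
        bias = variance_bias(pred[ok], obs[ok]) if param == "varG" else np.nan
        rows.append((param, trait, trait2, r, lo, hi, sig, n, bias))
    return pd.DataFrame(rows, columns=["parameter", "trait", "trait2", "r_MP",
                                       "ci_lo", "ci_hi", "significant",
                                       "n_families", "bias_pct"])
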