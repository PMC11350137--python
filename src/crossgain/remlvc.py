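"""Family-level genetic parameters from phenotypes via AI-REML.

Univariate model per family and trait:
    y = X b + Z_g g + Z_t t + e,   g ~ N(0, I s2_G), t ~ N(0, I s2_t)
with fixed effects X = intercept (+ optional set-level check covariate).
The bivariate extension stacks two traits measured on the same plots and
estimates full 2x2 genetic (G), environment (E) and residual (R)
covariance matrices, from which the genetic correlation is computed.

Both fitters use the average-information algorithm with likelihood-guarded
updates: the AI step is accepted only if the restricted log-likelihood does
not decrease; otherwise the step is halved toward the previous iterate, and
the univariate fitter additionally falls back to EM updates, which keeps
variance components inside the parameter space so boundary estimates
(s2_G = 0) remain representable for the likelihood-ratio test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

log = logging.getLogger(__name__)

__all__ = [
    "UnivariateFit",
    "BivariateFit",
    "fit_univariate_reml",
    "lrt_genotype",
    "cullis_reliability",
    "fit_bivariate_reml",
    "fisher_ci",
    "observed_family_stats",
    "estimate_family_params",
]

MAX_ITER = 200
LL_TOL = 1e-8


# ---------------------------------------------------------------------------
# Generic dense AI-REML core
# ---------------------------------------------------------------------------

class _VarModel:
    """V(theta) = sum_i theta_i V_i with V_i given as Z_i Z_i' or I.

    ``designs`` is a list of either an (n x q) design matrix or the string
    "identity". Subclasses/callers provide the data (y, X).
    """

    def __init__(self, y, X, designs, names):
        self.y = np.asarray(y, float)
        self.X = np.atleast_2d(np.asarray(X, float))
        if self.X.shape[0] != self.y.size:
            raise ValueError("X rows must match y")
        self.n = self.y.size
        self.designs = designs
        self.names = list(names)
        self.k = len(designs)
        self._K = []
        for Z in designs:
            if isinstance(Z, str):
                self._K.append(None)  # identity
            else:
                self._K.append(np.asarray(Z, float))

    def build_V(self, theta):
        V = np.zeros((self.n, self.n))
        for th, Z in zip(theta, self._K):
            if Z is None:
                V[np.diag_indices_from(V)] += th
            else:
                V += th * (Z @ Z.T)
        return V

    def rank_q(self, i):
        Z = self._K[i]
        return self.n if Z is None else Z.shape[1]


def _reml_pieces(model: _VarModel, theta):
    """Return (ll, P, Py) or None when V is not positive definite."""
    V = model.build_V(theta)
    try:
        c, low = cho_factor(V, lower=True, check_finite=False)
    except np.linalg.LinAlgError:
        return None
    logdetV = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vinv = cho_solve((c, low), np.eye(V.shape[0]), check_finite=False)
    W = Vinv @ model.X
    XtVX = model.X.T @ W
    try:
        cx = np.linalg.cholesky(XtVX)
    except np.linalg.LinAlgError:
        return None
    logdetX = 2.0 * float(np.sum(np.log(np.diag(cx))))
    Cinv = cho_solve((cx, True), np.eye(XtVX.shape[0]), check_finite=False)
    P = Vinv - W @ Cinv @ W.T
    Py = P @ model.y
    ll = -0.5 * (logdetV + logdetX + float(model.y @ Py))
    return ll, P, Py


def _scores_ai(model: _VarModel, P, Py):
    k = model.k
    tr = np.empty(k)
    quad = np.empty(k)
    S = np.empty((model.n, k))
    for i, Z in enumerate(model._K):
        if Z is None:
            tr[i] = float(np.trace(P))
            quad[i] = float(Py @ Py)
            S[:, i] = Py
        else:
            PZ = P @ Z
            tr[i] = float(np.sum(PZ * Z))
            v = Z.T @ Py
            quad[i] = float(v @ v)
            S[:, i] = Z @ v
    score = -0.5 * (tr - quad)
    AI = 0.5 * (S.T @ P @ S)
    return score, AI, tr, quad


def _ai_reml(model: _VarModel, theta0, floor_frac=1e-6, em_fallback=True,
             max_iter=MAX_ITER, tol=LL_TOL):
    """Run guarded AI-REML; returns dict with estimates and diagnostics."""
    scale = float(np.var(model.y, ddof=1)) or 1.0
    floor = floor_frac * scale
    theta = np.maximum(np.asarray(theta0, float), floor)
    pieces = _reml_pieces(model, theta)
    if pieces is None:
        raise RuntimeError("starting values give a singular covariance")
    ll, P, Py = pieces
    converged = False
    n_iter = 0
    AI = None
    for n_iter in range(1, max_iter + 1):
        score, AI, tr, quad = _scores_ai(model, P, Py)
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = score / np.maximum(np.diag(AI), 1e-12)
        accepted = False
        frac = 1.0
        for _ in range(30):  # step-halving toward the previous iterate
            cand = np.maximum(theta + frac * step, floor)
            pieces = _reml_pieces(model, cand)
            if pieces is not None and pieces[0] >= ll - 1e-12:
                accepted = True
                break
            frac *= 0.5
        if not accepted and em_fallback:
            # EM update: theta_i <- theta_i + theta_i^2 (y'PV_iPy - tr(PV_i)) / q_i
            q = np.array([model.rank_q(i) for i in range(model.k)], float)
            cand = np.maximum(theta + theta ** 2 * (quad - tr) / q, floor)
            pieces = _reml_pieces(model, cand)
            accepted = pieces is not None and pieces[0] >= ll - 1e-12
        if not accepted:
            # no improving step: the iterate is a fixed point of the guarded
            # update if an (almost) zero-length feasible step leaves the
            # likelihood unchanged to tolerance
            if pieces is not None and abs(pieces[0] - ll) <= 1e-6 * (1.0 + abs(ll)):
                converged = True
            break
        new_ll, P, Py = pieces
        theta = cand
        dll = new_ll - ll
        ll = new_ll
        if abs(dll) <= tol * (1.0 + abs(ll)):
            converged = True
            break
    # SEs from the inverse AI matrix at the optimum
    score, AI, tr, quad = _scores_ai(model, P, Py)
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(model.k, np.nan)
    at_floor = theta <= floor * (1 + 1e-9)
    theta_out = np.where(at_floor, 0.0, theta)
    return {
        "theta": theta_out,
        "theta_internal": theta,
        "se": se,
        "ll": ll,
        "converged": converged,
        "n_iter": n_iter,
        "P": P,
        "Py": Py,
        "at_floor": at_floor,
    }


# ---------------------------------------------------------------------------
# Univariate fit
# ---------------------------------------------------------------------------

@dataclass
class UnivariateFit:
    family: str
    trait: str
    sigma2_G: float
    sigma2_t: float
    sigma2_e: float
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    genotype_ids: np.ndarray
    n_env: int
    _P: np.ndarray = field(repr=False, default=None)
    _Zg: np.ndarray = field(repr=False, default=None)

    @property
    def n_genotypes(self) -> int:
        return self.genotype_ids.size


def _design_from_phenos(df: pd.DataFrame, covariate: str):
    lines, line_idx = np.unique(df["line_id"], return_inverse=True)
    envs, env_idx = np.unique(df["env_id"], return_inverse=True)
    n = len(df)
    Zg = np.zeros((n, lines.size))
    Zg[np.arange(n), line_idx] = 1.0
    Zt = np.zeros((n, envs.size))
    Zt[np.arange(n), env_idx] = 1.0
    X = [np.ones((n, 1))]
    if covariate == "checks" and "set_id" in df.columns and "is_check" in df.columns:
        from .blues import check_covariate
        checks = df[df["is_check"] == 1]
        if not checks.empty:
            cov = check_covariate(df)
            col = df["set_id"].map(cov).to_numpy(float)
            if not np.allclose(col, 0.0):
                X.append(col[:, None])
    return lines, envs, Zg, Zt, np.hstack(X)


def fit_univariate_reml(phenos: pd.DataFrame, trait: str, family: str = "",
                        covariate: str = "none",
                        include_genotype: bool = True,
                        max_iter: int = MAX_ITER) -> UnivariateFit:
    """AI-REML fit of (s2_G, s2_t, s2_e) for one family's plots of one trait.

    ``phenos`` must already be subset to the family; check plots (if any)
    are used only for the covariate, not as genotype levels.
    """
    df = phenos[phenos["trait"] == trait].copy()
    if "is_check" in df.columns:
        df_exp = df[df["is_check"] != 1]
    else:
        df_exp = df
    df_exp = df_exp[np.isfinite(df_exp["value"].to_numpy(float))]
    lines = df_exp["line_id"].nunique()
    envs = df_exp["env_id"].nunique()
    if include_genotype and lines < 2:
        raise ValueError("need >= 2 genotypes")
    if envs < 2:
        raise ValueError("need >= 2 environments")

    line_ids, env_ids, Zg, Zt, X = _design_from_phenos(df_exp, "none")
    if covariate == "checks":
        *_, X = _design_from_phenos_with_cov(df, df_exp)
    y = df_exp["value"].to_numpy(float)
    vy = float(np.var(y, ddof=1))
    if include_genotype:
        model = _VarModel(y, X, [Zg, Zt, "identity"], ["G", "t", "e"])
        start = np.full(3, vy / 3.0)
    else:
        model = _VarModel(y, X, [Zt, "identity"], ["t", "e"])
        start = np.full(2, vy / 2.0)
    res = _ai_reml(model, start, max_iter=max_iter)
    if not res["converged"]:
        log.warning("univariate REML did not converge (family=%s trait=%s)",
                    family, trait)
    if include_genotype:
        s2g, s2t, s2e = res["theta"]
        se = res["se"]
    else:
        s2g = 0.0
        s2t, s2e = res["theta"]
        se = np.concatenate([[np.nan], res["se"]])
    return UnivariateFit(family, trait, float(s2g), float(s2t), float(s2e),
                         se, res["ll"], res["converged"], res["n_iter"],
                         line_ids, env_ids.size, res["P"],
                         Zg if include_genotype else None)


def _design_from_phenos_with_cov(df_all, df_exp):
    """Covariate computed from check plots of the full family subset."""
    from .blues import check_covariate
    n = len(df_exp)
    X = [np.ones((n, 1))]
    if "is_check" in df_all.columns and (df_all["is_check"] == 1).any():
        cov = check_covariate(df_all)
        col = df_exp["set_id"].map(cov).to_numpy(float)
        if not np.allclose(col, 0.0):
            X.append(col[:, None])
    return None, None, None, None, np.hstack(X)


def lrt_genotype(phenos: pd.DataFrame, trait: str, family: str = "",
                 covariate: str = "none"):
    """LRT of s2_G = 0: full vs reduced model, boundary-mixture p-value.

    The null puts the variance on the boundary, so the reference
    distribution is the 50:50 mixture of a point mass at 0 and chi^2(1).
    Returns (full_fit, statistic, p_value).
    """
    full = fit_univariate_reml(phenos, trait, family, covariate,
                               include_genotype=True)
    reduced = fit_univariate_reml(phenos, trait, family, covariate,
                                  include_genotype=False)
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if stat == 0.0 else 0.5 * stats.chi2.sf(stat, df=1)
    return full, stat, p


def cullis_reliability(fit: UnivariateFit) -> float:
    """Entry-mean reliability i^2 = 1 - mean pairwise BLUP-difference
    variance over twice the genetic variance; clamped to [0, 1]."""
    s2g = fit.sigma2_G
    if s2g <= 0:
        log.warning("sigma2_G = 0; reliability set to 0 by convention")
        return 0.0
    if fit._P is None or fit._Zg is None:
        raise ValueError("fit does not carry the matrices needed for reliability")
    # PEV of genotype BLUPs: s2g I - s2g^2 Zg' P Zg
    ZPZ = fit._Zg.T @ fit._P @ fit._Zg
    pev = s2g * np.eye(ZPZ.shape[0]) - (s2g ** 2) * ZPZ
    d = np.diag(pev)
    q = d.size
    if q < 2:
        return 0.0
    # mean over unordered pairs of Var(blup_i - blup_j):
    # sum_{i<j} (pev_ii + pev_jj - 2 pev_ij) / (q(q-1)/2)
    sum_d = d.sum()
    off_sum = pev.sum() - sum_d
    v_diff = (2.0 / (q * (q - 1))) * ((q - 1) * sum_d - off_sum)
    return float(np.clip(1.0 - v_diff / (2.0 * s2g), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Bivariate fit
# ---------------------------------------------------------------------------

@dataclass
class BivariateFit:
    family: str
    traits: tuple
    G: np.ndarray
    E: np.ndarray
    R: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_genotypes: int

    @property
    def r_G(self) -> float:
        v1, v2 = self.G[0, 0], self.G[1, 1]
        if v1 <= 0 or v2 <= 0:
            return float("nan")
        return float(self.G[0, 1] / np.sqrt(v1 * v2))


class _BivariateModel:
    """Stacked two-trait model with Kronecker (B x M) covariance terms.

    theta = (G11, G12, G22, E11, E12, E22, R11, R12, R22); M matrices are
    Kg = Zg Zg', Kt = Zt Zt' and the identity (same-plot residual pairing).
    """

    _BASES = [(0, 0), (0, 1), (1, 1)]

    def __init__(self, y1, y2, Zg, Zt, X1):
        self.n = y1.size
        self.y = np.concatenate([y1, y2])
        z = np.zeros_like(X1)
        self.X = np.block([[X1, z], [z, X1]])
        self.Zg, self.Zt = Zg, Zt
        self.Kg = Zg @ Zg.T
        self.Kt = Zt @ Zt.T
        self.k = 9
        self.names = ["G11", "G12", "G22", "E11", "E12", "E22",
                      "R11", "R12", "R22"]
        self._var_idx = [0, 2, 3, 5, 6, 8]  # positions of variances in theta

    def _mats(self):
        return [self.Kg, self.Kt, None]

    def build_V(self, theta):
        n = self.n
        V = np.zeros((2 * n, 2 * n))
        for m_i, M in enumerate(self._mats()):
            for b_i, (a, b) in enumerate(self._BASES):
                th = theta[3 * m_i + b_i]
                if th == 0.0:
                    continue
                blk = th * (M if M is not None else 1.0)
                if M is None:
                    idx = np.diag_indices(n)
                    V[a * n + idx[0], b * n + idx[1]] += th
                    if a != b:
                        V[b * n + idx[0], a * n + idx[1]] += th
                else:
                    V[a * n:(a + 1) * n, b * n:(b + 1) * n] += blk
                    if a != b:
                        V[b * n:(b + 1) * n, a * n:(a + 1) * n] += blk
        return V

    def rank_q(self, i):
        M = self._mats()[i // 3]
        q = self.n if M is None else (self.Zg.shape[1] if i // 3 == 0
                                      else self.Zt.shape[1])
        a, b = self._BASES[i % 3]
        return q * (1 if a == b else 2)


def _biv_scores_ai(model: _BivariateModel, P, Py):
    n = model.n
    k = model.k
    Pb = [[P[a * n:(a + 1) * n, b * n:(b + 1) * n] for b in range(2)]
          for a in range(2)]
    p = [Py[:n], Py[n:]]
    mats = model._mats()
    Mp = []  # M @ p_b for each (M, b)
    for M in mats:
        Mp.append([p[b] if M is None else M @ p[b] for b in range(2)])
    tr = np.empty(k)
    quad = np.empty(k)
    S = np.empty((2 * n, k))
    for m_i, M in enumerate(mats):
        for b_i, (a, b) in enumerate(model._BASES):
            i = 3 * m_i + b_i
            if a == b:
                tr[i] = (float(np.trace(Pb[a][a])) if M is None
                         else float(np.sum(Pb[a][a] * M)))
                quad[i] = float(p[a] @ Mp[m_i][a])
                s = np.zeros(2 * n)
                s[a * n:(a + 1) * n] = Mp[m_i][a]
            else:
                tr[i] = (2.0 * float(np.trace(Pb[0][1])) if M is None
                         else 2.0 * float(np.sum(Pb[0][1] * M)))
                quad[i] = 2.0 * float(p[0] @ Mp[m_i][1])
                s = np.concatenate([Mp[m_i][1], Mp[m_i][0]])
            S[:, i] = s
    score = -0.5 * (tr - quad)
    AI = 0.5 * (S.T @ P @ S)
    return score, AI, tr, quad


def fit_bivariate_reml(phenos: pd.DataFrame, trait1: str, trait2: str,
                       family: str = "", covariate: str = "none",
                       start: np.ndarray | None = None,
                       max_iter: int = MAX_ITER) -> BivariateFit:
    """AI-REML for a trait pair within one family (full G, E, R 2x2).

    Both traits must be observed on shared plots (same line/env/set keys)
    for the residual covariance to be identified; plots missing either
    trait are dropped.
    """
    keys = ["line_id", "env_id"] + (["set_id"] if "set_id" in phenos.columns else [])
    df = phenos
    if "is_check" in df.columns:
        df = df[df["is_check"] != 1]
    wide = (df[df["trait"].isin([trait1, trait2])]
            .pivot_table(index=keys, columns="trait", values="value",
                         aggfunc="mean"))
    if trait1 not in wide.columns or trait2 not in wide.columns:
        raise ValueError("both traits must be observed")
    wide = wide.dropna(subset=[trait1, trait2]).reset_index()
    if wide.empty:
        raise ValueError(
            f"traits {trait1!r} and {trait2!r} share no plots; residual "
            "covariance is not identified")
    lines, line_idx = np.unique(wide["line_id"], return_inverse=True)
    envs, env_idx = np.unique(wide["env_id"], return_inverse=True)
    if lines.size < 2 or envs.size < 2:
        raise ValueError("need >= 2 genotypes and >= 2 environments")
    n = len(wide)
    Zg = np.zeros((n, lines.size))
    Zg[np.arange(n), line_idx] = 1.0
    Zt = np.zeros((n, envs.size))
    Zt[np.arange(n), env_idx] = 1.0
    X1 = np.ones((n, 1))
    if covariate == "checks" and "set_id" in phenos.columns \
            and "is_check" in phenos.columns:
        from .blues import check_covariate
        chk = phenos[phenos["trait"].isin([trait1, trait2])]
        if (chk["is_check"] == 1).any():
            cov = check_covariate(chk)
            col = wide["set_id"].map(cov).to_numpy(float)
            if not np.allclose(col, 0.0):
                X1 = np.hstack([X1, col[:, None]])
    y1 = wide[trait1].to_numpy(float)
    y2 = wide[trait2].to_numpy(float)
    model = _BivariateModel(y1, y2, Zg, Zt, X1)
    if start is None:
        v1 = float(np.var(y1, ddof=1))
        v2 = float(np.var(y2, ddof=1))
        start = np.array([v1 / 3, 0.0, v2 / 3, v1 / 3, 0.0, v2 / 3,
                          v1 / 3, 0.0, v2 / 3])
    res = _ai_reml_bivariate(model, start, max_iter=max_iter)
    th = res["theta"]
    G = np.array([[th[0], th[1]], [th[1], th[2]]])
    E = np.array([[th[3], th[4]], [th[4], th[5]]])
    R = np.array([[th[6], th[7]], [th[7], th[8]]])
    if not res["converged"]:
        log.warning("bivariate REML did not converge (family=%s, %s/%s)",
                    family, trait1, trait2)
    return BivariateFit(family, (trait1, trait2), G, E, R, res["se"],
                        res["ll"], res["converged"], res["n_iter"],
                        lines.size)


def _project_biv(theta, floor):
    """Keep each 2x2 component (G, E, R) PSD: floor variances, cap covariances."""
    th = np.asarray(theta, float).copy()
    for base in (0, 3, 6):
        v1 = max(th[base], floor)
        v2 = max(th[base + 2], floor)
        cap = np.sqrt(v1 * v2) * (1.0 - 1e-8)
        th[base], th[base + 2] = v1, v2
        th[base + 1] = float(np.clip(th[base + 1], -cap, cap))
    return th


def _ai_reml_bivariate(model: _BivariateModel, theta0, max_iter=MAX_ITER,
                       tol=LL_TOL):
    scale = float(np.var(model.y, ddof=1)) or 1.0
    floor = 1e-6 * scale
    var_idx = model._var_idx
    theta = _project_biv(theta0, floor)
    pieces = _reml_pieces(model, theta)
    if pieces is None:
        raise RuntimeError("starting values give a singular covariance")
    ll, P, Py = pieces
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        score, AI, tr, quad = _biv_scores_ai(model, P, Py)
        try:
            step = np.linalg.solve(AI, score)
        except np.linalg.LinAlgError:
            step = score / np.maximum(np.diag(AI), 1e-12)
        accepted = False
        frac = 1.0
        for _ in range(30):
            cand = _project_biv(theta + frac * step, floor)
            pieces = _reml_pieces(model, cand)
            if pieces is not None and pieces[0] >= ll - 1e-12:
                accepted = True
                break
            frac *= 0.5
        if not accepted:
            if pieces is not None and abs(pieces[0] - ll) <= 1e-6 * (1.0 + abs(ll)):
                converged = True
            break
        new_ll, P, Py = pieces
        theta = cand
        dll = new_ll - ll
        ll = new_ll
        if abs(dll) <= tol * (1.0 + abs(ll)):
            converged = True
            break
    score, AI, tr, quad = _biv_scores_ai(model, P, Py)
    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(model.k, np.nan)
    at_floor = np.zeros(model.k, bool)
    at_floor[var_idx] = theta[var_idx] <= floor * (1 + 1e-9)
    theta_out = theta.copy()
    theta_out[at_floor] = 0.0
    return {"theta": theta_out, "se": se, "ll": ll, "converged": converged,
            "n_iter": n_iter}


# ---------------------------------------------------------------------------
# Descriptive statistics and confidence intervals
# ---------------------------------------------------------------------------

def fisher_ci(r: float, n: int, level: float = 0.95):
    """Fisher-transform confidence interval for a correlation."""
    if n <= 3:
        raise ValueError("need n > 3 for the Fisher interval")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError("correlation must be finite with |r| <= 1")
    if abs(r) == 1.0:
        log.warning("|r| = 1: degenerate Fisher interval")
        return float(r), float(r)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def observed_family_stats(blues: pd.DataFrame, line_ids, trait: str,
                          p: float = 0.10, direction: str = "high"):
    """Family mean and superior-progeny mean from line BLUEs.

    mu = mean of the family's BLUEs; mu_SP = mean of the best
    max(1, round(p*n)) BLUEs in the favourable direction.
    """
    if direction not in ("high", "low"):
        raise ValueError(f"unknown direction {direction!r}")
    sub = blues[(blues["trait"] == trait) & blues["line_id"].isin(set(line_ids))]
    vals = sub["blue"].to_numpy(float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("family has no BLUEs for this trait")
    n_sel = max(1, int(round(p * vals.size)))
    srt = np.sort(vals)
    musp = srt[-n_sel:].mean() if direction == "high" else srt[:n_sel].mean()
    return float(vals.mean()), float(musp)


# ---------------------------------------------------------------------------
# Orchestration over families
# ---------------------------------------------------------------------------

def estimate_family_params(phenos: pd.DataFrame, blues: pd.DataFrame,
                           traits=None, trait_pairs=None, p: float = 0.10,
                           directions: dict | None = None,
                           covariate: str = "none"):
    """Observed family parameters for every family in the phenotype table.

    Returns ``(per_trait, per_pair)`` data frames:
    per_trait: family, trait, mu, musp, varG, varG_se, i2, lrt_stat, lrt_p;
    per_pair: family, trait1, trait2, rG, ci_lo, ci_hi, converged.
    """
    directions = directions or {}
    if traits is None:
        traits = list(pd.unique(phenos["trait"]))
    if trait_pairs is None:
        trait_pairs = [(a, b) for i, a in enumerate(traits)
                       for b in traits[i + 1:]]
    rows, prows = [], []
    for fam, fam_df in phenos.groupby("family_id", sort=True):
        fam_lines = fam_df.loc[fam_df.get("is_check", 0) != 1, "line_id"].unique()
        uni = {}
        for tr in traits:
            try:
                fit, stat, pval = lrt_genotype(fam_df, tr, str(fam), covariate)
            except ValueError as exc:
                log.warning("family %s trait %s: %s", fam, tr, exc)
                continue
            uni[tr] = fit
            i2 = cullis_reliability(fit)
            mu, musp = observed_family_stats(
                blues, fam_lines, tr, p, directions.get(tr, "high"))
            se_g = fit.se[0] if fit.se is not None else np.nan
            rows.append((fam, tr, mu, musp, fit.sigma2_G, se_g, i2, stat,
                         pval, fit.converged))
        for (t1, t2) in trait_pairs:
            if t1 not in uni or t2 not in uni:
                continue
            f1, f2 = uni[t1], uni[t2]
            start = np.array([
                max(f1.sigma2_G, 1e-8), 0.0, max(f2.sigma2_G, 1e-8),
                max(f1.sigma2_t, 1e-8), 0.0, max(f2.sigma2_t, 1e-8),
                max(f1.sigma2_e, 1e-8), 0.0, max(f2.sigma2_e, 1e-8),
            ])
            try:
                bfit = fit_bivariate_reml(fam_df, t1, t2, str(fam), covariate,
                                          start=start)
            except ValueError as exc:
                log.warning("family %s pair %s/%s: %s", fam, t1, t2, exc)
                continue
            r = bfit.r_G
            if np.isfinite(r) and abs(r) < 1:
                lo, hi = fisher_ci(np.clip(r, -1, 1), int(len(fam_lines)))
            elif np.isfinite(r):
                lo = hi = float(np.clip(r, -1, 1))
            else:
                lo = hi = float("nan")
            prows.append((fam, t1, t2, r, lo, hi, bfit.converged))
    per_trait = pd.DataFrame(
        rows, columns=["family", "trait", "mu", "musp", "varG", "varG_se",
                       "i2", "lrt_stat", "lrt_p", "converged"])
    per_pair = pd.DataFrame(
        prows, columns=["family", "trait1", "trait2", "rG", "ci_lo", "ci_hi",
                        "converged"])
    return per_trait, per_pair
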