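"""Ridge-regression BLUP estimation of genome-wide marker effects.

Model: y = 1*mu + Z u + e with u ~ N(0, I sigma_u^2), e ~ N(0, I sigma_e^2).
The ridge parameter lambda = sigma_e^2 / sigma_u^2 is estimated by REML
reduced to a one-dimensional profile through the spectral decomposition of
the centred marker matrix; marker effects then solve the mixed-model
equations exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .genotypes import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["MarkerEffects", "RRBlupSolver", "fit_rrblup", "predict_genetic_values"]

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


@dataclass
class MarkerEffects:
    """Per-trait RR-BLUP solution."""

    trait: str
    intercept: float
    effects: np.ndarray
    sigma2_u: float
    sigma2_e: float
    lam: float
    marker_ids: np.ndarray = None
    n_train: int = 0
    converged: bool = True
    at_bound: bool = False
    log_entries: list = field(default_factory=list)

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        if self.sigma2_u < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be >= 0")


class RRBlupSolver:
    """Caches the trait-independent spectral pieces for one training panel.

    Reuse a solver across traits (and across REML refits) when the
    genotype matrix is fixed — e.g. in cross-validation splits.
    """

    def __init__(self, genotypes: GenotypeMatrix):
        self.genotypes = genotypes
        Z = genotypes.imputed()
        n, m = Z.shape
        if n < 2:
            raise ValueError("need at least 2 training lines")
        self.Z = Z
        self.n, self.m = n, m
        Zc = Z - Z.mean(axis=0, keepdims=True)
        # eigenvalues of the centred ZZ' come from the SVD of centred Z;
        # the remaining n-1-rank eigenvalues are exactly zero
        U, s, _ = np.linalg.svd(Zc, full_matrices=False)
        keep = (s ** 2 > s.max() ** 2 * 1e-12) if s.size and s.max() > 0 \
            else np.zeros(s.size, bool)
        self.xi = (s ** 2)[keep]
        self._U = U[:, keep]
        self.ZtZ = Z.T @ Z
        self.Zt1 = Z.sum(axis=0)

    def _profile_restricted_ll(self, y: np.ndarray):
        """Return f(log_lambda) = restricted log-likelihood (profiled in sigma_u^2)."""
        yc = y - y.mean()
        xi = self.xi
        yt = self._U.T @ yc
        r2 = max(float(yc @ yc - yt @ yt), 0.0)
        nm1 = self.n - 1
        n_zero = nm1 - xi.size

        def ll(log_lam):
            lam = np.exp(log_lam)
            denom = xi + lam
            q = float(yt ** 2 @ (1.0 / denom))
            if n_zero > 0:
                q += r2 / lam
            sigma2_u = q / nm1
            if sigma2_u <= 0:
                return -np.inf
            logdet = float(np.log(denom).sum()) + n_zero * np.log(lam)
            return -0.5 * (nm1 * (np.log(sigma2_u) + 1.0) + logdet)

        return ll

    def fit(self, y, trait: str = "", lam: float | None = None) -> MarkerEffects:
        """Estimate (or accept) lambda, then solve the mixed-model equations."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("response length does not match training lines")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in response")
        entries = []
        at_bound = False
        if np.ptp(y) == 0.0:
            # constant response: no genetic signal, no residual information
            return MarkerEffects(trait, float(y[0]), np.zeros(self.m), 0.0, 0.0,
                                 np.inf, self.genotypes.marker_ids, self.n,
                                 True, True, ["constant response; u = 0"])
        if lam is None:
            ll = self._profile_restricted_ll(y)
            lo, hi = _LOG_LAMBDA_BOUNDS
            grid = np.linspace(lo, hi, 121)
            vals = np.array([ll(g) for g in grid])
            k = int(np.argmax(vals))
            a = grid[max(k - 1, 0)]
            b = grid[min(k + 1, grid.size - 1)]
            res = minimize_scalar(lambda t: -ll(t), bounds=(a, b),
                                  method="bounded",
                                  options={"xatol": 1e-10})
            log_lam = float(res.x)
            if log_lam >= hi - 0.05:
                at_bound = True
                entries.append("lambda at upper bound: no detectable genetic signal")
                log.warning("RR-BLUP %s: %s", trait, entries[-1])
            elif log_lam <= lo + 0.05:
                at_bound = True
                entries.append("lambda at lower bound: residual variance near 0")
            lam = float(np.exp(log_lam))
            sigma2_u = self._sigma2_u(y, lam)
        else:
            sigma2_u = self._sigma2_u(y, lam)
        sigma2_e = lam * sigma2_u if np.isfinite(lam) else 0.0

        # joint mixed-model equations for intercept and effects
        m = self.m
        C = np.empty((m + 1, m + 1))
        C[0, 0] = self.n
        C[0, 1:] = self.Zt1
        C[1:, 0] = self.Zt1
        C[1:, 1:] = self.ZtZ + lam * np.eye(m)
        rhs = np.concatenate([[y.sum()], self.Z.T @ y])
        sol = np.linalg.solve(C, rhs)
        mu, u = float(sol[0]), sol[1:]
        return MarkerEffects(trait, mu, u, sigma2_u, sigma2_e, lam,
                             self.genotypes.marker_ids, self.n, True,
                             at_bound, entries)

    def _sigma2_u(self, y, lam):
        """Profiled sigma_u^2 at a given lambda."""
        if not np.isfinite(lam):
            return 0.0
        yc = y - y.mean()
        yt = self._U.T @ yc
        r2 = max(float(yc @ yc - yt @ yt), 0.0)
        nm1 = self.n - 1
        q = float(yt ** 2 @ (1.0 / (self.xi + lam)))
        if nm1 - self.xi.size > 0:
            q += r2 / lam
        return q / nm1

    def restricted_ll(self, y, lam: float) -> float:
        """Profiled restricted log-likelihood at a given lambda (for checks)."""
        return self._profile_restricted_ll(np.asarray(y, float))(np.log(lam))


def fit_rrblup(blues, genotypes: GenotypeMatrix, trait: str) -> MarkerEffects:
    """Convenience wrapper: align BLUEs with genotype rows, then solve.

    ``blues`` is a data frame with line_id/trait/blue columns; lines
    without genotypes (or vice versa) are dropped.
    """
    sub = blues[blues["trait"] == trait]
    ids = [l for l in sub["line_id"] if genotypes.has_line(l)]
    if len(ids) < 2:
        raise ValueError("need >= 2 lines with both BLUEs and genotypes")
    y = sub.set_index("line_id").loc[ids, "blue"].to_numpy(float)
    solver = RRBlupSolver(genotypes.subset(ids))
    return solver.fit(y, trait=trait)


def predict_genetic_values(effects: MarkerEffects, genotypes: GenotypeMatrix) -> np.ndarray:
    """Predicted genetic value per line: intercept + dosage . effects."""
    if effects.effects.size != genotypes.n_markers:
        raise ValueError("marker panel mismatch between effects and genotypes")
    if effects.marker_ids is not None and not np.array_equal(
            np.asarray(effects.marker_ids, object), genotypes.marker_ids):
        raise ValueError("marker ids of effects and genotypes differ")
    return effects.intercept + genotypes.imputed() @ effects.effects
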