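"""Best linear unbiased estimates of genotype effects from plot data.

Genotype, environment and the optional set-level check covariate are all
fitted as fixed effects by ordinary least squares, deliberately avoiding
shrinkage so the estimates can serve as responses for marker-effect
estimation without double-shrinkage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components

log = logging.getLogger(__name__)

__all__ = ["check_covariate", "fit_blues", "DisconnectedDesignError"]

REQUIRED_COLUMNS = ("line_id", "env_id", "trait", "value")


class DisconnectedDesignError(ValueError):
    """Genotype-environment design splits into unconnected groups."""


def check_covariate(phenos: pd.DataFrame) -> pd.Series:
    """Set-level covariate from check/parent plot means, grand-centred.

    For every ``set_id``, the covariate is the mean of all check-flagged
    plot values in that set minus the grand mean over all check plots.
    Sets without any check plot get covariate 0 (with a warning).
    """
    if "set_id" not in phenos.columns or "is_check" not in phenos.columns:
        raise ValueError("phenotype table needs set_id and is_check columns")
    checks = phenos[(phenos["is_check"] == 1) & phenos["value"].notna()]
    sets = pd.unique(phenos["set_id"])
    if checks.empty:
        log.warning("no check plots found; covariate is 0 for all sets")
        return pd.Series(0.0, index=pd.Index(sets, name="set_id"))
    grand = checks["value"].mean()
    per_set = checks.groupby("set_id")["value"].mean() - grand
    cov = per_set.reindex(sets)
    n_missing = int(cov.isna().sum())
    if n_missing:
        log.warning("%d sets have no check plots; their covariate is 0", n_missing)
        cov = cov.fillna(0.0)
    cov.index.name = "set_id"
    return cov


def _check_connected(df: pd.DataFrame):
    lines, line_idx = np.unique(df["line_id"], return_inverse=True)
    envs, env_idx = np.unique(df["env_id"], return_inverse=True)
    n_l, n_e = lines.size, envs.size
    rows = np.concatenate([line_idx, env_idx + n_l])
    cols = np.concatenate([env_idx + n_l, line_idx])
    adj = sparse.coo_matrix(
        (np.ones(rows.size), (rows, cols)), shape=(n_l + n_e, n_l + n_e)
    )
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        groups = []
        for k in range(n_comp):
            in_k = labels[:n_l] == k
            groups.append(sorted(lines[in_k])[:5])
        raise DisconnectedDesignError(
            f"design is disconnected into {n_comp} groups; example lines per "
            f"group: {groups}"
        )


def fit_blues(phenos: pd.DataFrame, trait: str,
              covariate: str = "auto") -> pd.DataFrame:
    """OLS genotype BLUEs for one trait.

    Model: value ~ genotype + environment [+ check covariate | set effect],
    all fixed. ``covariate`` is one of ``"checks"`` (continuous set-level
    covariate from check means), ``"set"`` (fixed set effects), ``"none"``,
    or ``"auto"`` (checks when check plots exist, else none). Estimates are
    re-centred so the mean BLUE equals the grand mean of environment- and
    covariate-adjusted data. Returns columns line_id, trait, blue, se.
    """
    for col in REQUIRED_COLUMNS:
        if col not in phenos.columns:
            raise ValueError(f"phenotype table is missing column {col!r}")
    df = phenos[phenos["trait"] == trait].copy()
    df = df[np.isfinite(df["value"].to_numpy(float))]
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    has_checks = "is_check" in df.columns and (df["is_check"] == 1).any()
    if covariate == "auto":
        covariate = "checks" if has_checks else "none"
    if covariate not in ("checks", "set", "none"):
        raise ValueError(f"unknown covariate mode {covariate!r}")

    _check_connected(df)

    lines, line_idx = np.unique(df["line_id"], return_inverse=True)
    envs, env_idx = np.unique(df["env_id"], return_inverse=True)
    n = len(df)
    n_l, n_e = lines.size, envs.size
    y = df["value"].to_numpy(float)

    blocks = [sparse.coo_matrix(
        (np.ones(n), (np.arange(n), line_idx)), shape=(n, n_l))]
    env_cols = 0
    if n_e > 1:  # reference-level coding for environments
        env_d = sparse.coo_matrix(
            (np.ones(n), (np.arange(n), env_idx)), shape=(n, n_e)).tocsc()[:, 1:]
        blocks.append(env_d)
        env_cols = n_e - 1
    set_levels = None
    if covariate == "checks":
        cov = check_covariate(df)
        cov_col = df["set_id"].map(cov).to_numpy(float)
        if np.allclose(cov_col, 0.0):
            log.warning("check covariate is identically 0; dropping it")
        else:
            blocks.append(sparse.csc_matrix(cov_col[:, None]))
    elif covariate == "set":
        sets, set_idx = np.unique(df["set_id"], return_inverse=True)
        if sets.size > 1:
            set_d = sparse.coo_matrix(
                (np.ones(n), (np.arange(n), set_idx)),
                shape=(n, sets.size)).tocsc()[:, 1:]
            blocks.append(set_d)
            set_levels = (sets.size, set_idx)
    X = sparse.hstack(blocks, format="csc")
    p = X.shape[1]
    A = (X.T @ X).toarray()
    b = X.T @ y
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        raise DisconnectedDesignError(
            "normal equations are singular (collinear design); with set "
            "effects this usually means sets lack shared check genotypes"
        ) from None
    beta = np.linalg.solve(L.T, np.linalg.solve(L, b))
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid / dof) if dof > 0 else 0.0
    Ainv = np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diag(Ainv)[:n_l] * sigma2, 0.0))

    g_hat = beta[:n_l]
    # re-centre so the mean BLUE equals the grand mean of the adjusted data.
    # Categorical effects are centred across their levels first so the
    # adjustment (and hence the BLUE location) is invariant to relabelling.
    adj = y.astype(float).copy()
    pos = n_l
    if env_cols:
        env_beta = np.concatenate([[0.0], beta[pos:pos + env_cols]])
        adj -= (env_beta - env_beta.mean())[env_idx]
        pos += env_cols
    if covariate == "checks" and p > pos:
        adj -= X[:, pos].toarray().ravel() * beta[pos]
        pos += 1
    if set_levels is not None:
        n_s, set_idx = set_levels
        set_beta = np.concatenate([[0.0], beta[pos:pos + n_s - 1]])
        adj -= (set_beta - set_beta.mean())[set_idx]
    blues = g_hat - g_hat[line_idx].mean() + adj.mean()
    return pd.DataFrame(
        {"line_id": lines, "trait": trait, "blue": blues, "se": se}
    )


def fit_blues_all(phenos: pd.DataFrame, traits=None,
                  covariate: str = "auto") -> pd.DataFrame:
    """Per-trait BLUEs stacked into one table."""
    if traits is None:
        traits = list(pd.unique(phenos["trait"]))
    return pd.concat(
        [fit_blues(phenos, t, covariate=covariate) for t in traits],
        ignore_index=True,
    )
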