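"""Maximum-likelihood fitting of the parent-of-origin trio model.

Fits the full model (mating strata, child and optionally maternal
relative risks, imprinting parameter W) and the nested null model (W = 1)
to the observed-data likelihood, by quasi-Newton optimization on the log
scale.  Reports the imprinting relative risk Ŵ with a Wald 95% CI from
the numerically differentiated observed information, and a likelihood
ratio test of W = 1 against chi-square(1).

Parameters whose supporting cells are compatible with no observed family
(for example a mating stratum absent from the data) have their MLE on the
zero boundary; such cells are removed from the support and the parameter
is reported at the boundary stand-in ``exp(-30)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .pedio import MISSING, TrioGenotype
from .poe_model import (
    OBSERVABLE_CATEGORIES,
    PoeParams,
    aggregate_patterns,
    get_table,
)

__all__ = ["ModelConfig", "FitResult", "fit_snp", "fit_categories", "wald_ci"]

_BOUNDARY_LOG = -30.0  # stand-in log-value for zero-boundary parameters
_RESTART_SEED = 1799   # jittered-restart stream, fixed for reproducibility


@dataclass(frozen=True)
class ModelConfig:
    """Which effects enter the full model.

    ``maternal=False`` constrains S1 = S2 = 1 (no maternal genotype
    effect); the imprinting parameter is always present in the full model
    and fixed at 1 in the null.
    """

    maternal: bool = True
    n_restarts: int = 3
    gtol: float = 1e-8


@dataclass
class FitResult:
    """MLEs and the imprinting test for one SNP."""

    params_hat: PoeParams
    rr_poe: float              # Ŵ (NaN when unidentified)
    se_logW: float
    ci95: tuple[float, float]
    loglik_full: float
    loglik_null: float
    lrt_stat: float
    p_value: float
    converged: bool
    n_informative: int
    n_families: int

    def __post_init__(self) -> None:
        if self.lrt_stat < -1e-8:
            raise ValueError(f"negative LRT statistic {self.lrt_stat}")
        self.lrt_stat = max(self.lrt_stat, 0.0)


def wald_ci(
    logW_hat: float, se_logW: float, level: float = 0.95
) -> tuple[float, float]:
    """Wald confidence interval for the relative risk, on the log scale."""
    if not se_logW > 0:
        raise ValueError(f"se_logW must be positive, got {se_logW}")
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    z = stats.norm.ppf(0.5 + level / 2)
    return (
        float(np.exp(logW_hat - z * se_logW)),
        float(np.exp(logW_hat + z * se_logW)),
    )


def _design_columns(table, maternal: bool) -> tuple[np.ndarray, list[str]]:
    """Log-linear design matrix over cells; columns are free log-parameters."""
    cols = []
    names = []
    for j in range(5):  # stratum 5 ({0,0}) is the gauge
        cols.append((table.stratum == j).astype(float))
        names.append(f"mu{j}")
    cols.append((table.c == 1).astype(float)); names.append("R1")
    cols.append((table.c == 2).astype(float)); names.append("R2")
    if maternal:
        cols.append((table.m == 1).astype(float)); names.append("S1")
        cols.append((table.m == 2).astype(float)); names.append("S2")
    cols.append(table.paternal.astype(float)); names.append("W")
    return np.column_stack(cols), names


def _reduce_support(X, names, masks, logt):
    """Drop columns with no compatible observed cell, and their cells.

    A parameter appearing only in cells incompatible with every observed
    family has its MLE at the zero boundary; removing those cells realises
    the limit exactly and keeps the information matrix nonsingular.
    """
    keep_cells = np.ones(X.shape[0], dtype=bool)
    keep_cols = list(range(X.shape[1]))
    dropped: list[str] = []
    changed = True
    while changed:
        changed = False
        reachable = masks[:, keep_cells].any(axis=0)
        for ci in list(keep_cols):
            col = X[keep_cells, ci]
            if not np.any((col != 0) & reachable):
                cell_sel = np.flatnonzero(keep_cells)
                keep_cells[cell_sel[X[cell_sel, ci] != 0]] = False
                keep_cols.remove(ci)
                dropped.append(names[ci])
                changed = True
                break
    return (
        X[np.ix_(keep_cells, keep_cols)],
        [names[i] for i in keep_cols],
        masks[:, keep_cells],
        logt[keep_cells],
        dropped,
    )


def _negll_grad(theta, X, logt, G, n):
    eta = logt + X @ theta
    # center and floor so exp never underflows to an exact zero, which
    # would make empty-looking patterns produce log(0) mid line-search
    eta = np.clip(eta - eta.max(), -700.0, 0.0)
    w = np.exp(eta)
    Z = w.sum()
    Gw = G @ w
    ll = float(n @ np.log(Gw) - n.sum() * np.log(Z))
    wX = w[:, None] * X
    grad = (n / Gw) @ (G @ wX) - n.sum() * wX.sum(axis=0) / Z
    return -ll, -grad


def _optimize(X, logt, G, n, config: ModelConfig):
    rng = np.random.default_rng(_RESTART_SEED)
    best = None
    p = X.shape[1]
    starts = [np.zeros(p)]
    starts += [rng.normal(scale=0.3, size=p) for _ in range(config.n_restarts)]
    for x0 in starts:
        res = optimize.minimize(
            _negll_grad,
            x0,
            args=(X, logt, G, n),
            jac=True,
            method="L-BFGS-B",
            # box keeps boundary-drifting nuisance parameters (empty
            # strata under sparse data) at exp(+-30) instead of overflow
            bounds=[(_BOUNDARY_LOG, -_BOUNDARY_LOG)] * p,
            options={"maxiter": 1000, "ftol": 1e-13, "gtol": config.gtol},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    return best


def _hessian(theta, X, logt, G, n):
    """Observed information by central finite differences of the gradient."""
    p = theta.size
    H = np.zeros((p, p))
    h = 1e-5 * (1.0 + np.abs(theta))
    for i in range(p):
        step = np.zeros(p)
        step[i] = h[i]
        _, g_plus = _negll_grad(theta + step, X, logt, G, n)
        _, g_minus = _negll_grad(theta - step, X, logt, G, n)
        H[i] = (g_plus - g_minus) / (2 * h[i])
    return (H + H.T) / 2


def _params_from_theta(theta, names, dropped) -> PoeParams:
    logs = {name: _BOUNDARY_LOG for name in dropped}
    logs.update(dict(zip(names, theta)))
    mu = tuple(float(np.exp(logs.get(f"mu{j}", 0.0))) for j in range(5)) + (1.0,)
    return PoeParams(
        mu=mu,
        R1=float(np.exp(logs.get("R1", 0.0))),
        R2=float(np.exp(logs.get("R2", 0.0))),
        S1=float(np.exp(logs.get("S1", 0.0))),
        S2=float(np.exp(logs.get("S2", 0.0))),
        W=float(np.exp(logs.get("W", 0.0))),
    )


def _fit_patterns(masks, n, config: ModelConfig, n_informative: int) -> FitResult:
    table = get_table()
    logt = np.log(table.t)
    X_all, names_all = _design_columns(table, config.maternal)
    X, names, G, logt_red, dropped = _reduce_support(
        X_all, names_all, masks.astype(bool), logt
    )
    Gf = G.astype(float)
    n = np.asarray(n, dtype=float)

    w_identified = "W" in names and n_informative > 0

    full = _optimize(X, logt_red, Gf, n, config)
    if "W" in names:
        w_idx = names.index("W")
        null_cols = [i for i in range(len(names)) if i != w_idx]
        null = _optimize(X[:, null_cols], logt_red, Gf, n, config)
        theta_null = np.insert(null.x, w_idx, 0.0)
    else:
        null = full
        theta_null = full.x

    loglik_full = -full.fun
    loglik_null = -null.fun
    lrt = 2.0 * (loglik_full - loglik_null)
    converged = bool(full.success and null.success)

    if w_identified:
        w_idx = names.index("W")
        logW = float(full.x[w_idx])
        H = _hessian(full.x, X, logt_red, Gf, n)
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
        var = cov[w_idx, w_idx]
        se = float(np.sqrt(var)) if var > 0 else float("nan")
        rr = float(np.exp(logW))
        ci = wald_ci(logW, se) if se > 0 else (float("nan"), float("nan"))
        p_value = float(stats.chi2.sf(max(lrt, 0.0), df=1))
        params_hat = _params_from_theta(full.x, names, dropped)
    else:
        warnings.warn(
            "no origin-informative families: imprinting parameter "
            "unidentified, reporting p = 1",
            stacklevel=3,
        )
        rr, se, ci = float("nan"), float("nan"), (float("nan"), float("nan"))
        lrt = 0.0
        p_value = 1.0
        params_hat = _params_from_theta(theta_null, names, dropped + ["W"])

    return FitResult(
        params_hat=params_hat,
        rr_poe=rr,
        se_logW=se,
        ci95=ci,
        loglik_full=loglik_full,
        loglik_null=loglik_null,
        lrt_stat=lrt,
        p_value=p_value,
        converged=converged,
        n_informative=n_informative,
        n_families=int(round(float(n.sum()))),
    )


def _count_informative(masks, n, table) -> int:
    origin_tagged = table.paternal | np.array(
        [cell.origin == "maternal" for cell in table.cells]
    )
    has_origin = masks[:, origin_tagged].any(axis=1)
    return int(n[has_origin].sum())


def fit_snp(
    trios: list[TrioGenotype], config: ModelConfig | None = None
) -> FitResult:
    """Fit full and null (W = 1) models to one SNP's families.

    Families with a missing child genotype are dropped (the design
    ascertains on a genotyped case child).  Both models use identical
    optimizer settings; convergence failure is propagated in
    ``converged``, never silently dropped.
    """
    config = config or ModelConfig()
    usable = [t for t in trios if t.c != MISSING]
    if not usable:
        raise ValueError("no families with a genotyped case child")
    masks, n, _ = aggregate_patterns(usable)
    n_informative = _count_informative(masks, n, get_table())
    return _fit_patterns(masks, n, config, n_informative)


def fit_categories(
    counts, config: ModelConfig | None = None
) -> FitResult:
    """Fit from per-category complete-trio counts (may be non-integer).

    ``counts`` is a 15-vector over :data:`OBSERVABLE_CATEGORIES`; useful
    for fitting expected counts directly.
    """
    config = config or ModelConfig()
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (len(OBSERVABLE_CATEGORIES),):
        raise ValueError(
            f"expected {len(OBSERVABLE_CATEGORIES)} category counts"
        )
    if np.any(counts < 0):
        raise ValueError("negative counts")
    table = get_table()
    masks = np.stack(
        [table.compatibility_mask(m, f, c) for (m, f, c) in OBSERVABLE_CATEGORIES]
    )
    sel = counts > 0
    masks, n = masks[sel], counts[sel]
    n_informative_mask = masks[:, table.paternal | (np.char.equal(
        [cell.origin for cell in table.cells], "maternal"))].any(axis=1)
    n_informative = int(round(float(n[n_informative_mask].sum())))
    return _fit_patterns(masks, n, config, n_informative)
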