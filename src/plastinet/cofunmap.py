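"""Composite functional mapping of plasticity trajectories.

Stress response is treated as a longitudinal trait in its own right: the
plasticity vector z_i (control minus stress trajectory). Each SNP is tested
by comparing the fit of genotype-group-specific logistic mean curves
against a single population curve, both under a shared AR(1) longitudinal
covariance, via a likelihood-ratio (LR) statistic. Genome-wide significance
thresholds come from permutation tests: individual phenotype labels are
shuffled, the genome-wide maximum LR recorded per permutation, and the
empirical (1-alpha) quantile of those maxima taken as the threshold,
separately per marker class (testcross and intercross markers segregate
differently and get their own critical values).

A significant SNP's fitted group curves yield its time-varying genetic
effect curve g_s(t): the genetic standard deviation across genotype groups,
g_s(t) = sqrt( sum_j p_j (mu_j(t) - mu_bar(t))^2 ), smoothed with a Legendre
expansion and resampled on a dense grid for the downstream network stages.

Implementation note: after the null fit, the AR(1) covariance is held fixed
for all per-SNP and permutation fits. The LR then reduces to a difference
of generalized-least-squares criteria that depends on the data only through
per-group mean vectors, which allows every (SNP, group, permutation)
logistic fit to run in one batched Levenberg-Marquardt pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ar1 import AR1Covariance, ar1_quadform, profile_ar1_mle
from .curves import (
    LegendreCurve,
    LogisticParams,
    fit_legendre,
    fit_logistic,
    logistic_eval,
)
from .datamodel import MISSING, GenotypeTable, PlasticitySet, TimeGrid

log = logging.getLogger(__name__)

__all__ = [
    "GroupModel",
    "ScanResult",
    "EffectCurve",
    "loglik",
    "fit_null",
    "scan",
    "permutation_threshold",
    "effect_curve",
]


@dataclass
class GroupModel:
    """Genotype-group mean curves with a shared AR(1) covariance.

    ``groups`` maps genotype code -> (frequency p_j, LogisticParams).
    A single-group model is the null (no genetic effect at the locus).
    """

    groups: dict[int, tuple[float, LogisticParams]]
    covariance: AR1Covariance
    flagged: bool = False

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class EffectCurve:
    """Time-varying genetic effect of a SNP (genetic standard deviation).

    ``values`` are g_s at the measured times; ``legendre`` the smoothed
    representation; ``dense_times``/``dense_values`` a G-point resample used
    by the clustering and network stages.
    """

    snp_id: str
    times: np.ndarray
    values: np.ndarray
    legendre: LegendreCurve
    dense_times: np.ndarray
    dense_values: np.ndarray
    flagged: bool = False


@dataclass
class ScanResult:
    """Per-SNP LR statistics plus class-specific permutation thresholds."""

    snp_ids: list[str]
    lr: np.ndarray
    marker_class: list[str]
    skipped: np.ndarray  # SNPs with a genotype group below the size floor
    group_models: list[GroupModel | None]
    null_model: GroupModel
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def significant(self) -> np.ndarray:
        out = np.zeros(len(self.snp_ids), dtype=bool)
        for j, cls in enumerate(self.marker_class):
            thr = self.thresholds.get(cls)
            if thr is not None and not self.skipped[j]:
                out[j] = self.lr[j] >= thr
        return out


# ---------------------------------------------------------------------------
# likelihood


def loglik(model: GroupModel, z: PlasticitySet, assignment: np.ndarray) -> float:
    """Log-likelihood of plasticity trajectories under a group model.

    Each individual's z_i is multivariate normal about its genotype group's
    logistic mean curve with the shared AR(1) covariance; the AR(1) inverse
    and determinant are evaluated in closed form.
    """
    t = z.grid.times
    T = t.size
    cov = model.covariance
    assignment = np.asarray(assignment)
    total = 0.0
    n_used = 0
    for code, (_, params) in model.groups.items():
        mask = assignment == code
        if not mask.any():
            continue
        E = z.z[mask] - logistic_eval(params, t)[None, :]
        q = ar1_quadform(E, cov.rho).sum() / cov.sigma2
        total += -0.5 * (mask.sum() * (T * np.log(2 * np.pi) + cov.logdet(T)) + q)
        n_used += int(mask.sum())
    if n_used != assignment.size:
        unknown = assignment.size - n_used
        log.debug("loglik: %d individuals outside model groups ignored", unknown)
    return float(total)


# ---------------------------------------------------------------------------
# batched GLS logistic fitting (Levenberg-Marquardt)


def _logistic_mu_jac(theta: np.ndarray, t: np.ndarray):
    """Curve values and Jacobian for a batch of (a, b, r) parameter rows."""
    a = theta[:, 0:1]
    b = theta[:, 1:2]
    r = theta[:, 2:3]
    ert = np.exp(-r * t[None, :])
    denom = 1.0 + b * ert
    mu = a / denom
    d_a = 1.0 / denom
    d_b = -a * ert / denom**2
    d_r = a * b * t[None, :] * ert / denom**2
    return mu, np.stack([d_a, d_b, d_r], axis=2)


def fit_logistic_gls_batch(
    M: np.ndarray,
    t: np.ndarray,
    P: np.ndarray,
    theta0: np.ndarray,
    *,
    max_iter: int = 60,
    tol: float = 1e-10,
):
    """Minimize (mu(theta) - m)' P (mu(theta) - m) for each row m of M.

    Batched damped Gauss-Newton with per-row adaptive damping; rows are
    warm-started from ``theta0`` and steps are only accepted when the
    objective decreases, so the result never fits worse than the start.
    Returns (theta, objective) arrays.
    """
    M = np.atleast_2d(M)
    B = M.shape[0]
    theta = np.array(theta0, dtype=float)
    if theta.ndim == 1:
        theta = np.broadcast_to(theta, (B, 3)).copy()
    lo = 1e-10

    def objective(th):
        mu, _ = _logistic_mu_jac(th, t)
        e = mu - M
        return np.einsum("bi,ij,bj->b", e, P, e)

    obj = objective(theta)
    lam = np.full(B, 1e-3)
    eye = np.eye(3)
    for _ in range(max_iter):
        mu, J = _logistic_mu_jac(theta, t)
        e = mu - M
        PJ = np.einsum("ij,bjk->bik", P, J)
        g = np.einsum("bjk,bj->bk", PJ, e)
        H = np.einsum("bjk,bjl->bkl", J, PJ)
        Hd = H + lam[:, None, None] * eye[None, :, :]
        try:
            step = np.linalg.solve(Hd, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            Hd = Hd + 1e-8 * eye[None, :, :]
            step = np.linalg.solve(Hd, -g[..., None])[..., 0]
        cand = np.clip(theta + step, lo, None)
        obj_cand = objective(cand)
        accept = obj_cand < obj
        theta = np.where(accept[:, None], cand, theta)
        lam = np.where(accept, lam / 3.0, lam * 4.0)
        lam = np.clip(lam, 1e-12, 1e10)
        improved = obj - np.where(accept, obj_cand, obj)
        obj = np.where(accept, obj_cand, obj)
        if improved.max(initial=0.0) < tol and lam.min() > 1e-10:
            break
    return theta, obj


# ---------------------------------------------------------------------------
# null model


def fit_null(
    z: PlasticitySet, *, max_iter: int = 200, tol: float = 1e-6
) -> GroupModel:
    """Fit the no-QTL model: one logistic mean curve + AR(1) covariance.

    Alternates generalized-least-squares curve fitting (given the
    covariance) with closed-form-profiled AR(1) estimation (given the
    curve) until the log-likelihood stabilizes.
    """
    if z.n < 8:
        raise ValueError("need at least 8 individuals for the null fit")
    t = z.grid.times
    T = t.size
    zbar = z.z.mean(axis=0)
    total_var = float(z.z.var(axis=0).sum())  # between-individual variance
    if total_var <= 1e-20:
        cov = AR1Covariance(sigma2=1e-12, rho=0.0)
        return GroupModel(
            groups={0: (1.0, fit_logistic_flat(zbar))}, covariance=cov, flagged=True
        )

    params = fit_logistic(zbar, t)
    cov = profile_ar1_mle(z.z - logistic_eval(params, t)[None, :])
    last_ll = -np.inf
    for _ in range(max_iter):
        # curve given covariance: GLS fit to the grand mean vector
        P = cov.corr_inverse(T)
        theta0 = np.array([[params.a, params.b, params.r]])
        theta, _ = fit_logistic_gls_batch(zbar[None, :], t, P, theta0)
        params = LogisticParams(*(float(v) for v in theta[0]))
        # covariance given curve
        E = z.z - logistic_eval(params, t)[None, :]
        cov = profile_ar1_mle(E)
        ll = -0.5 * (
            z.n * (T * np.log(2 * np.pi) + cov.logdet(T))
            + ar1_quadform(E, cov.rho).sum() / cov.sigma2
        )
        if abs(ll - last_ll) < tol:
            break
        last_ll = ll
    return GroupModel(groups={0: (1.0, params)}, covariance=cov,
                      flagged=cov.sigma2 < 1e-10)


def fit_logistic_flat(y: np.ndarray) -> LogisticParams:
    """Degenerate 'fit' for flat data (no growth information)."""
    return LogisticParams(a=float(np.mean(y)) or 1e-12, b=1e-6, r=1e-6, flagged=True)


# ---------------------------------------------------------------------------
# scan


def _group_layout(g: GenotypeTable, min_group: int):
    """Per-SNP genotype groups and membership, skipping undersized groups.

    Returns (layout, skipped) where layout[j] is a list of
    (code, member_index_array) for scanned SNPs and None for skipped ones.
    """
    m, n = g.codes.shape
    layout: list[list[tuple[int, np.ndarray]] | None] = []
    skipped = np.zeros(m, dtype=bool)
    for j in range(m):
        row = g.codes[j]
        codes = np.unique(row[row != MISSING])
        if codes.size < 2:
            layout.append(None)
            skipped[j] = True
            continue
        groups = [(int(c), np.flatnonzero(row == c)) for c in codes]
        if any(idx.size < min_group for _, idx in groups):
            layout.append(None)
            skipped[j] = True
            continue
        layout.append(groups)
    return layout, skipped


def _lr_from_means(
    means: np.ndarray,
    counts: np.ndarray,
    snp_of_row: np.ndarray,
    n_snps: int,
    t: np.ndarray,
    P: np.ndarray,
    null_params: LogisticParams,
    sigma2: float,
):
    """LR per SNP from stacked per-group mean vectors (shared covariance).

    With the covariance fixed, the within-group scatter cancels between the
    full and null criteria, so LR depends only on group means and sizes:
    LR = sum_g n_g [ q(mean_g; mu_0) - q(mean_g; mu_g) ] / sigma2.
    Fits are warm-started at the null curve, guaranteeing LR >= 0.
    Returns (lr array, fitted theta per group row).
    """
    theta0 = np.array([null_params.a, null_params.b, null_params.r])
    mu0 = logistic_eval(null_params, t)
    e0 = means - mu0[None, :]
    q0 = np.einsum("bi,ij,bj->b", e0, P, e0)
    theta, qf = fit_logistic_gls_batch(means, t, P, theta0)
    contrib = counts * (q0 - qf) / sigma2
    lr = np.zeros(n_snps)
    np.add.at(lr, snp_of_row, contrib)
    return np.maximum(lr, 0.0), theta


def scan(
    z: PlasticitySet,
    g: GenotypeTable,
    *,
    null: GroupModel | None = None,
    min_group: int = 5,
) -> ScanResult:
    """Likelihood-ratio scan of every SNP against the plasticity trajectories.

    Per SNP, genotype-group logistic curves are fitted under the null
    model's AR(1) covariance and LR = 2(lnL_full - lnL_null) computed. SNPs
    with any genotype group smaller than ``min_group`` are skipped.
    """
    if list(g.individual_ids) != list(z.ids):
        raise ValueError("genotype individuals do not match phenotype ids")
    if null is None:
        null = fit_null(z)
    t = z.grid.times
    cov = null.covariance
    P = cov.corr_inverse(t.size)
    null_params = next(iter(null.groups.values()))[1]

    layout, skipped = _group_layout(g, min_group)
    rows_means, rows_counts, rows_snp, rows_code = [], [], [], []
    for j, groups in enumerate(layout):
        if groups is None:
            continue
        for code, idx in groups:
            rows_means.append(z.z[idx].mean(axis=0))
            rows_counts.append(idx.size)
            rows_snp.append(j)
            rows_code.append(code)
    lr = np.zeros(g.m)
    group_models: list[GroupModel | None] = [None] * g.m
    if rows_means:
        means = np.array(rows_means)
        counts = np.array(rows_counts, dtype=float)
        snp_of_row = np.array(rows_snp)
        lr, theta = _lr_from_means(
            means, counts, snp_of_row, g.m, t, P, null_params, cov.sigma2
        )
        # assemble fitted per-SNP group models
        n_obs = {}
        for j, groups in enumerate(layout):
            if groups is None:
                continue
            n_obs[j] = sum(idx.size for _, idx in groups)
        for row, j in enumerate(snp_of_row):
            fr = counts[row] / n_obs[int(j)]
            params = LogisticParams(*(float(v) for v in theta[row]))
            gm = group_models[int(j)]
            if gm is None:
                gm = GroupModel(groups={}, covariance=cov)
                group_models[int(j)] = gm
            gm.groups[rows_code[row]] = (float(fr), params)
    return ScanResult(
        snp_ids=list(g.snp_ids),
        lr=lr,
        marker_class=list(g.marker_class),
        skipped=skipped,
        group_models=group_models,
        null_model=null,
    )


def permutation_threshold(
    z: PlasticitySet,
    g: GenotypeTable,
    n_perm: int,
    alpha: float,
    marker_class: str,
    seed: int,
    *,
    null: GroupModel | None = None,
    min_group: int = 5,
) -> float:
    """Genome-wide LR threshold from permutation of phenotype labels.

    Genotype rows stay intact; individual phenotype vectors are permuted.
    The genome-wide maximum LR over SNPs of ``marker_class`` is recorded per
    permutation and the empirical (1-alpha) quantile of the maxima returned.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if n_perm * alpha < 1 and alpha < 1.0:
        raise ValueError(f"n_perm={n_perm} too small for alpha={alpha}")
    if null is None:
        null = fit_null(z)
    t = z.grid.times
    cov = null.covariance
    P = cov.corr_inverse(t.size)
    null_params = next(iter(null.groups.values()))[1]

    class_mask = np.array([c == marker_class for c in g.marker_class])
    gsub = g.subset_snps(class_mask)
    layout, _ = _group_layout(gsub, min_group)

    # stack (snp, group) membership once; per permutation only the means move
    rows_idx, rows_counts, rows_snp = [], [], []
    for j, groups in enumerate(layout):
        if groups is None:
            continue
        for _, idx in groups:
            rows_idx.append(idx)
            rows_counts.append(idx.size)
            rows_snp.append(j)
    if not rows_idx:
        raise ValueError(f"no scannable SNPs of class {marker_class!r}")
    counts = np.array(rows_counts, dtype=float)
    snp_of_row = np.array(rows_snp)
    n_rows = len(rows_idx)
    # membership matrix scaled to compute group means by one matmul per block
    A = np.zeros((n_rows, z.n))
    for r, idx in enumerate(rows_idx):
        A[r, idx] = 1.0 / idx.size

    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    # batch permutations to keep the batched LM fits large but bounded
    block = max(1, int(2e5) // max(n_rows, 1))
    done = 0
    while done < n_perm:
        nb = min(block, n_perm - done)
        perms = np.array([rng.permutation(z.n) for _ in range(nb)])
        Zp = z.z[perms]  # (nb, n, T)
        means = np.einsum("rn,bnt->brt", A, Zp).reshape(nb * n_rows, t.size)
        lr, _ = _lr_from_means(
            means,
            np.tile(counts, nb),
            np.concatenate(
                [snp_of_row + b * gsub.m for b in range(nb)]
            ),
            gsub.m * nb,
            t,
            P,
            null_params,
            cov.sigma2,
        )
        lr = lr.reshape(nb, gsub.m)
        maxima[done : done + nb] = lr.max(axis=1)
        done += nb
    return float(np.quantile(maxima, 1.0 - alpha, method="higher"))


# ---------------------------------------------------------------------------
# effect curves


def effect_curve(
    model: GroupModel,
    grid: TimeGrid,
    snp_id: str = "",
    *,
    order: int = 4,
    n_dense: int = 30,
) -> EffectCurve:
    """Time-varying genetic effect curve of a fitted SNP model.

    g_s(t) = sqrt( sum_j p_j (mu_j(t) - mu_bar(t))^2 ), the genetic standard
    deviation across genotype groups, Legendre-smoothed and resampled on a
    dense uniform grid.
    """
    t = grid.times
    if model.n_groups < 2:
        flat = LegendreCurve(np.zeros(order + 1), float(t[0]), float(t[-1]))
        dense_t = np.linspace(t[0], t[-1], n_dense)
        return EffectCurve(
            snp_id=snp_id,
            times=t,
            values=np.zeros(t.size),
            legendre=flat,
            dense_times=dense_t,
            dense_values=np.zeros(n_dense),
            flagged=True,
        )
    ps = np.array([p for p, _ in model.groups.values()])
    mus = np.array([logistic_eval(par, t) for _, par in model.groups.values()])
    ps = ps / ps.sum()
    mubar = ps @ mus
    gvals = np.sqrt(np.einsum("j,jk->k", ps, (mus - mubar[None, :]) ** 2))
    order_eff = min(order, t.size - 1)
    leg = fit_legendre(gvals, t, order_eff)
    dense_t = np.linspace(t[0], t[-1], n_dense)
    return EffectCurve(
        snp_id=snp_id,
        times=t,
        values=gvals,
        legendre=leg,
        dense_times=dense_t,
        dense_values=leg(dense_t),
    )
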