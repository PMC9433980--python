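"""Functional clustering of genetic effect curves into a module hierarchy.

Genome-wide effect curves are clustered by the similarity of their temporal
pattern with a Gaussian mixture whose component means are Legendre curves
and whose within-component covariance is AR(1) on the dense grid. The
number of modules is chosen by BIC minimization. Modules larger than a
manageable size are recursively re-clustered into submodules,
sub-submodules and so on, until every unit is at most the Dunbar threshold
(default 150) — the size at which a direct SNP-level network becomes
tractable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .ar1 import AR1Covariance, ar1_quadform
from .cofunmap import EffectCurve
from .curves import LegendreCurve, fit_legendre, legendre_design

log = logging.getLogger(__name__)

__all__ = [
    "MixtureModel",
    "ModuleNode",
    "ModuleTree",
    "em_fit",
    "bic_select",
    "recursive_cluster",
    "module_mean_curves",
]


@dataclass
class MixtureModel:
    """Fitted Gaussian mixture over effect curves.

    Component k has mixing proportion ``proportions[k]``, a Legendre mean
    curve and an AR(1) covariance on the dense grid. ``responsibilities``
    is (n_curves, K) with rows summing to 1.
    """

    K: int
    proportions: np.ndarray
    means: list[LegendreCurve]
    covariances: list[AR1Covariance]
    responsibilities: np.ndarray
    loglik: float
    order: int

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)

    def n_params(self) -> int:
        # per component: order+1 mean coefficients + (sigma2, rho); plus K-1
        # free mixing proportions
        return self.K * (self.order + 1 + 2) + (self.K - 1)

    def bic(self, n_curves: int) -> float:
        return -2.0 * self.loglik + self.n_params() * np.log(n_curves)


def _curve_matrix(curves: list[EffectCurve]) -> tuple[np.ndarray, np.ndarray]:
    t = curves[0].dense_times
    Y = np.array([c.dense_values for c in curves])
    return Y, np.asarray(t, dtype=float)


def _content_seed(Y: np.ndarray, seed: int) -> np.random.Generator:
    """RNG whose stream depends on curve content, not input order."""
    order = np.lexsort(Y.T[::-1])
    digest = hashlib.sha256(np.ascontiguousarray(Y[order]).tobytes()).digest()
    content = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng([seed, content]), order


def _component_logdens(Y, mu: np.ndarray, cov: AR1Covariance):
    G = mu.size
    E = Y - mu[None, :]
    q = ar1_quadform(E, cov.rho) / cov.sigma2
    return -0.5 * (G * np.log(2 * np.pi) + cov.logdet(G) + q)


def _mstep_component(
    Y, t, w, order: int, X: np.ndarray | None = None
) -> tuple[LegendreCurve, AR1Covariance]:
    """Weighted ML mean curve and AR(1) parameters for one component."""
    W = w.sum()
    ybar = (w[:, None] * Y).sum(axis=0) / W
    G = t.size
    if X is None:
        X = legendre_design(t, order, t.min(), t.max())

    def fit_coef(rho: float) -> np.ndarray:
        # GLS fit of the weighted mean vector under AR(1) correlation
        P = AR1Covariance(1.0, rho).corr_inverse(G)
        XtP = X.T @ P
        return np.linalg.solve(XtP @ X, XtP @ ybar)

    def neg2ll(rho: float) -> float:
        E = Y - X @ fit_coef(rho)
        q = (w * ar1_quadform(E, rho)).sum()
        sigma2 = max(q / (W * G), 1e-300)
        return W * G * np.log(sigma2) + W * (G - 1) * np.log1p(-(rho**2)) + W * G

    res = minimize_scalar(neg2ll, bounds=(-0.99, 0.99), method="bounded",
                          options={"xatol": 5e-3, "maxiter": 8})
    rho = float(res.x)
    coef = fit_coef(rho)
    mean = LegendreCurve(coef, float(t.min()), float(t.max()))
    E = Y - X @ coef
    sigma2 = float(max((w * ar1_quadform(E, rho)).sum() / (W * G), 1e-12))
    return mean, AR1Covariance(sigma2=sigma2, rho=rho)


def em_fit(
    curves: list[EffectCurve],
    K: int,
    seed: int = 0,
    *,
    order: int = 4,
    n_restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MixtureModel:
    """EM fit of a K-component curve mixture, keeping the best of several
    seeded restarts.

    Restart initializations are drawn from an RNG keyed to the curve
    *content* (sorted row hash), so the selected solution does not depend
    on input order. An emptied component is re-seeded from the worst-fit
    curve.
    """
    m = len(curves)
    if not 1 <= K <= m:
        raise ValueError(f"K={K} must be in 1..{m}")
    Y, t = _curve_matrix(curves)
    order = min(order, t.size - 1)
    X = legendre_design(t, order, t.min(), t.max())
    rng, sorted_idx = _content_seed(Y, seed)

    best: MixtureModel | None = None
    Ys = Y[sorted_idx]  # content order, so seeding ignores input order
    for _ in range(n_restarts if K > 1 else 1):
        # kmeans++-style seeding: start from a random curve, then pick
        # each next seed with probability proportional to its squared
        # distance from the nearest seed chosen so far
        pick = [int(rng.integers(m))]
        d2 = np.sum((Ys - Ys[pick[0]]) ** 2, axis=1)
        while len(pick) < K:
            probs = d2 / d2.sum() if d2.sum() > 0 else np.full(m, 1.0 / m)
            nxt = int(rng.choice(m, p=probs))
            pick.append(nxt)
            d2 = np.minimum(d2, np.sum((Ys - Ys[nxt]) ** 2, axis=1))
        means = [fit_legendre(Ys[i], t, order) for i in pick]
        resid0 = Y - Y.mean(axis=0)
        s2 = max(float(resid0.var()), 1e-8)
        covs = [AR1Covariance(s2, 0.0) for _ in range(K)]
        props = np.full(K, 1.0 / K)

        ll_prev = -np.inf
        ll = -np.inf
        R = None
        for _it in range(max_iter):
            logd = np.stack(
                [
                    _component_logdens(Y, X @ means[k].coefficients, covs[k])
                    for k in range(K)
                ],
                axis=1,
            ) + np.log(props)[None, :]
            norm = logsumexp(logd, axis=1)
            ll = float(norm.sum())
            R = np.exp(logd - norm[:, None])
            # M-step
            Nk = R.sum(axis=0)
            for k in range(K):
                if Nk[k] < 1e-8:
                    worst = int(np.argmin(norm))
                    R[:, k] = 0.0
                    R[worst, :] = 0.0
                    R[worst, k] = 1.0
                    Nk = R.sum(axis=0)
            props = Nk / m
            for k in range(K):
                means[k], covs[k] = _mstep_component(Y, t, R[:, k], order, X)
            if abs(ll - ll_prev) < tol * max(1.0, abs(ll)):
                break
            ll_prev = ll
        model = MixtureModel(
            K=K, proportions=props, means=means, covariances=covs,
            responsibilities=R, loglik=ll, order=order,
        )
        if best is None or model.loglik > best.loglik:
            best = model
    return best


def bic_select(
    curves: list[EffectCurve],
    K_range: range | list[int],
    seed: int = 0,
    *,
    order: int = 4,
    n_restarts: int = 10,
    early_stop: int | None = 3,
) -> tuple[int, MixtureModel]:
    """Choose the module count by BIC minimization; ties go to smaller K.

    ``early_stop`` aborts the sweep after that many consecutive K values
    with rising BIC (the curve is near-convex in practice); pass None to
    evaluate the whole range.
    """
    Ks = sorted(set(int(k) for k in K_range))
    if not Ks:
        raise ValueError("empty K range")
    m = len(curves)
    best_K, best_model, best_bic = None, None, np.inf
    rising = 0
    for K in Ks:
        if K > m:
            break
        model = em_fit(curves, K, seed, order=order, n_restarts=n_restarts)
        b = model.bic(m)
        log.debug("bic_select: K=%d lnL=%.3f BIC=%.3f", K, model.loglik, b)
        if b < best_bic - 1e-12:
            best_K, best_model, best_bic = K, model, b
            rising = 0
        else:
            rising += 1
            if early_stop is not None and rising >= early_stop:
                break
    return best_K, best_model


# ---------------------------------------------------------------------------
# module hierarchy


DEPTH_LABELS = ["module", "submodule", "sub-submodule"]


def _depth_label(depth: int) -> str:
    if depth - 1 < len(DEPTH_LABELS):
        return DEPTH_LABELS[depth - 1]
    return "sub" * (depth - 1) + "module"


@dataclass
class ModuleNode:
    id: str
    parent: str | None
    depth: int  # 1 = module
    snp_ids: list[str]
    mean_curve: LegendreCurve | None = None

    @property
    def size(self) -> int:
        return len(self.snp_ids)

    @property
    def label(self) -> str:
        return _depth_label(self.depth)


@dataclass
class ModuleTree:
    """Hierarchical partition of SNPs into modules/submodules/..."""

    nodes: dict[str, ModuleNode]
    dunbar: int

    def children(self, node_id: str | None) -> list[ModuleNode]:
        return [n for n in self.nodes.values() if n.parent == node_id]

    def level(self, depth: int) -> list[ModuleNode]:
        return [n for n in self.nodes.values() if n.depth == depth]

    def leaves(self) -> list[ModuleNode]:
        parents = {n.parent for n in self.nodes.values() if n.parent is not None}
        return [n for n in self.nodes.values() if n.id not in parents]

    @property
    def max_depth(self) -> int:
        return max(n.depth for n in self.nodes.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "dunbar": self.dunbar,
                "nodes": [
                    {
                        "id": n.id,
                        "parent": n.parent,
                        "depth": n.depth,
                        "label": n.label,
                        "snp_ids": n.snp_ids,
                        "mean_curve": None
                        if n.mean_curve is None
                        else n.mean_curve.to_dict(),
                    }
                    for n in self.nodes.values()
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ModuleTree":
        d = json.loads(text)
        nodes = {}
        for nd in d["nodes"]:
            nodes[nd["id"]] = ModuleNode(
                id=nd["id"],
                parent=nd["parent"],
                depth=nd["depth"],
                snp_ids=list(nd["snp_ids"]),
                mean_curve=None
                if nd["mean_curve"] is None
                else LegendreCurve.from_dict(nd["mean_curve"]),
            )
        return cls(nodes=nodes, dunbar=d["dunbar"])


def _mean_effect_curve(curves: list[EffectCurve], node_id: str, order: int) -> EffectCurve:
    Y, t = _curve_matrix(curves)
    mean = Y.mean(axis=0)
    leg = fit_legendre(mean, t, min(order, t.size - 1))
    return EffectCurve(
        snp_id=node_id,
        times=t,
        values=mean,
        legendre=leg,
        dense_times=t,
        dense_values=leg(t),
    )


def recursive_cluster(
    curves: list[EffectCurve],
    dunbar: int = 150,
    K_range: range | list[int] | None = None,
    seed: int = 0,
    *,
    order: int = 4,
    n_restarts: int = 10,
    K_range_sub: range | list[int] | None = None,
    max_depth: int = 6,
) -> ModuleTree:
    """Recursively cluster effect curves until every leaf is <= dunbar.

    BIC selects the split count at each node; a unit that BIC refuses to
    split (K*=1) but that exceeds the Dunbar threshold is force-split with
    K=2. Recursion depth is capped; any oversized unit at the cap is
    chunked so the leaf-size invariant always holds.
    """
    if dunbar < 2:
        raise ValueError("dunbar must be >= 2")
    m = len(curves)
    if K_range is None:
        K_range = range(1, min(80, max(m // 10, 2)) + 1)
    if K_range_sub is None:
        K_range_sub = range(1, 21)

    nodes: dict[str, ModuleNode] = {}

    def cluster_unit(unit: list[int], parent: str | None, depth: int, prefix: str):
        sub = [curves[i] for i in unit]
        Ks = K_range if depth == 1 else K_range_sub
        Ks = [k for k in Ks if k <= len(sub)]
        K, model = bic_select(sub, Ks, seed, order=order, n_restarts=n_restarts)
        labels = model.labels
        if K == 1 and len(sub) > dunbar:
            if len(sub) >= 2:
                K, model = 2, em_fit(sub, 2, seed, order=order,
                                     n_restarts=n_restarts)
                labels = model.labels
        groups = [np.flatnonzero(labels == k) for k in range(K)]
        groups = [g for g in groups if g.size > 0]
        if len(groups) == 1 and len(sub) > dunbar:
            # degenerate split: chunk deterministically to honour the cap
            idx = np.arange(len(sub))
            n_chunks = int(np.ceil(len(sub) / dunbar))
            groups = np.array_split(idx, n_chunks)
        for k, grp in enumerate(groups):
            member_idx = [unit[i] for i in grp]
            node_id = f"{prefix}{k + 1}"
            node = ModuleNode(
                id=node_id,
                parent=parent,
                depth=depth,
                snp_ids=[curves[i].snp_id for i in member_idx],
            )
            node.mean_curve = _mean_effect_curve(
                [curves[i] for i in member_idx], node_id, order
            ).legendre
            nodes[node_id] = node
            if node.size > dunbar and depth < max_depth:
                cluster_unit(member_idx, node_id, depth + 1, f"{node_id}.")
            elif node.size > dunbar:
                # depth cap reached: chunk into leaf-sized pieces
                n_chunks = int(np.ceil(node.size / dunbar))
                for c, piece in enumerate(np.array_split(np.array(member_idx), n_chunks)):
                    pid = f"{node_id}.c{c + 1}"
                    nodes[pid] = ModuleNode(
                        id=pid,
                        parent=node_id,
                        depth=depth + 1,
                        snp_ids=[curves[i].snp_id for i in piece],
                        mean_curve=_mean_effect_curve(
                            [curves[i] for i in piece], pid, order
                        ).legendre,
                    )

    cluster_unit(list(range(m)), None, 1, "M")
    return ModuleTree(nodes=nodes, dunbar=dunbar)


def module_mean_curves(
    tree: ModuleTree,
    curves: list[EffectCurve],
    depth: int = 1,
    *,
    order: int = 4,
) -> list[EffectCurve]:
    """Mean effect curve of every node at a hierarchy depth.

    The arithmetic mean of member curves on the dense grid, re-fitted with
    the Legendre basis.
    """
    nodes = tree.level(depth)
    if not nodes:
        raise ValueError(f"no nodes at depth {depth}")
    by_id = {c.snp_id: c for c in curves}
    out = []
    for n in sorted(nodes, key=lambda x: x.id):
        members = [by_id[s] for s in n.snp_ids]
        out.append(_mean_effect_curve(members, n.id, order))
    return out
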