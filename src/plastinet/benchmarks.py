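"""Self-contained evaluation runs used by the acceptance checks.

Each function simulates its own inputs from a seed, runs the relevant part
of the pipeline, and returns the measured quantity. Problem sizes are
chosen so the full battery runs on one CPU in minutes: the permutation
studies use a 20-SNP panel (the permutation null calibrates per SNP panel,
so the panel size affects only the threshold, not the validity of the
type-I rate), and the end-to-end run uses the GWAS-scale preset.
"""

from __future__ import annotations

import tempfile
import time
from pathlib import Path

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .cofunmap import fit_null, permutation_threshold, scan
from .curves import LogisticParams, fit_logistic, logistic_eval
from .datamodel import compute_plasticity
from .funclust import bic_select, recursive_cluster
from .netrecon import fit_qdode, rk4, select_regulators
from .synthdata import (
    QtlSpec,
    SimConfig,
    sample_stable_system,
    simulate_curve_clusters,
    simulate_population,
)

__all__ = [
    "plasticity_identity",
    "logistic_recovery",
    "rk4_accuracy",
    "type_one_error",
    "qtl_power",
    "clustering_recovery",
    "dunbar_audit",
    "decomposition_conservation",
    "network_recovery",
    "end_to_end",
]


def plasticity_identity(seed: int = 0) -> float:
    """Max abs deviation of z from x - y on a simulated ingest (exact: 0)."""
    cfg = SimConfig(n=50, m=10, seed=seed)
    traj, _, _ = simulate_population(cfg)
    z = compute_plasticity(traj)
    return float(np.abs(z.z - (traj.control - traj.stress)).max())


def logistic_recovery(seed: int = 0) -> float:
    """Max relative parameter error fitting noise-free (30, 9, 0.08) data."""
    t = np.arange(20.0, 121.0, 20.0)
    truth = LogisticParams(30.0, 9.0, 0.08)
    fit = fit_logistic(logistic_eval(truth, t), t)
    return float(max(abs(fit.a - 30) / 30, abs(fit.b - 9) / 9,
                     abs(fit.r - 0.08) / 0.08))


def rk4_accuracy(seed: int = 0) -> tuple[float, float]:
    """(max abs error at step 0.01, error ratio when halving a coarse step).

    Integrates dg/dt = r g (1 - g/a) and compares with the closed-form
    logistic solution; the convergence-order ratio is measured at coarse
    steps (2 -> 1 days) where truncation error dominates rounding.
    """
    a, b, r = 30.0, 9.0, 0.08
    f = lambda t, g: r * g * (1 - g / a)
    g0 = a / (1 + b)

    def err(h):
        ts, gs = rk4(f, g0, 0.0, 120.0, h)
        return float(np.abs(gs - a / (1 + b * np.exp(-r * ts))).max())

    return err(0.01), err(2.0) / err(1.0)


def _scan_hit(cfg: SimConfig, n_perm: int, alpha: float, seed: int,
              snp_index: int | None = None) -> bool:
    traj, geno, _ = simulate_population(cfg)
    z = compute_plasticity(traj)
    null = fit_null(z)
    result = scan(z, geno, null=null)
    thr = permutation_threshold(z, geno, n_perm, alpha, "gwas_biallelic",
                                seed, null=null)
    if snp_index is None:
        lr = result.lr[~result.skipped]
        return bool(lr.size and lr.max() >= thr)
    return bool(not result.skipped[snp_index] and result.lr[snp_index] >= thr)


def type_one_error(seed: int = 0, *, n_reps: int = 200, n_perm: int = 200,
                   alpha: float = 0.05, n: int = 100, m: int = 20) -> float:
    """Genome-wide false-positive rate over null simulations."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 10**6, size=n_reps)
    hits = 0
    for k in range(n_reps):
        cfg = SimConfig(n=n, m=m, seed=int(sub[k]))
        hits += _scan_hit(cfg, n_perm, alpha, int(sub[k]) + 1)
    return hits / n_reps


def qtl_power(seed: int = 0, *, n_reps: int = 200, n_perm: int = 200,
              alpha: float = 0.05, n: int = 100, m: int = 20) -> float:
    """Detection rate for a QTL with 2-sigma late-time group separation."""
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 10**6, size=n_reps)
    shift = 2.0 * np.sqrt(2.0)  # 2 sd of the plasticity noise per allele
    hits = 0
    for k in range(n_reps):
        cfg = SimConfig(n=n, m=m, seed=int(sub[k]),
                        qtls=[QtlSpec(snp_index=0, stress_shift=shift)])
        hits += _scan_hit(cfg, n_perm, alpha, int(sub[k]) + 1, snp_index=0)
    return hits / n_reps


def clustering_recovery(seed: int = 0, *, n_reps: int = 20) -> tuple[float, float]:
    """(fraction of reps with K*=3 and ARI >= 0.95, mean ARI).

    300 curves from 3 planted clusters at 5x separation per replicate.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=n_reps)
    ok = 0
    aris = []
    for k in range(n_reps):
        curves, labels = simulate_curve_clusters(300, 3, 5.0, seed=int(sub[k]))
        K, model = bic_select(curves, range(1, 7), seed=int(sub[k]),
                              n_restarts=2, early_stop=2)
        ari = adjusted_rand_score(labels, model.labels)
        aris.append(ari)
        ok += (K == 3 and ari >= 0.95)
    return ok / n_reps, float(np.mean(aris))


def dunbar_audit(seed: int = 0, *, dunbar: int = 40) -> int:
    """Max leaf size after recursive clustering (must be <= dunbar)."""
    curves, _ = simulate_curve_clusters(300, 4, 6.0, seed=seed)
    tree = recursive_cluster(curves, dunbar=dunbar, K_range=range(1, 7),
                             K_range_sub=range(1, 5), seed=seed, n_restarts=2)
    assert sorted(s for leaf in tree.leaves() for s in leaf.snp_ids) == sorted(
        c.snp_id for c in curves
    )
    return max(leaf.size for leaf in tree.leaves())


def decomposition_conservation(seed: int = 0) -> float:
    """Max deviation of (independent + dependent) from the net trajectory."""
    spec, curves, truth = sample_stable_system(10, 2, seed=seed)
    worst = 0.0
    for tgt in range(4):  # a handful of nodes exercises the audit
        cands = [c for i, c in enumerate(curves) if i != tgt]
        regs = select_regulators(curves[tgt], cands)
        by = {c.snp_id: c for c in cands}
        fit = fit_qdode(curves[tgt], [by[r] for r in regs], maxiter=200)
        worst = max(worst, float(np.abs(fit.components_sum - fit.net).max()))
    return worst


def network_recovery(seed: int = 0, *, n_seeds: int = 50,
                     fit_maxiter: int = 200) -> tuple[float, float]:
    """(regulator-selection F1, sign accuracy on recovered true edges).

    10-node planted driven systems, 2 regulators per node, SNR 10, G=30.
    """
    tp = fp = fn = 0
    sign_ok = sign_tot = 0
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 10**6, size=n_seeds)
    for k in range(n_seeds):
        spec, curves, truth = sample_stable_system(10, 2, seed=int(sub[k]))
        beta = {(f"node{s:03d}", f"node{d:03d}"): b for s, d, b in truth["edges"]}
        for tgt in range(10):
            tgt_id = curves[tgt].snp_id
            cands = [c for i, c in enumerate(curves) if i != tgt]
            sel = select_regulators(curves[tgt], cands)
            true = {f"node{s:03d}" for s in truth["regulators"][tgt]}
            tp += len(set(sel) & true)
            fp += len(set(sel) - true)
            fn += len(true - set(sel))
            hits = sorted(set(sel) & true)
            if hits:
                by = {c.snp_id: c for c in cands}
                fit = fit_qdode(curves[tgt], [by[r] for r in sel],
                                maxiter=fit_maxiter)
                for r in hits:
                    got = np.sign(np.mean(fit.dependent[r]))
                    want = np.sign(beta[(r, tgt_id)])
                    sign_tot += 1
                    sign_ok += got == want
    f1 = 2 * tp / max(2 * tp + fp + fn, 1)
    return f1, (sign_ok / sign_tot if sign_tot else 0.0)


def end_to_end(seed: int = 0, *, out_dir: str | None = None,
               n: int = 100, m: int = 500) -> tuple[float, int]:
    """(wall seconds, completed stage count) for a full GWAS-preset run."""
    from click.testing import CliRunner

    from .cli import main
    from .pipeline import RunConfig, run_pipeline

    base = Path(out_dir) if out_dir else Path(tempfile.mkdtemp())
    t0 = time.time()
    r = CliRunner().invoke(
        main,
        ["simulate", "--preset", "gwas", "--n", str(n), "--m", str(m),
         "--seed", str(seed), "--out", str(base / "sim")],
    )
    if r.exit_code != 0:  # pragma: no cover
        raise RuntimeError(f"simulate failed: {r.output}")
    cfg = RunConfig.from_yaml(base / "sim" / "config.yaml")
    cfg.n_perm = 200
    cfg.k_root_max = 6
    cfg.ode_maxiter = 60
    manifest = run_pipeline(cfg)
    return time.time() - t0, int(manifest["n_stages_completed"])
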