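"""End-to-end pipeline orchestration with a run manifest.

Stages: ingest -> plasticity -> map -> cluster -> network -> multilayer.
Each stage
writes its outputs under the run directory and records a content hash of
the parameters it depends on; re-running with an unchanged configuration
skips stages whose outputs are present and whose hash matches.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cofunmap import (
    EffectCurve,
    ScanResult,
    effect_curve,
    fit_null,
    permutation_threshold,
    scan,
)
from .curves import LegendreCurve
from .datamodel import (
    PlasticitySet,
    TimeGrid,
    filter_snps,
    read_genotypes,
    read_phenotypes,
    write_genotypes,
)
from .funclust import ModuleTree, recursive_cluster
from .multilayer import LayeredNetwork, NetConfig, build_multilayer, degree_report

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Single-file configuration for a full pipeline run."""

    pheno_path: str
    geno_path: str
    out_dir: str
    times: list[float]
    geno_format: str = "csv"
    alpha: float = 0.05
    n_perm: int = 1000
    min_group: int = 5
    maf_min: float = 0.05
    hwe_alpha: float = 1e-4
    legendre_order: int = 4
    n_dense: int = 30
    dunbar: int = 150
    k_root_max: int = 20
    k_sub_max: int = 10
    n_restarts: int = 3
    max_reg: int = 5
    d_ind: int = 3
    d_dep: int = 3
    ode_maxiter: int = 150
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def grid(self) -> TimeGrid:
        return TimeGrid(np.asarray(self.times, dtype=float))


def _hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_curves(curves: list[EffectCurve], path: Path) -> None:
    payload = [
        {
            "snp_id": c.snp_id,
            "times": c.times.tolist(),
            "values": c.values.tolist(),
            "legendre": c.legendre.to_dict(),
            "dense_times": c.dense_times.tolist(),
            "dense_values": c.dense_values.tolist(),
            "flagged": bool(c.flagged),
        }
        for c in curves
    ]
    path.write_text(json.dumps(payload))


def _read_curves(path: Path) -> list[EffectCurve]:
    out = []
    for d in json.loads(path.read_text()):
        out.append(
            EffectCurve(
                snp_id=d["snp_id"],
                times=np.array(d["times"]),
                values=np.array(d["values"]),
                legendre=LegendreCurve.from_dict(d["legendre"]),
                dense_times=np.array(d["dense_times"]),
                dense_values=np.array(d["dense_values"]),
                flagged=d["flagged"],
            )
        )
    return out


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = (
            json.loads(path.read_text()) if path.exists() else {"stages": {}}
        )

    def fresh(self, stage: str, h: str, outputs: list[Path]) -> bool:
        rec = self.data["stages"].get(stage)
        return (
            rec is not None
            and rec["hash"] == h
            and all(p.exists() for p in outputs)
        )

    def record(self, stage: str, h: str, outputs: list[Path], t0: float) -> None:
        self.data["stages"][stage] = {
            "hash": h,
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.time() - t0, 3),
            "completed": True,
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the run manifest as a dict.

    Stage failures raise with the failing stage named; outputs of earlier
    stages are preserved.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    manifest.data["config"] = asdict(cfg)
    manifest.data["seed"] = cfg.seed
    grid = cfg.grid()
    cfg_d = asdict(cfg)

    def stage_hash(*keys):
        return _hash({k: cfg_d[k] for k in keys})

    # ---- ingest --------------------------------------------------------
    tcols = [f"t{k+1}" for k in range(len(grid))]
    h = stage_hash("pheno_path", "geno_path", "geno_format", "times",
                   "maf_min", "hwe_alpha")
    traj_csv = out / "trajectories.csv"
    geno_csv = out / "genotypes_filtered.csv"
    t0 = time.time()
    if not manifest.fresh("ingest", h, [traj_csv, geno_csv]):
        try:
            traj = read_phenotypes(cfg.pheno_path, grid)
            geno = read_genotypes(cfg.geno_path, cfg.geno_format)
            geno = filter_snps(geno, cfg.maf_min, cfg.hwe_alpha)
            if list(geno.individual_ids) != list(traj.ids):
                raise ValueError(
                    f"individual ids in {cfg.geno_path} do not match phenotypes"
                )
            rows = []
            for cond, arr in (("control", traj.control), ("stress", traj.stress)):
                for i, gid in enumerate(traj.ids):
                    rows.append({"genotype": gid, "condition": cond,
                                 **dict(zip(tcols, arr[i]))})
            pd.DataFrame(rows).to_csv(traj_csv, index=False, float_format="%.17g")
            write_genotypes(geno, geno_csv)
        except Exception as e:
            raise RuntimeError(f"pipeline failed at stage 'ingest': {e}") from e
        manifest.record("ingest", h, [traj_csv, geno_csv], t0)
    else:
        log.info("ingest: cached")

    tdf = pd.read_csv(traj_csv, float_precision="round_trip")
    ctrl = tdf[tdf.condition == "control"].set_index("genotype")[tcols]
    strs = tdf[tdf.condition == "stress"].set_index("genotype")[tcols]
    ids = [str(g) for g in ctrl.index]
    geno = read_genotypes(geno_csv, "csv")

    # ---- plasticity ----------------------------------------------------
    h = stage_hash("pheno_path", "times")
    plast_csv = out / "plasticity.csv"
    t0 = time.time()
    if not manifest.fresh("plasticity", h, [plast_csv]):
        try:
            zmat = ctrl.to_numpy() - strs.loc[ctrl.index].to_numpy()
            df = pd.DataFrame(zmat, columns=tcols)
            df.insert(0, "genotype", ids)
            df.to_csv(plast_csv, index=False, float_format="%.17g")
        except Exception as e:
            raise RuntimeError(
                f"pipeline failed at stage 'plasticity': {e}"
            ) from e
        manifest.record("plasticity", h, [plast_csv], t0)
    else:
        log.info("plasticity: cached")

    df = pd.read_csv(plast_csv, float_precision="round_trip")
    z = PlasticitySet(
        ids=[str(g) for g in df["genotype"]],
        grid=grid,
        z=df[tcols].to_numpy(),
    )

    # ---- map -----------------------------------------------------------
    h = stage_hash("times", "alpha", "n_perm", "min_group", "legendre_order",
                   "n_dense", "seed")
    scan_tsv = out / "scan.tsv"
    curves_json = out / "effect_curves.json"
    t0 = time.time()
    if not manifest.fresh("map", h, [scan_tsv, curves_json]):
        try:
            null = fit_null(z)
            result = scan(z, geno, null=null, min_group=cfg.min_group)
            for cls in sorted(set(geno.marker_class)):
                result.thresholds[cls] = permutation_threshold(
                    z, geno, cfg.n_perm, cfg.alpha, cls, cfg.seed,
                    null=null, min_group=cfg.min_group,
                )
            sig = result.significant
            pd.DataFrame(
                {
                    "snp": result.snp_ids,
                    "chrom": geno.chrom if geno.chrom else ["."] * geno.m,
                    "pos": geno.pos if geno.pos is not None else [0] * geno.m,
                    "class": result.marker_class,
                    "LR": result.lr,
                    "threshold": [
                        result.thresholds.get(c, np.nan)
                        for c in result.marker_class
                    ],
                    "significant": sig,
                    "skipped": result.skipped,
                }
            ).to_csv(scan_tsv, sep="\t", index=False)
            curves = []
            for j, gm in enumerate(result.group_models):
                if gm is None:
                    continue
                curves.append(
                    effect_curve(gm, grid, result.snp_ids[j],
                                 order=cfg.legendre_order, n_dense=cfg.n_dense)
                )
            _write_curves(curves, curves_json)
        except Exception as e:
            raise RuntimeError(f"pipeline failed at stage 'map': {e}") from e
        manifest.record("map", h, [scan_tsv, curves_json], t0)
    else:
        log.info("map: cached")

    curves = _read_curves(curves_json)
    scan_df = pd.read_csv(scan_tsv, sep="\t")
    result = ScanResult(
        snp_ids=[str(s) for s in scan_df["snp"]],
        lr=scan_df["LR"].to_numpy(),
        marker_class=[str(c) for c in scan_df["class"]],
        skipped=scan_df["skipped"].to_numpy(bool),
        group_models=[None] * len(scan_df),
        null_model=None,  # type: ignore[arg-type]
        thresholds={
            c: float(scan_df.loc[scan_df["class"] == c, "threshold"].iloc[0])
            for c in set(scan_df["class"])
        },
    )

    # ---- cluster -------------------------------------------------------
    h = stage_hash("dunbar", "k_root_max", "k_sub_max", "n_restarts",
                   "legendre_order", "seed")
    tree_json = out / "module_tree.json"
    assign_tsv = out / "assignments.tsv"
    t0 = time.time()
    if not manifest.fresh("cluster", h, [tree_json, assign_tsv]):
        try:
            tree = recursive_cluster(
                curves,
                dunbar=cfg.dunbar,
                K_range=range(1, cfg.k_root_max + 1),
                K_range_sub=range(1, cfg.k_sub_max + 1),
                seed=cfg.seed,
                order=cfg.legendre_order,
                n_restarts=cfg.n_restarts,
            )
            tree_json.write_text(tree.to_json())
            rows = []
            for leaf in tree.leaves():
                lineage = [leaf.id]
                node = leaf
                while node.parent is not None:
                    node = tree.nodes[node.parent]
                    lineage.append(node.id)
                for snp in leaf.snp_ids:
                    rows.append({"snp": snp, "module": lineage[-1],
                                 "unit": leaf.id, "depth": leaf.depth})
            pd.DataFrame(rows).to_csv(assign_tsv, sep="\t", index=False)
        except Exception as e:
            raise RuntimeError(f"pipeline failed at stage 'cluster': {e}") from e
        manifest.record("cluster", h, [tree_json, assign_tsv], t0)
    else:
        log.info("cluster: cached")
    tree = ModuleTree.from_json(tree_json.read_text())

    netcfg = NetConfig(max_reg=cfg.max_reg, d_ind=cfg.d_ind,
                       d_dep=cfg.d_dep, maxiter=cfg.ode_maxiter)
    layers_dir = out / "layers"
    layers_dir.mkdir(exist_ok=True)

    def write_layers(net: LayeredNetwork) -> dict:
        info = {}
        for lid, network in net.layers.items():
            name = lid if lid else "root"
            network.to_edge_table().to_csv(
                layers_dir / f"{name}_edges.tsv", sep="\t", index=False
            )
            network.write_graphml(layers_dir / f"{name}.graphml")
            rep = degree_report(net, lid)
            rep.to_csv(layers_dir / f"{name}_degrees.tsv", sep="\t", index=False)
            info[name] = {
                "n_nodes": len(network.nodes),
                "n_edges": rep.attrs["n_edges"],
                "mean_out_degree": rep.attrs["mean_out_degree"],
                "worker_fraction": rep.attrs["worker_fraction"],
            }
        return info

    # ---- network (SNP-level, within each leaf unit) --------------------
    h = stage_hash("max_reg", "d_ind", "d_dep", "ode_maxiter", "seed")
    leaf_json = out / "leaf_layers.json"
    t0 = time.time()
    if not manifest.fresh("network", h, [leaf_json]):
        try:
            net_leaves = build_multilayer(
                tree, curves, scan=result, netcfg=netcfg, levels="leaves"
            )
            leaf_json.write_text(json.dumps(write_layers(net_leaves), indent=1))
        except Exception as e:
            raise RuntimeError(f"pipeline failed at stage 'network': {e}") from e
        manifest.record("network", h, [leaf_json], t0)
    else:
        log.info("network: cached")

    # ---- multilayer (module-level layers + assembly) -------------------
    h = stage_hash("max_reg", "d_ind", "d_dep", "ode_maxiter", "seed", "dunbar")
    summary_json = out / "network_summary.json"
    t0 = time.time()
    if not manifest.fresh("multilayer", h, [summary_json]):
        try:
            net_mods = build_multilayer(
                tree, curves, scan=result, netcfg=netcfg, levels="modules"
            )
            summary = {
                "layers": write_layers(net_mods),
                "leaf_layers": json.loads(leaf_json.read_text()),
                "qtl_containing": sorted(
                    k for k, v in net_mods.qtl_flags.items() if v
                ),
                "qtl_counts": net_mods.qtl_counts,
            }
            summary_json.write_text(json.dumps(summary, indent=1))
        except Exception as e:
            raise RuntimeError(
                f"pipeline failed at stage 'multilayer': {e}"
            ) from e
        manifest.record("multilayer", h, [summary_json], t0)
    else:
        log.info("multilayer: cached")

    manifest.data["n_stages_completed"] = len(manifest.data["stages"])
    manifest.path.write_text(json.dumps(manifest.data, indent=1))
    return manifest.data
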