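"""Multilayer genetic interactome assembly.

Networks are reconstructed at every level of the module hierarchy: the top
layer connects the root modules through their mean effect curves; each
internal node hosts a network over its children's mean curves; each leaf
hosts a SNP-level network over its member effect curves. Edges never cross
sibling groups — reconstruction is community-wise, which is what keeps the
genome-scale problem tractable. Modules containing at least one significant
SNP from the QTL scan are flagged QTL-containing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cofunmap import EffectCurve, ScanResult
from .funclust import ModuleTree, module_mean_curves, _mean_effect_curve
from .netrecon import Network, build_network, fit_qdode, select_regulators

log = logging.getLogger(__name__)

__all__ = ["NetConfig", "LayeredNetwork", "build_multilayer", "degree_report"]


@dataclass(frozen=True)
class NetConfig:
    """Knobs for per-layer network reconstruction."""

    max_reg: int = 5
    d_ind: int = 3
    d_dep: int = 3
    maxiter: int = 500
    refine: bool = True


@dataclass
class LayeredNetwork:
    """Networks per hierarchy unit: '' (root layer) or a module node id."""

    layers: dict[str, Network]
    qtl_flags: dict[str, bool] = field(default_factory=dict)
    qtl_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def _reconstruct(curves: list[EffectCurve], cfg: NetConfig) -> Network:
    fits = []
    for c in curves:
        cands = [x for x in curves if x.snp_id != c.snp_id]
        regs = select_regulators(c, cands, cfg.max_reg) if cands else []
        by_id = {x.snp_id: x for x in cands}
        fits.append(
            fit_qdode(
                c,
                [by_id[r] for r in regs],
                orders=(cfg.d_ind, cfg.d_dep),
                maxiter=cfg.maxiter,
                refine=cfg.refine,
            )
        )
    return build_network(fits)


def build_multilayer(
    tree: ModuleTree,
    curves: list[EffectCurve],
    scan: ScanResult | None = None,
    netcfg: NetConfig | None = None,
    *,
    levels: str = "all",
) -> LayeredNetwork:
    """Reconstruct a network at every level of the module hierarchy.

    The top layer spans the root modules' mean curves; every internal node
    spans its children's mean curves; every leaf spans its member SNPs'
    effect curves. With a ScanResult, a module is flagged QTL-containing if
    any member SNP is significant. ``levels`` restricts reconstruction to
    "modules" (top + internal layers), "leaves" (SNP-level layers), or
    "all".
    """
    if levels not in ("all", "modules", "leaves"):
        raise ValueError(f"unknown levels {levels!r}")
    cfg = netcfg or NetConfig()
    by_id = {c.snp_id: c for c in curves}
    missing = [
        s for n in tree.nodes.values() for s in n.snp_ids if s not in by_id
    ]
    if missing:
        raise ValueError(f"tree references unknown curves, e.g. {missing[:3]}")
    sig_ids: set[str] = set()
    if scan is not None:
        sig = scan.significant
        sig_ids = {scan.snp_ids[j] for j in np.flatnonzero(sig)}

    layers: dict[str, Network] = {}
    qtl_flags: dict[str, bool] = {}
    qtl_counts: dict[str, int] = {}

    # top layer over root children
    if levels in ("all", "modules"):
        root_means = module_mean_curves(tree, curves, depth=1)
        if len(root_means) >= 2:
            layers[""] = _reconstruct(root_means, cfg)

    for node in tree.nodes.values():
        qtl_counts[node.id] = len(set(node.snp_ids) & sig_ids)
        qtl_flags[node.id] = qtl_counts[node.id] > 0
        children = tree.children(node.id)
        if children:
            if levels == "leaves":
                continue
            means = [
                _mean_effect_curve([by_id[s] for s in ch.snp_ids], ch.id, order=4)
                for ch in sorted(children, key=lambda x: x.id)
            ]
            if len(means) >= 2:
                layers[node.id] = _reconstruct(means, cfg)
        else:
            if node.size > tree.dunbar:
                raise ValueError(
                    f"leaf {node.id} exceeds the Dunbar threshold "
                    f"({node.size} > {tree.dunbar})"
                )
            if levels == "modules":
                continue
            members = [by_id[s] for s in node.snp_ids]
            if len(members) >= 2:
                layers[node.id] = _reconstruct(members, cfg)
    return LayeredNetwork(layers=layers, qtl_flags=qtl_flags, qtl_counts=qtl_counts)


def degree_report(net: LayeredNetwork, layer: str = "") -> pd.DataFrame:
    """Per-node degree/role table for one layer, with summary attributes.

    The returned frame carries layer summaries in ``df.attrs``: mean out-
    and in-degree, the worker-node fraction, and the edge count.
    """
    if layer not in net.layers:
        raise KeyError(f"no layer {layer!r}")
    g = net.layers[layer]
    rows = []
    for node in g.nodes:
        rows.append(
            {
                "node": node,
                "out_degree": g.out_degree(node),
                "in_degree": g.in_degree(node),
                "role": g.roles[node],
                "qtl_count": net.qtl_counts.get(node, 0),
            }
        )
    df = pd.DataFrame(rows, columns=["node", "out_degree", "in_degree",
                                     "role", "qtl_count"])
    n = max(len(df), 1)
    df.attrs["mean_out_degree"] = float(df["out_degree"].mean()) if len(df) else 0.0
    df.attrs["mean_in_degree"] = float(df["in_degree"].mean()) if len(df) else 0.0
    df.attrs["worker_fraction"] = float((df["role"] == "worker").sum() / n)
    df.attrs["n_edges"] = int(df["out_degree"].sum())
    return df
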