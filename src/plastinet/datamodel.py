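"""Core data containers and file ingest/output.

Phenotypes are longitudinal trait measurements per genotype under two
conditions (control, stress), typically with clonal replicates; replicates
are averaged on ingest. The plasticity trajectory of a genotype is the
elementwise difference control - stress, a signed vector whose magnitude at
each time reflects how strongly that genotype responds to the stress.

Genotypes are integer-coded SNP markers: 0/1/2 alternate-allele counts for
GWAS biallelic SNPs, or the 2-class/3-class codes of an F1 mapping
population (testcross / intercross markers).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CONDITIONS = ("control", "stress")

MISSING = -9

__all__ = [
    "TimeGrid",
    "TraitTrajectorySet",
    "PlasticitySet",
    "GenotypeTable",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "filter_snps",
    "compute_plasticity",
    "hwe_exact_test",
]


@dataclass(frozen=True)
class TimeGrid:
    """Ordered measurement schedule (t_1, ..., t_T) in days."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 4:
            raise ValueError("TimeGrid needs at least 4 measurement times")
        if not np.all(np.diff(t) > 0):
            raise ValueError("measurement times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    @property
    def T(self) -> int:
        return self.times.size


@dataclass
class TraitTrajectorySet:
    """Replicate-averaged trajectories per genotype under both conditions.

    ``control`` and ``stress`` are (n, T) arrays aligned with ``ids``.
    """

    ids: list[str]
    grid: TimeGrid
    control: np.ndarray
    stress: np.ndarray
    units: str = "cm"

    def __post_init__(self):
        self.control = np.asarray(self.control, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        n, T = len(self.ids), len(self.grid)
        if self.control.shape != (n, T) or self.stress.shape != (n, T):
            raise ValueError("trajectory arrays must be (n_genotypes, T)")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class PlasticitySet:
    """Per-genotype plasticity trajectories z_i = x_i - y_i (control - stress)."""

    ids: list[str]
    grid: TimeGrid
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.shape != (len(self.ids), len(self.grid)):
            raise ValueError("z must be (n_genotypes, T)")

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class GenotypeTable:
    """Integer-coded SNP genotypes, one row per SNP, one column per individual.

    ``codes`` uses -9 for missing. ``marker_class`` per SNP is one of
    'gwas_biallelic', 'testcross', 'intercross'. ``usable`` flags SNPs that
    segregate (monomorphic SNPs are retained but unusable for mapping).
    """

    snp_ids: list[str]
    individual_ids: list[str]
    codes: np.ndarray
    marker_class: list[str]
    chrom: list[str] | None = None
    pos: np.ndarray | None = None  # 1-based

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int16)
        m, n = len(self.snp_ids), len(self.individual_ids)
        if self.codes.shape != (m, n):
            raise ValueError("codes must be (n_snps, n_individuals)")
        if len(self.marker_class) != m:
            raise ValueError("marker_class length mismatch")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=np.int64)

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    @property
    def usable(self) -> np.ndarray:
        """SNPs with at least two observed genotype classes."""
        out = np.zeros(self.m, dtype=bool)
        for j in range(self.m):
            obs = self.codes[j][self.codes[j] != MISSING]
            out[j] = np.unique(obs).size >= 2
        return out

    def subset_snps(self, mask) -> "GenotypeTable":
        idx = np.flatnonzero(np.asarray(mask))
        return GenotypeTable(
            snp_ids=[self.snp_ids[i] for i in idx],
            individual_ids=list(self.individual_ids),
            codes=self.codes[idx],
            marker_class=[self.marker_class[i] for i in idx],
            chrom=None if self.chrom is None else [self.chrom[i] for i in idx],
            pos=None if self.pos is None else self.pos[idx],
        )


# ---------------------------------------------------------------------------
# phenotype ingest


def read_phenotypes(path, grid: TimeGrid) -> TraitTrajectorySet:
    """Read a wide phenotype CSV and average clonal replicates.

    Expected columns: genotype, condition, replicate, t1..tT. Genotypes
    lacking either condition are dropped with a warning. Duplicate
    (genotype, condition, replicate) rows are an error.
    """
    df = pd.read_csv(path)
    T = len(grid)
    tcols = [f"t{k}" for k in range(1, T + 1)]
    required = ["genotype", "condition", "replicate", *tcols]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype file missing columns: {missing_cols}")
    if df.duplicated(["genotype", "condition", "replicate"]).any():
        raise ValueError("duplicate (genotype, condition, replicate) rows")
    bad = df["condition"].isin(CONDITIONS)
    if not bad.all():
        raise ValueError(
            f"unknown condition labels: {sorted(df.loc[~bad, 'condition'].unique())}"
        )
    vals = df[tcols].apply(pd.to_numeric, errors="coerce")
    if vals.isna().any().any():
        raise ValueError("non-numeric phenotype cell")
    df = pd.concat([df[["genotype", "condition"]], vals], axis=1)

    # replicate mean per genotype x condition
    means = df.groupby(["genotype", "condition"], sort=True)[tcols].mean()
    by_cond = {c: means.xs(c, level="condition") for c in CONDITIONS}
    complete = sorted(set(by_cond["control"].index) & set(by_cond["stress"].index))
    dropped = sorted(
        set(means.index.get_level_values("genotype")) - set(complete)
    )
    for g in dropped:
        msg = f"genotype {g!r} lacks one condition; dropped"
        log.warning(msg)
        warnings.warn(msg, stacklevel=2)
    ids = [str(g) for g in complete]
    return TraitTrajectorySet(
        ids=ids,
        grid=grid,
        control=by_cond["control"].loc[complete].to_numpy(),
        stress=by_cond["stress"].loc[complete].to_numpy(),
    )


def write_phenotypes(traj: TraitTrajectorySet, path) -> None:
    """Write a TraitTrajectorySet back to the ingest CSV layout (1 replicate)."""
    T = len(traj.grid)
    tcols = [f"t{k}" for k in range(1, T + 1)]
    rows = []
    for cond, arr in (("control", traj.control), ("stress", traj.stress)):
        for i, gid in enumerate(traj.ids):
            rows.append({"genotype": gid, "condition": cond, "replicate": 1,
                         **dict(zip(tcols, arr[i]))})
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotype ingest


def _infer_marker_class(obs_codes: np.ndarray, default: str) -> str:
    classes = np.unique(obs_codes[obs_codes != MISSING])
    if set(classes.tolist()) <= {0, 1} or set(classes.tolist()) <= {1, 2}:
        # two segregating classes -> testcross in an F1 family
        return "testcross" if default != "gwas_biallelic" else "gwas_biallelic"
    return default


def read_genotypes(
    path, format: str = "csv", *, default_class: str = "gwas_biallelic"
) -> GenotypeTable:
    """Read genotypes from a VCF or a coded CSV.

    CSV layout: columns snp, chrom (optional), pos (optional), then one
    column per individual with integer codes (-9 missing). VCF: biallelic
    records become 0/1/2 alternate-allele counts; multi-allelic records are
    skipped with a warning.

    ``default_class`` decides how three-class SNPs are labelled
    ('gwas_biallelic' or 'intercross'); two-class SNPs in an F1 family
    (default_class='intercross') are labelled 'testcross'.
    """
    if format == "vcf":
        return _read_vcf(path, default_class=default_class)
    if format != "csv":
        raise ValueError(f"unknown genotype format {format!r}")
    df = pd.read_csv(path)
    if "snp" not in df.columns:
        raise ValueError("genotype CSV must have an 'snp' column")
    meta_cols = [c for c in ("snp", "chrom", "pos") if c in df.columns]
    ind_cols = [c for c in df.columns if c not in meta_cols]
    if not ind_cols:
        raise ValueError("genotype CSV has no individual columns")
    codes = df[ind_cols].to_numpy()
    try:
        codes = codes.astype(np.int16)
    except (TypeError, ValueError) as e:
        raise ValueError(f"non-integer genotype code: {e}") from e
    marker_class = [
        _infer_marker_class(codes[j], default_class) for j in range(codes.shape[0])
    ]
    return GenotypeTable(
        snp_ids=[str(s) for s in df["snp"]],
        individual_ids=[str(c) for c in ind_cols],
        codes=codes,
        marker_class=marker_class,
        chrom=[str(c) for c in df["chrom"]] if "chrom" in df.columns else None,
        pos=df["pos"].to_numpy() if "pos" in df.columns else None,
    )


def _read_vcf(path, *, default_class: str) -> GenotypeTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = list(vcf.samples)
    snp_ids, chrom, pos, rows = [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            msg = f"skipping multi-allelic record at {rec.CHROM}:{rec.POS}"
            log.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        gt = np.asarray(rec.genotype.array())[:, :2]
        row = np.where((gt < 0).any(axis=1), MISSING, gt.clip(min=0).sum(axis=1))
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chrom.append(str(rec.CHROM))
        pos.append(rec.POS)
        rows.append(row.astype(np.int16))
    codes = np.array(rows, dtype=np.int16)
    marker_class = [
        _infer_marker_class(codes[j], default_class) for j in range(codes.shape[0])
    ]
    return GenotypeTable(
        snp_ids=snp_ids,
        individual_ids=individual_ids,
        codes=codes,
        marker_class=marker_class,
        chrom=chrom,
        pos=np.array(pos, dtype=np.int64),
    )


def write_genotypes(g: GenotypeTable, path) -> None:
    df = pd.DataFrame(g.codes, columns=g.individual_ids)
    df.insert(0, "snp", g.snp_ids)
    if g.chrom is not None:
        df.insert(1, "chrom", g.chrom)
    if g.pos is not None:
        df.insert(2 if g.chrom is not None else 1, "pos", g.pos)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SNP filtering


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value from genotype counts.

    Sums the probabilities of all heterozygote counts (given fixed allele
    counts) no more likely than the observed one, using the stable recurrence
    of the haplotype-conditional distribution.
    """
    obs_het = int(n_het)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het  # rare allele copies
    # heterozygote count has the parity of the rare allele count
    het_values = np.arange(rare % 2, rare + 1, 2)
    probs = np.zeros(het_values.size)
    # start at the mode-ish midpoint and recurse both ways
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    idx_mid = int(np.searchsorted(het_values, mid))
    probs[idx_mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / ((rare-h+2)(2n-rare-h+2))
    for i in range(idx_mid, 0, -1):
        h = het_values[i]
        probs[i - 1] = probs[i] * h * (h - 1) / (
            (rare - h + 2) * (2 * n - rare - h + 2)
        )
    # upward recurrence: P(h+2)/P(h) = (rare-h)(2n-rare-h) / ((h+2)(h+1))
    for i in range(idx_mid, het_values.size - 1):
        h = het_values[i]
        probs[i + 1] = probs[i] * (rare - h) * (2 * n - rare - h) / (
            (h + 2.0) * (h + 1.0)
        )
    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(het_values, obs_het))]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def filter_snps(
    g: GenotypeTable, maf_min: float = 0.05, hwe_alpha: float = 1e-4
) -> GenotypeTable:
    """Drop GWAS biallelic SNPs failing minor-allele-frequency or HWE tests.

    Non-GWAS marker classes pass through untouched. Counts are logged.
    """
    keep = np.ones(g.m, dtype=bool)
    n_maf = n_hwe = 0
    for j in range(g.m):
        if g.marker_class[j] != "gwas_biallelic":
            continue
        c = g.codes[j][g.codes[j] != MISSING]
        if c.size == 0:
            keep[j] = False
            continue
        n0 = int((c == 0).sum())
        n1 = int((c == 1).sum())
        n2 = int((c == 2).sum())
        alt = n1 + 2 * n2
        maf = min(alt, 2 * c.size - alt) / (2 * c.size)
        if maf < maf_min:
            keep[j] = False
            n_maf += 1
            continue
        if hwe_exact_test(n0, n1, n2) < hwe_alpha:
            keep[j] = False
            n_hwe += 1
    log.info(
        "filter_snps: %d/%d kept (%d MAF<%g, %d HWE p<%g)",
        int(keep.sum()), g.m, n_maf, maf_min, n_hwe, hwe_alpha,
    )
    return g.subset_snps(keep)


# ---------------------------------------------------------------------------
# plasticity


def compute_plasticity(traj: TraitTrajectorySet) -> PlasticitySet:
    """Plasticity trajectories z_i(t_k) = x_i(t_k) - y_i(t_k), sign preserved."""
    if traj.control.shape != traj.stress.shape:
        raise ValueError("control/stress shape mismatch")
    return PlasticitySet(ids=list(traj.ids), grid=traj.grid,
                         z=traj.control - traj.stress)
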