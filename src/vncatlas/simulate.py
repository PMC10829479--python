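"""Synthetic count-matrix and ROI-table generators with ground truth.

Counts follow a gamma-Poisson (negative binomial) model: gene g in cell c
has mean mu_cg = lib_c * base_g * program multipliers, where lib_c is a
log-normal library-size factor and base_g a per-gene baseline mean. Cell
types are planted as marker programs (strong induction of transmitter
marker genes plus a block of type-specific "identity programme" genes that
gives clusters a recoverable multivariate signature). Optional planted
structure: QC-failing cells built to violate a designated filter rule,
cell-cycle phase programmes, neuropeptide programmes, and doublets formed
by summing two parent cells.

Every draw comes from one seeded generator, so a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datamodel import ExpressionDataset, GeneSetCatalog
from .qc import QCThresholds

__all__ = ["CellType", "SimConfig", "SimTruth", "generate", "generate_roi_table", "write_bundle"]


@dataclass(frozen=True)
class CellType:
    name: str
    proportion: float
    markers: tuple[str, ...]  # genes strongly induced (detection markers)
    marker_mult: float = 2000.0
    program_size: int = 20  # type-specific identity genes
    program_mult: float = 6.0


def _default_cell_types() -> tuple[CellType, ...]:
    """A fast-transmitter mix plus a small monoaminergic population, echoing
    the cholinergic/GABAergic/glutamatergic dominance of insect VNC data."""
    return (
        CellType("ACh", 0.43, ("VAChT", "ChAT")),
        CellType("GABA", 0.33, ("GAT", "Gad1")),
        CellType("Glu", 0.19, ("VGlut",)),
        CellType("Mono", 0.05, ("Vmat", "SerT", "TH", "Dat", "Tbh")),
    )


@dataclass
class SimConfig:
    """Generator settings; defaults give a clean three-type neuronal mix.

    ``qc_thresholds`` are the filter settings the planted QC failures are
    built against; the count-based cutoffs are scaled to the matrix size
    (100 genes / 500 UMIs and a 0.6 log-ratio at the default 300-gene,
    ~2000-UMI scale, where a healthy cell sits near log(250)/log(2000) ~
    0.73) while the percentage rules keep their standard values.
    """

    n_cells: int = 2000
    n_genes: int = 300
    mean_umi: float = 2000.0
    libsize_sigma: float = 0.25  # sd of log library-size factor
    dispersion: float = 2.0  # NB size parameter theta; var = mu + mu^2/theta
    cell_types: tuple[CellType, ...] = field(default_factory=_default_cell_types)
    marker_baseline: float = 0.005  # per-cell baseline mean of marker/NP genes
    mito_share: float = 0.06  # expected fraction of counts in mito genes
    ribo_share: float = 0.20
    hs_share: float = 0.01
    qc_fail_fractions: dict = field(default_factory=dict)  # mode -> fraction
    qc_thresholds: QCThresholds = field(
        default_factory=lambda: QCThresholds(min_genes=100, min_umi=500, min_log_ratio=0.6)
    )
    doublet_rate: float = 0.0
    phase_fractions: dict = field(
        default_factory=lambda: {"G1": 0.70, "S": 0.15, "G2M": 0.15}
    )
    phase_mult: float = 15.0
    np_programs: tuple = (("NP01", "Mono", 2000.0), ("NP02", "GABA", 2000.0))
    np_pct: float = 1.0  # fraction of the host type's cells carrying the programme
    seed: int = 0

    def __post_init__(self) -> None:
        props = [t.proportion for t in self.cell_types]
        if self.cell_types and abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"cell-type proportions sum to {sum(props)}, not 1")
        for mode, frac in self.qc_fail_fractions.items():
            if mode not in ("low_gene", "high_mito", "ribo_out", "high_hs"):
                raise ValueError(f"unknown QC-fail mode {mode!r}")
            if not 0 <= frac <= 1:
                raise ValueError("QC-fail fractions must be in [0, 1]")
        if abs(sum(self.phase_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("phase fractions must sum to 1")
        if not 0 <= self.doublet_rate <= 1:
            raise ValueError("doublet_rate must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")


_MARKER_SYMBOLS = ("VAChT", "ChAT", "GAT", "Gad1", "VGlut", "Vmat", "Tbh", "SerT", "TH", "Dat")
_N_MITO, _N_RIBO, _N_HS, _N_PHASE, _N_NP = 8, 30, 5, 20, 42


def _gene_table(cfg: SimConfig) -> pd.DataFrame:
    """Symbols, family/program roles, and baseline means for every gene."""
    symbols: list[str] = list(_MARKER_SYMBOLS)
    roles: list[str] = ["marker"] * len(_MARKER_SYMBOLS)
    symbols += [f"mt-{i:02d}" for i in range(1, _N_MITO + 1)]
    roles += ["mito"] * _N_MITO
    symbols += [f"RpL{i:02d}" for i in range(1, _N_RIBO + 1)]
    roles += ["ribo"] * _N_RIBO
    symbols += [f"Hsp{i:02d}" for i in range(1, _N_HS + 1)]
    roles += ["heat_shock"] * _N_HS
    symbols += [f"CycS{i:02d}" for i in range(1, _N_PHASE + 1)]
    roles += ["s_phase"] * _N_PHASE
    symbols += [f"CycG{i:02d}" for i in range(1, _N_PHASE + 1)]
    roles += ["g2m_phase"] * _N_PHASE
    symbols += [f"NP{i:02d}" for i in range(1, _N_NP + 1)]
    roles += ["neuropeptide"] * _N_NP
    n_special = len(symbols)
    if cfg.n_genes < n_special + sum(t.program_size for t in cfg.cell_types) + 20:
        raise ValueError(
            f"n_genes={cfg.n_genes} too small; need room for {n_special} annotated genes, "
            "type programmes and filler"
        )
    for t in cfg.cell_types:
        symbols += [f"{t.name}prog{i:02d}" for i in range(1, t.program_size + 1)]
        roles += [f"program_{t.name}"] * t.program_size
    n_fill = cfg.n_genes - len(symbols)
    symbols += [f"FILL{i:04d}" for i in range(1, n_fill + 1)]
    roles += ["filler"] * n_fill
    return pd.DataFrame(
        {
            "gene_id": [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)],
            "symbol": symbols,
            "role": roles,
        }
    )


def _baseline_means(cfg: SimConfig, genes: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Per-gene baseline mean counts per (unit-libsize) cell.

    Family shares are fixed targets; markers/neuropeptides sit near the
    detection floor; phase and programme genes get moderate baselines;
    filler genes carry the remaining mass with log-normal spread.
    """
    base = np.zeros(len(genes))
    role = genes["role"].to_numpy()
    total = cfg.mean_umi
    base[np.isin(role, ["marker", "neuropeptide"])] = cfg.marker_baseline
    for fam, share in (("mito", cfg.mito_share), ("ribo", cfg.ribo_share), ("heat_shock", cfg.hs_share)):
        m = role == fam
        raw = rng.lognormal(0.0, 0.5, m.sum())
        base[m] = raw / raw.sum() * share * total
    # low, spread-out baselines: spreading keeps phase genes from sharing
    # expression bins (their controls stay mostly non-phase genes), and the
    # low level makes non-cycling cells score below their matched controls
    phase_m = np.isin(role, ["s_phase", "g2m_phase"])
    base[phase_m] = np.exp(rng.normal(np.log(0.25), 1.2, phase_m.sum()))
    prog_m = np.char.startswith(role.astype(str), "program_")
    base[prog_m] = 0.5
    fill_m = role == "filler"
    raw = rng.lognormal(0.0, 1.8, fill_m.sum())
    assigned = base.sum()
    base[fill_m] = raw / raw.sum() * max(total - assigned, total * 0.1)
    return base


@dataclass
class SimTruth:
    """Ground truth for every planted feature of a generated dataset."""

    cell_type: np.ndarray
    phase: np.ndarray
    qc_fail_mode: np.ndarray  # "" for clean cells
    doublet: np.ndarray
    lib_factors: np.ndarray
    base_means: np.ndarray
    dispersion: float
    gene_table: pd.DataFrame
    catalog: GeneSetCatalog
    config: SimConfig

    def type_proportions(self) -> pd.Series:
        clean = (self.qc_fail_mode == "") & ~self.doublet
        return pd.Series(self.cell_type[clean]).value_counts(normalize=True)


def _build_catalog(genes: pd.DataFrame) -> GeneSetCatalog:
    cat = GeneSetCatalog.default()
    role = genes["role"]
    sym = genes["symbol"]
    cat.update(
        {
            "mito": sym[role == "mito"].tolist(),
            "ribo": sym[role == "ribo"].tolist(),
            "heat_shock": sym[role == "heat_shock"].tolist(),
            "s_phase": sym[role == "s_phase"].tolist(),
            "g2m_phase": sym[role == "g2m_phase"].tolist(),
            "neuropeptide": sym[role == "neuropeptide"].tolist(),
        }
    )
    return cat


def generate(cfg: SimConfig | None = None) -> tuple[ExpressionDataset, SimTruth]:
    """Generate a dataset and its ground truth; same seed, same bits."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_table(cfg)
    base = _baseline_means(cfg, genes, rng)
    sym_idx = {s: j for j, s in enumerate(genes["symbol"])}

    n = cfg.n_cells
    type_names = [t.name for t in cfg.cell_types]
    props = [t.proportion for t in cfg.cell_types]
    cell_type = rng.choice(type_names, size=n, p=props) if cfg.cell_types else np.full(n, "", object)
    cell_type = np.asarray(cell_type, dtype=object)

    phase_names = list(cfg.phase_fractions)
    phase = np.asarray(
        rng.choice(phase_names, size=n, p=list(cfg.phase_fractions.values())), dtype=object
    )

    qc_mode = np.full(n, "", dtype=object)
    cursor = 0
    order = rng.permutation(n)
    for mode, frac in cfg.qc_fail_fractions.items():
        k = int(round(frac * n))
        qc_mode[order[cursor : cursor + k]] = mode
        cursor += k

    lib = np.exp(rng.normal(-cfg.libsize_sigma**2 / 2, cfg.libsize_sigma, n))

    # per-cell x per-gene mean multipliers
    mult = np.ones((n, len(genes)))
    for t in cfg.cell_types:
        rows = np.where(cell_type == t.name)[0]
        for mk in t.markers:
            mult[rows, sym_idx[mk]] *= t.marker_mult
        prog_cols = np.where(genes["role"] == f"program_{t.name}")[0]
        mult[np.ix_(rows, prog_cols)] *= t.program_mult
    for ph, role in (("S", "s_phase"), ("G2M", "g2m_phase")):
        rows = np.where(phase == ph)[0]
        cols = np.where(genes["role"] == role)[0]
        mult[np.ix_(rows, cols)] *= cfg.phase_mult
    for np_gene, host_type, np_mult in cfg.np_programs:
        host_rows = np.where(cell_type == host_type)[0]
        if cfg.np_pct < 1.0:
            k = int(round(cfg.np_pct * len(host_rows)))
            host_rows = host_rows[rng.permutation(len(host_rows))[:k]]
        mult[host_rows, sym_idx[np_gene]] *= np_mult

    mu = lib[:, None] * base[None, :] * mult

    # planted QC failures (percentage rules via family boosts; count rules
    # via support restriction)
    fam_cols = {
        fam: np.where(genes["role"] == fam)[0] for fam in ("mito", "ribo", "heat_shock")
    }
    shares = {"mito": cfg.mito_share, "ribo": cfg.ribo_share, "heat_shock": cfg.hs_share}

    def _share_boost(fam: str, target: float) -> float:
        s0 = shares[fam]
        return target * (1 - s0) / (s0 * (1 - target))

    ribo_parity = 0
    for i in np.where(qc_mode != "")[0]:
        mode = qc_mode[i]
        if mode == "low_gene":
            support_size = max(5, cfg.qc_thresholds.min_genes // 3)
            support = rng.choice(len(genes), size=support_size, replace=False)
            keep = np.zeros(len(genes), dtype=bool)
            keep[support] = True
            mu[i, ~keep] = 0.0
            mu[i, keep] *= cfg.mean_umi / max(mu[i, keep].sum(), 1e-9)
        elif mode == "high_mito":
            mu[i, fam_cols["mito"]] *= _share_boost("mito", 0.50)
        elif mode == "ribo_out":
            if ribo_parity % 2 == 0:
                mu[i, fam_cols["ribo"]] *= _share_boost("ribo", 0.60)
            else:
                mu[i, fam_cols["ribo"]] *= 0.01
            ribo_parity += 1
        elif mode == "high_hs":
            mu[i, fam_cols["heat_shock"]] *= _share_boost("heat_shock", 0.15)

    theta = cfg.dispersion
    lam = rng.gamma(shape=theta, scale=mu / theta)
    counts = rng.poisson(lam).astype(np.int64)

    doublet = np.zeros(n, dtype=bool)
    if cfg.doublet_rate > 0:
        n_doub = int(round(cfg.doublet_rate * n))
        clean = np.where(qc_mode == "")[0]
        parents = rng.choice(clean, size=(n_doub, 2))
        doub_counts = counts[parents[:, 0]] + counts[parents[:, 1]]
        counts = np.vstack([counts, doub_counts])
        cell_type = np.concatenate([cell_type, np.asarray(["doublet"] * n_doub, dtype=object)])
        phase = np.concatenate([phase, phase[parents[:, 0]]])
        qc_mode = np.concatenate([qc_mode, np.asarray([""] * n_doub, dtype=object)])
        lib = np.concatenate([lib, lib[parents[:, 0]] + lib[parents[:, 1]]])
        doublet = np.concatenate([doublet, np.ones(n_doub, dtype=bool)])

    n_total = counts.shape[0]
    ds = ExpressionDataset(
        counts=sp.csr_matrix(counts),
        cell_ids=[f"CELL{i:06d}" for i in range(1, n_total + 1)],
        gene_ids=genes["gene_id"].to_numpy(dtype=object),
        gene_symbols=genes["symbol"].to_numpy(dtype=object),
    )
    ds.cell_meta["true_type"] = cell_type
    ds.cell_meta["true_phase"] = phase
    ds.log_op("simulate", seed=cfg.seed, n_cells=n_total, n_genes=cfg.n_genes)
    truth = SimTruth(
        cell_type=cell_type,
        phase=phase,
        qc_fail_mode=qc_mode,
        doublet=doublet,
        lib_factors=lib,
        base_means=base,
        dispersion=theta,
        gene_table=genes,
        catalog=_build_catalog(genes),
        config=cfg,
    )
    return ds, truth


def generate_roi_table(
    n: int,
    class_means: tuple[float, float, float] = (5_000.0, 30_000.0, 80_000.0),
    class_props: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    noise_sd: float = 1_000.0,
    frame: tuple[float, float] = (0.0, 100.0),
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """ROI table with a trimodal CTCF distribution plus truth classes.

    ``class_means`` are CTCF targets for the low/medium/high populations
    (they must straddle the 15k and 50k breakpoints); integrated density is
    back-computed from a drawn area and background so that
    ctcf(integrated_density, area, background) reproduces the target.
    """
    if not (class_means[0] < 15_000 < class_means[1] < 50_000 < class_means[2]):
        raise ValueError("class means must straddle the 15k/50k thresholds in order")
    rng = np.random.default_rng(seed)
    labels = np.asarray(["low", "medium", "high"], dtype=object)
    truth = rng.choice(labels, size=n, p=class_props)
    means = dict(zip(labels, class_means))
    target = np.asarray([rng.normal(means[t], noise_sd) for t in truth])
    area = rng.uniform(100, 300, n)
    background = rng.uniform(50, 150, n)
    lo, hi = frame
    table = pd.DataFrame(
        {
            "roi_id": [f"ROI{i:04d}" for i in range(1, n + 1)],
            "integrated_density": target + area * background,
            "area": area,
            "background_mean": background,
            "x": rng.uniform(lo, hi, n),
            "y": rng.uniform(lo, hi, n),
        }
    )
    return table, truth


def write_bundle(ds: ExpressionDataset, truth: SimTruth, outdir) -> None:
    """Write the 10x triple, catalog TSV and truth JSON for end-to-end runs
    that start from files."""
    import json
    from pathlib import Path

    from .io import write_gene_catalog, write_mtx_triple

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_mtx_triple(ds, outdir / "matrix")
    write_gene_catalog(truth.catalog, outdir / "catalog.tsv")
    payload = {
        "cell_type": truth.cell_type.tolist(),
        "phase": truth.phase.tolist(),
        "qc_fail_mode": truth.qc_fail_mode.tolist(),
        "doublet": truth.doublet.astype(bool).tolist(),
        "seed": truth.config.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(payload))
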