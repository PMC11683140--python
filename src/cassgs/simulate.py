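"""Synthetic genotypes and multi-environment trial phenotypes.

The generator mirrors the structure of a drought-phenotyping trial series for
a clonal crop: a panel of genotyped clones evaluated over several years
(environments) in randomized complete blocks laid out on a row/column field
grid.  Phenotypes are built additively from the same components the
stage-one mixed model estimates,

    y = mu + env + block(env) + row(env) + col(env) + g_clone + gxe + e,

each drawn independent normal at its configured variance.  Clone genetic
values have an additive part (centered-dosage coding at a random QTL subset)
and an optional dominance part (genotypic dominance coding at a second QTL
subset); both are rescaled so the realized genetic variance matches the
target exactly, which makes recovery tests calibrated regardless of QTL
count.  The true values and marker effects are returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from cassgs.markers import MarkerMatrix, dominance_design

__all__ = ["SimulationConfig", "GroundTruth", "simulate_genotypes",
           "simulate_trials", "toy_fixture", "DEFAULT_TRAITS"]

#: the twelve agronomic traits of the motivating drought trials
DEFAULT_TRAITS = ["DMC", "FRY", "HI", "N_Roots", "Nstem.Plant", "Plant.Height",
                  "Root.Di", "Root.Le", "ShY", "StC", "Stem.D", "StY"]


def _default_variances() -> dict[str, float]:
    # proportions roughly: residual ~45%, genotype ~25%, gxe ~12%, env ~10%,
    # row ~4%, column ~4% — the typical partition for these trials
    return {"genotype": 1.0, "environment": 0.4, "gxe": 0.5,
            "row": 0.15, "column": 0.15, "residual": 1.8}


@dataclass
class SimulationConfig:
    """Settings for one simulated trial series."""

    n_clones: int = 300
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl_additive: int = 100
    n_qtl_dominance: int = 100
    variance_targets: dict[str, float] = field(default_factory=_default_variances)
    dominance_ratio: float = 0.0  # sigma_d^2 / (sigma_a^2 + sigma_d^2)
    n_environments: int = 4
    n_blocks: int = 4
    field_rows: int = 40
    field_cols: int = 30
    traits: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    mu: float = 10.0
    block_variance: float = 0.1
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_qtl_additive > self.n_markers or self.n_qtl_dominance > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        required = {"genotype", "environment", "gxe", "row", "column", "residual"}
        missing = required - set(self.variance_targets)
        if missing:
            raise ValueError(f"variance_targets missing components: {sorted(missing)}")
        if any(v < 0 for v in self.variance_targets.values()):
            raise ValueError("variance_targets must be nonnegative")
        if self.variance_targets["residual"] <= 0:
            raise ValueError("residual variance must be positive")
        if not 0.0 <= self.dominance_ratio <= 1.0:
            raise ValueError("dominance_ratio must lie in [0, 1]")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """True genetic values and marker effects behind a simulated TrialTable."""

    true_additive_value: pd.DataFrame   # clone x trait
    true_dominance_value: pd.DataFrame  # clone x trait
    true_total_value: pd.DataFrame      # clone x trait
    marker_effects: dict[str, pd.DataFrame]  # trait -> (marker, additive, dominance)
    realized_h2: dict[str, float]
    realized_H2: dict[str, float]

    def to_csv(self, path) -> None:
        long = []
        for col in self.true_total_value.columns:
            long.append(pd.DataFrame({
                "clone": self.true_total_value.index,
                "trait": col,
                "additive": self.true_additive_value[col].values,
                "dominance": self.true_dominance_value[col].values,
                "total": self.true_total_value[col].values,
            }))
        pd.concat(long, ignore_index=True).to_csv(path, index=False)


def simulate_genotypes(cfg: SimulationConfig) -> MarkerMatrix:
    """Draw biallelic dosages under Hardy-Weinberg at uniform allele frequencies."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.maf_range
    p = rng.uniform(lo, hi, size=cfg.n_markers)
    dosages = rng.binomial(2, p, size=(cfg.n_clones, cfg.n_markers)).astype(float)
    clones = [f"CL{i + 1:04d}" for i in range(cfg.n_clones)]
    markers = [f"SNP{j + 1:05d}" for j in range(cfg.n_markers)]
    return MarkerMatrix(clones, markers, dosages)


def _scale_to_variance(x: np.ndarray, target: float) -> np.ndarray:
    v = float(np.var(x))
    if target == 0.0 or v == 0.0:
        return np.zeros_like(x), 0.0
    f = np.sqrt(target / v)
    return x * f, f


def _genetic_values(geno: MarkerMatrix, cfg: SimulationConfig, rng):
    """Sample QTL effects and return calibrated additive/dominance clone values."""
    sg2 = cfg.variance_targets["genotype"]
    sa2 = (1.0 - cfg.dominance_ratio) * sg2
    sd2 = cfg.dominance_ratio * sg2
    p = geno.allele_freq
    Z = geno.dosages - 2.0 * p
    H = dominance_design(geno)

    eff = pd.DataFrame({"marker": geno.marker_ids, "additive": 0.0, "dominance": 0.0})
    qtl_a = rng.choice(geno.n_markers, size=cfg.n_qtl_additive, replace=False)
    ua = rng.standard_normal(cfg.n_qtl_additive)
    ga = Z[:, qtl_a] @ ua
    ga, fa = _scale_to_variance(ga, sa2)
    eff.loc[qtl_a, "additive"] = ua * fa

    gd = np.zeros(geno.n_clones)
    if sd2 > 0 and cfg.n_qtl_dominance > 0:
        qtl_d = rng.choice(geno.n_markers, size=cfg.n_qtl_dominance, replace=False)
        ud = rng.standard_normal(cfg.n_qtl_dominance)
        gd = H[:, qtl_d] @ ud
        # orthogonalize against the additive part so component variances are exact
        if np.var(ga) > 0:
            gd = gd - ga * (np.cov(gd, ga)[0, 1] / np.var(ga))
        gd, fd = _scale_to_variance(gd, sd2)
        eff.loc[qtl_d, "dominance"] = ud * fd
    return ga - ga.mean(), gd - gd.mean(), eff


def simulate_trials(genotypes: MarkerMatrix, cfg: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate plot-level phenotypes for every trait plus the ground truth.

    Returns a long-format TrialTable with columns
    ``clone, env, block, row, col, trait, value``.
    """
    if genotypes.n_clones != cfg.n_clones:
        raise ValueError("genotypes inconsistent with cfg.n_clones")
    plots_per_env = cfg.n_clones * cfg.n_blocks
    if plots_per_env > cfg.field_rows * cfg.field_cols:
        raise ValueError(
            f"layout error: {plots_per_env} plots per environment exceed the "
            f"{cfg.field_rows} x {cfg.field_cols} field grid")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7151]))
    vt = cfg.variance_targets
    clones = genotypes.clone_ids
    envs = [f"E{i + 1}" for i in range(cfg.n_environments)]
    blocks = [f"B{k + 1}" for k in range(cfg.n_blocks)]

    # field layout per environment: plots fill the grid row-major, blocks
    # contiguous, clone order randomized within block
    layout = {}
    for env in envs:
        pos = 0
        for blk in blocks:
            order = rng.permutation(cfg.n_clones)
            for ci in order:
                layout[(env, blk, clones[ci])] = (pos // cfg.field_cols + 1,
                                                  pos % cfg.field_cols + 1)
                pos += 1

    # design-factor effects shared across traits only through the layout;
    # each trait draws its own effects
    records = []
    add_vals, dom_vals, tot_vals = {}, {}, {}
    effects_per_trait, h2s, H2s = {}, {}, {}
    for trait in cfg.traits:
        ga, gd, eff = _genetic_values(genotypes, cfg, rng)
        g_tot = ga + gd
        effects_per_trait[trait] = eff
        add_vals[trait], dom_vals[trait], tot_vals[trait] = ga, gd, g_tot
        sa2 = float(np.var(ga))
        sd2 = float(np.var(gd))
        sr2 = vt["residual"]
        h2s[trait] = sa2 / (sa2 + sr2)
        H2s[trait] = (sa2 + sd2) / (sa2 + sd2 + sr2)

        env_eff = dict(zip(envs, rng.normal(0, np.sqrt(vt["environment"]), cfg.n_environments)))
        blk_eff = {(e, b): v for (e, b), v in zip(
            [(e, b) for e in envs for b in blocks],
            rng.normal(0, np.sqrt(cfg.block_variance), cfg.n_environments * cfg.n_blocks))}
        row_eff = {(e, r): v for (e, r), v in zip(
            [(e, r) for e in envs for r in range(1, cfg.field_rows + 1)],
            rng.normal(0, np.sqrt(vt["row"]), cfg.n_environments * cfg.field_rows))}
        col_eff = {(e, c): v for (e, c), v in zip(
            [(e, c) for e in envs for c in range(1, cfg.field_cols + 1)],
            rng.normal(0, np.sqrt(vt["column"]), cfg.n_environments * cfg.field_cols))}
        gxe = rng.normal(0, np.sqrt(vt["gxe"]), (cfg.n_clones, cfg.n_environments))
        resid = rng.normal(0, np.sqrt(vt["residual"]),
                           (cfg.n_clones, cfg.n_environments, cfg.n_blocks))

        for ei, env in enumerate(envs):
            for bi, blk in enumerate(blocks):
                for ci, clone in enumerate(clones):
                    r, c = layout[(env, blk, clone)]
                    y = (cfg.mu + env_eff[env] + blk_eff[(env, blk)]
                         + row_eff[(env, r)] + col_eff[(env, c)]
                         + g_tot[ci] + gxe[ci, ei] + resid[ci, ei, bi])
                    records.append((clone, env, blk, r, c, trait, y))

    table = pd.DataFrame(records, columns=["clone", "env", "block", "row", "col",
                                           "trait", "value"])
    truth = GroundTruth(
        true_additive_value=pd.DataFrame(add_vals, index=clones),
        true_dominance_value=pd.DataFrame(dom_vals, index=clones),
        true_total_value=pd.DataFrame(tot_vals, index=clones),
        marker_effects=effects_per_trait,
        realized_h2=h2s, realized_H2=H2s)
    return table, truth


# -- deterministic toy fixture -----------------------------------------------

_TOY_DOSAGES = np.array([
    [0, 1, 2, 1, 0, 0],
    [1, 2, 0, 0, 1, 0],
    [2, 0, 1, 2, 1, 0],
    [1, 1, 1, 1, 2, 0],
    [0, 2, 2, 0, 1, 0],
    [2, 1, 0, 2, 0, 0],
    [1, 0, 1, 1, 2, 0],
    [2, 2, 0, 0, 0, 0],
], dtype=float)

# hard-coded "residual" draws for the 32 toy plots, fixed across releases
_TOY_NOISE = [
    0.12, -0.31, 0.05, 0.44, -0.22, 0.18, -0.07, 0.29,
    -0.15, 0.08, 0.33, -0.41, 0.02, -0.26, 0.37, -0.09,
    0.21, -0.14, -0.35, 0.27, 0.11, -0.02, 0.40, -0.19,
    -0.28, 0.16, 0.06, -0.38, 0.23, -0.11, 0.30, 0.01,
]

# clone planting order inside each (env, block), fixed
_TOY_ORDERS = {
    ("E1", "B1"): [0, 3, 5, 1, 7, 2, 6, 4],
    ("E1", "B2"): [4, 6, 1, 0, 2, 7, 3, 5],
    ("E2", "B1"): [2, 5, 0, 7, 6, 4, 1, 3],
    ("E2", "B2"): [7, 1, 4, 3, 5, 0, 2, 6],
}


def toy_fixture() -> tuple[MarkerMatrix, pd.DataFrame]:
    """A tiny hard-coded dataset (8 clones, 6 markers, 2 envs, 2 blocks).

    Marker TM6 is monomorphic (frequency 0), so downstream MAF filtering at
    any positive threshold keeps exactly 5 of the 6 markers.  Every phenotype
    is a deterministic sum of printed constants — suitable for exact
    regression tests.
    """
    clones = [f"C{i + 1}" for i in range(8)]
    markers = [f"TM{j + 1}" for j in range(6)]
    geno = MarkerMatrix(clones, markers, _TOY_DOSAGES.copy())

    g = _TOY_DOSAGES[:, 0] - 1.0          # genetic values from marker TM1
    env_eff = {"E1": 1.0, "E2": -1.0}
    blk_eff = {"B1": 0.5, "B2": -0.5}
    records, k = [], 0
    for env in ("E1", "E2"):
        for blk in ("B1", "B2"):
            base_row = 1 if blk == "B1" else 3
            for pos, ci in enumerate(_TOY_ORDERS[(env, blk)]):
                r = base_row + pos // 4
                c = pos % 4 + 1
                y = (10.0 + env_eff[env] + blk_eff[blk] + 0.05 * r - 0.05 * c
                     + g[ci] + _TOY_NOISE[k])
                records.append((clones[ci], env, blk, r, c, "toy_trait", y))
                k += 1
    table = pd.DataFrame(records, columns=["clone", "env", "block", "row", "col",
                                           "trait", "value"])
    return geno, table
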