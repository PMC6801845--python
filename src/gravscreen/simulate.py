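"""Synthetic RNA-seq counts with the clinostat study's factorial structure.

The generator emulates a 36-sample experiment — standing 1G (ST) and rotating
simulated-microgravity (RO) fibroblast cultures, unirradiated (N=6 each) or
harvested 3/24 h after 1 Gy of X-rays or carbon ions (N=3 per condition) —
and plants known expression programs so that every downstream stage of the
screen can be validated against ground truth:

* a highly expressed, radiation-responsive cell-cycle panel subset (the
  genes a maximum-expression filter should retain),
* a small set of genes whose irradiated response is modified by simulated
  microgravity (the "synergy" genes the five-step screen must recover),
* a weak microgravity-alone program in a dedicated non-panel gene set, and
* generic radiation up/down programs in the non-panel background.

Counts are negative-binomial: gene g in sample j of condition c has mean
``lib_factor_j * mu_gc`` and variance ``mu + phi * mu**2`` with a common
dispersion phi. Baseline expression across genes is log-normal (heavy-tailed,
like real RNA-seq abundance), and per-sample library-size factors are drawn
uniformly so that normalization is a real step, not a no-op.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import io
from .design import CONDITION_ORDER, DEFAULT_REPLICATES, IRRADIATED_CONDITIONS, build_design

#: 84-gene cell-cycle panel (synthetic stand-in modelled on a commercial
#: human cell-cycle PCR array gene list).
DEFAULT_PANEL: tuple[str, ...] = (
    "ABL1", "ANAPC2", "ANAPC4", "ATM", "ATR", "AURKA", "AURKB", "BCCIP",
    "BCL2", "BIRC5", "BRCA1", "BRCA2", "CCNA2", "CCNB1", "CCNB2", "CCNC",
    "CCND1", "CCND2", "CCND3", "CCNE1", "CCNF", "CCNG1", "CCNG2", "CCNH",
    "CCNT1", "CCNT2", "CDC16", "CDC20", "CDC25A", "CDC25C", "CDC34", "CDC6",
    "CDK1", "CDK2", "CDK4", "CDK5R1", "CDK6", "CDK7", "CDK8", "CDKN1A",
    "CDKN1B", "CDKN2A", "CDKN2B", "CDKN3", "CHEK1", "CHEK2", "CUL1", "CUL2",
    "CUL3", "DIRAS3", "E2F1", "E2F4", "GADD45A", "GTF2H1", "GTSE1", "HUS1",
    "KNTC1", "KPNA2", "MAD2L1", "MCM2", "MCM3", "MCM4", "MCM5", "MDM2",
    "MKI67", "MNAT1", "MRE11", "NBN", "PCNA", "RAD1", "RAD17", "RAD51",
    "RAD9A", "RB1", "RBBP8", "RBL1", "RBL2", "SERTAD1", "SKP2", "STMN1",
    "TFDP1", "TFDP2", "TP53", "WEE1",
)

#: Panel genes planted above the maximum-expression filter threshold, in
#: priority order: first the nine synergy genes, then four radiation-responsive
#: genes with no gravity sensitivity at all (modelled on ATM/CDC20/CDK6/TFDP1).
_HIGH_PRIORITY: tuple[str, ...] = (
    "ABL1", "CDKN1A", "MDM2",                        # synergy: enhanced decrease
    "CCNB1", "CCND1", "KPNA2", "MCM4", "MKI67", "STMN1",  # synergy: enhanced increase
    "ATM", "CDC20", "CDK6", "TFDP1",
)
_SYNERGY_DECREASE: frozenset[str] = frozenset({"ABL1", "CDKN1A", "MDM2"})

#: Sign of the radiation main effect planted on the high-expression panel
#: genes (mirrors checkpoint induction / cell-cycle shutdown after damage).
_HIGH_RADIATION_SIGN: dict[str, int] = {
    "CDKN1A": +1, "MDM2": +1,
    "CCNB1": -1, "KPNA2": -1, "MCM4": -1, "MKI67": -1, "STMN1": -1, "CDC20": -1,
    "ABL1": 0, "CCND1": 0, "ATM": 0, "CDK6": 0, "TFDP1": 0,
}

#: Panel genes reported as absent from the fixture (zero counts everywhere).
_UNDETECTED_PRIORITY: tuple[str, ...] = ("DIRAS3", "CDKN2A", "CCND2", "BCL2")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Effect sizes are log2 fold changes; ``effect_log2fc_synergy`` is the
    *extra* shift applied only under gravity=RO AND radiation!=none, on top
    of whatever main effects a gene carries.
    """

    n_genes: int = 2000
    panel_size: int = 84
    panel_detected: int = 82
    baseline_mean: float = 60.0       # median expected count per gene
    baseline_sdlog: float = 1.2       # sdlog of the log-normal across genes
    dispersion: float = 0.1           # NB dispersion phi; var = mu + phi mu^2
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    effect_log2fc_radiation: float = 2.0
    effect_log2fc_microgravity: float = 1.5
    effect_log2fc_synergy: float = 2.0
    n_synergy_genes: int = 9
    n_step2_genes: int = 13           # panel genes planted above the expression filter
    n_microgravity_genes: int = 3     # non-panel microgravity-alone program
    n_radiation_up: int = 40          # non-panel radiation-up program
    n_radiation_down: int = 40        # non-panel radiation-down program
    n_panel_radiation_down: int = 30  # low-expression panel genes shut down by radiation
    high_expression_mean: float = 2000.0  # median expected count of the planted high genes
    high_expression_sdlog: float = 0.4
    low_panel_mean_cap: float = 80.0  # cap keeps non-planted panel genes below the filter
    microgravity_gene_mean: float = 500.0
    replicates: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_REPLICATES))
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < self.panel_size:
            raise ValueError("n_genes must be at least panel_size")
        if not (0 <= self.panel_detected <= self.panel_size):
            raise ValueError("panel_detected must lie in [0, panel_size]")
        if self.n_synergy_genes > self.n_step2_genes:
            raise ValueError("synergy genes must be a subset of the planted high-expression genes")
        if self.n_step2_genes > self.panel_detected:
            raise ValueError("planted high-expression genes must be detected panel genes")
        for name in ("baseline_mean", "high_expression_mean", "microgravity_gene_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        lo, hi = self.lib_size_range
        if not (0 < lo <= hi):
            raise ValueError("lib_size_range must be positive with lo <= hi")
        if set(self.replicates) != set(CONDITION_ORDER):
            raise ValueError("replicates map must cover exactly the 10 design conditions")


def _panel_genes(config: SimulationConfig) -> list[str]:
    if config.panel_size <= len(DEFAULT_PANEL):
        return list(DEFAULT_PANEL[: config.panel_size])
    extra = [f"PANEL{i:03d}" for i in range(config.panel_size - len(DEFAULT_PANEL))]
    return list(DEFAULT_PANEL) + extra


def _true_means(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Ground-truth table: per-gene flags, per-condition true means.

    Returns a DataFrame indexed by gene_id with columns ``in_panel``,
    ``detected``, ``synergy_class_truth`` and one ``mean_<condition>``
    column per design condition.
    """
    panel = _panel_genes(config)
    n_background = config.n_genes - config.panel_size
    background = [f"G{i:05d}" for i in range(n_background)]
    genes = panel + background

    n_undetected = config.panel_size - config.panel_detected
    undetected = [g for g in _UNDETECTED_PRIORITY if g in panel][:n_undetected]
    if len(undetected) < n_undetected:
        pool = [g for g in panel if g not in _HIGH_PRIORITY and g not in undetected]
        undetected += pool[: n_undetected - len(undetected)]
    undetected_set = set(undetected)

    high = [g for g in _HIGH_PRIORITY if g in panel and g not in undetected_set]
    if len(high) < config.n_step2_genes:
        pool = [g for g in panel if g not in high and g not in undetected_set]
        high += pool[: config.n_step2_genes - len(high)]
    high = high[: config.n_step2_genes]
    synergy = high[: config.n_synergy_genes]
    synergy_class = {
        g: ("enhanced_decrease" if g in _SYNERGY_DECREASE else "enhanced_increase")
        for g in synergy
    }
    # genes appended beyond the named priority list alternate directions
    for i, g in enumerate(synergy):
        if g not in _HIGH_PRIORITY:
            synergy_class[g] = "enhanced_decrease" if i % 2 else "enhanced_increase"

    low_panel = [g for g in panel if g not in set(high) | undetected_set]

    # baseline means
    base = pd.Series(0.0, index=pd.Index(genes, name="gene_id"))
    base.loc[background] = config.baseline_mean * np.exp(
        rng.normal(0.0, config.baseline_sdlog, size=n_background)
    )
    base.loc[high] = config.high_expression_mean * np.exp(
        rng.normal(0.0, config.high_expression_sdlog, size=len(high))
    )
    base.loc[low_panel] = np.minimum(
        config.low_panel_mean_cap,
        0.5 * config.baseline_mean * np.exp(rng.normal(0.0, 0.8, size=len(low_panel))),
    )
    base.loc[list(undetected_set)] = 0.0

    # per-gene log2 effects
    rad_effect = pd.Series(0.0, index=base.index)   # applied under radiation != none
    grav_effect = pd.Series(0.0, index=base.index)  # applied under gravity = RO
    syn_effect = pd.Series(0.0, index=base.index)   # applied under RO AND irradiated

    for g in high:
        sign = _HIGH_RADIATION_SIGN.get(g, (-1) ** (high.index(g)))
        rad_effect.loc[g] = sign * config.effect_log2fc_radiation
    rad_effect.loc[low_panel[: config.n_panel_radiation_down]] = -config.effect_log2fc_radiation

    bg = list(background)
    mg_genes = bg[: config.n_microgravity_genes]
    up_genes = bg[config.n_microgravity_genes : config.n_microgravity_genes + config.n_radiation_up]
    down_genes = bg[
        config.n_microgravity_genes
        + config.n_radiation_up : config.n_microgravity_genes
        + config.n_radiation_up
        + config.n_radiation_down
    ]
    base.loc[mg_genes] = config.microgravity_gene_mean
    grav_effect.loc[mg_genes] = config.effect_log2fc_microgravity
    rad_effect.loc[up_genes] = config.effect_log2fc_radiation
    rad_effect.loc[down_genes] = -config.effect_log2fc_radiation

    for g, cls in synergy_class.items():
        syn_effect.loc[g] = (
            config.effect_log2fc_synergy if cls == "enhanced_increase" else -config.effect_log2fc_synergy
        )

    truth = pd.DataFrame(index=base.index)
    truth["in_panel"] = truth.index.isin(panel)
    truth["detected"] = base > 0
    truth["synergy_class_truth"] = [synergy_class.get(g, "none") for g in truth.index]
    truth["microgravity_program"] = truth.index.isin(mg_genes)
    for cond in CONDITION_ORDER:
        log2fc = pd.Series(0.0, index=base.index)
        if cond.startswith("RO"):
            log2fc = log2fc + grav_effect
        if cond in IRRADIATED_CONDITIONS:
            log2fc = log2fc + rad_effect
            if cond.startswith("RO"):
                log2fc = log2fc + syn_effect
        truth[f"mean_{cond}"] = base * np.power(2.0, log2fc)
    return truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draw of NB counts with mean ``mean`` and dispersion phi."""
    mean = np.asarray(mean, dtype=float)
    if phi == 0:
        return rng.poisson(mean)
    lam = np.where(mean > 0, rng.gamma(1.0 / phi, phi * np.maximum(mean, 1e-300)), 0.0)
    return rng.poisson(lam)


def simulate_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (counts, design, truth) for one synthetic experiment.

    Same seed, same config -> bit-identical output. The truth table records
    every planted effect as per-condition true means plus class flags.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = build_design(config.replicates)
    truth = _true_means(config, rng)

    lo, hi = config.lib_size_range
    lib_factors = rng.uniform(lo, hi, size=len(design))

    cols = {}
    for j, row in enumerate(design.itertuples(index=False)):
        mu = truth[f"mean_{row.condition}"].to_numpy() * lib_factors[j]
        cols[row.sample_id] = _nb_draw(rng, mu, config.dispersion)
    counts = pd.DataFrame(cols, index=truth.index)
    return counts, design, truth


def build_gene_sets(
    config: SimulationConfig,
    truth: pd.DataFrame,
    n_decoys: int = 5,
    decoy_size: int = 25,
    mg_set_extra: int = 5,
) -> dict[str, list[str]]:
    """Gene-set collection matched to the fixture, for enrichment tests.

    Contains the cell-cycle panel, a small microgravity-responsive set (the
    planted microgravity-program genes plus a few null members), and random
    decoy sets drawn from the background. Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed + 1)
    panel = truth.index[truth["in_panel"]].tolist()
    mg = truth.index[truth["microgravity_program"]].tolist()
    background = truth.index[~truth["in_panel"] & ~truth["microgravity_program"]].tolist()
    sets: dict[str, list[str]] = {
        "CELL_CYCLE_PANEL": panel,
        "MICROGRAVITY_RESPONSE": mg + list(rng.choice(background, size=mg_set_extra, replace=False)),
    }
    for k in range(n_decoys):
        members = rng.choice(background, size=decoy_size, replace=False)
        sets[f"DECOY_SET_{k + 1}"] = sorted(members)
    return sets


def write_fixture(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    truth: pd.DataFrame,
    directory: str | os.PathLike,
    gene_sets: dict[str, list[str]] | None = None,
) -> dict[str, str]:
    """Write counts/design/truth TSVs, the panel file and a GMT to a directory.

    Returns a name -> path map of everything written. Files round-trip
    losslessly through the readers in :mod:`gravscreen.io`.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    paths = {
        "counts": os.path.join(directory, "counts.tsv"),
        "design": os.path.join(directory, "design.tsv"),
        "truth": os.path.join(directory, "truth.tsv"),
        "panel": os.path.join(directory, "panel.txt"),
        "gene_sets": os.path.join(directory, "gene_sets.gmt"),
    }
    io.write_counts(counts, paths["counts"])
    io.write_design(design, paths["design"])
    io.write_table(truth.reset_index(), paths["truth"])
    panel = truth.index[truth["in_panel"]].tolist()
    io.write_panel(panel, paths["panel"])
    if gene_sets is None:
        mg = (
            truth.index[truth["microgravity_program"]].tolist()
            if "microgravity_program" in truth
            else []
        )
        background = truth.index[~truth["in_panel"]].tolist()
        rng = np.random.default_rng(0)
        gene_sets = {"CELL_CYCLE_PANEL": panel}
        if mg:
            gene_sets["MICROGRAVITY_RESPONSE"] = mg
        for k in range(3):
            gene_sets[f"DECOY_SET_{k + 1}"] = sorted(
                rng.choice(background, size=min(25, len(background)), replace=False)
            )
    io.write_gmt(gene_sets, paths["gene_sets"])
    return paths


def simulate_fixture(
    config: SimulationConfig | None = None,
    directory: str | os.PathLike | None = None,
    seed: int | None = None,
):
    """Convenience wrapper: simulate with defaults and optionally write files."""
    config = config or SimulationConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    counts, design, truth = simulate_counts(config)
    gene_sets = build_gene_sets(config, truth)
    if directory is not None:
        write_fixture(counts, design, truth, directory, gene_sets)
    return counts, design, truth, gene_sets
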