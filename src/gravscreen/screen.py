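"""Five-step screen for genes whose radiation response is modified by
simulated microgravity, plus relative-expression summaries.

The funnel:

1. restrict the gene universe to a curated cell-cycle panel (detected genes
   only);
2. keep genes whose maximum normalized expression in the standing-1G
   samples reaches a threshold (default 1000);
3. for each irradiation arm (X3, X24, C3, C24), exact NB test of standing
   vs rotating irradiated replicates; a gene passes with p < alpha in at
   least one arm;
4. genes failing step 3 are tested for a microgravity-alone effect
   (non-irradiated ST vs RO, N=6 vs N=6);
5. for genes passing step 3 or 4, the rotating irradiated mean is converted
   by the ratio r of non-irradiated means (r = mean ST / mean RO), and the
   adjusted fold change converted / mean(ST, arm) classifies the gene as
   enhanced_decrease (< 1) or enhanced_increase (> 1) per arm.

Because the conversion divides out the gene's microgravity baseline shift,
a non-unit adjusted fold change isolates the interaction: the part of the
irradiated response attributable to the *combination* of stressors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import CONDITION_ORDER, IRRADIATION_ARMS, condition_samples
from .detest import Contrast, exact_nb_test, equalize_library_sizes, run_contrast

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "step1_panel_filter",
    "step2_expression_filter",
    "step3_gravity_contrasts",
    "step4_microgravity_alone",
    "step5_convert_and_classify",
    "run_screen",
    "relative_expression",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable parameters of the screen.

    ``step2_scope`` selects which samples count as "the 1G sample" for the
    maximum-expression filter: ``"all_standing"`` (every ST sample,
    irradiated or not; the default) or ``"nonirradiated"`` (ST only).
    ``step2_replicate_max`` takes the max over individual replicates
    (default); set False to take the max over condition means instead.
    """

    panel: tuple[str, ...] = ()
    step2_threshold: float = 1000.0
    alpha: float = 0.05
    step2_scope: str = "all_standing"
    step2_replicate_max: bool = True
    arms: tuple[str, ...] = IRRADIATION_ARMS

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.step2_threshold <= 0:
            raise ValueError("step2_threshold must be positive")
        if self.step2_scope not in ("all_standing", "nonirradiated"):
            raise ValueError("step2_scope must be 'all_standing' or 'nonirradiated'")


@dataclass
class ScreenResult:
    """Per-gene trace through the funnel plus the selected-gene summary."""

    records: pd.DataFrame
    config: ScreenConfig
    phi: float
    step_sets: dict[str, list[str]] = field(default_factory=dict)

    @property
    def selected(self) -> list[str]:
        return self.records.loc[self.records["selected"], "gene_id"].tolist()

    def selected_summary(self) -> list[dict]:
        """JSON-ready summary of the selected genes."""
        out = []
        for row in self.records[self.records["selected"]].itertuples(index=False):
            out.append(
                {
                    "gene_id": row.gene_id,
                    "ratio_r": row.ratio_r,
                    "entered_via": "step3" if row.step3_pass else "step4",
                    "synergy_class": row.synergy_class,
                    "classes": {
                        arm: getattr(row, f"class_{arm}") for arm in self.config.arms
                    },
                    "adjusted_fc": {
                        arm: getattr(row, f"adjusted_fc_{arm}") for arm in self.config.arms
                    },
                }
            )
        return out


def step1_panel_filter(
    counts: pd.DataFrame, panel: Iterable[str]
) -> list[str]:
    """Detected panel genes: panel members with at least one nonzero count."""
    panel = list(panel)
    if not panel:
        raise ValueError("panel must be nonempty")
    detected = set(counts.index[(counts > 0).any(axis=1)])
    kept = [g for g in panel if g in detected]
    if not kept:
        import warnings

        warnings.warn("no panel gene is detected in the count matrix", stacklevel=2)
    return kept


def step2_expression_filter(
    normalized: pd.DataFrame,
    standing_samples: Sequence[str],
    threshold: float = 1000.0,
    genes: Sequence[str] | None = None,
    replicate_max: bool = True,
    design: pd.DataFrame | None = None,
) -> list[str]:
    """Genes whose maximum normalized value in the standing samples meets
    the threshold.

    With ``replicate_max=False`` the maximum is taken over condition means
    instead of individual replicates (requires ``design``).
    """
    if not len(standing_samples):
        raise ValueError("standing_samples must be nonempty")
    sub = normalized[list(standing_samples)]
    if genes is not None:
        sub = sub.loc[[g for g in genes if g in sub.index]]
    if replicate_max:
        maxima = sub.max(axis=1)
    else:
        if design is None:
            raise ValueError("condition-mean maximum requires the design table")
        cond = design.set_index("sample_id")["condition"]
        maxima = sub.T.groupby(cond).mean().T.max(axis=1)
    return maxima.index[maxima >= threshold].tolist()


def _arm_contrast(design: pd.DataFrame, arm: str) -> Contrast:
    st = condition_samples(design, f"ST-{arm}")
    ro = condition_samples(design, f"RO-{arm}")
    if not st or not ro:
        raise ValueError(f"design is missing samples for irradiation arm {arm!r}")
    return Contrast(name=arm, group_a=tuple(st), group_b=tuple(ro))


def step3_gravity_contrasts(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    genes: Sequence[str],
    alpha: float,
    phi: float,
    arms: Sequence[str] = IRRADIATION_ARMS,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Exact NB tests of ST-irradiated vs RO-irradiated per arm.

    Returns a DataFrame indexed by gene with one ``step3_p_<arm>`` column
    per arm and a ``step3_pass`` flag (p < alpha in at least one arm).
    """
    genes = list(genes)
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for arm in arms:
        contrast = _arm_contrast(design, arm)
        table = run_contrast(
            counts.loc[genes],
            counts.loc[genes].astype(float),  # means unused here
            contrast,
            phi=phi,
            alpha=alpha,
            lib_sizes=lib_sizes,
        ).set_index("gene_id")
        out[f"step3_p_{arm}"] = table["p_value"]
    pcols = [f"step3_p_{arm}" for arm in arms]
    out["step3_pass"] = (out[pcols] < alpha).any(axis=1) if genes else False
    return out


def step4_microgravity_alone(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    genes: Sequence[str],
    alpha: float,
    phi: float,
    lib_sizes: pd.Series | None = None,
) -> pd.Series:
    """Exact NB test of non-irradiated ST vs RO for the given genes.

    Returns a boolean Series (pass = p < alpha) alongside the p-values in
    its ``.attrs['p']``.
    """
    genes = list(genes)
    st = condition_samples(design, "ST")
    ro = condition_samples(design, "RO")
    if not st or not ro:
        raise ValueError("design is missing non-irradiated ST/RO samples")
    if not genes:
        result = pd.Series(dtype=bool, name="step4_pass")
        result.attrs["p"] = pd.Series(dtype=float)
        return result
    contrast = Contrast(name="RO_vs_ST", group_a=tuple(st), group_b=tuple(ro))
    table = run_contrast(
        counts.loc[genes],
        counts.loc[genes].astype(float),
        contrast,
        phi=phi,
        alpha=alpha,
        lib_sizes=lib_sizes,
    ).set_index("gene_id")
    passed = table["p_value"] < alpha
    passed.name = "step4_pass"
    passed.attrs["p"] = table["p_value"]
    return passed


def _condition_means(
    normalized: pd.DataFrame, design: pd.DataFrame, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    sub = normalized if genes is None else normalized.loc[list(genes)]
    cond = design.set_index("sample_id")["condition"]
    means = sub.T.groupby(cond).mean().T
    order = [c for c in CONDITION_ORDER if c in means.columns]
    return means[order]


def step5_convert_and_classify(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    genes: Sequence[str],
    arms: Sequence[str] = IRRADIATION_ARMS,
) -> pd.DataFrame:
    """Gravity-corrected fold changes and synergy classes per arm.

    Per gene: r = mean(ST non-irradiated) / mean(RO non-irradiated);
    converted(arm) = r * mean(RO-arm); adjusted_fc(arm) = converted(arm) /
    mean(ST-arm). Strictly below 1 -> enhanced_decrease, strictly above ->
    enhanced_increase, exactly 1 -> none. Genes with a zero non-irradiated
    RO mean are flagged unclassifiable.
    """
    genes = list(genes)
    means = _condition_means(normalized, design, genes)
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    ro0 = means["RO"]
    st0 = means["ST"]
    unclassifiable = ro0 == 0
    r = st0 / ro0.where(~unclassifiable)
    out["ratio_r"] = r
    out["unclassifiable"] = unclassifiable
    for arm in arms:
        converted = r * means[f"RO-{arm}"]
        st_arm = means[f"ST-{arm}"]
        adjusted = converted / st_arm.where(st_arm > 0)
        out[f"converted_{arm}"] = converted
        out[f"adjusted_fc_{arm}"] = adjusted
        cls = pd.Series("none", index=out.index)
        cls[adjusted < 1.0] = "enhanced_decrease"
        cls[adjusted > 1.0] = "enhanced_increase"
        cls[adjusted.isna()] = "none"
        out[f"class_{arm}"] = cls
    return out


def run_screen(
    counts: pd.DataFrame,
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    config: ScreenConfig,
    phi: float,
    lib_sizes: pd.Series | None = None,
) -> ScreenResult:
    """Run the full five-step funnel and assemble per-gene records.

    A gene is *selected* when it survives steps 1-2 and passes step 3 or
    step 4 (and is classifiable in step 5). The per-gene ``synergy_class``
    is the class of the arm with the strongest step-3 evidence (smallest
    p-value; step-4 entrants use the overall smallest arm p as well).
    """
    panel = list(config.panel)
    step1 = step1_panel_filter(counts, panel)

    if config.step2_scope == "all_standing":
        standing = design.loc[design["gravity"] == "ST", "sample_id"].tolist()
    else:
        standing = condition_samples(design, "ST")
    step2 = step2_expression_filter(
        normalized,
        standing,
        threshold=config.step2_threshold,
        genes=step1,
        replicate_max=config.step2_replicate_max,
        design=design,
    )

    step3 = step3_gravity_contrasts(
        counts, design, step2, config.alpha, phi, arms=config.arms, lib_sizes=lib_sizes
    )
    failed3 = step3.index[~step3["step3_pass"]].tolist()
    step4 = step4_microgravity_alone(
        counts, design, failed3, config.alpha, phi, lib_sizes=lib_sizes
    )
    entered = step3.index[step3["step3_pass"]].tolist() + step4.index[step4].tolist()
    step5 = step5_convert_and_classify(normalized, design, entered, arms=config.arms)

    records = pd.DataFrame({"gene_id": panel})
    records["step1_pass"] = records["gene_id"].isin(step1)
    records["step2_pass"] = records["gene_id"].isin(step2)
    records = records.merge(step3.reset_index(), on="gene_id", how="left")
    records["step3_pass"] = records["step3_pass"].isin([True])
    step4_p = step4.attrs.get("p", pd.Series(dtype=float))
    records["step4_p"] = records["gene_id"].map(step4_p)
    records["step4_pass"] = records["gene_id"].map(step4).astype("boolean")
    records = records.merge(step5.reset_index(), on="gene_id", how="left")
    records["unclassifiable"] = records["unclassifiable"].isin([True])
    records["selected"] = (
        records["step1_pass"]
        & records["step2_pass"]
        & (records["step3_pass"] | records["step4_pass"].isin([True]))
        & ~records["unclassifiable"]
    )

    pcols = [f"step3_p_{arm}" for arm in config.arms]
    pmat = records[pcols].astype(float)
    has_p = pmat.notna().any(axis=1)
    best_arm = pd.Series(pd.NA, index=records.index, dtype=object)
    if has_p.any():
        best_arm[has_p] = (
            pmat[has_p].idxmin(axis=1).str.replace("step3_p_", "", regex=False)
        )
    cls = []
    for i, row in records.iterrows():
        if not row["selected"] or pd.isna(best_arm[i]):
            cls.append("none")
        else:
            cls.append(row[f"class_{best_arm[i]}"])
    records["synergy_class"] = cls

    step_sets = {
        "step1": step1,
        "step2": step2,
        "step3_pass": step3.index[step3["step3_pass"]].tolist(),
        "step4_pass": step4.index[step4].tolist(),
        "selected": records.loc[records["selected"], "gene_id"].tolist(),
    }
    _assert_funnel(step_sets)
    return ScreenResult(records=records, config=config, phi=phi, step_sets=step_sets)


def _assert_funnel(step_sets: dict[str, list[str]]) -> None:
    """Funnel monotonicity: step1 >= step2 >= (step3 | step4) >= selected."""
    s1, s2 = set(step_sets["step1"]), set(step_sets["step2"])
    entered = set(step_sets["step3_pass"]) | set(step_sets["step4_pass"])
    sel = set(step_sets["selected"])
    if not (s2 <= s1 and entered <= s2 and sel <= entered):
        raise AssertionError("screen funnel monotonicity violated")


def relative_expression(
    normalized: pd.DataFrame,
    design: pd.DataFrame,
    genes: Sequence[str],
    counts: pd.DataFrame | None = None,
    phi: float | None = None,
    alpha: float = 0.05,
    pairs: Sequence[tuple[str, str]] | None = None,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene relative expression (condition mean / per-gene max) with
    standard errors, plus direction calls for tested condition pairs.

    The per-gene maximum is taken over condition means, so exactly one
    condition per gene has relative value 1.0. The standard error is the
    sample SD of replicate relative values divided by sqrt(N). When
    ``counts`` and ``phi`` are given, each pair (a, b) receives a direction
    call: ``up``/``down`` when the exact test is significant at ``alpha``
    (sign of the b-vs-a difference of means), ``ns`` otherwise. Default
    pairs compare each irradiated condition with its non-irradiated control
    and each rotating condition with its standing counterpart.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("genes must be nonempty")
    means = _condition_means(normalized, design, genes)
    gene_max = means.max(axis=1)
    rel = means.div(gene_max.where(gene_max > 0), axis=0).fillna(0.0)

    cond = design.set_index("sample_id")["condition"]
    replicate_rel = normalized.loc[genes].div(gene_max.where(gene_max > 0), axis=0)
    se = (
        replicate_rel.T.groupby(cond)
        .agg(lambda x: x.std(ddof=1) / math.sqrt(len(x)))
        .T[means.columns]
    )

    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    for c in means.columns:
        out[f"rel_{c}"] = rel[c]
        out[f"se_{c}"] = se[c]

    if counts is not None and phi is not None:
        if pairs is None:
            pairs = [("ST", c) for c in CONDITION_ORDER if c.startswith("ST-")]
            pairs += [("RO", c) for c in CONDITION_ORDER if c.startswith("RO-")]
            pairs += [(f"ST-{arm}", f"RO-{arm}") for arm in IRRADIATION_ARMS]
            pairs += [("ST", "RO")]
        for a, b in pairs:
            contrast = Contrast(
                name=f"{b}_vs_{a}",
                group_a=tuple(condition_samples(design, a)),
                group_b=tuple(condition_samples(design, b)),
            )
            table = run_contrast(
                counts.loc[genes],
                normalized.loc[genes],
                contrast,
                phi=phi,
                alpha=alpha,
                lib_sizes=lib_sizes,
            ).set_index("gene_id")
            direction = pd.Series("ns", index=out.index)
            sig = table["p_value"] < alpha
            direction[sig & (table["mean_b"] > table["mean_a"])] = "up"
            direction[sig & (table["mean_b"] < table["mean_a"])] = "down"
            out[f"dir_{b}_vs_{a}"] = direction
    return out
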