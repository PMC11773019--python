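"""Secondary-assay statistics: fold changes and per-miRNA two-way ANOVA.

The validation assay measures dead fractions by dye exclusion under
matched light and dark conditions, for a candidate miRNA mimic and a
non-targeting negative mimic.  Two quantities are reported:

* the light/dark fold change per biological replicate — a sample's dead
  fraction under light divided by its matched dark dead fraction, which
  normalises away transfection toxicity; and
* a classical two-factor fixed-effects ANOVA per miRNA.  The default
  design crosses treatment (mimic vs negative mimic) with illumination
  (light vs dark) on dead fractions; the treatment x illumination
  interaction is the protection term.  An alternative design (treatment
  x biological replicate on fold changes) is selectable.

The ANOVA sums of squares are computed explicitly from cell means (the
textbook balanced decomposition) rather than through a formula
interface, so every term is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

DESIGN_TREATMENT_X_LIGHT = "treatment_x_light"
DESIGN_TREATMENT_X_REPLICATE = "treatment_x_replicate"

DIRECTION_PROTECTIVE = "protective"
DIRECTION_NEUTRAL = "neutral"
DIRECTION_DELETERIOUS = "deleterious"


@dataclass(frozen=True)
class AnovaTable:
    """Balanced two-factor fixed-effects decomposition."""

    factor_a: str
    factor_b: str
    ss: dict[str, float]
    df: dict[str, int]
    f: dict[str, float]
    p: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SecondaryResult:
    """Outcome of the validation assay for one miRNA."""

    mirna_id: str
    fc_mimic: list[float]
    fc_negative: list[float]
    fc_mimic_mean: float
    fc_negative_mean: float
    effect_direction: str
    test_stat: dict[str, float]
    p_values: dict[str, float]
    significant: bool
    alpha: float
    design: str
    anova: AnovaTable | None = field(default=None, repr=False)


def dead_fractions(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-well dead fraction = dead / (live + dead)."""
    frame = counts.copy()
    total = frame["live"] + frame["dead"]
    if (total <= 0).any():
        raise ValueError("wells with zero counted cells")
    frame["dead_fraction"] = frame["dead"] / total
    return frame


def fold_change(counts: pd.DataFrame) -> pd.DataFrame:
    """Light/dark fold change per (miRNA, treatment, biological replicate).

    Technical duplicates within a condition are averaged before the
    ratio.  Replicates whose dark dead fraction is zero are flagged
    undefined and excluded with a warning.
    """
    frame = dead_fractions(counts)
    keys = ["mirna_id", "treatment", "replicate", "condition"]
    means = (frame.groupby(keys, sort=True)["dead_fraction"]
             .mean().unstack("condition"))
    for cond in ("light", "dark"):
        if cond not in means.columns:
            raise ValueError(f"missing {cond!r} condition rows")
    if means[["light", "dark"]].isna().any().any():
        raise ValueError("every light well needs a matched dark well "
                         "(same treatment, same replicate)")
    out = means.reset_index()
    zero_dark = out["dark"] == 0
    if zero_dark.any():
        bad = out.loc[zero_dark, ["mirna_id", "treatment", "replicate"]]
        warnings.warn(f"excluding {len(bad)} replicate(s) with zero dark "
                      f"dead fraction: {bad.to_dict('records')}", stacklevel=2)
        out = out[~zero_dark]
    out = out.rename(columns={"light": "light_fraction",
                              "dark": "dark_fraction"})
    out["fold_change"] = out["light_fraction"] / out["dark_fraction"]
    return out.reset_index(drop=True)


def two_way_anova(values: np.ndarray, a_labels: np.ndarray,
                  b_labels: np.ndarray, *, factor_a: str = "A",
                  factor_b: str = "B") -> AnovaTable:
    """Classical balanced two-factor ANOVA with interaction.

    Sums of squares are computed directly from marginal and cell means
    (type I = type II = type III in the balanced case).  Requires a
    balanced design with at least two observations per cell, so the
    error term has degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(a_labels)
    b = np.asarray(b_labels)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factor labels disagree in length")

    a_levels = np.unique(a)
    b_levels = np.unique(b)
    I, J = len(a_levels), len(b_levels)
    if I < 2 or J < 2:
        raise ValueError("both factors need at least two levels")

    cell_n = {(ai, bj): int(np.sum((a == ai) & (b == bj)))
              for ai in a_levels for bj in b_levels}
    ns = set(cell_n.values())
    if len(ns) != 1:
        raise ValueError(f"unbalanced design: cell sizes {sorted(ns)}")
    n = ns.pop()
    if n < 2:
        raise ValueError("need >= 2 observations per design cell "
                         "(no error degrees of freedom otherwise)")

    grand = y.mean()
    mean_a = {ai: y[a == ai].mean() for ai in a_levels}
    mean_b = {bj: y[b == bj].mean() for bj in b_levels}
    mean_ab = {(ai, bj): y[(a == ai) & (b == bj)].mean()
               for ai in a_levels for bj in b_levels}

    ss_a = n * J * sum((mean_a[ai] - grand) ** 2 for ai in a_levels)
    ss_b = n * I * sum((mean_b[bj] - grand) ** 2 for bj in b_levels)
    ss_ab = n * sum((mean_ab[(ai, bj)] - mean_a[ai] - mean_b[bj] + grand) ** 2
                    for ai in a_levels for bj in b_levels)
    ss_e = 0.0
    for ai in a_levels:
        for bj in b_levels:
            resid = y[(a == ai) & (b == bj)] - mean_ab[(ai, bj)]
            ss_e += float(np.sum(resid ** 2))

    df_a, df_b = I - 1, J - 1
    df_ab = df_a * df_b
    df_e = I * J * (n - 1)

    ms_e = ss_e / df_e
    terms = {factor_a: (ss_a, df_a), factor_b: (ss_b, df_b),
             "interaction": (ss_ab, df_ab)}
    f_stats, p_vals, ss_out, df_out = {}, {}, {}, {}
    for name, (ss, df) in terms.items():
        ss_out[name] = float(ss)
        df_out[name] = int(df)
        if ms_e == 0.0:
            f_stats[name] = 0.0 if ss == 0.0 else float("inf")
        else:
            f_stats[name] = float((ss / df) / ms_e)
        p_vals[name] = float(stats.f.sf(f_stats[name], df, df_e)) \
            if np.isfinite(f_stats[name]) else 0.0
    ss_out["error"] = float(ss_e)
    df_out["error"] = int(df_e)
    return AnovaTable(factor_a=factor_a, factor_b=factor_b, ss=ss_out,
                      df=df_out, f=f_stats, p=p_vals)


def two_way_test(counts: pd.DataFrame, *,
                 design: str = DESIGN_TREATMENT_X_LIGHT,
                 alpha: float = 0.05,
                 decision_term: str = "interaction",
                 transform: str | None = None,
                 sidak_m: int | None = None) -> SecondaryResult:
    """Run the two-factor test for one miRNA against its negative mimic.

    ``counts`` holds live/dead counts for a single miRNA (columns
    mirna_id, condition, treatment, replicate, live, dead; an optional
    duplicate column).  ``decision_term`` selects which term's p-value
    drives ``significant`` — the treatment x illumination interaction by
    default, since a mimic that changes light-induced death specifically
    shows up there.  ``transform='arcsine'`` applies the
    arcsine-square-root variance stabilisation to dead fractions.
    ``sidak_m`` optionally Sidak-adjusts alpha for m parallel tests.
    """
    mirnas = [m for m in counts["mirna_id"].unique()]
    if len(mirnas) != 1:
        raise ValueError(f"two_way_test expects one miRNA, got {mirnas}")
    mirna_id = str(mirnas[0])
    treatments = set(counts["treatment"].unique())
    if treatments != {"mimic", "negative_mimic"}:
        raise ValueError(f"expected mimic and negative_mimic rows, got "
                         f"{sorted(treatments)}")

    fc = fold_change(counts)
    fc_mimic = fc.loc[fc["treatment"] == "mimic", "fold_change"].tolist()
    fc_negative = fc.loc[fc["treatment"] == "negative_mimic",
                         "fold_change"].tolist()

    frame = dead_fractions(counts)
    if design == DESIGN_TREATMENT_X_LIGHT:
        y = frame["dead_fraction"].to_numpy(float)
        if transform == "arcsine":
            y = np.arcsin(np.sqrt(np.clip(y, 0.0, 1.0)))
        elif transform is not None:
            raise ValueError(f"unknown transform {transform!r}")
        table = two_way_anova(y, frame["treatment"].to_numpy(),
                              frame["condition"].to_numpy(),
                              factor_a="treatment", factor_b="condition")
    elif design == DESIGN_TREATMENT_X_REPLICATE:
        # Fold changes per technical duplicate keep >= 2 obs per cell.
        dup_col = "duplicate" if "duplicate" in counts.columns else None
        if dup_col is None:
            raise ValueError("treatment_x_replicate design needs a "
                             "'duplicate' column")
        keys = ["mirna_id", "treatment", "replicate", dup_col, "condition"]
        means = (frame.groupby(keys, sort=True)["dead_fraction"]
                 .mean().unstack("condition").reset_index())
        if (means["dark"] == 0).any():
            raise ValueError("zero dark dead fraction in fold-change design")
        means["fold_change"] = means["light"] / means["dark"]
        table = two_way_anova(means["fold_change"].to_numpy(float),
                              means["treatment"].to_numpy(),
                              means["replicate"].to_numpy(),
                              factor_a="treatment", factor_b="replicate")
    else:
        raise ValueError(f"unknown design {design!r}")

    if decision_term not in table.p:
        raise ValueError(f"decision term {decision_term!r} not in "
                         f"{sorted(table.p)}")
    alpha_eff = alpha if sidak_m is None else 1.0 - (1.0 - alpha) ** (1.0 / sidak_m)
    significant = bool(table.p[decision_term] <= alpha_eff)

    fc_m = float(np.mean(fc_mimic)) if fc_mimic else float("nan")
    fc_n = float(np.mean(fc_negative)) if fc_negative else float("nan")
    if significant and fc_m < fc_n:
        direction = DIRECTION_PROTECTIVE
    elif significant and fc_m > fc_n:
        direction = DIRECTION_DELETERIOUS
    else:
        direction = DIRECTION_NEUTRAL

    return SecondaryResult(
        mirna_id=mirna_id,
        fc_mimic=fc_mimic, fc_negative=fc_negative,
        fc_mimic_mean=fc_m, fc_negative_mean=fc_n,
        effect_direction=direction,
        test_stat=dict(table.f), p_values=dict(table.p),
        significant=significant, alpha=float(alpha_eff),
        design=design, anova=table,
    )


def results_to_frame(results: list[SecondaryResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "mirna_id": r.mirna_id,
            "fc_mimic_mean": r.fc_mimic_mean,
            "fc_negative_mean": r.fc_negative_mean,
            "effect_direction": r.effect_direction,
            "f_treatment": r.test_stat.get("treatment", np.nan),
            "f_interaction": r.test_stat.get("interaction", np.nan),
            "p_treatment": r.p_values.get("treatment", np.nan),
            "p_interaction": r.p_values.get("interaction", np.nan),
            "significant": r.significant,
            "design": r.design,
        })
    return pd.DataFrame(rows)
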