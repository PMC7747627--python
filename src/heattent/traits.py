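"""Agronomic and grain-quality response pipeline.

Trait derivation (harvest index, grain-filling duration), treatment
summaries with percent-difference and per-degree-Celsius statistics, the
non-infected-seed extrapolation, emergence metrics, split-plot ANOVA with
Tukey HSD letter grouping, the check-line spatial-uniformity test and a
synthetic replicate-level trait generator.

Reported percentages round half away from zero to 2 decimals; overall
percent differences are computed from the means of the per-genotype
treatment means (mean-of-means), with the mean of per-genotype percent
differences available as a secondary statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GENOTYPES",
    "CHECK_GENOTYPE",
    "TREATMENT_CONTROL",
    "TREATMENT_HNT",
    "DEFAULT_DELTA_T_C",
    "SeedSample",
    "EmergenceRecord",
    "AnovaResult",
    "TraitEffect",
    "DEFAULT_TRAIT_EFFECTS",
    "round_half_up",
    "pct_difference",
    "per_degC",
    "protein_from_nitrogen",
    "extrapolate_noninfected",
    "harvest_index",
    "grain_filling_duration",
    "emergence_metrics",
    "splitplot_anova",
    "checkline_uniformity",
    "generate_trait_data",
    "summarize_treatments",
    "recover_treatment_effect",
]

TREATMENT_CONTROL = "control"
TREATMENT_HNT = "HNT"

#: The 12 winter wheat genotypes of the packaged fixture.
GENOTYPES = (
    "Everest",
    "Jagger X060724",
    "KS 070736K-1",
    "KS 070729K-26",
    "KS 070717M-1",
    "Larry",
    "P1 X060725",
    "SY-Monument",
    "Tascosa",
    "Tx86A5606",
    "WB-4458",
    "WB-Cedar",
)
CHECK_GENOTYPE = "Everest"

#: Season-mean night differential used to normalize reductions to %/degC.
DEFAULT_DELTA_T_C = 3.8

OBS_COLUMNS = ["genotype", "treatment", "tent", "block", "trait", "value"]


# ---------------------------------------------------------------------------
# elementary statistics


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (matches the printed table formatting)."""
    factor = 10.0**ndigits
    return float(np.floor(abs(x) * factor + 0.5) / factor * (1.0 if x >= 0 else -1.0))


def pct_difference(mean_control: float, mean_hnt: float) -> float:
    """Percent difference of the HNT mean relative to the control mean, 2 dp."""
    if mean_control == 0:
        raise ValueError("mean_control must be nonzero")
    return round_half_up(100.0 * (mean_hnt - mean_control) / mean_control)


def per_degC(pct_reduction: float, delta_T_C: float = DEFAULT_DELTA_T_C) -> float:
    """Percent change per degree Celsius of night warming, 2 dp."""
    if delta_T_C <= 0:
        raise ValueError("delta_T_C must be > 0")
    return round_half_up(pct_reduction / delta_T_C)


def protein_from_nitrogen(n_pct: float) -> float:
    """Grain protein concentration from nitrogen concentration (factor 5.7)."""
    if n_pct < 0:
        raise ValueError("n_pct must be >= 0")
    return 5.7 * n_pct


@dataclass(frozen=True)
class SeedSample:
    """Counts and weights of a harvested sample split by Fusarium infection."""

    n_infected: int
    n_noninfected: int
    wt_infected_g: float
    wt_noninfected_g: float

    def __post_init__(self) -> None:
        if self.n_infected < 0 or self.n_noninfected < 0:
            raise ValueError("counts must be >= 0")
        if self.wt_infected_g < 0 or self.wt_noninfected_g < 0:
            raise ValueError("weights must be >= 0")


def extrapolate_noninfected(sample: SeedSample, total_count: Optional[int] = None) -> float:
    """Whole-sample weight extrapolated from the non-infected single-seed weight.

    average single (non-infected) seed weight x total seed count.
    """
    if sample.n_noninfected == 0:
        raise ValueError("extrapolation undefined with no non-infected seeds")
    if total_count is None:
        total_count = sample.n_infected + sample.n_noninfected
    return sample.wt_noninfected_g / sample.n_noninfected * total_count


def harvest_index(grain_yield: float, total_biomass: float) -> float:
    """Grain yield over total aboveground biomass (grain included)."""
    if total_biomass <= 0:
        raise ValueError("total_biomass must be > 0")
    return grain_yield / total_biomass


def grain_filling_duration(anthesis: date, maturity: date) -> int:
    """Days from 50% anthesis to physiological maturity."""
    d = (maturity - anthesis).days
    if d < 0:
        raise ValueError("maturity precedes anthesis")
    return d


@dataclass(frozen=True)
class EmergenceRecord:
    """Daily newly-emerged seedling counts for one genotype x treatment."""

    genotype: str
    treatment: str
    daily_counts: Tuple[int, ...]
    n_planted: int = 24

    def __post_init__(self) -> None:
        if self.n_planted <= 0:
            raise ValueError("n_planted must be > 0")
        if any(c < 0 for c in self.daily_counts):
            raise ValueError("daily counts must be >= 0")
        if sum(self.daily_counts) > self.n_planted:
            raise ValueError("cumulative emergence exceeds n_planted")


def emergence_metrics(rec: EmergenceRecord) -> Tuple[float, float]:
    """(total emergence %, emergence index).

    The index uses the speed-of-emergence form: sum over days of (newly
    emerged on day d) / d, with day 1 the first day after planting.
    """
    total = sum(rec.daily_counts)
    pct = 100.0 * total / rec.n_planted
    index = sum(c / (d + 1) for d, c in enumerate(rec.daily_counts))
    return pct, index


# ---------------------------------------------------------------------------
# split-plot ANOVA


@dataclass
class AnovaResult:
    trait: str
    p_T: float
    p_G: float
    p_TxG: float
    anova_table: pd.DataFrame
    treatment_means: pd.DataFrame
    genotype_means: pd.DataFrame
    alpha: float = 0.05


@lru_cache(maxsize=None)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))


def _compact_letters(means: pd.Series, hsd: float) -> pd.Series:
    """Compact letter display for a constant Tukey HSD threshold.

    With a single threshold, non-significance is an interval relation on the
    sorted means, so letters are the maximal sorted runs whose spread stays
    below the HSD.  Ties in means are broken alphabetically by level name.
    """
    order = means.sort_values(ascending=False, kind="mergesort")
    order = order.iloc[np.lexsort((order.index.astype(str), -order.to_numpy()))]
    n = len(order)
    groups: List[Tuple[int, int]] = []
    start = 0
    while start < n:
        end = start
        while end + 1 < n and order.iloc[start] - order.iloc[end + 1] <= hsd:
            end += 1
        if not groups or end > groups[-1][1]:
            groups.append((start, end))
        start += 1
    letters = {lvl: "" for lvl in order.index}
    for gi, (lo, hi) in enumerate(groups):
        ch = chr(ord("a") + gi)
        for lvl in order.index[lo : hi + 1]:
            letters[lvl] += ch
    return pd.Series(letters).reindex(means.index)


def _aggregate_cells(obs: pd.DataFrame, trait: str) -> pd.DataFrame:
    df = obs[obs["trait"] == trait]
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    return (
        df.groupby(["treatment", "tent", "genotype"], as_index=False)["value"].mean()
    )


def splitplot_anova(obs: pd.DataFrame, trait: str, alpha: float = 0.05) -> AnovaResult:
    """Split-plot ANOVA: temperature is the main-plot factor (whole plot =
    tent nested in treatment), genotype the sub-plot factor.

    Temperature is tested against the tent-within-treatment stratum; genotype
    and the interaction against the residual.  Duplicate rows per
    (treatment, tent, genotype) — e.g. the replicated check line — are
    averaged before analysis.  Requires a balanced layout with at least two
    tents per treatment.
    """
    cells = _aggregate_cells(obs, trait)
    treatments = sorted(cells["treatment"].unique())
    tents = sorted(cells["tent"].unique())
    genotypes = sorted(cells["genotype"].unique())
    a, t, g = len(treatments), len(tents), len(genotypes)
    if a < 2:
        raise ValueError("need both treatments")
    if t < 2:
        raise ValueError("main-plot test undefined with a single tent per treatment")
    wide = cells.pivot_table(index=["treatment", "tent"], columns="genotype", values="value")
    if wide.isna().any().any() or wide.shape != (a * t, g):
        raise ValueError("unbalanced layout: every treatment x tent x genotype cell is required")
    y = wide.to_numpy(float).reshape(a, t, g)

    N = a * t * g
    grand = y.sum()
    C = grand**2 / N
    ss_total = float((y**2).sum() - C)
    ss_T = float((y.sum(axis=(1, 2)) ** 2).sum() / (t * g) - C)
    ss_wp = float((y.sum(axis=2) ** 2).sum() / g - C)
    ss_Ea = ss_wp - ss_T
    ss_G = float((y.sum(axis=(0, 1)) ** 2).sum() / (a * t) - C)
    ss_TG = float((y.sum(axis=1) ** 2).sum() / t - C - ss_T - ss_G)
    ss_Eb = ss_total - ss_wp - ss_G - ss_TG

    df_T, df_Ea = a - 1, a * (t - 1)
    df_G, df_TG = g - 1, (a - 1) * (g - 1)
    df_Eb = a * (t - 1) * (g - 1)
    ms = {
        "T": ss_T / df_T,
        "Ea": ss_Ea / df_Ea,
        "G": ss_G / df_G,
        "TxG": ss_TG / df_TG,
        "Eb": ss_Eb / df_Eb,
    }
    eps = np.finfo(float).tiny
    F_T = ms["T"] / max(ms["Ea"], eps)
    F_G = ms["G"] / max(ms["Eb"], eps)
    F_TG = ms["TxG"] / max(ms["Eb"], eps)
    p_T = float(stats.f.sf(F_T, df_T, df_Ea))
    p_G = float(stats.f.sf(F_G, df_G, df_Eb))
    p_TG = float(stats.f.sf(F_TG, df_TG, df_Eb))

    table = pd.DataFrame(
        {
            "source": ["temperature", "tent(T)", "genotype", "TxG", "residual"],
            "df": [df_T, df_Ea, df_G, df_TG, df_Eb],
            "ss": [ss_T, ss_Ea, ss_G, ss_TG, ss_Eb],
            "ms": [ms["T"], ms["Ea"], ms["G"], ms["TxG"], ms["Eb"]],
            "F": [F_T, np.nan, F_G, F_TG, np.nan],
            "p": [p_T, np.nan, p_G, p_TG, np.nan],
        }
    )

    tr_means = pd.Series(y.mean(axis=(1, 2)), index=treatments)
    hsd_T = _q_crit(alpha, a, df_Ea) * np.sqrt(max(ms["Ea"], eps) / (t * g))
    tr_letters = _compact_letters(tr_means, hsd_T)
    treatment_means = pd.DataFrame(
        {"treatment": treatments, "mean": tr_means.to_numpy(), "letter": tr_letters.to_numpy()}
    )

    g_means = pd.Series(y.mean(axis=(0, 1)), index=genotypes)
    hsd_G = _q_crit(alpha, g, df_Eb) * np.sqrt(max(ms["Eb"], eps) / (a * t))
    g_letters = _compact_letters(g_means, hsd_G)
    genotype_means = pd.DataFrame(
        {"genotype": genotypes, "mean": g_means.to_numpy(), "letter": g_letters.to_numpy()}
    )

    return AnovaResult(
        trait=trait,
        p_T=p_T,
        p_G=p_G,
        p_TxG=p_TG,
        anova_table=table,
        treatment_means=treatment_means,
        genotype_means=genotype_means,
        alpha=alpha,
    )


def checkline_uniformity(
    obs: pd.DataFrame,
    check_genotype: str = CHECK_GENOTYPE,
    traits: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-tent positional uniformity test on the replicated check line.

    Within each tent the check rows are grouped by block position (blocks
    1-4 vs 5-8) and a one-way ANOVA is run per trait.  Tents with missing
    blocks are skipped with a warning.  Returns a frame with one row per
    (treatment, tent, trait) and a uniformity verdict at ``alpha``.
    """
    df = obs[obs["genotype"] == check_genotype]
    if df.empty:
        raise ValueError(f"no observations for check genotype {check_genotype!r}")
    if traits is None:
        traits = sorted(df["trait"].unique())
    rows = []
    for (treatment, tent), sub in df.groupby(["treatment", "tent"]):
        for trait in traits:
            tr = sub[sub["trait"] == trait]
            if set(tr["block"]) != set(range(1, 9)):
                warnings.warn(
                    f"tent {treatment}/{tent} trait {trait!r}: missing blocks, skipped",
                    stacklevel=2,
                )
                continue
            lo = tr[tr["block"] <= 4]["value"].to_numpy(float)
            hi = tr[tr["block"] >= 5]["value"].to_numpy(float)
            ss_between = len(lo) * (lo.mean() - tr["value"].mean()) ** 2 + len(hi) * (
                hi.mean() - tr["value"].mean()
            ) ** 2
            ss_within = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
            if ss_between <= 1e-12 * max(ss_within, 1.0):
                p = 1.0
            elif ss_within == 0:
                p = 0.0
            else:
                _, p = stats.f_oneway(lo, hi)
            rows.append(
                {
                    "treatment": treatment,
                    "tent": tent,
                    "trait": trait,
                    "p_value": float(p),
                    "uniform": bool(p >= alpha),
                }
            )
    return pd.DataFrame(rows, columns=["treatment", "tent", "trait", "p_value", "uniform"])


# ---------------------------------------------------------------------------
# synthetic replicate-level generator


@dataclass(frozen=True)
class TraitEffect:
    """Generator settings for one trait.

    ``effect_pct`` is the multiplicative HNT treatment effect on the
    genotype mean; the three SDs are the genotype spread, the between-tent
    (whole plot) SD and the residual SD, all in trait units.
    """

    trait: str
    control_mean: float
    effect_pct: float
    genotype_sd: float
    tent_sd: float
    resid_sd: float

    def __post_init__(self) -> None:
        if min(self.genotype_sd, self.tent_sd, self.resid_sd) < 0:
            raise ValueError("SDs must be >= 0")


#: Defaults calibrated to the packaged main-effect means.
DEFAULT_TRAIT_EFFECTS: Dict[str, TraitEffect] = {
    e.trait: e
    for e in [
        TraitEffect("grain_filling_duration_d", 42.0, -7.38, 2.0, 0.6, 1.5),
        TraitEffect("kernel_weight_200_g", 5.7, -7.02, 0.45, 0.08, 0.3),
        TraitEffect("grain_yield_g_m2", 512.8, -17.14, 45.0, 12.0, 40.0),
        TraitEffect("seed_number_m2", 18112.6, -12.33, 1500.0, 400.0, 1300.0),
        TraitEffect("biomass_g_m2", 607.7, -6.20, 55.0, 18.0, 50.0),
        TraitEffect("harvest_index", 0.38, -7.89, 0.025, 0.007, 0.02),
        TraitEffect("starch_pct", 59.0, -15.25, 7.5, 1.2, 3.5),
        TraitEffect("protein_pct", 14.1, 2.84, 0.9, 0.2, 0.5),
    ]
}


def generate_trait_data(
    effects: Optional[Mapping[str, TraitEffect]] = None,
    seed: int = 0,
    genotypes: Sequence[str] = GENOTYPES,
    n_tents: int = 3,
    n_blocks: int = 8,
    check_genotype: Optional[str] = CHECK_GENOTYPE,
) -> pd.DataFrame:
    """Replicate-level synthetic trait observations.

    12 genotypes x 2 treatments x ``n_tents`` tents, one row per genotype per
    tent, plus — when ``check_genotype`` is one of the genotypes — one check
    row in each of the ``n_blocks`` blocks of every tent.  Deterministic
    under ``seed``.  Genotype and tent effects are additive Gaussians; the
    treatment effect is multiplicative on the genotype mean.
    """
    if effects is None:
        effects = DEFAULT_TRAIT_EFFECTS
    rng = np.random.default_rng(seed)
    treatments = (TREATMENT_CONTROL, TREATMENT_HNT)
    rows = []
    for trait, eff in effects.items():
        g_eff = {g: rng.normal(0.0, eff.genotype_sd) if eff.genotype_sd > 0 else 0.0 for g in genotypes}
        tent_eff = {
            (tr, tent): rng.normal(0.0, eff.tent_sd) if eff.tent_sd > 0 else 0.0
            for tr in treatments
            for tent in range(1, n_tents + 1)
        }
        for tr in treatments:
            mult = 1.0 + (eff.effect_pct / 100.0 if tr == TREATMENT_HNT else 0.0)
            for tent in range(1, n_tents + 1):
                for gi, g in enumerate(genotypes):
                    mean = (eff.control_mean + g_eff[g]) * mult + tent_eff[(tr, tent)]
                    if g == check_genotype:
                        blocks = range(1, n_blocks + 1)
                    else:
                        blocks = [gi % n_blocks + 1]
                    for b in blocks:
                        noise = rng.normal(0.0, eff.resid_sd) if eff.resid_sd > 0 else 0.0
                        rows.append(
                            {
                                "genotype": g,
                                "treatment": tr,
                                "tent": tent,
                                "block": b,
                                "trait": trait,
                                "value": mean + noise,
                            }
                        )
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


# ---------------------------------------------------------------------------
# treatment summaries


def summarize_treatments(
    obs: pd.DataFrame,
    traits: Optional[Sequence[str]] = None,
    delta_T_C: Optional[float] = None,
) -> pd.DataFrame:
    """Per-genotype and overall treatment summary for each trait.

    The overall row uses the mean of per-genotype treatment means; a
    secondary ``mean of per-genotype % differences`` statistic is included
    in the overall row as ``pct_diff_mean_of_rows``.  ``per_degC`` columns
    are emitted only when ``delta_T_C`` is given (never inferred silently).
    """
    if traits is None:
        traits = sorted(obs["trait"].unique())
    out = []
    for trait in traits:
        cells = obs[obs["trait"] == trait].groupby(["genotype", "treatment"])["value"].mean().unstack()
        if TREATMENT_CONTROL not in cells or TREATMENT_HNT not in cells:
            raise ValueError(f"trait {trait!r} lacks one of the treatments")
        pcts = []
        for g, row in cells.iterrows():
            pd_ = pct_difference(row[TREATMENT_CONTROL], row[TREATMENT_HNT])
            pcts.append(pd_)
            rec = {
                "trait": trait,
                "genotype": g,
                "mean_control": row[TREATMENT_CONTROL],
                "mean_hnt": row[TREATMENT_HNT],
                "pct_diff": pd_,
            }
            if delta_T_C is not None:
                rec["per_degC"] = per_degC(abs(pd_), delta_T_C)
            out.append(rec)
        mc, mh = cells[TREATMENT_CONTROL].mean(), cells[TREATMENT_HNT].mean()
        overall = {
            "trait": trait,
            "genotype": "Overall average",
            "mean_control": mc,
            "mean_hnt": mh,
            "pct_diff": pct_difference(mc, mh),
            "pct_diff_mean_of_rows": round_half_up(float(np.mean(pcts))),
        }
        if delta_T_C is not None:
            overall["per_degC"] = per_degC(abs(overall["pct_diff"]), delta_T_C)
        out.append(overall)
    return pd.DataFrame(out)


def recover_treatment_effect(obs: pd.DataFrame, trait: str) -> Tuple[float, float]:
    """Estimate the multiplicative treatment effect (%) and its standard error.

    The estimate is the HNT-vs-control percent difference of the grand
    means; the SE comes from the between-tent variation of tent-level means
    (the whole-plot stratum), propagated through the ratio.
    """
    df = obs[obs["trait"] == trait]
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    tent_means = df.groupby(["treatment", "tent"])["value"].mean()
    mc = tent_means[TREATMENT_CONTROL]
    mh = tent_means[TREATMENT_HNT]
    C, H = mc.mean(), mh.mean()
    var_C = mc.var(ddof=1) / len(mc)
    var_H = mh.var(ddof=1) / len(mh)
    est = 100.0 * (H - C) / C
    se = 100.0 * np.sqrt(var_H / C**2 + (H**2 / C**4) * var_C)
    return float(est), float(se)
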