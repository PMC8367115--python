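"""Repeated-measures analysis of colour differences across conditions.

Each of the 19 medications is the within-subjects unit, observed in all
12 background × flash × EV cells. The module provides:

* per-condition ΔE summaries (mean, sample SD over medications),
* a three-way repeated-measures ANOVA (background × flash × EV, all
  within-subject, uncorrected F tests; Greenhouse–Geisser optional),
* one-way RM-ANOVA over EV within each background × flash stratum,
  followed by Bonferroni-adjusted paired t tests over the three EV
  pairs (adjusted p = min(1, 3·raw p)),
* the Spearman association between per-condition mean ΔE and top-k
  recognition accuracy, flagging conditions that break the expected
  "larger colour shift → lower accuracy" ordering,
* seeded Monte-Carlo helpers for type-I-error and power calibration of
  the three-way design.

Significance is declared at α = .05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.anova import AnovaRM

from .catalog import parse_condition_name
from .color import DeltaERecord
from .recognize import TopKResult

ALPHA = 0.05
EV_LEVELS = (-2.0, 0.0, 2.0)
WITHIN_FACTORS = ("background", "flash", "ev")


class DesignError(ValueError):
    """The within-subject crossing is incomplete or degenerate."""


@dataclass(frozen=True)
class AnovaResult:
    """One F test: effect name, F, (df1, df2), p."""

    effect: str
    F: float
    df1: float
    df2: float
    p_value: float

    def __post_init__(self) -> None:
        if self.F < -1e-12:
            raise ValueError("F must be nonnegative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class PairwiseComparison:
    """Bonferroni-adjusted paired comparison of two EV levels in a stratum."""

    stratum: tuple[str, str]       # (background, flash)
    pair: tuple[float, float]      # EV levels compared
    raw_p: float
    adjusted_p: float


def delta_e_table(records: Iterable[DeltaERecord]) -> pd.DataFrame:
    """Long-format ΔE table with parsed condition factors.

    Columns: medication, condition, background, flash, ev, delta_e —
    one row per (medication, condition) cell.
    """
    rows = []
    for rec in records:
        background, flash, ev = parse_condition_name(rec.condition_name)
        rows.append({"medication": rec.pill_label, "condition": rec.condition_name,
                     "background": background, "flash": flash, "ev": ev,
                     "delta_e": rec.delta_e})
    return pd.DataFrame(rows)


def summarize_delta_e(records: Iterable[DeltaERecord]) -> pd.DataFrame:
    """Per-condition mean and sample SD (n−1) of ΔE over medications.

    A single-record condition reports SD 0.0 by convention. Raises on an
    empty record set.
    """
    df = delta_e_table(records)
    if df.empty:
        raise ValueError("no ΔE records to summarize")
    out = (df.groupby("condition", sort=True)["delta_e"]
             .agg(n="size", mean_delta_e="mean", sd_delta_e=lambda s: s.std(ddof=1))
             .reset_index())
    out["sd_delta_e"] = out["sd_delta_e"].fillna(0.0)
    return out


def _check_crossing(table: pd.DataFrame, factors: Sequence[str]) -> None:
    counts = table.groupby(["medication", *factors], observed=True).size()
    levels = [sorted(table[f].unique()) for f in factors]
    subjects = sorted(table["medication"].unique())
    expected = len(subjects) * int(np.prod([len(lv) for lv in levels]))
    if counts.max() > 1:
        dup = counts.idxmax()
        raise DesignError(f"cell {dup} observed more than once; aggregate first")
    if len(counts) != expected:
        seen = set(counts.index)
        for s in subjects:
            for combo in _product(levels):
                key = (s, *combo)
                if key not in seen:
                    raise DesignError(f"missing cell: subject {s}, "
                                      f"{dict(zip(factors, combo))}")


def _product(levels: Sequence[Sequence]) -> Iterable[tuple]:
    if not levels:
        yield ()
        return
    for head in levels[0]:
        for tail in _product(levels[1:]):
            yield (head, *tail)


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from a subjects × cells matrix."""
    k = wide.shape[1]
    S = np.cov(wide, rowvar=False)
    mean_diag = np.trace(S) / k
    grand = S.mean()
    row_means = S.mean(axis=0)
    num = (k * (mean_diag - grand)) ** 2
    den = (k - 1) * (np.sum(S * S) - 2 * k * np.sum(row_means ** 2)
                     + k * k * grand ** 2)
    return float(num / den) if den > 0 else 1.0


def three_way_rm_anova(table: pd.DataFrame,
                       gg_correction: bool = False) -> list[AnovaResult]:
    """Within-subjects F tests for background, flash, EV and interactions.

    Requires the complete 2×2×3 crossing per medication; raises
    DesignError naming the first missing cell otherwise. Uncorrected
    univariate F by default; gg_correction applies Greenhouse–Geisser
    epsilon to the degrees of freedom of each effect.
    """
    _check_crossing(table, WITHIN_FACTORS)
    wide = table.pivot_table(index="medication", columns=list(WITHIN_FACTORS),
                             values="delta_e", observed=True).to_numpy()
    if np.ptp(wide, axis=1).max() < 1e-12:
        # response constant across cells within every subject: no
        # condition variance to test, the 0/0 F is reported as null
        n1 = wide.shape[0] - 1
        out = []
        for effect, df1 in (("background", 1), ("flash", 1), ("ev", 2),
                            ("background:flash", 1), ("background:ev", 2),
                            ("flash:ev", 2), ("background:flash:ev", 2)):
            out.append(AnovaResult(effect=effect, F=0.0, df1=float(df1),
                                   df2=float(n1 * df1), p_value=1.0))
        return out
    fit = AnovaRM(data=table, depvar="delta_e", subject="medication",
                  within=list(WITHIN_FACTORS)).fit()
    results = []
    for effect, row in fit.anova_table.iterrows():
        F, df1, df2 = float(row["F Value"]), float(row["Num DF"]), float(row["Den DF"])
        if gg_correction:
            factors = effect.split(":")
            cols = table.pivot_table(index="medication", columns=factors,
                                     values="delta_e", observed=True)
            eps = _gg_epsilon(cols.to_numpy()) if df1 > 1 else 1.0
            df1, df2 = df1 * eps, df2 * eps
        p = float(sps.f.sf(F, df1, df2))
        # zero between- and within-cell variance leaves F numerically
        # undefined (0/0); report the null outcome
        if not np.isfinite(F) or F < 0:
            F, p = 0.0, 1.0
        results.append(AnovaResult(effect=effect, F=F, df1=df1, df2=df2, p_value=p))
    return results


def ev_stratified_anova(table: pd.DataFrame
                        ) -> tuple[list[AnovaResult], list[PairwiseComparison]]:
    """One-way RM-ANOVA over EV inside each background × flash stratum,
    then Bonferroni-adjusted paired t tests for the three EV pairs."""
    anovas, pairwise = [], []
    for background in ("black", "white"):
        for flash in ("on", "off"):
            sub = table[(table["background"] == background)
                        & (table["flash"] == flash)]
            if set(sub["ev"].unique()) != set(EV_LEVELS):
                raise DesignError(f"stratum ({background}, {flash}) must "
                                  f"contain all EV levels {EV_LEVELS}")
            _check_crossing(sub, ["ev"])
            fit = AnovaRM(data=sub, depvar="delta_e", subject="medication",
                          within=["ev"]).fit()
            row = fit.anova_table.iloc[0]
            F, p = float(row["F Value"]), float(row["Pr > F"])
            if not np.isfinite(F) or F < 0:
                F, p = 0.0, 1.0
            anovas.append(AnovaResult(
                effect=f"{background}/{flash}:ev", F=F,
                df1=float(row["Num DF"]), df2=float(row["Den DF"]), p_value=p))

            wide = sub.pivot(index="medication", columns="ev", values="delta_e")
            pairs = [(-2.0, 0.0), (0.0, 2.0), (-2.0, 2.0)]
            for lo, hi in pairs:
                t = sps.ttest_rel(wide[lo], wide[hi])
                raw = float(t.pvalue)
                pairwise.append(PairwiseComparison(
                    stratum=(background, flash), pair=(lo, hi),
                    raw_p=raw, adjusted_p=min(1.0, len(pairs) * raw)))
    return anovas, pairwise


def accuracy_vs_delta_e(accuracies: Sequence[TopKResult],
                        summary: pd.DataFrame) -> dict:
    """Spearman association between per-condition mean ΔE and accuracy.

    Returns {"spearman": {k: rho}, "n_conditions": ..., "violations":
    {k: [...]}} where a violation is a condition pair ordered against
    the expected inverse relation (larger ΔE but larger top-k accuracy,
    relative to a condition with smaller ΔE and smaller accuracy).
    Degenerate (constant) rankings report rho 0.0 with a flag.
    """
    de = dict(zip(summary["condition"], summary["mean_delta_e"]))
    by_k: dict[int, dict[str, float]] = {}
    for res in accuracies:
        by_k.setdefault(res.k, {})[res.condition_name] = res.accuracy
    report: dict = {"spearman": {}, "degenerate": {}, "violations": {}}
    for k, acc in sorted(by_k.items()):
        conds = sorted(acc)
        if set(conds) != set(de):
            raise ValueError("accuracy and ΔE tables cover different conditions")
        x = np.array([de[c] for c in conds])
        y = np.array([acc[c] for c in conds])
        degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
        rho = 0.0 if degenerate else float(sps.spearmanr(x, y).statistic)
        report["spearman"][k] = rho
        report["degenerate"][k] = bool(degenerate)
        viol = []
        for i, ci in enumerate(conds):
            for j, cj in enumerate(conds):
                if x[i] < x[j] and y[i] < y[j]:
                    viol.append((ci, cj))
        report["violations"][k] = viol
    report["n_conditions"] = len(de)
    return report


# ---------------------------------------------------------------------------
# Monte-Carlo calibration of the three-way design
# ---------------------------------------------------------------------------

def simulate_table(n_subjects: int = 19, noise_sd: float = 1.0,
                   subject_sd: float = 1.0, ev_effect_sd: float = 0.0,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """One synthetic ΔE table over the 2×2×3 design.

    Under the null (ev_effect_sd = 0) every cell is subject intercept +
    N(0, noise_sd). A nonzero ev_effect_sd injects a linear EV main
    effect whose across-level SD equals ev_effect_sd.
    """
    rng = rng or np.random.default_rng()
    subj = rng.normal(0, subject_sd, n_subjects)
    # linear contrast (-1, 0, 1) has across-level SD sqrt(2/3)
    ev_shift = {ev: np.sign(ev) * ev_effect_sd / np.sqrt(2.0 / 3.0)
                for ev in EV_LEVELS}
    rows = []
    for s in range(n_subjects):
        for background in ("black", "white"):
            for flash in ("on", "off"):
                for ev in EV_LEVELS:
                    rows.append({
                        "medication": s + 1, "background": background,
                        "flash": flash, "ev": ev,
                        "delta_e": subj[s] + ev_shift[ev]
                                   + rng.normal(0, noise_sd),
                    })
    return pd.DataFrame(rows)


def rejection_rates(n_reps: int, n_subjects: int = 19, noise_sd: float = 1.0,
                    subject_sd: float = 1.0, ev_effect_sd: float = 0.0,
                    alpha: float = ALPHA, seed: int = 0) -> dict[str, float]:
    """Per-effect rejection rate of the three-way RM-ANOVA over n_reps
    simulated tables: the type-I error rate under the null, power when
    an EV effect is injected."""
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for _ in range(n_reps):
        table = simulate_table(n_subjects, noise_sd, subject_sd,
                               ev_effect_sd, rng)
        for res in three_way_rm_anova(table):
            counts[res.effect] = counts.get(res.effect, 0) + (res.p_value < alpha)
    return {effect: c / n_reps for effect, c in counts.items()}
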