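"""Yeast growth quantification and genotype-phenotype comparison.

Growth in low-K+ liquid medium is quantified as OD600 fold changes over the
inoculation value.  Mutants are compared to the WT channel three ways:

* two-tailed unpaired Student's t-test on replicate fold changes (equal
  variance by default, Welch behind a flag), p < 0.05 significant;
* Pearson correlation between a channel feature (e.g. the time-averaged
  current |i_meas,-140 x P_O,-140|) and growth;
* a WT-anchored quadrant classification: a mutant is *concordant* when its
  channel feature and its growth land on the same side of the WT reference
  point, *discordant* otherwise; exact ties with WT are excluded.

A multilinear OD600 model (intercept + current + P_O + their product) gives
the R-squared of the best linear genotype-to-growth mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FoldChangeSummary",
    "ClassificationOutcome",
    "CorrelationReport",
    "MultilinearFit",
    "validate_growth_table",
    "fold_change",
    "fold_change_summary",
    "ttest_vs_wt",
    "pearson_r",
    "classify_vs_wt",
    "multilinear_r2",
    "activity_growth_correlation",
    "decorrelation_curve",
]

#: Feature selectors that are currents and therefore compared as |values|.
CURRENT_FEATURES = frozenset(
    {"activity_meas", "activity_true", "i_meas", "activity_p140"}
)


def validate_growth_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy growth table (genotype, replicate, time_h, od600)."""
    required = {"genotype", "replicate", "time_h", "od600"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"growth table misses columns: {sorted(missing)}")
    if np.any(table["od600"].to_numpy() <= 0):
        raise ValueError("od600 values must be positive")
    if np.any(table["time_h"].to_numpy() < 0):
        raise ValueError("time_h values must be >= 0")
    return table


def _replicate_folds(table: pd.DataFrame, genotype: str, time: float) -> np.ndarray:
    sub = table[table["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"genotype {genotype!r} not in growth table")
    folds = []
    for rep, grp in sub.groupby("replicate"):
        t0 = grp[np.isclose(grp["time_h"], 0.0)]
        if t0.empty:
            raise ValueError(
                f"genotype {genotype!r} replicate {rep!r} has no time-0 entry"
            )
        tt = grp[np.isclose(grp["time_h"], time)]
        if tt.empty:
            continue
        folds.append(float(tt["od600"].iloc[0]) / float(t0["od600"].iloc[0]))
    if not folds:
        raise ValueError(f"no replicate of {genotype!r} was measured at {time} h")
    return np.asarray(folds)


def fold_change(
    table: pd.DataFrame, genotype: str, time: float
) -> tuple[float, float, int]:
    """Mean, sample sd, and n of per-replicate OD600(t)/OD600(0)."""
    folds = _replicate_folds(validate_growth_table(table), genotype, time)
    sd = float(np.std(folds, ddof=1)) if folds.size > 1 else float("nan")
    return float(np.mean(folds)), sd, folds.size


@dataclass
class FoldChangeSummary:
    """Per genotype x time fold-change statistics."""

    table: pd.DataFrame  # columns genotype, time_h, mean_fold, sd_fold, n

    def at(self, genotype: str, time: float) -> float:
        sub = self.table[
            (self.table["genotype"] == genotype)
            & np.isclose(self.table["time_h"], time)
        ]
        if sub.empty:
            raise KeyError(f"no fold change for {genotype!r} at {time} h")
        return float(sub["mean_fold"].iloc[0])


def fold_change_summary(
    table: pd.DataFrame, times: list[float] = (24.0, 48.0)
) -> FoldChangeSummary:
    validate_growth_table(table)
    rows = []
    for genotype in pd.unique(table["genotype"]):
        for t in times:
            mean, sd, n = fold_change(table, genotype, t)
            rows.append(
                {"genotype": genotype, "time_h": t, "mean_fold": mean,
                 "sd_fold": sd, "n": n}
            )
    return FoldChangeSummary(pd.DataFrame(rows))


def ttest_vs_wt(
    mutant_folds: np.ndarray, wt_folds: np.ndarray, welch: bool = False
) -> tuple[float, bool]:
    """Two-tailed unpaired t-test of mutant vs WT fold changes.

    Returns ``(p, significant)`` with significance at p < 0.05.  Classical
    equal-variance Student statistic by default; ``welch=True`` drops the
    equal-variance assumption.
    """
    a = np.asarray(mutant_folds, dtype=float)
    b = np.asarray(wt_folds, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 replicates")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    if np.isnan(p):  # both groups constant and identical
        p = 1.0
    return p, p < 0.05


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("Pearson correlation needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class CorrelationReport:
    x_label: str
    y_label: str
    r: float
    n: int
    timepoint: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("correlation coefficient must lie in [-1, 1]")


@dataclass(frozen=True)
class ClassificationOutcome:
    """WT-anchored quadrant call for one mutant."""

    genotype: str
    feature: str
    feature_relation: str  # above_wt | below_wt | tie
    growth_relation: str
    call: str  # concordant | discordant | tie-excluded

    def __post_init__(self) -> None:
        concordant = (
            self.feature_relation == self.growth_relation
            and self.feature_relation != "tie"
        )
        if (self.call == "concordant") != concordant:
            raise ValueError("call inconsistent with its relations")


def _relation(value: float, reference: float) -> str:
    if value > reference:
        return "above_wt"
    if value < reference:
        return "below_wt"
    return "tie"


def classify_vs_wt(
    features: dict[str, float],
    growth: dict[str, float],
    wt_label: str,
    feature: str = "activity_meas",
) -> tuple[list[ClassificationOutcome], dict[str, int]]:
    """Quadrant classification of every mutant against the WT reference.

    ``features`` maps genotype -> channel feature value (taken as absolute
    values when the selector is a current), ``growth`` maps genotype ->
    growth fold change at the chosen timepoint.  The WT point sits on both
    dividing lines and is never itself classified.
    """
    if wt_label not in features or wt_label not in growth:
        raise ValueError(f"WT label {wt_label!r} missing from features or growth")
    take_abs = feature in CURRENT_FEATURES
    trans = abs if take_abs else float
    wt_feature = trans(features[wt_label])
    wt_growth = float(growth[wt_label])
    outcomes: list[ClassificationOutcome] = []
    counts = {"concordant": 0, "discordant": 0, "tie-excluded": 0}
    for genotype in features:
        if genotype == wt_label or genotype not in growth:
            continue
        f_rel = _relation(trans(features[genotype]), wt_feature)
        g_rel = _relation(float(growth[genotype]), wt_growth)
        if "tie" in (f_rel, g_rel):
            call = "tie-excluded"
            warnings.warn(
                f"{genotype}: exact tie with WT; excluded from classification",
                stacklevel=2,
            )
        elif f_rel == g_rel:
            call = "concordant"
        else:
            call = "discordant"
        counts[call] += 1
        outcomes.append(ClassificationOutcome(genotype, feature, f_rel, g_rel, call))
    return outcomes, counts


@dataclass
class MultilinearFit:
    """OLS fit of growth on (1, i, P_O, i x P_O)."""

    intercept: float
    beta_i: float
    beta_po: float
    beta_product: float
    r2: float
    n: int

    def __post_init__(self) -> None:
        if not -1e-12 <= self.r2 <= 1 + 1e-12:
            raise ValueError("R-squared must lie in [0, 1]")
        self.r2 = float(min(max(self.r2, 0.0), 1.0))


def multilinear_r2(
    growth: np.ndarray, i: np.ndarray, po: np.ndarray
) -> MultilinearFit:
    """Fit growth ~ 1 + i + P_O + i*P_O by OLS; R^2 = 1 - SS_res/SS_tot.

    The intercept keeps R^2 comparable across software.  Collinear
    regressors raise an error naming the offending one.
    """
    import statsmodels.api as sm

    y = np.asarray(growth, dtype=float)
    i = np.asarray(i, dtype=float)
    po = np.asarray(po, dtype=float)
    if not (y.size == i.size == po.size):
        raise ValueError("growth, i, and po must have equal length")
    if y.size < 5:
        raise ValueError("multilinear fit needs n >= 5")
    names = ["i", "po", "i*po"]
    cols = [i, po, i * po]
    x = np.column_stack([np.ones_like(y)] + cols)
    rank = np.linalg.matrix_rank(x, tol=1e-10 * max(1.0, float(np.abs(x).max())))
    if rank < x.shape[1]:
        for j, name in enumerate(names):
            reduced = np.delete(x, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"regressor {name!r} is collinear with the others")
        raise ValueError("design matrix is rank deficient")
    if np.std(y) == 0:
        # constant response: the model explains nothing beyond the mean
        return MultilinearFit(float(y[0]), 0.0, 0.0, 0.0, 0.0, y.size)
    model = sm.OLS(y, x).fit()
    b = model.params
    return MultilinearFit(
        float(b[0]), float(b[1]), float(b[2]), float(b[3]),
        float(model.rsquared), y.size,
    )


# ---------------------------------------------------------------------------
# hidden-variable decorrelation demo
# ---------------------------------------------------------------------------


def activity_growth_correlation(
    activities: dict[str, float],
    growth_model,
    expression_sigma: float = 0.0,
    time: float = 48.0,
    seed=None,
) -> float:
    """Pearson r between |activity| and the growth fold change at ``time``.

    Hidden per-genotype expression factors are drawn log-normally
    (``exp(N(0, sigma))``); at sigma = 0 growth is a deterministic monotone
    function of activity, and increasing sigma lets the hidden variable
    dominate the phenotype.
    """
    from .gatingsim import simulate_growth

    rng = np.random.default_rng(seed)
    labels = sorted(activities)
    folds = []
    feats = []
    from dataclasses import replace

    for label in labels:
        ef = float(np.exp(rng.normal(0.0, expression_sigma))) if expression_sigma > 0 else 1.0
        gm = replace(growth_model, expression_factor=ef)
        records = simulate_growth(
            activities[label], gm, rng, genotype_label=label, n_replicates=1
        )
        od = {r.time: r.od600 for r in records}
        folds.append(od[time] / od[0.0])
        feats.append(abs(activities[label]))
    return pearson_r(np.asarray(feats), np.asarray(folds))


def decorrelation_curve(
    activities: dict[str, float],
    growth_model,
    sigmas: list[float],
    n_seeds: int = 20,
    seed=None,
) -> list[float]:
    """Median (over seeds) activity-growth Pearson r per expression sigma."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(sigmas) * n_seeds)
    medians = []
    for k, sigma in enumerate(sigmas):
        rs = [
            activity_growth_correlation(
                activities, growth_model, sigma, seed=children[k * n_seeds + j]
            )
            for j in range(n_seeds)
        ]
        medians.append(float(np.median(rs)))
    return medians
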