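"""Evaluation and inference suite for imaging-derived bloom counts.

Contents:

- regression through the origin of imaging counts on manual (reference)
  counts, with uncentered R² and RMSE;
- counting-error analyses (signed error histograms, relative errors,
  per-bloom-load mean errors, cumulative-percentage decile errors);
- two-way factorial ANOVA (genotype × transplant batch, Type-II sums of
  squares for unbalanced designs) and one-way ANOVA with Tukey-HSD
  compact letter displays;
- Cohen's f effect size and the minimum per-group replicate number that
  achieves a target power in a fixed-effects one-way ANOVA, via the
  noncentral F distribution (the G*Power "A priori" computation).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# Regression through the origin


@dataclass(frozen=True)
class RegressionResult:
    """No-intercept linear fit of imaging counts against manual counts."""

    slope: float
    r2: float
    rmse: float
    n: int


def regress_origin(x, y) -> RegressionResult:
    """Least-squares regression of y on x with no intercept term.

    slope b = Σxy/Σx²; RMSE = sqrt(mean (y − b·x)²); R² is the uncentered
    coefficient of determination 1 − Σ(y − b·x)²/Σy², the standard choice
    for a model without an intercept (the centered definition can be
    negative there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise ValueError("regression needs at least 2 samples")
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("all manual counts are zero; slope undefined")
    b = float(x @ y) / sxx
    resid = y - b * x
    rmse = float(np.sqrt(np.mean(resid**2)))
    syy = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 1.0
    return RegressionResult(slope=b, r2=r2, rmse=rmse, n=len(x))


# ---------------------------------------------------------------------------
# Counting-error analysis


@dataclass
class ErrorAnalysis:
    """Error decomposition of imaging counts against manual reference counts.

    ``error_hist`` — signed error (imaging − manual) histogram on integer
    bins. ``relative_hist`` — relative errors e/manual for the subset with
    |e| ≤ 1 and manual > 0, binned by sign and magnitude. Samples with
    manual = 0 but imaging > 0 form their own labeled bin
    (``zero_manual_nonzero_imaging``). ``per_load_mean_error`` — mean
    signed error by true bloom load 0..12 (higher loads clipped to 12).
    ``per_decile_mean_pct_error`` — mean signed difference between imaging
    and manual cumulative percentages (percentage points), grouped by the
    manual cumulative-percentage decile.
    """

    n: int
    error_hist: dict[int, int]
    relative_errors: np.ndarray
    relative_hist: dict[str, int]
    zero_manual_nonzero_imaging: int
    per_load_mean_error: dict[int, float]
    per_load_n: dict[int, int]
    per_decile_mean_pct_error: dict[str, float] = field(default_factory=dict)


_REL_BINS = [
    ("<=-20%", -np.inf, -0.20),
    ("(-20%,-10%]", -0.20, -0.10),
    ("(-10%,0%)", -0.10, -1e-12),
    ("0%", -1e-12, 1e-12),
    ("(0%,10%)", 1e-12, 0.10 - 1e-12),
    ("[10%,20%)", 0.10 - 1e-12, 0.20 - 1e-12),
    (">=20%", 0.20 - 1e-12, np.inf),
]


def _bin_relative(rel: np.ndarray) -> dict[str, int]:
    out = {}
    for label, lo, hi in _REL_BINS:
        out[label] = int(np.sum((rel > lo) & (rel <= hi)))
    return out


def error_analysis(
    imaging: pd.DataFrame, manual: pd.DataFrame, max_load: int = 12
) -> ErrorAnalysis:
    """Join imaging and manual count tables on (plant_id, dap) and analyze.

    ``imaging`` needs columns plant_id, dap, count; ``manual`` needs
    plant_id, dap, manual_count. Manual counts are the reference: the
    per-load grouping clips manual counts above ``max_load`` into the top
    group, and the decile grouping uses the manual cumulative percentage.
    """
    joined = imaging[["plant_id", "dap", "count"]].merge(
        manual[["plant_id", "dap", "manual_count"]], on=["plant_id", "dap"], how="inner"
    )
    if joined.empty:
        raise ValueError("imaging and manual tables share no (plant_id, dap) samples")
    e = joined["count"].to_numpy(float) - joined["manual_count"].to_numpy(float)
    man = joined["manual_count"].to_numpy(float)

    err_int = np.rint(e).astype(int)
    error_hist = {int(k): int(v) for k, v in zip(*np.unique(err_int, return_counts=True))}

    asterisk = int(np.sum((man == 0) & (e > 0)))
    sel = (np.abs(e) <= 1) & (man > 0)
    rel = e[sel] / man[sel]

    loads = np.minimum(man, max_load).astype(int)
    per_load_mean = {}
    per_load_n = {}
    for load in range(0, max_load + 1):
        mask = loads == load
        per_load_n[load] = int(mask.sum())
        per_load_mean[load] = float(e[mask].mean()) if mask.any() else float("nan")

    # cumulative-percentage deciles: per plant, both methods' cumulative
    # fractions on the joined scan dates; decile assignment by the manual one
    decile_sums = np.zeros(10)
    decile_ns = np.zeros(10, dtype=int)
    for _, sub in joined.groupby("plant_id"):
        sub = sub.sort_values("dap")
        tot_i = sub["count"].sum()
        tot_m = sub["manual_count"].sum()
        if tot_i <= 0 or tot_m <= 0:
            continue
        p_i = np.cumsum(sub["count"].to_numpy(float)) / tot_i
        p_m = np.cumsum(sub["manual_count"].to_numpy(float)) / tot_m
        dec = np.minimum((p_m * 10).astype(int), 9)
        np.add.at(decile_sums, dec, (p_i - p_m) * 100.0)
        np.add.at(decile_ns, dec, 1)
    per_decile = {
        f"{10*d}-{10*(d+1)}%": (float(decile_sums[d] / decile_ns[d]) if decile_ns[d] else float("nan"))
        for d in range(10)
    }

    return ErrorAnalysis(
        n=len(joined),
        error_hist=error_hist,
        relative_errors=rel,
        relative_hist=_bin_relative(rel),
        zero_manual_nonzero_imaging=asterisk,
        per_load_mean_error=per_load_mean,
        per_load_n=per_load_n,
        per_decile_mean_pct_error=per_decile,
    )


# ---------------------------------------------------------------------------
# ANOVA


def anova_factorial(
    data: pd.DataFrame, response: str, factor_a: str = "genotype", factor_b: str = "transplant_batch"
) -> pd.DataFrame:
    """Two-way factorial ANOVA with interaction, Type-II sums of squares.

    Type II is appropriate for the unbalanced genotype × batch design
    (unequal survivors per batch). Returns the statsmodels anova_lm table
    with rows for both main effects, the interaction, and residual.
    """
    df = data[[response, factor_a, factor_b]].dropna().copy()
    for f in (factor_a, factor_b):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")
    formula = f"{response} ~ C({factor_a}) * C({factor_b})"
    model = smf.ols(formula, data=df).fit()
    if model.df_resid < 1:
        raise ValueError("insufficient residual degrees of freedom")
    if np.allclose(df[response].to_numpy(float), df[response].iloc[0]):
        # constant response: SS are all ~0; report zero F with a flag column
        table = sm.stats.anova_lm(model, typ=2)
        table["F"] = 0.0
        table["PR(>F)"] = 1.0
        table["flag"] = "constant_response"
        return table
    return sm.stats.anova_lm(model, typ=2)


@dataclass
class OneWayResult:
    """One-way ANOVA with per-group summaries and a multiple-comparison display."""

    table: pd.DataFrame  # anova_lm table (between row named after the factor)
    group_means: pd.Series
    group_ns: pd.Series
    letters: dict[str, str]
    marks: dict[str, str]  # '+' / '-' / '+-' / '' relative-standing display
    tukey: pd.DataFrame
    eta_squared: float
    cohens_f: float


def cohens_f(ss_between: float, ss_total: float) -> float:
    """Cohen's f from one-way ANOVA sums of squares.

    f = sqrt(η²/(1−η²)) with η² = SS_between/SS_total — the convention
    G*Power uses when deriving "Effect size f" from variances.
    """
    if ss_total <= 0:
        return 0.0
    eta2 = ss_between / ss_total
    if eta2 >= 1.0:
        raise ValueError("eta-squared is 1 (no within-group variance); f is infinite")
    return float(np.sqrt(eta2 / (1.0 - eta2)))


def _letters_from_nonsig(groups: list[str], nonsig_pairs: set[frozenset]) -> dict[str, str]:
    """Compact letter display via maximal cliques of the non-significance graph.

    Two groups share a letter iff some maximal clique (a set of mutually
    non-different groups) contains both, so sharing a letter certifies
    adjusted p >= alpha for that pair.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    g.add_edges_from(tuple(p) for p in nonsig_pairs if len(p) == 2)
    cliques = list(nx.find_cliques(g))
    order = {name: i for i, name in enumerate(groups)}
    cliques.sort(key=lambda c: min(order[m] for m in c))
    alphabet = string.ascii_lowercase
    if len(cliques) > len(alphabet):
        alphabet = [a + b for a in string.ascii_lowercase for b in string.ascii_lowercase]
    out = {name: "" for name in groups}
    for letter, clique in zip(alphabet, cliques):
        for member in clique:
            out[member] += letter
    return {k: "".join(sorted(v)) for k, v in out.items()}


def anova_oneway_letters(
    data: pd.DataFrame,
    response: str,
    group: str,
    alpha: float = 0.05,
    posthoc: str = "tukey",
) -> OneWayResult:
    """One-way ANOVA with post-hoc pairwise grouping letters.

    Pairwise comparisons use Tukey's HSD by default (``posthoc='holm-t'``
    switches to pairwise t-tests with Holm adjustment). Groups are sorted
    by ascending mean before letter assignment, so the group with the
    lowest mean carries 'a'. ``marks`` gives the coarser display: '+' for
    a group significantly higher than every group it differs from, '-'
    significantly lower, '+-' mixed, '' no significant differences.
    """
    df = data[[response, group]].dropna().copy()
    counts = df.groupby(group)[response].count()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).all():
        raise ValueError("all groups are singletons; no within-group variance")
    model = smf.ols(f"{response} ~ C({group})", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_between = float(table["sum_sq"].iloc[0])
    ss_total = float(table["sum_sq"].sum())
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    f_eff = cohens_f(ss_between, ss_total) if eta2 < 1 else float("inf")

    means = df.groupby(group)[response].mean().sort_values()
    groups = [str(g) for g in means.index]

    if df[response].nunique() == 1:
        nonsig = {frozenset((a, b)) for i, a in enumerate(groups) for b in groups[i + 1:]}
        tukey_df = pd.DataFrame(columns=["group1", "group2", "meandiff", "p-adj", "reject"])
    elif posthoc == "tukey":
        res = pairwise_tukeyhsd(df[response], df[group].astype(str), alpha=alpha)
        tukey_df = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
        nonsig = {
            frozenset((str(r["group1"]), str(r["group2"])))
            for _, r in tukey_df.iterrows()
            if not r["reject"]
        }
    elif posthoc == "holm-t":
        pairs, pvals = [], []
        for i, a in enumerate(groups):
            for b in groups[i + 1:]:
                xa = df.loc[df[group].astype(str) == a, response]
                xb = df.loc[df[group].astype(str) == b, response]
                pairs.append((a, b))
                pvals.append(sps.ttest_ind(xa, xb, equal_var=True).pvalue)
        reject, padj, _, _ = multipletests(pvals, alpha=alpha, method="holm")
        tukey_df = pd.DataFrame(
            {"group1": [p[0] for p in pairs], "group2": [p[1] for p in pairs],
             "meandiff": np.nan, "p-adj": padj, "reject": reject}
        )
        nonsig = {frozenset(p) for p, rej in zip(pairs, reject) if not rej}
    else:
        raise ValueError(f"unknown posthoc {posthoc!r}")

    letters = _letters_from_nonsig(groups, nonsig)

    marks = {}
    for name in groups:
        higher = lower = 0
        for other in groups:
            if other == name or frozenset((name, other)) in nonsig:
                continue
            if means[name] > means[other]:
                higher += 1
            else:
                lower += 1
        marks[name] = {(True, False): "+", (False, True): "-", (True, True): "+-",
                       (False, False): ""}[(higher > 0, lower > 0)]

    return OneWayResult(
        table=table,
        group_means=means,
        group_ns=counts.reindex(means.index),
        letters=letters,
        marks=marks,
        tukey=tukey_df,
        eta_squared=eta2,
        cohens_f=f_eff,
    )


# ---------------------------------------------------------------------------
# Power analysis / replicate estimation


@dataclass(frozen=True)
class PowerSpec:
    """Target for a fixed-effects one-way ANOVA power computation."""

    effect_size_f: float
    k: int
    alpha: float = 0.05
    power: float = 0.95

    def __post_init__(self) -> None:
        if self.effect_size_f <= 0:
            raise ValueError("effect size f must be > 0")
        if self.k < 2:
            raise ValueError("need k >= 2 groups")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def anova_power(f: float, k: int, n: int, alpha: float = 0.05) -> float:
    """Power of a balanced fixed-effects one-way ANOVA.

    k groups with n replicates each; the F statistic has df1 = k−1 and
    df2 = N−k = k(n−1) and, under the alternative, a noncentral F
    distribution with noncentrality λ = f²·N where N = n·k. Power is
    P(F' > F_crit) with F_crit the central-F upper-alpha quantile.
    """
    if n < 2:
        raise ValueError("need n >= 2 replicates per group for positive error df")
    df1 = k - 1
    df2 = k * (n - 1)
    fcrit = sps.f.ppf(1.0 - alpha, df1, df2)
    lam = f * f * n * k
    return float(sps.ncf.sf(fcrit, df1, df2, lam))


def required_replicates(spec: PowerSpec, n_max: int = 10_000) -> int:
    """Smallest per-group n (>= 2) reaching the target power.

    Short integer search upward from n = 2; power is monotone in n, so the
    first n that attains the target is minimal.
    """
    for n in range(2, n_max + 1):
        if anova_power(spec.effect_size_f, spec.k, n, spec.alpha) >= spec.power:
            return n
    raise ValueError(
        f"no n <= {n_max} reaches power {spec.power} at f={spec.effect_size_f}, "
        f"k={spec.k}, alpha={spec.alpha}"
    )
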