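"""Formula-level statistical battery.

Every test statistic here is computed from its defining formula; SciPy is used
only for reference distributions (chi-square, F, normal, studentized range)
and for mid-rank assignment.  Rank tests use the normal / chi-square
approximations with tie corrections; exact small-sample enumeration is out of
scope.

Dispatch convention (mirroring common chronobiology practice): data that pass
a D'Agostino-Pearson normality check plus a Brown-Forsythe homogeneity check
go to parametric ANOVA; otherwise a log transform is retried; otherwise the
nonparametric branch (Kruskal-Wallis / Scheirer-Ray-Hare) applies.

Significance tiers render as ``*`` p<0.05, ``**`` p<0.01, ``***`` p<0.001,
``****`` p<0.0001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import f as _fdist
from scipy.stats import norm as _norm
from scipy.stats import rankdata as _rankdata
from scipy.stats import studentized_range as _srange

__all__ = [
    "DispatchDecision",
    "EffectResult",
    "GateResult",
    "PairwiseComparison",
    "TestResult",
    "adjust_pvalues",
    "benjamini_hochberg",
    "dagostino_pearson",
    "dunn_posthoc",
    "kruskal_wallis",
    "levene_median",
    "log_transform_gate",
    "mann_whitney",
    "one_way_anova",
    "scheirer_ray_hare",
    "select_test",
    "significance_stars",
    "tukey_hsd",
    "two_way_anova",
    "wilcoxon_bh",
    "wilcoxon_signed_rank",
]


def significance_stars(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class PairwiseComparison:
    a: str
    b: str
    statistic: float
    p_raw: float
    p_adj: float
    stars: str


@dataclass(frozen=True)
class EffectResult:
    effect: str
    statistic: float
    df: float
    p: float


@dataclass
class TestResult:
    name: str  # statistic name: H, F, K2, W, z, ...
    statistic: float
    df: Union[float, tuple]
    p: float
    pairwise: Optional[list[PairwiseComparison]] = None
    effects: Optional[list[EffectResult]] = None
    extras: dict = field(default_factory=dict)

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def _as_groups(groups: Sequence) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float).ravel() for g in groups]
    for g in out:
        if not np.all(np.isfinite(g)):
            raise ValueError("finite values only")
    return out


def _tie_term(pooled_ranks: np.ndarray) -> float:
    """Sum of t^3 - t over tie groups (computed from the rank multiset)."""
    _, counts = np.unique(pooled_ranks, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


# ---------------------------------------------------------------------------
# normality gate


def dagostino_pearson(values: Sequence[float]) -> TestResult:
    """Omnibus K^2 normality test from skewness and kurtosis z-transforms."""
    x = np.asarray(values, dtype=float).ravel()
    n = len(x)
    if n < 8:
        raise ValueError(f"n >= 8 required, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: moments undefined")
    mu = x.mean()
    m2 = ((x - mu) ** 2).mean()
    m3 = ((x - mu) ** 3).mean()
    m4 = ((x - mu) ** 4).mean()
    g1 = m3 / m2**1.5
    b2 = m4 / m2**2

    # D'Agostino (1970) skewness transform
    y = g1 * np.sqrt(((n + 1.0) * (n + 3.0)) / (6.0 * (n - 2.0)))
    beta2 = (
        3.0 * (n**2 + 27.0 * n - 70.0) * (n + 1.0) * (n + 3.0)
        / ((n - 2.0) * (n + 5.0) * (n + 7.0) * (n + 9.0))
    )
    w2 = -1.0 + np.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / np.sqrt(0.5 * np.log(w2))
    alpha = np.sqrt(2.0 / (w2 - 1.0))
    y = np.where(y == 0, 1.0, y)
    z_skew = delta * np.log(y / alpha + np.sqrt((y / alpha) ** 2 + 1.0))

    # Anscombe & Glynn (1983) kurtosis transform
    e_b2 = 3.0 * (n - 1.0) / (n + 1.0)
    var_b2 = 24.0 * n * (n - 2.0) * (n - 3.0) / ((n + 1.0) ** 2 * (n + 3.0) * (n + 5.0))
    xk = (b2 - e_b2) / np.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n**2 - 5.0 * n + 2.0)
        / ((n + 7.0) * (n + 9.0))
        * np.sqrt(6.0 * (n + 3.0) * (n + 5.0) / (n * (n - 2.0) * (n - 3.0)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (2.0 / sqrt_beta1 + np.sqrt(1.0 + 4.0 / sqrt_beta1**2))
    denom = 1.0 + xk * np.sqrt(2.0 / (a - 4.0))
    term = np.sign(denom) * np.abs((1.0 - 2.0 / a) / np.abs(denom)) ** (1.0 / 3.0)
    z_kurt = (1.0 - 2.0 / (9.0 * a) - term) / np.sqrt(2.0 / (9.0 * a))

    k2 = float(z_skew**2 + z_kurt**2)
    p = float(_chi2.sf(k2, 2))
    return TestResult("K2", k2, 2, p, extras={"z_skew": float(z_skew), "z_kurt": float(z_kurt)})


@dataclass
class GateResult:
    values: np.ndarray
    branch: str  # "parametric" | "parametric-log" | "nonparametric"
    transformed: bool
    p_normality: Optional[float]


def log_transform_gate(values: Sequence[float], alpha: float = 0.05) -> GateResult:
    """Return data unchanged if normal; else log-retest; else flag nonparametric."""
    x = np.asarray(values, dtype=float).ravel()
    p = dagostino_pearson(x).p
    if p >= alpha:
        return GateResult(x, "parametric", False, p)
    if np.any(x <= 0):
        return GateResult(x, "nonparametric", False, p)
    lx = np.log(x)
    p_log = dagostino_pearson(lx).p
    if p_log >= alpha:
        return GateResult(lx, "parametric-log", True, p_log)
    return GateResult(x, "nonparametric", False, p_log)


def levene_median(groups: Sequence) -> TestResult:
    """Brown-Forsythe homogeneity-of-variance test (deviations from medians)."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise ValueError("need >= 2 groups")
    z = [np.abs(g - np.median(g)) for g in gs]
    try:
        return one_way_anova(z, name="Levene-F")
    except ValueError:
        return TestResult("Levene-F", 0.0, (len(gs) - 1, sum(map(len, gs)) - len(gs)), 1.0)


# ---------------------------------------------------------------------------
# rank tests


def kruskal_wallis(groups: Sequence, labels: Optional[Sequence[str]] = None) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square(k-1) p-value."""
    gs = _as_groups(groups)
    k = len(gs)
    if k < 2 or any(len(g) < 1 for g in gs):
        raise ValueError("need >= 2 non-empty groups")
    ns = np.array([len(g) for g in gs])
    n_total = int(ns.sum())
    if n_total < 3:
        raise ValueError("need N >= 3")
    pooled = np.concatenate(gs)
    ranks = _rankdata(pooled)
    if np.ptp(pooled) == 0:
        return TestResult("H", 0.0, k - 1, 1.0)
    splits = np.split(ranks, np.cumsum(ns)[:-1])
    rbar = np.array([r.mean() for r in splits])
    h = 12.0 / (n_total * (n_total + 1.0)) * float((ns * rbar**2).sum()) - 3.0 * (n_total + 1.0)
    correction = 1.0 - _tie_term(ranks) / (n_total**3 - n_total)
    if correction <= 0:
        return TestResult("H", 0.0, k - 1, 1.0)
    h /= correction
    return TestResult("H", float(h), k - 1, float(_chi2.sf(h, k - 1)))


def adjust_pvalues(pvals: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(1.0, p * m)
    if method == "sidak":
        return 1.0 - (1.0 - p) ** m
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            adj[i] = min(1.0, running)
        return adj
    if method in ("bh", "benjamini-hochberg", "fdr"):
        return benjamini_hochberg(p)
    raise ValueError(f"unknown adjustment {method!r}")


def dunn_posthoc(
    groups: Sequence,
    labels: Optional[Sequence[str]] = None,
    adjustment: str = "bonferroni",
) -> list[PairwiseComparison]:
    """Dunn's z on pooled mean ranks with tie correction and family control.

    The default Bonferroni family control over k(k-1)/2 pairs is what
    "Dunn's multiple comparisons test" means in common analysis software;
    Holm and Sidak are exposed via ``adjustment``.
    """
    gs = _as_groups(groups)
    k = len(gs)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    ns = np.array([len(g) for g in gs])
    n_total = int(ns.sum())
    ranks = _rankdata(np.concatenate(gs))
    splits = np.split(ranks, np.cumsum(ns)[:-1])
    rbar = [r.mean() for r in splits]
    tie = _tie_term(ranks)
    base_var = n_total * (n_total + 1.0) / 12.0 - tie / (12.0 * (n_total - 1.0))
    zs, raws, pairs = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(base_var * (1.0 / ns[i] + 1.0 / ns[j]))
            z = 0.0 if se == 0 else (rbar[i] - rbar[j]) / se
            p_raw = float(min(1.0, 2.0 * _norm.sf(abs(z))))
            zs.append(z)
            raws.append(p_raw)
            pairs.append((labels[i], labels[j]))
    adj = adjust_pvalues(raws, adjustment)
    return [
        PairwiseComparison(a, b, float(z), pr, float(pa), significance_stars(pa))
        for (a, b), z, pr, pa in zip(pairs, zs, raws, adj)
    ]


def mann_whitney(x, y, alternative: str = "two-sided") -> TestResult:
    """Rank-sum test (normal approximation, mid-ranks, tie-corrected variance)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n = nx + ny
    ranks = _rankdata(pooled)
    w = float(ranks[:nx].sum())
    mu = nx * (n + 1.0) / 2.0
    tie = _tie_term(ranks)
    var = nx * ny / 12.0 * ((n + 1.0) - tie / (n * (n - 1.0)))
    if var <= 0:
        return TestResult("W", w, np.nan, 1.0)
    z = (w - mu) / np.sqrt(var)
    p = _tail_p(z, alternative)
    return TestResult("W", w, np.nan, p, extras={"z": float(z)})


def wilcoxon_signed_rank(x, y=None, alternative: str = "two-sided") -> TestResult:
    """Paired signed-rank test on x - y (or on x directly when y is None)."""
    d = np.asarray(x, dtype=float).ravel()
    if y is not None:
        d = d - np.asarray(y, dtype=float).ravel()
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("W", 0.0, np.nan, 1.0)
    ranks = _rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1.0) / 4.0
    tie = _tie_term(ranks)
    var = n * (n + 1.0) * (2.0 * n + 1.0) / 24.0 - tie / 48.0
    if var <= 0:
        return TestResult("W", w_plus, np.nan, 1.0)
    z = (w_plus - mu) / np.sqrt(var)
    p = _tail_p(z, alternative)
    return TestResult("W", w_plus, np.nan, p, extras={"z": float(z)})


def _tail_p(z: float, alternative: str) -> float:
    if alternative == "two-sided":
        return float(min(1.0, 2.0 * _norm.sf(abs(z))))
    if alternative == "greater":
        return float(_norm.sf(z))
    if alternative == "less":
        return float(_norm.cdf(z))
    raise ValueError(f"unknown alternative {alternative!r}")


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (monotone after cumulative-min smoothing)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    scaled = p[order] * m / np.arange(1, m + 1)
    smoothed = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(1.0, smoothed)
    return adj


def wilcoxon_bh(
    sets_by_day: Sequence[tuple],
    paired: bool = True,
    alternative: str = "two-sided",
) -> list[tuple[float, float]]:
    """Per-day Wilcoxon rank tests with BH correction over the day family.

    Returns ``[(p_raw, p_adj), ...]`` in day order.
    """
    raws = []
    for x, y in sets_by_day:
        if paired:
            raws.append(wilcoxon_signed_rank(x, y, alternative).p)
        else:
            raws.append(mann_whitney(x, y, alternative).p)
    adj = benjamini_hochberg(raws)
    return list(zip(raws, adj.tolist()))


# ---------------------------------------------------------------------------
# parametric ANOVA


def one_way_anova(groups: Sequence, name: str = "F") -> TestResult:
    gs = _as_groups(groups)
    k = len(gs)
    if k < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    ns = np.array([len(g) for g in gs])
    n_total = int(ns.sum())
    grand = np.concatenate(gs).mean()
    means = np.array([g.mean() for g in gs])
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in gs))
    if ss_within == 0:
        raise ValueError("zero within-group variance")
    df_b, df_w = k - 1, n_total - k
    f = (ss_between / df_b) / (ss_within / df_w)
    return TestResult(name, float(f), (df_b, df_w), float(_fdist.sf(f, df_b, df_w)))


def tukey_hsd(
    groups: Sequence, labels: Optional[Sequence[str]] = None
) -> list[PairwiseComparison]:
    """Tukey HSD via the studentized-range distribution (unequal n: Tukey-Kramer)."""
    gs = _as_groups(groups)
    k = len(gs)
    if k < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    ns = np.array([len(g) for g in gs])
    n_total = int(ns.sum())
    ms_within = sum(((g - g.mean()) ** 2).sum() for g in gs) / (n_total - k)
    if ms_within == 0:
        raise ValueError("zero within-group variance")
    means = [g.mean() for g in gs]
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(means[i] - means[j]) / se
            p = float(_srange.sf(q, k, n_total - k))
            out.append(
                PairwiseComparison(labels[i], labels[j], float(q), p, p, significance_stars(p))
            )
    return out


def _dummy(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    out = np.zeros((len(codes), n_levels - 1))
    for lv in range(1, n_levels):
        out[codes == lv, lv - 1] = 1.0
    return out


def _rss(x: np.ndarray, yv: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, yv, rcond=None)
    resid = yv - x @ beta
    return float(resid @ resid)


def _two_way_ss(
    yv: np.ndarray, fa: np.ndarray, fb: np.ndarray
) -> tuple[dict[str, float], dict[str, int], int]:
    """Type-II sums of squares for a two-factor layout with interaction."""
    a_levels, a_codes = np.unique(fa, return_inverse=True)
    b_levels, b_codes = np.unique(fb, return_inverse=True)
    na, nb = len(a_levels), len(b_levels)
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 levels per factor")
    cells = np.zeros((na, nb), dtype=int)
    np.add.at(cells, (a_codes, b_codes), 1)
    if (cells == 0).any():
        empty = [
            f"({a_levels[i]}, {b_levels[j]})"
            for i, j in zip(*np.nonzero(cells == 0))
        ]
        raise ValueError(f"empty cells: {', '.join(empty)}")
    n = len(yv)
    ones = np.ones((n, 1))
    da = _dummy(a_codes, na)
    db = _dummy(b_codes, nb)
    dab = np.einsum("ni,nj->nij", da, db).reshape(n, -1)
    x_ab = np.hstack([ones, da, db])
    x_full = np.hstack([x_ab, dab])
    rss_full = _rss(x_full, yv)
    rss_ab = _rss(x_ab, yv)
    ss = {
        "A": _rss(np.hstack([ones, db]), yv) - rss_ab,
        "B": _rss(np.hstack([ones, da]), yv) - rss_ab,
        "A:B": rss_ab - rss_full,
        "error": rss_full,
        "total": float(((yv - yv.mean()) ** 2).sum()),
    }
    df = {
        "A": na - 1,
        "B": nb - 1,
        "A:B": (na - 1) * (nb - 1),
        "error": n - na * nb,
    }
    if df["error"] <= 0:
        raise ValueError("one observation per cell: interaction untestable")
    return ss, df, n


def two_way_anova(values, factor_a, factor_b) -> TestResult:
    """Two-way ANOVA (Type-II SS for unbalanced cells): main effects + interaction.

    The primary (name/statistic/df/p) slot reports the interaction; all three
    effects are listed in ``effects``.
    """
    yv = np.asarray(values, dtype=float).ravel()
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    if not (len(yv) == len(fa) == len(fb)):
        raise ValueError("values and factors must share one length")
    if not np.all(np.isfinite(yv)):
        raise ValueError("finite values only")
    ss, df, _ = _two_way_ss(yv, fa, fb)
    ms_err = ss["error"] / df["error"]
    effects = []
    for eff in ("A", "B", "A:B"):
        if ms_err > 0:
            f = (ss[eff] / df[eff]) / ms_err
            p = float(_fdist.sf(f, df[eff], df["error"]))
        elif ss[eff] <= 1e-12:  # degenerate: no variance anywhere
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
        effects.append(EffectResult(eff, float(f), df[eff], p))
    inter = effects[2]
    return TestResult(
        "F",
        inter.statistic,
        (df["A:B"], df["error"]),
        inter.p,
        effects=effects,
        extras={"ss": ss, "df": df},
    )


def scheirer_ray_hare(values, factor_a, factor_b) -> TestResult:
    """Scheirer-Ray-Hare: two-way SS decomposition on mid-ranks.

    H_effect = SS_effect / (SS_total / (N - 1)), chi-square with the effect's
    df.  SS on ranks uses the same Type-II decomposition as
    :func:`two_way_anova` (identical to the textbook decomposition for
    balanced designs).  Ties get mid-ranks, no further correction.
    """
    yv = np.asarray(values, dtype=float).ravel()
    ranks = _rankdata(yv)
    ss, df, n = _two_way_ss(ranks, np.asarray(factor_a), np.asarray(factor_b))
    if n < 6:
        raise ValueError("need N >= 6")
    ms_total = ss["total"] / (n - 1)
    effects = []
    for eff in ("A", "B", "A:B"):
        h = ss[eff] / ms_total if ms_total > 0 else 0.0
        p = float(_chi2.sf(h, df[eff])) if ms_total > 0 else 1.0
        effects.append(EffectResult(eff, float(h), df[eff], p))
    inter = effects[2]
    return TestResult(
        "H",
        inter.statistic,
        df["A:B"],
        inter.p,
        effects=effects,
        extras={"ss": ss, "df": df},
    )


# ---------------------------------------------------------------------------
# dispatch


@dataclass
class DispatchDecision:
    branch: str  # "parametric" | "parametric-log" | "nonparametric"
    transformed: bool
    normality_p: list[float]
    homogeneity_p: Optional[float]


def select_test(groups: Sequence, alpha: float = 0.05) -> DispatchDecision:
    """The pipeline's test-selection rule: normality (+ homogeneity) gates
    parametric ANOVA; otherwise log-retest; otherwise nonparametric."""
    gs = _as_groups(groups)

    def _all_normal(data: list[np.ndarray]) -> tuple[bool, list[float]]:
        ps = []
        for g in data:
            try:
                ps.append(dagostino_pearson(g).p)
            except ValueError:
                ps.append(0.0)
        return all(p >= alpha for p in ps), ps

    ok, ps = _all_normal(gs)
    if ok:
        hom = levene_median(gs).p
        if hom >= alpha:
            return DispatchDecision("parametric", False, ps, hom)
    if all(np.all(g > 0) for g in gs):
        logs = [np.log(g) for g in gs]
        ok_log, ps_log = _all_normal(logs)
        if ok_log:
            hom = levene_median(logs).p
            if hom >= alpha:
                return DispatchDecision("parametric-log", True, ps_log, hom)
    return DispatchDecision("nonparametric", False, ps, None)
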