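"""Motif-level statistics over triad PID tables.

Operates on tidy per-triad tables (one row per triad, as produced by the
pipeline: network id, motif class fields, PID terms, entropies, edge
weights) and on per-(network, motif) summaries.  The battery mirrors how
motif-style analyses of effective networks are usually reported:

* paired Wilcoxon signed-rank comparisons across networks (recurrent vs
  feedback motifs, each motif group vs the default-motif baseline),
* a within-network permutation null that shuffles motif labels across
  triads,
* a two-factor (recurrence x feedback, 3 levels each) repeated-measures
  ANOVA over per-network cell means, with the two chiral (1,1) motifs
  averaged into one cell,
* Spearman rank correlations, OLS residualization ("regress-out") controls,
  per-network multiple regressions of normalized synergy on edge weights,
* percentile bootstrap confidence intervals,
* synergy-share accounting (percent of network-wide synergy vs percent of
  triads per motif, tested against ratio 1), and
* the decile trend of edge-significance probability vs TE weight.

Undefined aggregates (empty cells, zero normalizers) are NaN and excluded
listwise per test, with counts logged.  No multiple-testing correction is
applied; alpha is 0.05 per test unless a caller states otherwise.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .infoflow import ConfigError

__all__ = [
    "StatResult",
    "summarize",
    "recurrent_vs_feedback_test",
    "baseline_and_permutation_comparison",
    "rm_anova",
    "spearman",
    "regress_out",
    "per_network_weight_regression",
    "bootstrap_ci",
    "synergy_share",
    "decile_significance_trend",
    "motif_group",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatResult:
    """One statistical test: name, statistic, p, sample size, extras."""

    name: str
    statistic: float
    p_value: float
    n: int
    df: tuple[float, float] | None = None
    direction: str | None = None
    ci: tuple[float, float] | None = None

    def as_row(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "df": "" if self.df is None else f"{self.df[0]:g},{self.df[1]:g}",
            "direction": self.direction or "",
            "ci_low": self.ci[0] if self.ci else float("nan"),
            "ci_high": self.ci[1] if self.ci else float("nan"),
        }


def motif_group(recurrent_count: int, feedback_count: int) -> str:
    """'recurrent' if more recurrent than feedback edges, 'feedback' if the
    converse, 'default' for (0,0), else 'balanced'."""
    if recurrent_count > feedback_count:
        return "recurrent"
    if feedback_count > recurrent_count:
        return "feedback"
    return "default" if recurrent_count == 0 else "balanced"


_TRIAD_KEY = ["network_id", "sender_a", "sender_b", "receiver"]


def summarize(
    triad_table: pd.DataFrame,
    value_fields: Sequence[str] = (
        "synergy_norm",
        "synergy",
        "redundancy",
        "mvte",
        "receiver_entropy",
        "sender_entropy",
    ),
) -> pd.DataFrame:
    """Per-(network, motif) means of the PID fields plus triad counts.

    Input must have one row per triad with the key columns
    ``network_id, sender_a, sender_b, receiver`` plus ``motif_id,
    recurrent_count, feedback_count`` and the value fields.  Duplicate triad
    keys are an input error.  Cells that a network lacks simply do not
    appear; callers treat missing cells as undefined.
    """
    missing = [c for c in _TRIAD_KEY + ["motif_id"] if c not in triad_table.columns]
    if missing:
        raise ValueError(f"triad table lacks columns {missing}")
    if triad_table.duplicated(subset=_TRIAD_KEY).any():
        dup = triad_table[triad_table.duplicated(subset=_TRIAD_KEY, keep=False)]
        raise ValueError(f"duplicated triad keys:\n{dup[_TRIAD_KEY].head()}")
    fields = [f for f in value_fields if f in triad_table.columns]
    grouped = triad_table.groupby(
        ["network_id", "motif_id", "recurrent_count", "feedback_count"], as_index=False
    ).agg(**{f: (f, "mean") for f in fields}, triad_count=("motif_id", "size"))
    return grouped


def _paired_wilcoxon(
    name: str, x: np.ndarray, y: np.ndarray
) -> StatResult:
    mask = np.isfinite(x) & np.isfinite(y)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("%s: excluding %d networks with undefined aggregates", name, dropped)
    x, y = x[mask], y[mask]
    d = x - y
    if x.size < 6:
        raise ValueError(f"{name}: need >= 6 paired networks, have {x.size}")
    if np.all(d == 0):
        raise ValueError(f"{name}: all paired differences are zero (degenerate)")
    res = stats.wilcoxon(x, y, zero_method="wilcox", method="approx")
    direction = "greater" if np.median(d) > 0 else "less"
    return StatResult(name, float(res.statistic), float(res.pvalue), int(x.size),
                      direction=direction)


def _network_group_means(
    summary: pd.DataFrame, value: str, group: str
) -> pd.Series:
    """Triad-count-weighted mean of `value` over motifs in a group, per network."""
    g = summary[
        summary.apply(
            lambda r: motif_group(r["recurrent_count"], r["feedback_count"]) == group,
            axis=1,
        )
    ]
    if g.empty:
        return pd.Series(dtype=float)
    w = g["triad_count"]
    return g.assign(_w=w * g[value]).groupby("network_id").apply(
        lambda s: s["_w"].sum() / s["triad_count"].sum(), include_groups=False
    )


def recurrent_vs_feedback_test(
    summary: pd.DataFrame, value: str = "synergy_norm"
) -> StatResult:
    """Paired signed-rank: per-network mean in recurrent vs feedback motifs."""
    rec = _network_group_means(summary, value, "recurrent")
    fb = _network_group_means(summary, value, "feedback")
    nets = rec.index.intersection(fb.index)
    return _paired_wilcoxon(
        f"recurrent_vs_feedback[{value}]",
        rec.loc[nets].to_numpy(),
        fb.loc[nets].to_numpy(),
    )


def baseline_and_permutation_comparison(
    triad_table: pd.DataFrame,
    group: str = "recurrent",
    value: str = "synergy_norm",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[StatResult, StatResult]:
    """A motif group vs the default-motif baseline, two ways.

    (i) Paired signed-rank of per-network group means against per-network
    default-motif means.  (ii) A permutation null: motif labels are shuffled
    across triads *within* each network, the group-minus-default contrast is
    recomputed, and an add-one empirical p is reported for the observed mean
    contrast (two-sided).  Requires ``n_perm >= 1/alpha - 1``.
    """
    needed = int(math.ceil(1.0 / alpha)) - 1
    if n_perm < needed:
        raise ConfigError(
            f"n_perm={n_perm} cannot resolve alpha={alpha}; need >= {needed}"
        )
    df = triad_table.copy()
    df["_group"] = [
        motif_group(r, f)
        for r, f in zip(df["recurrent_count"], df["feedback_count"])
    ]

    def contrast(frame: pd.DataFrame) -> pd.Series:
        means = frame.groupby(["network_id", "_group"])[value].mean().unstack()
        if group not in means.columns or "default" not in means.columns:
            return pd.Series(dtype=float)
        return (means[group] - means["default"]).dropna()

    obs = contrast(df)
    if obs.empty:
        raise ValueError(f"no networks with both '{group}' and default triads")
    wil = _paired_wilcoxon(
        f"{group}_vs_default[{value}]", obs.to_numpy(), np.zeros(obs.size)
    )

    rng = np.random.default_rng(seed)
    obs_stat = float(obs.mean())
    label_cols = ["motif_id", "recurrent_count", "feedback_count", "_group"]
    count = 0
    shuffled = df.copy()
    groups = list(df.groupby("network_id").indices.values())
    labels = df[label_cols].to_numpy(dtype=object)
    for _ in range(n_perm):
        perm_labels = labels.copy()
        for idx in groups:
            perm_labels[idx] = labels[np.asarray(idx)[rng.permutation(len(idx))]]
        shuffled[label_cols] = perm_labels
        stat = contrast(shuffled).mean()
        if np.isfinite(stat) and abs(stat) >= abs(obs_stat) - 1e-15:
            count += 1
    p_perm = (1.0 + count) / (1.0 + n_perm)
    perm = StatResult(
        f"{group}_vs_default_permutation[{value}]",
        obs_stat,
        p_perm,
        int(obs.size),
        direction="greater" if obs_stat > 0 else "less",
    )
    return wil, perm


# ---------------------------------------------------------------------------
# Two-factor repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _rm_anova_from_grid(cells: np.ndarray) -> list[StatResult]:
    """Univariate RM-ANOVA on an (n_subjects, a, b) array, one obs per cell.

    Error terms are the factor-by-subject interactions; df are
    ``(a-1, (a-1)(n-1))`` for main effects and ``((a-1)(b-1),
    (a-1)(b-1)(n-1))`` for the interaction.  Zero-variance responses give
    F = 0, p = 1 rather than 0/0.
    """
    n, a, b = cells.shape
    if n < 3:
        raise ValueError(f"need >= 3 complete networks, have {n}")
    grand = cells.mean()
    m_s = cells.mean(axis=(1, 2))
    m_a = cells.mean(axis=(0, 2))
    m_b = cells.mean(axis=(0, 1))
    m_ab = cells.mean(axis=0)
    m_sa = cells.mean(axis=2)
    m_sb = cells.mean(axis=1)

    ss_a = b * n * np.sum((m_a - grand) ** 2)
    ss_b = a * n * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_b[None, :] - m_s[:, None] + grand) ** 2)
    ss_total = np.sum((cells - grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_abs = ss_total - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs

    def effect(name: str, ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> StatResult:
        if ss_eff <= 1e-300 and ss_err <= 1e-300:
            return StatResult(name, 0.0, 1.0, n, df=(df_eff, df_err))
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err <= 0:
            return StatResult(name, float("inf"), 0.0, n, df=(df_eff, df_err))
        f = ms_eff / ms_err
        p = float(stats.f.sf(f, df_eff, df_err))
        return StatResult(name, float(f), p, n, df=(df_eff, df_err))

    return [
        effect("recurrence", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        effect("feedback", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        effect(
            "recurrence_x_feedback",
            ss_ab,
            (a - 1) * (b - 1),
            max(ss_abs, 0.0),
            (a - 1) * (b - 1) * (n - 1),
        ),
    ]


def rm_anova(
    summary: pd.DataFrame, value: str = "synergy_norm"
) -> tuple[StatResult, StatResult, StatResult]:
    """Two-factor (recurrence x feedback, 3 levels each) RM-ANOVA.

    Builds per-network 3x3 cell means from the motif summary, averaging the
    two chiral (1,1) motifs into one cell (the 10-to-9 grouping); networks
    missing any cell are excluded listwise.  Returns (recurrence, feedback,
    interaction) results with F, p and df.
    """
    cells_df = (
        summary.groupby(["network_id", "recurrent_count", "feedback_count"])[value]
        .mean()
        .unstack(["recurrent_count", "feedback_count"])
    )
    full = [(r, f) for r in range(3) for f in range(3)]
    missing_cols = [c for c in full if c not in cells_df.columns]
    if missing_cols:
        raise ValueError(
            f"no network exhibits cells {missing_cols}; cannot form the 3x3 grid"
        )
    cells_df = cells_df[full].dropna()
    n_dropped = summary["network_id"].nunique() - len(cells_df)
    if n_dropped:
        logger.info("rm_anova: %d networks dropped for incomplete grids", n_dropped)
    grid = cells_df.to_numpy().reshape(-1, 3, 3)
    return tuple(_rm_anova_from_grid(grid))


# ---------------------------------------------------------------------------
# Correlations, residualization, regressions
# ---------------------------------------------------------------------------


def spearman(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation with average ranks for ties.

    p is exact by permutation enumeration for n <= 8, otherwise the
    large-sample t approximation.  Zero variance in either input is a
    degenerate-input error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input; rank correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    n = x.size
    if n <= 8:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = np.corrcoef(rx, ry[list(perm)])[0, 1]
            count += abs(r) >= abs(rho) - 1e-12
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return StatResult("spearman", rho, p, n,
                      direction="greater" if rho > 0 else "less")


def regress_out(
    response: np.ndarray, covariates: np.ndarray, add_intercept: bool = True
) -> np.ndarray:
    """OLS residuals of response on covariates (columns).

    Residuals are orthogonal to every covariate column.  A rank-deficient
    covariate matrix raises, naming the collinear columns.
    """
    y = np.asarray(response, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size:
        raise ValueError("response and covariates must have equal length")
    if add_intercept:
        X = np.column_stack([np.ones(y.size), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [int(i) for i in np.where(np.abs(np.diag(R)) < 1e-10)[0]]
        raise np.linalg.LinAlgError(
            f"covariate matrix rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns {bad}"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def per_network_weight_regression(
    triad_table: pd.DataFrame,
    value: str = "synergy_norm",
    predictors: Sequence[str] = (
        "ff_weight_mean",
        "recurrent_weight_mean",
        "feedback_weight_mean",
    ),
    min_triads: int = 10,
) -> tuple[pd.DataFrame, dict[str, StatResult]]:
    """Per-network OLS of normalized synergy on edge-weight predictors.

    Absent recurrent/feedback edges contribute weight 0.  Networks with
    fewer than ``min_triads`` triads or a degenerate design are skipped and
    logged.  Returns the per-network beta table and, per predictor, a
    signed-rank test of the beta distribution against zero across networks.
    """
    rows = []
    for net, frame in triad_table.groupby("network_id"):
        frame = frame.dropna(subset=[value])
        if len(frame) < min_triads:
            logger.info("weight regression: network %s skipped (%d triads)",
                        net, len(frame))
            continue
        X = np.column_stack(
            [np.ones(len(frame))] + [frame[p].to_numpy(float) for p in predictors]
        )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            logger.info("weight regression: network %s skipped (degenerate design)", net)
            continue
        beta, *_ = np.linalg.lstsq(X, frame[value].to_numpy(float), rcond=None)
        rows.append({"network_id": net,
                     **{p: b for p, b in zip(predictors, beta[1:])}})
    betas = pd.DataFrame(rows)
    tests = {}
    for p in predictors:
        if len(betas) >= 6 and p in betas:
            b = betas[p].to_numpy()
            res = stats.wilcoxon(b, method="approx")
            tests[p] = StatResult(
                f"beta[{p}] vs 0", float(res.statistic), float(res.pvalue),
                len(b), direction="greater" if np.median(b) > 0 else "less",
            )
    return betas, tests


def bootstrap_ci(
    values: Sequence[float],
    statistic: str = "mean",
    n_boot: int = 10_000,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean or median; seed-reproducible."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return (float("nan"), float("nan"))
    fn = {"mean": np.mean, "median": np.median}[statistic]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    boots = fn(v[idx], axis=1)
    lo = float(np.percentile(boots, 100 * (1 - level) / 2))
    hi = float(np.percentile(boots, 100 * (1 + level) / 2))
    return lo, hi


def synergy_share(
    triad_table: pd.DataFrame, value: str = "synergy_norm"
) -> tuple[pd.DataFrame, dict[str, StatResult]]:
    """Percent of triads vs percent of network-wide synergy, per motif.

    Network-wide synergy is the sum of the synergy values over all triads in
    a network; each motif's synergy share is its summed synergy divided by
    that total, its triad share the analogous count fraction.  The ratio
    share/count exceeding 1 means the motif contributes more synergy than
    its frequency predicts; ratios are tested against 1 with a one-sample
    t-test across networks (per motif and per recurrent/feedback group).
    Networks with zero total synergy yield NaN shares (logged, excluded).
    """
    rows = []
    for net, frame in triad_table.groupby("network_id"):
        total_syn = frame[value].sum()
        n_triads = len(frame)
        if not np.isfinite(total_syn) or total_syn <= 0:
            logger.info("synergy_share: network %s has zero/NaN total synergy", net)
            continue
        for motif_id, sub in frame.groupby("motif_id"):
            syn_share = sub[value].sum() / total_syn
            triad_share = len(sub) / n_triads
            rows.append(
                {
                    "network_id": net,
                    "motif_id": motif_id,
                    "group": motif_group(
                        int(sub["recurrent_count"].iloc[0]),
                        int(sub["feedback_count"].iloc[0]),
                    ),
                    "triad_share": triad_share,
                    "synergy_share": syn_share,
                    "ratio": syn_share / triad_share,
                }
            )
    shares = pd.DataFrame(rows)
    tests: dict[str, StatResult] = {}
    if shares.empty:
        return shares, tests
    for key, sub in itertools.chain(
        shares.groupby("motif_id"), shares.groupby("group")
    ):
        ratios = sub["ratio"].to_numpy()
        if ratios.size < 3 or np.ptp(ratios) == 0:
            continue
        t = stats.ttest_1samp(ratios, 1.0)
        tests[f"ratio[{key}] vs 1"] = StatResult(
            f"ratio[{key}] vs 1", float(t.statistic), float(t.pvalue),
            ratios.size,
            direction="greater" if ratios.mean() > 1 else "less",
        )
    return shares, tests


def decile_significance_trend(
    edge_table: pd.DataFrame, n_quantiles: int = 10
) -> tuple[pd.DataFrame, StatResult]:
    """Probability of edge significance per TE decile, and its trend.

    ``edge_table`` needs columns ``network_id, te_raw, sig``.  Within each
    network TE values are ranked into deciles; the per-decile probability of
    significance is computed; the per-network trend is the rank correlation
    between decile index and that probability.  Networks whose edges are all
    significant or all non-significant contribute a zero (tie).  The trend
    across networks is a signed-rank test of the correlations against zero.
    """
    rows = []
    rhos = []
    for net, frame in edge_table.groupby("network_id"):
        te = frame["te_raw"].to_numpy(float)
        sig = frame["sig"].to_numpy(bool)
        if te.size < n_quantiles:
            raise ValueError(
                f"network {net}: need >= {n_quantiles} candidate edges, have {te.size}"
            )
        ranks = stats.rankdata(te, method="ordinal") - 1
        decile = (ranks * n_quantiles // te.size).astype(int)
        probs = np.array(
            [sig[decile == q].mean() for q in range(n_quantiles)]
        )
        for q, p in enumerate(probs):
            rows.append({"network_id": net, "decile": q, "p_significant": p})
        if np.ptp(probs) == 0:
            rhos.append(0.0)
        else:
            rhos.append(float(stats.spearmanr(np.arange(n_quantiles), probs).statistic))
    rhos = np.asarray(rhos)
    if np.all(rhos == 0):
        trend = StatResult("decile_trend", 0.0, 1.0, rhos.size, direction="none")
    else:
        res = stats.wilcoxon(rhos, method="approx")
        trend = StatResult(
            "decile_trend", float(res.statistic), float(res.pvalue), rhos.size,
            direction="greater" if np.median(rhos) > 0 else "less",
        )
    return pd.DataFrame(rows), trend
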