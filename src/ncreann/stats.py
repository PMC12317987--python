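"""Group statistics: behavioral summaries, 2x2 repeated-measures ANOVA,
normality-routed paired comparisons, Spearman correlation matrices and
Benjamini-Hochberg FDR control.

The behavioral design crosses response relation (repetition vs alternation)
with feature overlap (none vs full) within subjects; binding effects show
up as the interaction.  Paired comparisons test for normality of the
differences first (Lilliefors-corrected Kolmogorov-Smirnov by default) and
route to a paired t-test or a Wilcoxon signed-rank test accordingly.
Spearman correlations use the subjects complete on each pair, and the
step-up Benjamini-Hochberg procedure controls the false discovery rate
across correlation families.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .containers import ValidationError
from .synthetic import OVERLAP_LEVELS, RESPONSE_LEVELS

CELLS = [(r, o) for r in RESPONSE_LEVELS for o in OVERLAP_LEVELS]


def summarize_behavior(table: pd.DataFrame) -> pd.DataFrame:
    """Per subject x design cell hit rate (%) and mean correct-trial RT.

    Hit rate counts correct probe responses over all events of the cell
    (misses and false responses stay in the denominator); mean RT is over
    correct-R2 trials only and is NaN when a subject has none in a cell.
    """
    required = {"subject", "response_relation", "overlap", "correct_r2", "rt_ms"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"behavior table is missing columns: {sorted(missing)}")
    rows = []
    for (subj, resp, ov), g in table.groupby(
        ["subject", "response_relation", "overlap"], sort=True
    ):
        rows.append(
            {
                "subject": subj,
                "response_relation": resp,
                "overlap": ov,
                "n_trials": len(g),
                "hit_rate_pct": 100.0 * g["correct_r2"].sum() / len(g),
                "mean_rt_ms": g.loc[g["correct_r2"], "rt_ms"].mean(),
            }
        )
    out = pd.DataFrame(rows)
    counts = out.groupby("subject")["response_relation"].count()
    bad = counts[counts < 4]
    if len(bad):
        first = bad.index[0]
        have = set(zip(out.loc[out.subject == first, "response_relation"],
                       out.loc[out.subject == first, "overlap"]))
        missing_cells = [c for c in CELLS if c not in have]
        raise ValidationError(f"subject {first} has empty design cells: {missing_cells}")
    return out


@dataclass
class AnovaEffect:
    name: str
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


def rm_anova_2x2(cell_means: np.ndarray) -> dict[str, AnovaEffect]:
    """Within-subject 2x2 ANOVA from an (n_subjects, 2, 2) cell-mean array.

    Axis 1 is factor A (response relation), axis 2 factor B (overlap).
    Each effect has 1 numerator df and is tested against its own
    effect-by-subject interaction; for these 1-df effects the F statistic
    equals the squared paired t on the per-subject contrast.  Partial eta
    squared is SS_effect / (SS_effect + SS_error).
    """
    y = np.asarray(cell_means, dtype=float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ValidationError("cell_means must be (n_subjects, 2, 2)")
    n = y.shape[0]
    if n < 3:
        raise ValidationError("repeated-measures ANOVA needs >= 3 subjects")
    if not np.all(np.isfinite(y)):
        raise ValidationError("cell means contain missing values")
    grand = y.mean()
    mean_a = y.mean(axis=(0, 2))        # (2,)
    mean_b = y.mean(axis=(0, 1))
    mean_s = y.mean(axis=(1, 2))        # (n,)
    mean_ab = y.mean(axis=0)            # (2, 2)
    mean_as = y.mean(axis=2)            # (n, 2)
    mean_bs = y.mean(axis=1)            # (n, 2)

    ss_a = 2 * n * np.sum((mean_a - grand) ** 2)
    ss_b = 2 * n * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum((mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((mean_as - mean_a[None, :] - mean_s[:, None] + grand) ** 2)
    ss_bs = 2 * np.sum((mean_bs - mean_b[None, :] - mean_s[:, None] + grand) ** 2)
    resid = (
        y
        - mean_ab[None, :, :]
        - mean_as[:, :, None]
        - mean_bs[:, None, :]
        + mean_a[None, :, None]
        + mean_b[None, None, :]
        + mean_s[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)

    df_err = n - 1
    out: dict[str, AnovaEffect] = {}
    for name, ss_eff, ss_err in (
        ("response", ss_a, ss_as),
        ("overlap", ss_b, ss_bs),
        ("interaction", ss_ab, ss_abs),
    ):
        if ss_err == 0:
            f = 0.0 if ss_eff == 0 else np.inf
        else:
            f = (ss_eff / 1.0) / (ss_err / df_err)
        p = 1.0 if (ss_eff == 0 and ss_err == 0) else float(sps.f.sf(f, 1, df_err))
        eta = 0.0 if (ss_eff + ss_err) == 0 else float(ss_eff / (ss_eff + ss_err))
        out[name] = AnovaEffect(name=name, F=float(f), df1=1, df2=df_err, p=p,
                                partial_eta_sq=eta)
    return out


def cell_mean_array(summary: pd.DataFrame, value: str = "hit_rate_pct") -> np.ndarray:
    """Pivot a per-subject-cell summary into the (n, 2, 2) ANOVA layout."""
    wide = summary.pivot_table(
        index="subject", columns=["response_relation", "overlap"], values=value
    )
    arr = np.empty((len(wide), 2, 2))
    for a, resp in enumerate(RESPONSE_LEVELS):
        for b, ov in enumerate(OVERLAP_LEVELS):
            arr[:, a, b] = wide[(resp, ov)].to_numpy()
    return arr


@dataclass
class PairedTestResult:
    test: str            # "t" or "wilcoxon"
    statistic: float
    p: float
    n: int
    df: int | None
    normality_p: float | None


def paired_compare(
    a: np.ndarray,
    b: np.ndarray,
    alpha_normality: float = 0.05,
    normality_test: str = "lilliefors",
) -> PairedTestResult:
    """Two-tailed paired comparison with KS-routed test choice.

    The differences are screened for normality (Lilliefors-corrected KS by
    default, plain KS with estimated moments via
    ``normality_test='ks'``); normal-looking differences get a paired
    t-test, otherwise a Wilcoxon signed-rank test (Pratt handling of zero
    differences).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("paired samples must be equal-length 1-D arrays")
    keep = np.isfinite(a) & np.isfinite(b)
    d = (a - b)[keep]
    n = d.size
    if n < 5:
        raise ValidationError(f"need >= 5 complete pairs, got {n}")
    if np.all(d == d[0]):
        if d[0] == 0.0:
            return PairedTestResult("t", 0.0, 1.0, n, n - 1, None)
        d_norm_p = None
    else:
        if normality_test == "lilliefors":
            _, d_norm_p = lilliefors(d, dist="norm")
        elif normality_test == "ks":
            _, d_norm_p = sps.kstest(d, "norm", args=(d.mean(), d.std(ddof=1)))
        else:
            raise ValidationError(f"unknown normality test {normality_test!r}")
    if d_norm_p is None or d_norm_p >= alpha_normality:
        t, p = sps.ttest_1samp(d, 0.0)
        return PairedTestResult("t", float(t), float(p), n, n - 1, d_norm_p)
    res = sps.wilcoxon(d, zero_method="pratt", alternative="two-sided", method="approx")
    return PairedTestResult("wilcoxon", float(res.statistic), float(res.pvalue), n, None, d_norm_p)


def spearman_matrix(
    values: pd.DataFrame,
    min_n: int = 5,
    exact_below: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations with pairwise-complete missing handling.

    For each variable pair only the subjects complete on that pair enter;
    ranks use midranks for ties.  Two-tailed p-values come from the t
    approximation for n >= ``exact_below`` and from exact permutation of
    one variable's pairing below that.  Pairs with fewer than ``min_n``
    complete subjects are reported missing with a warning.  Returns
    (r_s, p, n_used) as variable x variable DataFrames.
    """
    if values.shape[1] < 2:
        raise ValidationError("need at least 2 variables")
    cols = list(values.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    nmat = np.zeros((k, k), dtype=int)
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    for i in range(k):
        nmat[i, i] = int(values[cols[i]].notna().sum())
        for j in range(i + 1, k):
            sub = values[[cols[i], cols[j]]].dropna()
            n = len(sub)
            nmat[i, j] = nmat[j, i] = n
            if n < min_n:
                warnings.warn(
                    f"pair ({cols[i]}, {cols[j]}): only {n} complete subjects; reported missing",
                    stacklevel=2,
                )
                continue
            x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            rho = float(sps.spearmanr(x, y).statistic)
            if n < exact_below:
                def stat(perm_y, _x=x):
                    return sps.spearmanr(_x, perm_y).statistic
                perm = sps.permutation_test(
                    (y,), stat, permutation_type="pairings",
                    alternative="two-sided", n_resamples=np.inf,
                )
                pv = float(perm.pvalue)
            else:
                pv = float(sps.spearmanr(x, y).pvalue)
            r[i, j] = r[j, i] = rho
            p[i, j] = p[j, i] = pv
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
        pd.DataFrame(nmat, index=cols, columns=cols),
    )


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up FDR control at level q.

    Sorts the m p-values ascending, finds the largest i with
    p_(i) <= (i/m) q, and rejects every p-value <= p_(i).  Returns the
    rejection mask (original order) and the critical value p_(i) (0 when
    nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) / m) * q
    if not below.any():
        return np.zeros(m, dtype=bool), 0.0
    critical = float(sorted_p[np.nonzero(below)[0][-1]])
    return p <= critical, critical


def asymmetry_tests(matrices: np.ndarray, labels: list[str] | None = None) -> pd.DataFrame:
    """Paired i->j vs j->i comparisons of directed edge strengths.

    ``matrices`` is (n_subjects, M, M) with entry (i, j) the strength of
    i -> j; each unordered region pair yields one normality-routed paired
    test across subjects (diagonal self-influence is never involved).
    """
    arr = np.asarray(matrices, dtype=float)
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValidationError("matrices must be (n_subjects, M, M)")
    m = arr.shape[1]
    labels = labels or [f"ch{i}" for i in range(m)]
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            res = paired_compare(arr[:, i, j], arr[:, j, i])
            rows.append(
                {
                    "source": labels[i], "target": labels[j],
                    "forward_mean": float(np.nanmean(arr[:, i, j])),
                    "reverse_mean": float(np.nanmean(arr[:, j, i])),
                    "test": res.test, "statistic": res.statistic,
                    "p": res.p, "n": res.n,
                }
            )
    return pd.DataFrame(rows)
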