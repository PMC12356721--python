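"""Inference chain for the between/within design.

Mixed (split-plot) ANOVA with Mauchly sphericity testing and
Greenhouse-Geisser correction, Levene-gated post-hoc independent-samples
t-tests (Student or Welch), Bonferroni correction within each
three-comparison family, Cohen's d, and the default JZS Bayes factor for
the independent-samples t (Cauchy prior on standardized effect size,
scale sqrt(2)/2, evaluated by numerical integration).

Every two-sample statistic is computable either from raw samples or
from printed group summaries (mean, SD, n); both routes agree exactly.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "SummaryStats",
    "StatResult",
    "summarize",
    "levene_test",
    "independent_t",
    "cohens_d",
    "bf10_jzs",
    "mauchly_gg",
    "mixed_anova",
    "bonferroni_alpha",
    "posthoc_chain",
    "load_reference_stats",
    "reproduce_reference",
]

DEFAULT_PRIOR_SCALE = np.sqrt(2.0) / 2.0


@dataclass(frozen=True)
class SummaryStats:
    """Sufficient statistics of one group: mean, SD (ddof=1), n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass
class StatResult:
    """One post-hoc comparison."""

    pair: Tuple[str, str]
    test: str  # "student_t" | "welch_t"
    t: float
    df: float
    p: float
    d: float
    bf10: float
    alpha_corrected: float
    significant: bool


def summarize(x) -> SummaryStats:
    """SummaryStats of a raw sample (pass-through for SummaryStats)."""
    if isinstance(x, SummaryStats):
        return x
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return SummaryStats(float(x.mean()), float(x.std(ddof=1)), int(x.size))


def levene_test(*groups, center: str = "mean") -> Tuple[float, float]:
    """Levene's test for equality of variances (classical, mean-centered)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if np.asarray(g).size < 2:
            raise ValueError("every group needs n >= 2")
    with np.errstate(divide="ignore", invalid="ignore"):
        W, p = sps.levene(*groups, center=center)
    # degenerate zero-spread groups yield nan; downstream gating treats
    # that as no evidence of variance inequality
    return float(W), float(p)


def independent_t(a, b, welch: bool = False) -> Tuple[float, float]:
    """Independent-samples t and its degrees of freedom.

    Student: pooled variance, df = n1 + n2 - 2.  Welch: unpooled
    standard error with Welch-Satterthwaite df.  ``a``/``b`` may be raw
    samples or :class:`SummaryStats`; both give identical results.
    """
    a, b = summarize(a), summarize(b)
    va, vb = a.sd ** 2, b.sd ** 2
    if welch:
        sea, seb = va / a.n, vb / b.n
        se = np.sqrt(sea + seb)
        df = (sea + seb) ** 2 / (sea ** 2 / (a.n - 1) + seb ** 2 / (b.n - 1))
    else:
        sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / (a.n + b.n - 2)
        se = np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
        df = a.n + b.n - 2
    if se == 0:
        raise ZeroDivisionError("zero variance in both groups")
    return float((a.mean - b.mean) / se), float(df)


def cohens_d(a, b) -> float:
    """Cohen's d with the (n-1)-weighted pooled SD."""
    a, b = summarize(a), summarize(b)
    sp = np.sqrt(((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2)
                 / (a.n + b.n - 2))
    if sp == 0:
        return 0.0
    return float((a.mean - b.mean) / sp)


def bf10_jzs(t: float, n1: int, n2: int,
             r: float = DEFAULT_PRIOR_SCALE) -> float:
    """Default JZS Bayes factor for an independent-samples t statistic.

    BF10 is the ratio of the marginal likelihood of ``t`` under H1
    (Cauchy(0, r) prior on the standardized effect size delta) to its
    likelihood under H0 (delta = 0).  The marginal is a noncentral-t
    density integrated over the prior; quadrature is run to an absolute
    tolerance well below 1e-6.  BF10 > 1 favors H1.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    nu = n1 + n2 - 2
    n_eff = n1 * n2 / (n1 + n2)
    root = np.sqrt(n_eff)

    def integrand(delta):
        return sps.nct.pdf(t, nu, delta * root) * sps.cauchy.pdf(delta, 0.0, r)

    # Split at the likelihood peak so quadrature cannot miss a narrow mode.
    peak = t / root
    pts = sorted({peak, 0.0})
    num, _ = integrate.quad(integrand, -np.inf, np.inf, points=None,
                            limit=200, epsabs=1e-10, epsrel=1e-10)
    if num == 0.0:  # extremely large |t|: integrate around the peak only
        width = 10.0 * max(abs(peak), 1.0)
        num, _ = integrate.quad(integrand, peak - width, peak + width,
                                points=pts, limit=200, epsabs=1e-300)
    den = sps.t.pdf(t, nu)
    return float(num / den)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (normalized Helmert)."""
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    return c


def mauchly_gg(scores: np.ndarray, n_groups: int = 1,
               contrasts: np.ndarray | None = None
               ) -> Tuple[float, float, float]:
    """Mauchly's sphericity test and Greenhouse-Geisser epsilon.

    ``scores``: subjects x levels matrix of within-subject scores.  With
    ``n_groups`` > 1 the rows are assumed group-centred already and the
    error degrees of freedom are reduced accordingly (pooled
    within-group covariance).  Returns (W, p, epsilon) with epsilon in
    [1/(k-1), 1].
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if k < 2:
        raise ValueError("need at least 2 within levels")
    d_err = n - n_groups
    if d_err < k:
        raise ValueError("need more subjects than within levels")
    if contrasts is None:
        contrasts = _orthonormal_contrasts(k)
    m = contrasts.shape[0]
    centred = scores - scores.mean(axis=0)
    cov = centred.T @ centred / d_err
    sc = contrasts @ cov @ contrasts.T
    tr = np.trace(sc)
    eps = tr ** 2 / (m * np.trace(sc @ sc)) if tr > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / m, 1.0))
    if m == 1:
        return 1.0, 1.0, 1.0
    det = np.linalg.det(sc)
    W = float(det / (tr / m) ** m) if tr > 0 else 1.0
    W = min(max(W, np.finfo(float).tiny), 1.0)
    mult = d_err - (2.0 * m ** 2 + m + 2.0) / (6.0 * m)
    chi2 = -mult * np.log(W)
    df = m * (m + 1) / 2.0 - 1.0
    p = float(sps.chi2.sf(chi2, df))
    return W, p, eps


def _cell_tensor(table: pd.DataFrame, dv: str, subject: str, between: str,
                 within: Sequence[str]):
    """Pivot a long table into a balanced (a, n, b, c) tensor."""
    within = list(within)
    dup = table.duplicated([between, subject] + within)
    if dup.any():
        raise ValueError("duplicate rows for at least one design cell")
    wide = table.pivot_table(index=[between, subject], columns=within,
                             values=dv, aggfunc="mean", sort=True)
    if wide.isna().any().any():
        raise ValueError("incomplete design: missing cells")
    sizes = wide.groupby(level=0).size()
    if sizes.nunique() != 1:
        raise ValueError("unbalanced design: unequal group sizes")
    groups = list(sizes.index)
    b_levels = sorted(table[within[0]].unique())
    if len(within) > 1:
        c_levels = sorted(table[within[1]].unique())
        wide = wide.reindex(
            columns=pd.MultiIndex.from_product([b_levels, c_levels]))
    else:
        c_levels = [None]
        wide = wide.reindex(columns=b_levels)
    a, n = len(groups), int(sizes.iloc[0])
    y = wide.to_numpy().reshape(a, n, len(b_levels), len(c_levels))
    return y, groups, b_levels, c_levels


def mixed_anova(table: pd.DataFrame, dv: str, subject: str, between: str,
                within: Sequence[str], gg_alpha: float = 0.05
                ) -> pd.DataFrame:
    """Univariate split-plot ANOVA with one between and 1-2 within factors.

    Between-subject effects are tested against subjects-within-groups;
    each within effect (and its interaction with the between factor)
    against its own subject-interaction error term.  For every within
    effect, Mauchly's test is run on the pooled within-group covariance
    of the effect's orthonormal contrasts; when it rejects at
    ``gg_alpha``, the Greenhouse-Geisser corrected p-value (``p_gg``)
    uses epsilon-shrunk degrees of freedom, otherwise ``p_gg`` equals
    the uncorrected ``p``.  Effect size is classical eta-squared,
    SS_effect / SS_total.

    Requires a balanced, complete design (the study design is balanced).
    """
    within = list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("supports exactly 1 or 2 within factors")
    y, groups, b_levels, c_levels = _cell_tensor(
        table, dv, subject, between, within)
    a, n, b, c = y.shape
    if n < 2:
        raise ValueError("need at least 2 subjects per group")

    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()

    m_a = y.mean(axis=(1, 2, 3))
    m_b = y.mean(axis=(0, 1, 3))
    m_c = y.mean(axis=(0, 1, 2))
    m_ab = y.mean(axis=(1, 3))
    m_ac = y.mean(axis=(1, 2))
    m_bc = y.mean(axis=(0, 1))
    m_abc = y.mean(axis=1)
    m_as = y.mean(axis=(2, 3))
    m_asb = y.mean(axis=3)
    m_asc = y.mean(axis=2)

    ss_a = n * b * c * ((m_a - grand) ** 2).sum()
    ss_s = b * c * ((m_as - m_a[:, None]) ** 2).sum()
    ss_b = a * n * c * ((m_b - grand) ** 2).sum()
    ss_ab = n * c * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_bs = c * ((m_asb - m_as[:, :, None] - m_ab[:, None, :]
                  + m_a[:, None, None]) ** 2).sum()
    ss_c = a * n * b * ((m_c - grand) ** 2).sum()
    ss_ac = n * b * ((m_ac - m_a[:, None] - m_c[None, :] + grand) ** 2).sum()
    ss_cs = b * ((m_asc - m_as[:, :, None] - m_ac[:, None, :]
                  + m_a[:, None, None]) ** 2).sum()
    ss_bc = a * n * ((m_bc - m_b[:, None] - m_c[None, :] + grand) ** 2).sum()
    ss_abc = n * ((m_abc - m_ab[:, :, None] - m_ac[:, None, :]
                   - m_bc[None, :, :] + m_a[:, None, None]
                   + m_b[None, :, None] + m_c[None, None, :] - grand) ** 2).sum()
    ss_bcs = ss_total - (ss_a + ss_s + ss_b + ss_ab + ss_bs
                         + ss_c + ss_ac + ss_cs + ss_bc + ss_abc)
    ss_bcs = max(ss_bcs, 0.0)

    w1 = within[0]
    w2 = within[1] if len(within) > 1 else None

    # Pooled within-group contrast covariances per within effect.  If the
    # design is too small to estimate the contrast covariance (error df
    # below the number of cells) no correction is applied.
    def _sph(scores, group_means, contrasts):
        centred = scores - np.repeat(group_means, n, axis=0)
        try:
            return mauchly_gg(centred + scores.mean(axis=0), n_groups=a,
                              contrasts=contrasts)
        except ValueError:
            return (np.nan, 1.0, 1.0)

    cb = _orthonormal_contrasts(b)
    sph: Dict[str, Tuple[float, float, float]] = {}
    if b > 2:
        sph[w1] = _sph(m_asb.reshape(a * n, b), m_ab, cb)
    else:
        sph[w1] = (1.0, 1.0, 1.0)
    if w2 is not None:
        cc = _orthonormal_contrasts(c)
        if c > 2:
            sph[w2] = _sph(m_asc.reshape(a * n, c), m_ac, cc)
        else:
            sph[w2] = (1.0, 1.0, 1.0)
        if b > 2 or c > 2:
            cells = y.reshape(a, n, b * c)
            sph[f"{w1}*{w2}"] = _sph(cells.reshape(a * n, b * c),
                                     cells.mean(axis=1), np.kron(cb, cc))
        else:
            sph[f"{w1}*{w2}"] = (1.0, 1.0, 1.0)

    def row(effect, ss, df1, ss_err, df2, eps_key=None):
        ms, ms_err = ss / df1, ss_err / df2
        F = ms / ms_err if ms_err > 0 else 0.0
        p = float(sps.f.sf(F, df1, df2)) if ms_err > 0 else 1.0
        W = mp = np.nan
        eps = 1.0
        p_gg, df1_gg, df2_gg = p, df1, df2
        if eps_key is not None:
            W, mp, eps = sph[eps_key]
            if mp < gg_alpha:
                df1_gg, df2_gg = df1 * eps, df2 * eps
                p_gg = float(sps.f.sf(F, df1_gg, df2_gg)) if ms_err > 0 else 1.0
        return {"effect": effect, "SS": ss, "df1": df1, "df2": df2, "F": F,
                "p": p, "eta_sq": ss / ss_total if ss_total > 0 else 0.0,
                "mauchly_W": W, "mauchly_p": mp, "gg_epsilon": eps,
                "df1_gg": df1_gg, "df2_gg": df2_gg, "p_gg": p_gg}

    rows = [
        row(between, ss_a, a - 1, ss_s, a * (n - 1)),
        row(w1, ss_b, b - 1, ss_bs, a * (n - 1) * (b - 1), w1),
        row(f"{between}*{w1}", ss_ab, (a - 1) * (b - 1),
            ss_bs, a * (n - 1) * (b - 1), w1),
    ]
    if w2 is not None:
        rows += [
            row(w2, ss_c, c - 1, ss_cs, a * (n - 1) * (c - 1), w2),
            row(f"{between}*{w2}", ss_ac, (a - 1) * (c - 1),
                ss_cs, a * (n - 1) * (c - 1), w2),
            row(f"{w1}*{w2}", ss_bc, (b - 1) * (c - 1),
                ss_bcs, a * (n - 1) * (b - 1) * (c - 1), f"{w1}*{w2}"),
            row(f"{between}*{w1}*{w2}", ss_abc, (a - 1) * (b - 1) * (c - 1),
                ss_bcs, a * (n - 1) * (b - 1) * (c - 1), f"{w1}*{w2}"),
        ]
    return pd.DataFrame(rows)


def bonferroni_alpha(alpha: float = 0.05, m: int = 3) -> float:
    """Family-wise corrected per-comparison threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def posthoc_chain(groups: Mapping[str, object], m: int | None = None,
                  alpha: float = 0.05,
                  welch: Mapping[Tuple[str, str], bool] | bool | None = None,
                  prior_scale: float = DEFAULT_PRIOR_SCALE,
                  pairs: Sequence[Tuple[str, str]] | None = None
                  ) -> List[StatResult]:
    """All pairwise post-hoc comparisons of the given groups.

    For raw samples the Student/Welch choice is gated per pair by
    Levene's test (Welch when Levene p < .05); for summary statistics
    Levene is not computable and ``welch`` must supply the choice (bool
    for all pairs or a per-pair mapping; default Student).  Each result
    carries Cohen's d, the JZS BF10 (computed from the Student t with
    pooled df; with equal group sizes the Student and Welch t coincide),
    and the Bonferroni flag at alpha / m.
    """
    names = list(groups)
    if pairs is None:
        pairs = list(itertools.combinations(names, 2))
    m = m if m is not None else len(pairs)
    thresh = bonferroni_alpha(alpha, m)
    out = []
    for pair in pairs:
        g1, g2 = groups[pair[0]], groups[pair[1]]
        raw = not (isinstance(g1, SummaryStats) or isinstance(g2, SummaryStats))
        if raw:
            _, lev_p = levene_test(np.asarray(g1, float), np.asarray(g2, float))
            use_welch = bool(lev_p < 0.05)
        elif isinstance(welch, Mapping):
            use_welch = bool(welch.get(tuple(pair),
                                       welch.get((pair[1], pair[0]), False)))
        else:
            use_welch = bool(welch)
        t, df = independent_t(g1, g2, welch=use_welch)
        p = float(2.0 * sps.t.sf(abs(t), df))
        d = cohens_d(g1, g2)
        s1, s2 = summarize(g1), summarize(g2)
        t_student, _ = independent_t(s1, s2, welch=False)
        bf = bf10_jzs(t_student, s1.n, s2.n, r=prior_scale)
        out.append(StatResult(
            pair=tuple(pair), test="welch_t" if use_welch else "student_t",
            t=t, df=df, p=p, d=d, bf10=bf, alpha_corrected=thresh,
            significant=bool(p < thresh)))
    return out


def results_frame(results: Iterable[StatResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


# ---------------------------------------------------------------------------
# Worked-example regression against the published summary table
# ---------------------------------------------------------------------------

def load_reference_stats() -> dict:
    """Bundled published latency summaries and reported post-hoc results."""
    with resources.files("erpcompare.data").joinpath(
            "reference_stats.json").open() as fh:
        return json.load(fh)


def reproduce_reference(prior_scale: float = DEFAULT_PRIOR_SCALE
                        ) -> pd.DataFrame:
    """Recompute every reported latency post-hoc from the group summaries.

    For each published comparison the t (Student or Welch, as reported),
    its df, Cohen's d and the JZS BF10 are recomputed from (mean, SD, n)
    and set against the printed values.  Magnitudes are compared;
    printed sign conventions varied by pair ordering.
    """
    ref = load_reference_stats()
    rows = []
    for rep in ref["reported_posthoc"]:
        comp = rep["component"]
        s = {g: SummaryStats(**v) for g, v in
             ref["latency_summaries"][comp].items()}
        g1, g2 = rep["pair"]
        use_welch = rep["test"] == "welch"
        t, df = independent_t(s[g1], s[g2], welch=use_welch)
        p = float(2.0 * sps.t.sf(abs(t), df))
        d = cohens_d(s[g1], s[g2])
        t_stud, _ = independent_t(s[g1], s[g2], welch=False)
        bf = bf10_jzs(t_stud, s[g1].n, s[g2].n, r=prior_scale)
        rows.append({
            "component": comp, "pair": f"{g1}-{g2}", "test": rep["test"],
            "t": t, "t_reported": rep["t"],
            "df": df, "df_reported": rep["df"],
            "d": d, "d_reported": rep["d"],
            "bf10": bf, "bf10_reported": rep["bf10"],
            "p": p, "significant": p < bonferroni_alpha(
                ref["alpha"], ref["n_comparisons_per_family"]),
            "significant_reported": rep["significant"],
        })
    return pd.DataFrame(rows)
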