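"""Inferential toolkit used by the gaze analyses.

Implements, from formulas, the tests the experiments rely on: one-sample /
paired / independent t tests, default (JZS) Bayes factors for those designs,
balanced repeated-measures and split-plot (mixed) ANOVA with
Greenhouse-Geisser correction triggered by Mauchly's sphericity test, simple
main effects with slice-specific error terms, and Bonferroni-adjusted
pairwise comparisons.

The JZS Bayes factor follows the default-prior construction for t designs: a
Cauchy prior with scale ``r`` on the standardised effect size and a Jeffreys
prior on the variance.  Writing the Cauchy as a scale mixture of normals,

    BF10 = [ integral_0^inf (1 + N r^2 g)^(-1/2)
             * (1 + t^2 / ((1 + N r^2 g) nu))^(-(nu+1)/2)
             * (2 pi)^(-1/2) g^(-3/2) exp(-1/(2 g)) dg ]
           / (1 + t^2/nu)^(-(nu+1)/2),

with effective sample size N (= n for one-sample/paired, n1 n2/(n1+n2) for
independent groups) and degrees of freedom nu.  The integral is evaluated by
adaptive quadrature on the half-line; the same integrand can be checked
against the R ``BayesFactor`` package.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "BayesFactorResult",
    "AnovaResult",
    "t_test",
    "jzs_bf",
    "rm_anova",
    "simple_main_effects",
    "bonferroni_pairwise",
]

ALPHA = 0.05  # two-sided decision threshold used throughout
MAUCHLY_ALPHA = 0.05  # sphericity-violation threshold triggering GG


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    n: int
    p: float
    design: str
    mean: float  # mean difference (or mean - mu)

    def __post_init__(self) -> None:
        expected = {"one_sample": self.n - 1, "paired": self.n - 1}.get(self.design)
        if expected is not None and self.df != expected:
            raise ValueError("df inconsistent with design and n")


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    r: float
    quadrature_error: float

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10

    @property
    def direction(self) -> str:
        return "alternative" if self.bf10 > 1 else "null"

    def report(self) -> str:
        """The value the way results sections print it: the factor in favor
        of the better-supported hypothesis."""
        value = self.bf10 if self.bf10 > 1 else self.bf01
        return f"BF = {value:.2f} in favor of the {self.direction}"


def t_test(x, y=None, design: str = "one_sample", mu: float = 0.0) -> TTestResult:
    """Student t test (two-sided).

    one_sample: x against mu.  paired: x - y against 0.  independent: pooled-
    variance two-sample test.  Degenerate (zero-variance) input is an error.
    """
    x = np.asarray(x, dtype=float)
    if design in ("one_sample", "paired"):
        d = x - mu if design == "one_sample" else x - np.asarray(y, dtype=float)
        n = d.size
        if n < 2:
            raise ValueError("need at least two observations")
        sd = d.std(ddof=1)
        if sd == 0:
            raise ValueError("zero variance: t statistic undefined")
        t = d.mean() / (sd / np.sqrt(n))
        df = n - 1
        mean = float(d.mean())
    elif design == "independent":
        y = np.asarray(y, dtype=float)
        n1, n2 = x.size, y.size
        if n1 < 2 or n2 < 2:
            raise ValueError("need at least two observations per group")
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
        if sp2 == 0:
            raise ValueError("zero variance: t statistic undefined")
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        n = n1 + n2
        mean = float(x.mean() - y.mean())
    else:
        raise ValueError(f"unknown design {design!r}")
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), int(df), int(n), float(p), design, mean)


def jzs_bf(t: float, n1: int, n2: int | None = None, r: float = 0.707) -> BayesFactorResult:
    """Default JZS Bayes factor for a t statistic.

    One-sample/paired designs use N = n1, nu = n1 - 1; independent-groups
    designs use N = n1 n2 / (n1 + n2), nu = n1 + n2 - 2.  The mixture
    integral is evaluated with an adaptive rule on the transformed half-line
    g = z / (1 - z); failure to converge raises rather than returning a
    silently truncated value.
    """
    if not np.isfinite(t):
        raise ValueError("t must be finite")
    if n1 < 2:
        raise ValueError("n1 must be >= 2")
    if n2 is None:
        N, nu = float(n1), n1 - 1
    else:
        N, nu = n1 * n2 / (n1 + n2), n1 + n2 - 2

    def integrand(z: float) -> float:
        g = z / (1.0 - z)
        jac = 1.0 / (1.0 - z) ** 2
        a = 1.0 + N * r * r * g
        return (
            a ** -0.5
            * (1.0 + t * t / (a * nu)) ** (-(nu + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g ** -1.5
            * np.exp(-1.0 / (2 * g))
            * jac
        )

    num, err = integrate.quad(integrand, 0.0, 1.0, epsabs=1e-12, epsrel=1e-8,
                              limit=200)
    if not np.isfinite(num) or num <= 0:
        raise ArithmeticError("JZS quadrature failed to converge")
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2)
    bf10 = num / den
    if err / num > 1e-6:
        raise ArithmeticError(f"JZS quadrature error too large ({err/num:.2e})")
    return BayesFactorResult(float(bf10), r, float(err / num))


# ---------------------------------------------------------------------------
# repeated-measures / split-plot ANOVA


@dataclass
class AnovaResult:
    """Per-effect table of a repeated-measures or split-plot ANOVA.

    ``table`` holds one row per effect: F, df pair, p, partial eta squared
    and, for within effects with more than one numerator df, the
    Greenhouse-Geisser epsilon, Mauchly test, and the corrected df/p used
    when sphericity is rejected.  ``p_reported`` is the corrected p where the
    correction applies and the uncorrected p otherwise.
    """

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect named {name!r}")
        return rows.iloc[0]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal basis orthogonal to the unit vector (Helmert)."""
    h = np.zeros((k - 1, k))
    for i in range(1, k):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def _effect_contrast(levels: list[int], subset: tuple[int, ...]) -> np.ndarray:
    """Orthonormal contrast matrix of a within effect over the flattened cell
    axis: Kronecker product of per-factor contrast bases (mean rows for
    factors outside the effect)."""
    mat = np.ones((1, 1))
    for i, k in enumerate(levels):
        block = (_orthonormal_contrasts(k) if i in subset
                 else np.full((1, k), 1 / np.sqrt(k)))
        mat = np.kron(mat, block)
    return mat


def _center(arr: np.ndarray, axis: int) -> np.ndarray:
    return arr - arr.mean(axis=axis, keepdims=True)


def rm_anova(data: pd.DataFrame, dv: str, within, subject: str,
             between: str | None = None) -> AnovaResult:
    """Balanced repeated-measures ANOVA, optionally with one between factor.

    Sums of squares follow the classical subject-within decomposition: each
    within effect is evaluated against its interaction with subjects (nested
    in groups for split-plot designs), the between factor against subjects
    within groups.  Every subject must contribute exactly one observation per
    within-cell; unbalanced cells raise.  Unequal group sizes are handled
    with weighted (per-subject) means.

    GG epsilon is computed from the pooled covariance of the effect's
    orthonormal contrast scores and applied when Mauchly's test rejects at
    .05 (trivially skipped for single-df effects).
    """
    within = list(within)
    if not within:
        raise ValueError("need at least one within factor")
    levels = {w: sorted(data[w].unique()) for w in within}
    shape = [len(levels[w]) for w in within]
    n_cells = int(np.prod(shape))

    counts = data.groupby([subject] + within, observed=True)[dv].count()
    if (counts != 1).any():
        raise ValueError("unbalanced within-factor cells: every subject needs "
                         "exactly one observation per cell")

    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            sort=True)
    # order columns lexicographically over level order
    cols = list(itertools.product(*[levels[w] for w in within]))
    wide = wide[cols if len(within) > 1 else [c[0] for c in cols]]
    if wide.isna().any().any():
        raise ValueError("missing cells")

    if between is not None:
        grp = data.groupby(subject, observed=True)[between].agg(
            lambda s: s.iloc[0])
        n_mix = data.groupby(subject, observed=True)[between].nunique()
        if (n_mix != 1).any():
            raise ValueError("between factor must be constant within subject")
        group_labels = sorted(grp.unique())
        groups = [wide.loc[sorted(grp[grp == g].index)].to_numpy()
                  for g in group_labels]
    else:
        group_labels = ["_all"]
        groups = [wide.to_numpy()]

    G = len(groups)
    ns = [g.shape[0] for g in groups]
    N = sum(ns)
    rows = []

    # ---- between-subject stratum
    subj_means = [g.mean(axis=1) for g in groups]
    grand = float(np.concatenate(subj_means).mean())
    ss_subj_within = n_cells * sum(((m - m.mean()) ** 2).sum()
                                   for m in subj_means)
    df_subj_within = N - G
    if between is not None:
        ss_b = n_cells * sum(n * (m.mean() - grand) ** 2
                             for n, m in zip(ns, subj_means))
        df_b = G - 1
        ms_b, ms_e = ss_b / df_b, ss_subj_within / df_subj_within
        f = ms_b / ms_e
        rows.append({
            "effect": between, "SS": ss_b, "df1": df_b, "df2": df_subj_within,
            "F": f, "p": float(sps.f.sf(f, df_b, df_subj_within)),
            "np2": ss_b / (ss_b + ss_subj_within),
            "eps": np.nan, "mauchly_W": np.nan, "mauchly_p": np.nan,
            "sphericity_corrected": False, "df1_corr": df_b,
            "df2_corr": df_subj_within, "p_reported": float(
                sps.f.sf(f, df_b, df_subj_within)),
        })

    # ---- within-subject strata
    axes = tuple(range(len(within)))
    for k in range(1, len(within) + 1):
        for subset in itertools.combinations(axes, k):
            name = " * ".join(within[i] for i in subset)
            df_eff = int(np.prod([shape[i] - 1 for i in subset]))
            m_rest = int(np.prod([shape[i] for i in axes if i not in subset]))

            # per-subject effect scores: center over effect axes, average out
            # the others
            zs = []
            for g in groups:
                arr = g.reshape((g.shape[0],) + tuple(shape))
                z = arr
                for i in subset:
                    z = _center(z, axis=1 + i)
                other = tuple(1 + i for i in axes if i not in subset)
                if other:
                    z = z.mean(axis=other)
                zs.append(z.reshape(g.shape[0], -1))

            zbar_g = [z.mean(axis=0) for z in zs]
            zbar = sum(n * zb for n, zb in zip(ns, zbar_g)) / N
            ss_eff = m_rest * N * float((zbar ** 2).sum())
            ss_err = m_rest * sum(float(((z - zb) ** 2).sum())
                                  for z, zb in zip(zs, zbar_g))
            df_err = df_eff * (N - G)

            sub_rows = [(name, ss_eff, df_eff)]
            if between is not None:
                ss_int = m_rest * sum(
                    n * float(((zb - zbar) ** 2).sum())
                    for n, zb in zip(ns, zbar_g))
                sub_rows.append((f"{name} * {between}", ss_int,
                                 df_eff * (G - 1)))

            # GG epsilon / Mauchly from the pooled contrast covariance
            C = _effect_contrast(shape, subset)
            eps, W, p_m = 1.0, np.nan, np.nan
            if df_eff > 1 and N - G > df_eff:
                U = [g @ C.T for g in groups]
                S = sum(((u - u.mean(axis=0)).T @ (u - u.mean(axis=0)))
                        for u in U) / (N - G)
                tr = np.trace(S)
                eps = float(tr ** 2 / (df_eff * (S ** 2).sum()))
                eps = min(max(eps, 1.0 / df_eff), 1.0)
                detS = np.linalg.det(S)
                mean_eig = tr / df_eff
                if detS > 0 and mean_eig > 0:
                    W = float(detS / mean_eig ** df_eff)
                    d = df_eff
                    factor = (N - G) - (2 * d * d + d + 2) / (6 * d)
                    chi2 = -factor * np.log(W)
                    df_m = d * (d + 1) // 2 - 1
                    p_m = float(sps.chi2.sf(chi2, df_m))
                else:
                    W, p_m = 0.0, 0.0

            for eff_name, ss, df1 in sub_rows:
                ms, ms_e = ss / df1, ss_err / df_err
                # a zero effect against a zero error term is no effect at all
                f = 0.0 if ms == 0 else (ms / ms_e if ms_e > 0 else np.inf)
                p = float(sps.f.sf(f, df1, df_err))
                np2 = ss / (ss + ss_err) if ss + ss_err > 0 else 0.0
                corrected = df_eff > 1 and not np.isnan(p_m) and p_m < MAUCHLY_ALPHA
                df1c, df2c = (df1 * eps, df_err * eps) if corrected else (df1, df_err)
                p_rep = float(sps.f.sf(f, df1c, df2c))
                rows.append({
                    "effect": eff_name, "SS": ss, "df1": df1, "df2": df_err,
                    "F": f, "p": p, "np2": np2,
                    "eps": eps if df_eff > 1 else 1.0,
                    "mauchly_W": W, "mauchly_p": p_m,
                    "sphericity_corrected": bool(corrected),
                    "df1_corr": df1c, "df2_corr": df2c,
                    "p_reported": p_rep if corrected else p,
                })
    return AnovaResult(pd.DataFrame(rows))


def simple_main_effects(data: pd.DataFrame, dv: str, factor: str, at: str,
                        subject: str, between: str | None = None) -> pd.DataFrame:
    """Effect of ``factor`` at each level of ``at``.

    Each slice is analysed with its own (level-specific) error term: a
    one-within-factor ANOVA when ``factor`` varies within subjects, a one-way
    between-groups ANOVA when ``factor`` is the between factor.
    """
    rows = []
    for level in sorted(data[at].unique()):
        chunk = data[data[at] == level]
        if between is not None and factor == between:
            groups = [g[dv].to_numpy() for _, g in chunk.groupby(factor)]
            k, n = len(groups), sum(len(g) for g in groups)
            grand = np.concatenate(groups).mean()
            ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
            ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
            df1, df2 = k - 1, n - k
            f = (ssb / df1) / (ssw / df2) if ssw > 0 else np.inf
            p = float(sps.f.sf(f, df1, df2))
        else:
            res = rm_anova(chunk, dv=dv, within=[factor], subject=subject)
            row = res.effect(factor)
            f, df1, df2, p = row["F"], row["df1"], row["df2"], row["p_reported"]
        rows.append({"at": level, "F": float(f), "df1": df1, "df2": df2,
                     "p": p, "significant": p < ALPHA})
    return pd.DataFrame(rows)


def bonferroni_pairwise(groups: dict, design: str = "independent") -> pd.DataFrame:
    """All pairwise t tests between groups, p multiplied by the number of
    comparisons and capped at 1."""
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        if design == "paired":
            res = t_test(groups[a], groups[b], design="paired")
        else:
            res = t_test(groups[a], groups[b], design="independent")
        rows.append({"a": a, "b": b, "t": res.t, "df": res.df, "p": res.p,
                     "p_bonf": min(res.p * m, 1.0), "n_comparisons": m})
    return pd.DataFrame(rows)
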