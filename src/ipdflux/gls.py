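"""Quadratic response-surface GLS with heterogeneous compound symmetry.

The repeated-measures model for a response measured on each plot in each of
m seasons: fixed effects are polynomial (up to quadratic) functions of the
warming and CO2 dose levels, season, and their interactions; the residual
covariance within a plot is compound-symmetric across seasons with
season-specific variances, Σ = D(σ_season) R(ρ) D(σ_season), independent
between plots.  Variance parameters are estimated by REML (profile over the
fixed effects), fixed effects by generalized least squares at the REML
estimates, and each term is tested with a Wald F using a between–within
(containment) denominator-df split.

Dose levels are coded 0/1/2 (ambient, mid, high) for both factors so the
linear and quadratic terms are well scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps
from scipy.special import expit, logit

from .design import SEASONS

#: candidate fixed-effect terms of the full quadratic response-surface model
ALL_TERMS = (
    "season",
    "co2",
    "temp",
    "temp2",
    "co22",
    "season:co2",
    "season:temp",
    "co2:temp",
    "season:temp2",
    "season:co22",
    "season:co2:temp",
)

#: direct marginality parents (an interaction/quadratic implies these)
TERM_PARENTS: dict[str, frozenset[str]] = {
    "season": frozenset(),
    "co2": frozenset(),
    "temp": frozenset(),
    "temp2": frozenset({"temp"}),
    "co22": frozenset({"co2"}),
    "season:co2": frozenset({"season", "co2"}),
    "season:temp": frozenset({"season", "temp"}),
    "co2:temp": frozenset({"co2", "temp"}),
    "season:temp2": frozenset({"season:temp", "temp2"}),
    "season:co22": frozenset({"season:co2", "co22"}),
    "season:co2:temp": frozenset({"season:co2", "season:temp", "co2:temp"}),
}


def marginality_closure(terms) -> set[str]:
    """All terms implied by ``terms`` under the marginality principle."""
    out: set[str] = set()
    stack = list(terms)
    while stack:
        t = stack.pop()
        if t not in out:
            out.add(t)
            stack.extend(TERM_PARENTS[t])
    return out


def is_marginality_closed(terms) -> bool:
    terms = set(terms)
    return marginality_closure(terms) == terms


@dataclass
class ModelSpec:
    """Response, candidate terms, and transform for one GLS analysis."""

    response: str
    terms: tuple[str, ...] = ALL_TERMS
    transform: str = "none"  # "none" | "log"
    alpha: float = 0.05
    subject: str = "plot_id"
    season_col: str = "season"
    temp_col: str = "temp_level"
    co2_col: str = "co2_level"

    def __post_init__(self) -> None:
        unknown = set(self.terms) - set(ALL_TERMS)
        if unknown:
            raise ValueError(f"unknown terms: {sorted(unknown)}")
        if not is_marginality_closed(self.terms):
            raise ValueError(
                "term set is not marginality-closed: "
                f"missing {sorted(marginality_closure(self.terms) - set(self.terms))}"
            )
        if self.transform not in {"none", "log"}:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class ModelFitResult:
    """Fitted fixed effects, covariance structure, and per-term F-tests."""

    spec: ModelSpec
    terms: tuple[str, ...]
    coefficients: pd.Series
    cov_coefficients: pd.DataFrame
    rho: float
    season_sd: dict[str, float]
    loglik: float
    anova: pd.DataFrame  # term, num_df, den_df, F, p
    n_obs: int
    n_subjects: int
    reduction_trail: list = field(default_factory=list)

    def term_p(self, term: str) -> float:
        row = self.anova[self.anova.term == term]
        return float(row.p.iloc[0]) if len(row) else np.nan


def _term_columns(term: str, season_dummies: np.ndarray, t: np.ndarray,
                  c: np.ndarray, season_names: list[str]):
    """Design columns and names for one model term."""
    base = {
        "co2": (c[:, None], ["co2"]),
        "temp": (t[:, None], ["temp"]),
        "temp2": ((t**2)[:, None], ["temp2"]),
        "co22": ((c**2)[:, None], ["co22"]),
        "co2:temp": ((c * t)[:, None], ["co2:temp"]),
    }
    if term in base:
        return base[term]
    if term == "season":
        return season_dummies, [f"season[{s}]" for s in season_names[1:]]
    factor = {
        "season:co2": (c, "co2"),
        "season:temp": (t, "temp"),
        "season:temp2": (t**2, "temp2"),
        "season:co22": (c**2, "co22"),
        "season:co2:temp": (c * t, "co2:temp"),
    }[term]
    vec, label = factor
    cols = season_dummies * vec[:, None]
    names = [f"season[{s}]:{label}" for s in season_names[1:]]
    return cols, names


def build_design(df: pd.DataFrame, spec: ModelSpec):
    """Build the design matrix for ``spec.terms`` on ``df``.

    Returns (X, column_names, term_slices) where term_slices maps each term
    (plus "Intercept") to its column indices.
    """
    season_names = [s for s in SEASONS if s in set(df[spec.season_col])]
    extra = sorted(set(df[spec.season_col]) - set(season_names))
    season_names += extra
    codes = pd.Categorical(
        df[spec.season_col], categories=season_names
    ).codes.astype(int)
    m = len(season_names)
    dummies = np.zeros((len(df), m - 1))
    for j in range(1, m):
        dummies[codes == j, j - 1] = 1.0

    t = df[spec.temp_col].to_numpy(float) / 1.5
    c = df[spec.co2_col].to_numpy(float) / 150.0

    blocks = [np.ones((len(df), 1))]
    names = ["Intercept"]
    term_slices: dict[str, list[int]] = {"Intercept": [0]}
    pos = 1
    for term in spec.terms:
        cols, cnames = _term_columns(term, dummies, t, c, season_names)
        blocks.append(cols)
        names.extend(cnames)
        term_slices[term] = list(range(pos, pos + cols.shape[1]))
        pos += cols.shape[1]
    X = np.hstack(blocks)

    # alias check via pivoted QR
    r_diag = np.abs(np.diag(np.linalg.qr(X, mode="r")))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        scale = np.max(r_diag)
        aliased = [names[i] for i in range(len(names)) if r_diag[i] < 1e-10 * scale]
        raise ValueError(
            f"singular design: aliased columns {aliased or '(undetermined)'}"
        )
    return X, names, term_slices, codes, season_names


class _REMLProblem:
    """Pattern-grouped REML objective for heterogeneous CS covariance."""

    def __init__(self, y, X, subject_codes, season_codes, m_seasons,
                 reml=True, fix_rho=None, homoscedastic=False):
        self.m = m_seasons
        self.reml = reml
        self.fix_rho = fix_rho
        self.homoscedastic = homoscedastic
        self.n, self.p = X.shape
        self.rho_lo = -1.0 / (m_seasons - 1) if m_seasons > 1 else -1.0

        order = np.lexsort((season_codes, subject_codes))
        y, X = y[order], X[order]
        subject_codes = subject_codes[order]
        season_codes = season_codes[order]

        # group subjects by their season pattern
        self.groups = []
        self.raw_groups = []
        subjects, starts = np.unique(subject_codes, return_index=True)
        bounds = list(starts) + [len(y)]
        patterns: dict[tuple, list[int]] = {}
        for si in range(len(subjects)):
            lo, hi = bounds[si], bounds[si + 1]
            pat = tuple(season_codes[lo:hi])
            patterns.setdefault(pat, []).append(si)
        for pat, subj_list in patterns.items():
            rows = np.concatenate(
                [np.arange(bounds[si], bounds[si + 1]) for si in subj_list]
            )
            k = len(subj_list)
            mp = len(pat)
            Y = y[rows].reshape(k, mp)
            XX = X[rows].reshape(k, mp, self.p)
            # season-pair cross-products: the covariance weights are the only
            # per-iteration quantities, so X'V⁻¹X etc. reduce to weighted sums
            gxx = np.einsum("kma,knb->mnab", XX, XX)
            gxy = np.einsum("kma,kn->mna", XX, Y)
            gyy = np.einsum("km,kn->mn", Y, Y)
            self.groups.append((np.asarray(pat, int), k, gxx, gxy, gyy))
            self.raw_groups.append((np.asarray(pat, int), Y, XX))
        self.n_subjects = len(subjects)

    @property
    def balanced(self) -> bool:
        """True when every subject has the complete season set, in order."""
        return len(self.raw_groups) == 1 and len(self.raw_groups[0][0]) == self.m

    def n_var_params(self) -> int:
        return 1 if self.homoscedastic else self.m

    def unpack(self, x):
        if self.fix_rho is None:
            rho = self.rho_lo + (1.0 - self.rho_lo) * expit(x[0])
            log_sd = x[1:]
        else:
            rho = self.fix_rho
            log_sd = x
        if self.homoscedastic:
            sd = np.full(self.m, np.exp(log_sd[0]))
        else:
            sd = np.exp(log_sd)
        return rho, sd

    def _assemble(self, rho, sd):
        """Accumulate GLS quantities over pattern groups."""
        p = self.p
        xtwx = np.zeros((p, p))
        xtwy = np.zeros(p)
        ytwy = 0.0
        logdet_v = 0.0
        for pat, k, gxx, gxy, gyy in self.groups:
            s = sd[pat]
            mp = len(pat)
            sigma = np.outer(s, s) * (
                np.full((mp, mp), rho) + (1 - rho) * np.eye(mp)
            )
            sign, ld = np.linalg.slogdet(sigma)
            if sign <= 0:
                return None
            w = np.linalg.inv(sigma)
            logdet_v += k * ld
            xtwx += np.tensordot(w, gxx, axes=([0, 1], [0, 1]))
            xtwy += np.tensordot(w, gxy, axes=([0, 1], [0, 1]))
            ytwy += float(np.sum(w * gyy))
        return xtwx, xtwy, ytwy, logdet_v

    def neg_loglik(self, x) -> float:
        rho, sd = self.unpack(x)
        out = self._assemble(rho, sd)
        if out is None:
            return 1e12
        xtwx, xtwy, ytwy, logdet_v = out
        try:
            beta = np.linalg.solve(xtwx, xtwy)
        except np.linalg.LinAlgError:
            return 1e12
        ypy = ytwy - xtwy @ beta
        ll = -0.5 * (logdet_v + ypy)
        if self.reml:
            sign, ld_x = np.linalg.slogdet(xtwx)
            if sign <= 0:
                return 1e12
            ll -= 0.5 * ld_x
        return -ll

    def solve(self, x):
        rho, sd = self.unpack(x)
        xtwx, xtwy, ytwy, logdet_v = self._assemble(rho, sd)
        beta = np.linalg.solve(xtwx, xtwy)
        cov = np.linalg.inv(xtwx)
        return rho, sd, beta, cov


def _initial_params(problem: _REMLProblem, y, X, season_codes):
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    if problem.homoscedastic:
        log_sd = [np.log(resid.std() + 1e-8)]
    else:
        log_sd = [
            np.log(resid[season_codes == j].std() + 1e-8)
            for j in range(problem.m)
        ]
    if problem.fix_rho is not None:
        return np.asarray(log_sd)
    return np.asarray([logit(0.55)] + log_sd)  # mild positive start for rho


def fit_gls(
    df: pd.DataFrame,
    spec: ModelSpec,
    reml: bool = True,
    fix_rho: float | None = None,
    homoscedastic: bool = False,
) -> ModelFitResult:
    """Fit the heterogeneous-CS GLS model and compute per-term Wald F-tests.

    ``fix_rho``/``homoscedastic`` constrain the covariance (``fix_rho=0`` with
    ``homoscedastic=True`` reduces the fixed-effect solution to OLS).
    """
    data = df.dropna(subset=[spec.response]).reset_index(drop=True)
    y = data[spec.response].to_numpy(float)
    if spec.transform == "log":
        if np.any(y <= 0):
            raise ValueError(
                f"log transform requested but {spec.response} has values <= 0"
            )
        y = np.log(y)

    X, names, term_slices, season_codes, season_names = build_design(data, spec)
    subject_codes = pd.Categorical(data[spec.subject]).codes.astype(int)
    m = len(season_names)

    problem = _REMLProblem(
        y, X, subject_codes, season_codes, m,
        reml=reml, fix_rho=fix_rho, homoscedastic=homoscedastic,
    )
    x0 = _initial_params(problem, y, X, season_codes)
    res = optimize.minimize(
        problem.neg_loglik, x0, method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-9, "maxiter": 1000},
    )
    if not res.success:  # pragma: no cover - rare
        warnings.warn(f"variance optimization did not converge: {res.message}")
    rho, sd, beta, cov = problem.solve(res.x)
    loglik = -problem.neg_loglik(res.x)

    # between-within df split: a column is "between" if constant within subject
    is_between = []
    for j in range(X.shape[1]):
        col = X[:, j]
        dev = pd.Series(col).groupby(subject_codes).transform("mean").to_numpy()
        is_between.append(np.max(np.abs(col - dev)) < 1e-10)
    is_between = np.asarray(is_between)
    g = problem.n_subjects
    n = len(y)
    p_between = int(is_between.sum())
    p_within = X.shape[1] - p_between
    df_between = max(g - p_between, 1)
    df_within = max(n - g - p_within, 1)

    # Between-plot terms are tested in the between stratum proper: an OLS
    # F on covariance-weighted plot means, which is exact under the model
    # (conditional on the weights) for balanced data.  Within-plot terms use
    # the Wald F with the containment df.
    between_tests: dict[str, tuple[float, float, int]] = {}
    if problem.balanced and df_between >= 1:
        pat, Y, XX = problem.raw_groups[0]
        # unweighted season means: for balanced data the plot means are iid
        # with a common variance whatever (rho, sigma_season) are, so the
        # between-stratum F is exact, like the classic split-plot analysis
        m_means = Y.mean(axis=1)
        xb = XX[:, 0, :][:, is_between]
        bb, *_ = np.linalg.lstsq(xb, m_means, rcond=None)
        rss = float(np.sum((m_means - xb @ bb) ** 2))
        sigma2_b = rss / df_between
        cov_b = sigma2_b * np.linalg.inv(xb.T @ xb)
        col_of = {j: jj for jj, j in enumerate(np.flatnonzero(is_between))}
        for term in spec.terms:
            idx = term_slices[term]
            if not bool(is_between[idx].all()):
                continue
            bidx = [col_of[j] for j in idx]
            bt = bb[bidx]
            ct = cov_b[np.ix_(bidx, bidx)]
            f_stat = float(bt @ np.linalg.solve(ct, bt)) / len(idx)
            between_tests[term] = (
                f_stat, float(sps.f.sf(f_stat, len(idx), df_between)), df_between
            )

    rows = []
    for term in spec.terms:
        idx = term_slices[term]
        q = len(idx)
        if term in between_tests:
            f_stat, p_val, den = between_tests[term]
        else:
            b = beta[idx]
            c_tt = cov[np.ix_(idx, idx)]
            f_stat = float(b @ np.linalg.solve(c_tt, b)) / q
            den = df_between if bool(is_between[idx].all()) else df_within
            p_val = float(sps.f.sf(f_stat, q, den))
        rows.append(
            {"term": term, "num_df": q, "den_df": den, "F": f_stat, "p": p_val}
        )

    return ModelFitResult(
        spec=spec,
        terms=tuple(spec.terms),
        coefficients=pd.Series(beta, index=names),
        cov_coefficients=pd.DataFrame(cov, index=names, columns=names),
        rho=float(rho),
        season_sd={season_names[j]: float(sd[j]) for j in range(m)},
        loglik=float(loglik),
        anova=pd.DataFrame(rows),
        n_obs=n,
        n_subjects=g,
    )
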