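"""Trait-behavior association inference.

Behavioral/physiological measures (rows: participant x topic) are
winsorized at 3 SD and z-standardized, then each trait factor is
related to each measure with a linear mixed model containing a random
intercept per participant. With exactly one observation per
participant-topic cell, a topic-within-participant random component
adds sigma^2 * I to each participant's covariance and is therefore
indistinguishable from the residual: the random-intercept model is the
identifiable equivalent and is the default; the literal
variance-component parameterization can be requested and falls back to
the intercept-only fit on failure.

Reported per test: standardized beta, Wald 95% CI (beta +/- 1.96 SE),
t = beta / SE with df = number of participants - 2, two-sided p, and
Benjamini-Hochberg FDR-adjusted p over the family of all trait x
measure tests in the run. Cross-trait similarity of behavioral
signatures is the Pearson correlation between two traits' beta
vectors over the nine measures, with a Fisher-z confidence interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .synthetic_dyads import MEASURES, TRAIT_NAMES

__all__ = [
    "ModelResult",
    "PatternSimilarity",
    "winsorize_and_standardize",
    "fit_trait_model",
    "fit_all",
    "bh_fdr",
    "pattern_correlation",
    "pattern_similarity_table",
    "power_correlation",
    "expected_chance_count",
]


@dataclass
class ModelResult:
    trait: str
    measure: str
    beta: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    p_adj: float = float("nan")
    n_obs: int = 0
    n_participants: int = 0
    fallback: bool = False


@dataclass
class PatternSimilarity:
    pair: tuple[str, str]
    r: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float


def winsorize_and_standardize(
    matrix: pd.DataFrame, sd_limit: float = 3.0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per measure, pooled over all observations: clip values beyond
    ``sd_limit`` SDs from the mean to the limit (mean/SD from the
    original data), then z-score with the post-winsorization moments.

    Returns the transformed matrix and the percentage of corrected
    observations per measure. Non-measure columns pass through.
    """
    out = matrix.copy()
    corrected: dict[str, float] = {}
    for col in MEASURES:
        if col not in out.columns:
            continue
        x = out[col].to_numpy(dtype=float)
        finite = np.isfinite(x)
        if finite.sum() < 3:
            raise ValueError(f"measure '{col}' has fewer than 3 observations")
        mu, sd = x[finite].mean(), x[finite].std(ddof=1)
        if sd == 0:
            raise ValueError(f"measure '{col}' has zero variance")
        lo, hi = mu - sd_limit * sd, mu + sd_limit * sd
        clipped = np.clip(x, lo, hi)
        corrected[col] = 100.0 * float(
            np.sum((x[finite] < lo) | (x[finite] > hi)) / finite.sum()
        )
        mu2, sd2 = clipped[finite].mean(), clipped[finite].std(ddof=1)
        out[col] = (clipped - mu2) / sd2
    return out, corrected


def fit_trait_model(
    matrix: pd.DataFrame,
    factors: pd.DataFrame,
    trait: str,
    measure: str,
    include_topic_vc: bool = False,
    df_convention: str = "n_minus_2",
) -> ModelResult:
    """Mixed-model association between one trait factor and one measure.

    ``matrix`` holds standardized per-topic measures with columns
    ``participant`` and ``topic``; ``factors`` the standardized factor
    scores per ``participant_id``. The trait enters as a fixed effect
    with a random intercept per participant (see module docstring for
    why this is the identifiable form of the topic-within-participant
    structure; ``include_topic_vc=True`` requests the literal
    parameterization, falling back on failure).
    """
    f = factors.set_index("participant_id")[trait]
    d = matrix[["participant", "topic", measure]].copy()
    d["trait"] = d["participant"].map(f)
    d = d.dropna(subset=[measure, "trait"])
    n_participants = d["participant"].nunique()
    if n_participants < 3:
        raise ValueError("too few participants with data")
    y = d[measure].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(d)), d["trait"].to_numpy(dtype=float)])
    groups = d["participant"].to_numpy()

    fallback = False
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if include_topic_vc:
            import statsmodels.formula.api as smf

            dd = d.rename(columns={measure: "value"})
            try:
                md = smf.mixedlm(
                    "value ~ trait",
                    dd,
                    groups="participant",
                    re_formula="1",
                    vc_formula={"topic": "0 + C(topic)"},
                )
                res = md.fit(reml=True)
                if not res.converged or not np.isfinite(np.asarray(res.bse_fe)[1]):
                    res = None
            except Exception:
                res = None
            if res is None:
                fallback = True
        if res is None:
            try:
                res = MixedLM(y, X, groups=groups).fit(reml=True)
            except Exception:
                res = MixedLM(y, X, groups=groups).fit(reml=True, method="powell")
    beta = float(np.asarray(res.fe_params)[1])
    se = float(np.asarray(res.bse_fe)[1])
    if df_convention == "n_minus_2":
        df = int(n_participants - 2)
    else:
        df = int(len(d) - 2)
    tval = beta / se
    p = 2.0 * stats.t.sf(abs(tval), df)
    return ModelResult(
        trait=trait,
        measure=measure,
        beta=beta,
        ci_low=beta - 1.96 * se,
        ci_high=beta + 1.96 * se,
        t=tval,
        df=df,
        p=float(p),
        n_obs=len(d),
        n_participants=n_participants,
        fallback=fallback,
    )


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(p_adjusted, significant)`` where adjusted values are
    monotone in the raw values and significance is ``p_adj <= alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def fit_all(
    matrix: pd.DataFrame,
    factors: pd.DataFrame,
    alpha: float = 0.05,
    include_topic_vc: bool = False,
) -> pd.DataFrame:
    """Fit every trait x measure model and apply the FDR correction
    over the whole family. Returns one row per test."""
    results = []
    for trait in TRAIT_NAMES:
        for measure in MEASURES:
            if measure not in matrix.columns:
                continue
            results.append(
                fit_trait_model(
                    matrix, factors, trait, measure, include_topic_vc=include_topic_vc
                )
            )
    p_adj, _ = bh_fdr([r.p for r in results], alpha=alpha)
    for r, pa in zip(results, p_adj):
        r.p_adj = float(max(pa, r.p))
    return pd.DataFrame([vars(r) for r in results])


def pattern_correlation(
    betas_a: np.ndarray, betas_b: np.ndarray, pair: tuple[str, str] = ("a", "b")
) -> PatternSimilarity:
    """Pearson similarity of two traits' beta patterns across measures,
    with ``t = r * sqrt(n-2) / sqrt(1-r^2)`` on ``df = n - 2`` and a
    Fisher-z 95% interval."""
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need equal-length beta vectors with n >= 3")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance beta vector")
    r = float(np.corrcoef(a, b)[0, 1])
    n = a.size
    df = n - 2
    denom = max(1.0 - r * r, 1e-15)
    tval = r * math.sqrt(df) / math.sqrt(denom)
    p = 2.0 * stats.t.sf(abs(tval), df)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    zse = 1.0 / math.sqrt(n - 3)
    ci = np.tanh([z - 1.959963984540054 * zse, z + 1.959963984540054 * zse])
    return PatternSimilarity(pair, r, float(ci[0]), float(ci[1]), tval, df, float(p))


def pattern_similarity_table(results: pd.DataFrame) -> pd.DataFrame:
    """Pairwise beta-pattern correlations between traits, computed over
    the measures where both traits have estimates."""
    pivot = results.pivot(index="measure", columns="trait", values="beta")
    rows = []
    for i, a in enumerate(TRAIT_NAMES):
        for b in TRAIT_NAMES[i + 1 :]:
            sub = pivot[[a, b]].dropna()
            sim = pattern_correlation(sub[a], sub[b], (a, b))
            rows.append(
                {
                    "trait_a": a,
                    "trait_b": b,
                    "n_measures": len(sub),
                    "r": sim.r,
                    "ci_low": sim.ci_low,
                    "ci_high": sim.ci_high,
                    "t": sim.t,
                    "df": sim.df,
                    "p": sim.p,
                }
            )
    return pd.DataFrame(rows)


def power_correlation(
    n: int,
    rho: float,
    alpha: float = 0.05,
    n_sims: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Power of the two-sided test of zero Pearson correlation.

    Analytic value via the bias-corrected Fisher-z approximation
    (mean ``atanh(rho) + rho / (2(n-1))``, SD ``1/sqrt(n-3)``); if
    ``n_sims > 0``, additionally a Monte Carlo estimate over bivariate
    normal samples using the exact t test of the sample correlation.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    zcrit = stats.norm.ppf(1.0 - alpha / 2.0)
    mu = math.atanh(rho) + rho / (2.0 * (n - 1.0))
    se = 1.0 / math.sqrt(n - 3.0)
    analytic = float(
        stats.norm.sf(zcrit - mu / se) + stats.norm.cdf(-zcrit - mu / se)
    )
    out = {"analytic": analytic}
    if n_sims > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, n - 2)
        hits = 0
        chunk = max(1, int(2e6 // n))
        left = n_sims
        while left > 0:
            m = min(chunk, left)
            x = rng.standard_normal((m, n))
            e = rng.standard_normal((m, n))
            y = rho * x + math.sqrt(1 - rho * rho) * e
            xc = x - x.mean(axis=1, keepdims=True)
            yc = y - y.mean(axis=1, keepdims=True)
            r = np.sum(xc * yc, axis=1) / np.sqrt(
                np.sum(xc**2, axis=1) * np.sum(yc**2, axis=1)
            )
            tvals = r * math.sqrt(n - 2) / np.sqrt(np.maximum(1 - r**2, 1e-15))
            hits += int(np.sum(np.abs(tvals) > tcrit))
            left -= m
        out["monte_carlo"] = hits / n_sims
    return out


def expected_chance_count(m: int, threshold: float) -> float:
    """Expected number of tests significant by chance: ``m * threshold``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return m * threshold
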