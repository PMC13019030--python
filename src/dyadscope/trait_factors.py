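"""Trait factors from questionnaire scale scores.

Each of the three trait constructs — social anxiety, general
psychopathology, and verticality — is summarized as the first principal
component of its group of z-standardized scale scores (the leading
eigenvector of the group's correlation matrix). Factor scores are
standardized to mean 0, SD 1 and sign-oriented so that the group's
anchor scale (social interaction anxiety / trait anxiety / personal
sense of power) loads positively, making "higher = more anxious / more
psychopathology / more verticality" reproducible across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_dyads import ANCHOR_SCALES, SCALE_GROUPS, TRAIT_NAMES

__all__ = [
    "FactorResult",
    "pca_first_component",
    "build_factors",
    "validate_loadings",
    "cronbach_alpha",
]


@dataclass
class FactorResult:
    """First-component scores and diagnostics for one scale group."""

    group: str
    scores: pd.Series  # standardized, indexed by participant
    loadings: pd.Series  # eigenvector entries per scale
    explained_variance: float  # proportion of group variance
    n_dropped: int = 0  # participants removed as incomplete
    dropped: list[str] = field(default_factory=list)


def pca_first_component(
    scores: pd.DataFrame, group: str, anchor: str | None = None
) -> FactorResult:
    """First principal component of one group of scale scores.

    ``scores`` has participants as rows and the group's scales as
    columns; rows with missing values are excluded (complete-case).
    Scales are z-standardized, the leading eigenvector of their
    correlation matrix extracted, component scores standardized, and
    the sign oriented so the anchor scale loads positively.
    """
    if scores.shape[1] < 3:
        raise ValueError(f"group '{group}' needs at least 3 scales")
    complete = scores.dropna()
    dropped = [str(i) for i in scores.index.difference(complete.index)]
    X = complete.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = complete.columns[np.flatnonzero(sd == 0)][0]
        raise ValueError(f"scale '{bad}' is constant across participants")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (Z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]
    if anchor is None:
        anchor = ANCHOR_SCALES.get(group, complete.columns[0])
    a_idx = list(complete.columns).index(anchor)
    if v[a_idx] < 0:
        v = -v
    raw = Z @ v
    std = (raw - raw.mean()) / raw.std(ddof=1)
    return FactorResult(
        group=group,
        scores=pd.Series(std, index=complete.index, name=group),
        loadings=pd.Series(v, index=complete.columns, name=group),
        explained_variance=float(eigvals[-1] / eigvals.sum()),
        n_dropped=len(dropped),
        dropped=dropped,
    )


def build_factors(traits: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, FactorResult]]:
    """Compute all three trait factors from a scale-score table.

    ``traits`` must contain a ``participant_id`` column and the 17
    scale columns. Returns a DataFrame ``(participant_id, sa, p, v)``
    and the per-group :class:`FactorResult` diagnostics.
    """
    df = traits.set_index("participant_id") if "participant_id" in traits else traits
    results = {}
    cols = {}
    for g in TRAIT_NAMES:
        missing = [c for c in SCALE_GROUPS[g] if c not in df.columns]
        if missing:
            raise ValueError(f"traits table lacks scale columns: {missing}")
        res = pca_first_component(df[list(SCALE_GROUPS[g])], g)
        results[g] = res
        cols[g] = res.scores
    out = pd.DataFrame(cols)
    out.index.name = "participant_id"
    return out.reset_index(), results


def validate_loadings(
    factors: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of each factor with each of its constituent
    scales (rows: scale; columns: group, r)."""
    f = factors.set_index("participant_id")
    t = traits.set_index("participant_id")
    rows = []
    for g in TRAIT_NAMES:
        for scale in SCALE_GROUPS[g]:
            sub = pd.concat([f[g], t[scale]], axis=1).dropna()
            r = float(np.corrcoef(sub[g], sub[scale])[0, 1])
            rows.append({"group": g, "scale": scale, "r": r})
    return pd.DataFrame(rows)


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha: ``k/(k-1) * (1 - sum(item variances) /
    variance(item sum))``."""
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a respondents-by-items matrix with >= 2 items")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))
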