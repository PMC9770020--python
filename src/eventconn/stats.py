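"""Group statistics over the pair table.

The central model is a linear mixed model with the per-pair connectivity
index as dependent variable, zone/region/outcome factors as fixed effects,
spike-coupling rate and inter-contact distance as covariates, and a random
intercept per patient (pairs within a patient share recording conditions and
electrode geometry, so they are not independent).  Group differences are
reported as differences of estimated marginal means with Bonferroni
correction; rank tests, Cohen's d and Pearson correlations cover the
non-model comparisons.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "ModelSpec",
    "ContrastResult",
    "MixedModelResult",
    "fit_mixed_model",
    "rank_test",
    "cohens_d",
    "pearson_r",
    "bonferroni",
]


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, m p)."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, m * p)


def rank_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns (W, p) where W is the rank sum of the first sample.  Uses the
    exact null distribution for small tie-free samples, the tie-corrected
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate input: all observations tied")
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(x.size, y.size) <= 25) else "auto"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    W = float(res.statistic + x.size * (x.size + 1) / 2.0)
    return W, float(res.pvalue)


def cohens_d(x, y) -> float:
    """(mean x - mean y) / pooled SD, with the unbiased pooled variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each sample needs at least 2 observations")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 == 0:
        raise ValueError("zero pooled standard deviation")
    return float((x.mean() - y.mean()) / math.sqrt(sp2))


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    r, p = sstats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ModelSpec:
    """Specification of the mixed model over the pair table."""

    dependent: str = "h_hg"
    factors: list[str] = field(default_factory=lambda: ["zone_pair", "outcome"])
    covariates: list[str] = field(default_factory=lambda: ["spike_rate", "distance_mm"])
    group: str = "patient"
    interactions: bool = True
    transform: str | None = None  # None | "log" | "rank"

    @property
    def formula(self) -> str:
        if self.interactions and len(self.factors) > 1:
            fixed = "*".join(f"C({f})" for f in self.factors)
        else:
            fixed = " + ".join(f"C({f})" for f in self.factors)
        terms = [fixed] + list(self.covariates)
        return f"{self.dependent} ~ " + " + ".join(terms)


@dataclass
class ContrastResult:
    contrast: str
    estimate: float  # difference of estimated marginal means
    se: float
    statistic: float
    p: float
    p_corrected: float
    effect_size: float | None = None
    n: int = 0


@dataclass
class MixedModelResult:
    spec: ModelSpec
    params: pd.Series
    contrasts: list[ContrastResult]
    converged: bool
    singular: bool
    n_obs: int
    n_groups: int
    result: object = None  # statsmodels MixedLMResults

    def coefficient(self, name_fragment: str) -> float:
        """First fixed-effect coefficient whose name contains the fragment."""
        for name, val in self.params.items():
            if name_fragment in name:
                return float(val)
        raise KeyError(name_fragment)


def _apply_transform(table: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    if spec.transform is None:
        return table
    t = table.copy()
    y = t[spec.dependent].to_numpy(dtype=float)
    if spec.transform == "log":
        t[spec.dependent] = np.log(y + 1e-6)
    elif spec.transform == "rank":
        t[spec.dependent] = sstats.rankdata(y) / (y.size + 1.0)
    else:
        raise ValueError(f"unknown transform {spec.transform!r}")
    return t


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec | None = None) -> MixedModelResult:
    """REML fit with a random intercept per patient, plus cell contrasts.

    Estimated marginal means are computed for every cell of the crossed
    factor grid with covariates held at their grand means; all pairwise cell
    differences are reported with Wald tests and Bonferroni correction over
    the contrast family.  A singular random-effects fit is flagged on the
    result, never silently dropped.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    spec = spec or ModelSpec()
    data = table.dropna(subset=[spec.dependent] + spec.covariates).copy()
    if data[spec.group].nunique() < 2:
        raise ValueError("need at least 2 patients")
    for f in spec.factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    data = _apply_transform(data, spec)

    singular = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = smf.mixedlm(spec.formula, data, groups=data[spec.group])
        fitted = model.fit(reml=True)
        for wmsg in caught:
            if issubclass(wmsg.category, (ConvergenceWarning, RuntimeWarning)):
                singular = True
    converged = bool(getattr(fitted, "converged", True))

    contrasts = _emm_contrasts(fitted, data, spec)
    return MixedModelResult(
        spec=spec,
        params=fitted.fe_params,
        contrasts=contrasts,
        converged=converged,
        singular=singular or not converged,
        n_obs=int(len(data)),
        n_groups=int(data[spec.group].nunique()),
        result=fitted,
    )


def _emm_contrasts(fitted, data: pd.DataFrame, spec: ModelSpec) -> list[ContrastResult]:
    """All pairwise differences of estimated marginal means over factor cells."""
    from patsy import dmatrix

    design_info = fitted.model.data.design_info
    levels = {f: sorted(data[f].unique()) for f in spec.factors}
    cov_means = {c: float(data[c].mean()) for c in spec.covariates}

    cells = list(itertools.product(*[levels[f] for f in spec.factors]))
    rows = {}
    for cell in cells:
        grid = dict(zip(spec.factors, cell))
        grid.update(cov_means)
        X = np.asarray(dmatrix(design_info, pd.DataFrame([grid])))
        rows[cell] = X[0]

    beta = np.asarray(fitted.fe_params)
    k = beta.size
    cov = np.asarray(fitted.cov_params())[:k, :k]

    pairs = list(itertools.combinations(cells, 2))
    m = len(pairs)
    out = []
    for c1, c2 in pairs:
        L = rows[c1] - rows[c2]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        mask1 = np.logical_and.reduce(
            [data[f] == v for f, v in zip(spec.factors, c1)])
        mask2 = np.logical_and.reduce(
            [data[f] == v for f, v in zip(spec.factors, c2)])
        n1, n2 = int(mask1.sum()), int(mask2.sum())
        if se > 0:
            z = est / se
            p = 2.0 * sstats.norm.sf(abs(z))
        else:
            z, p = np.nan, np.nan
        try:
            d = cohens_d(data.loc[mask1, spec.dependent],
                         data.loc[mask2, spec.dependent])
        except ValueError:
            d = None
        name1 = "/".join(map(str, c1))
        name2 = "/".join(map(str, c2))
        out.append(ContrastResult(
            contrast=f"{name1} - {name2}",
            estimate=est, se=se, statistic=z,
            p=float(p) if np.isfinite(p) else np.nan,
            p_corrected=bonferroni(p, m) if np.isfinite(p) else np.nan,
            effect_size=d, n=n1 + n2,
        ))
    return out


def contrasts_frame(result: MixedModelResult) -> pd.DataFrame:
    """Contrast results as a tidy table (hypothesis, estimate, p, effect, n)."""
    return pd.DataFrame(
        [{
            "hypothesis": c.contrast,
            "estimate": c.estimate,
            "se": c.se,
            "statistic": c.statistic,
            "p": c.p,
            "p_bonferroni": c.p_corrected,
            "cohens_d": c.effect_size,
            "n": c.n,
        } for c in result.contrasts]
    )
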