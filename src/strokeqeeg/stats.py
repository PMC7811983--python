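"""Outcome statistics: Spearman correlation with Bonferroni control and
univariate logistic regression of good 12-month outcome on ln-features.

Spearman's rho is the product-moment correlation of midranks (average ranks
for ties).  Its p-value is exact — computed by enumerating the full
permutation distribution — for n ≤ 9, and uses the Student-t approximation
with n − 2 degrees of freedom for larger samples, where a 20-patient cohort
sits.  The logistic stage fits good-vs-bad outcome on intercept +
ln(feature) by IRLS and reports the odds ratio per unit ln-increase with a
95% Wald interval.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

#: The six EEG parameters reported per outcome family.
EEG_FEATURES = ("rel_delta", "rel_theta", "rel_alpha", "rel_beta", "dar", "dtabr")

#: Default Bonferroni family size: one family of 6 EEG parameters per outcome.
DEFAULT_FAMILY_SIZE = 6

#: Outcome columns correlated against the EEG features.
CORRELATION_OUTCOMES = ("nihss_admission", "nihss_7d", "nihss_12m", "final_volume_ml")

#: Largest n for which the exact permutation p-value is computed.
EXACT_P_MAX_N = 9


class ConstantInputError(ValueError):
    """Correlation or regression requested on a constant vector."""


@dataclass(frozen=True)
class PatientOutcomes:
    """Clinical and morphological outcomes for one patient."""

    nihss_admission: int
    nihss_7d: int
    nihss_12m: int
    mrs_premorbid: int
    mrs_12m: int
    final_volume_ml: float

    def __post_init__(self) -> None:
        for name in ("nihss_admission", "nihss_7d", "nihss_12m"):
            v = getattr(self, name)
            if not 0 <= v <= 42:
                raise ValueError(f"{name}={v} outside the 0–42 NIHSS range")
        for name in ("mrs_premorbid", "mrs_12m"):
            v = getattr(self, name)
            if not 0 <= v <= 6:
                raise ValueError(f"{name}={v} outside the 0–6 mRS range")
        if self.final_volume_ml < 0:
            raise ValueError("final_volume_ml must be ≥ 0")


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    n: int
    method: str  # "exact-permutation" or "t-approximation"


@dataclass(frozen=True)
class CorrelationResult:
    feature_name: str
    outcome_name: str
    rho: float
    p_raw: float
    alpha_adjusted: float
    significant: bool
    n: int


@dataclass(frozen=True)
class LogisticResult:
    feature_name: str
    beta: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool
    separated: bool = False
    n: int = 0


@dataclass(frozen=True)
class StatsConfig:
    bonferroni_m: int = DEFAULT_FAMILY_SIZE
    alpha: float = 0.05
    mrs3_is_bad: bool = True  # False → literal ">3 is bad" (mRS 3 unassigned)


@dataclass(frozen=True)
class CorrelationReport:
    """Full association grid: 6 features × 4 outcomes plus 6 logistic fits."""

    correlations: tuple[CorrelationResult, ...]
    logistic: tuple[LogisticResult, ...]
    n_patients: int
    pairwise_n: dict[str, int] = field(default_factory=dict)

    def correlation_table(self) -> pd.DataFrame:
        rows = []
        for feat in EEG_FEATURES:
            row: dict[str, object] = {"feature": feat}
            for res in self.correlations:
                if res.feature_name == feat:
                    row[f"rho_{res.outcome_name}"] = res.rho
                    row[f"p_{res.outcome_name}"] = res.p_raw
                    row[f"sig_{res.outcome_name}"] = res.significant
            rows.append(row)
        return pd.DataFrame(rows).set_index("feature")

    def logistic_table(self) -> pd.DataFrame:
        rows = [
            {
                "feature": r.feature_name,
                "or": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "converged": r.converged,
            }
            for r in self.logistic
        ]
        return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# Spearman correlation


def _midranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based), ties receive the mean of their positions."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
    if denom == 0:
        raise ConstantInputError("correlation undefined for a constant vector")
    return float(rxc @ ryc) / denom


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided p from the full permutation distribution of rho.

    Enumerates all n! pairings of the y-ranks against the x-ranks; the
    p-value is the fraction with |rho| ≥ |rho_obs| (ties in |rho| counted
    as at least as extreme).
    """
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry.mean()
    denom = math.sqrt(float(rxc @ rxc) * float((ry - ry.mean()) @ (ry - ry.mean())))
    rhos = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: np.ndarray, y: np.ndarray) -> SpearmanResult:
    """Spearman rank correlation with an exact permutation p for small n.

    Raises :class:`ConstantInputError` if either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx, ry = _midranks(x), _midranks(y)
    rho = _rank_corr(rx, ry)
    if n <= EXACT_P_MAX_N:
        p = _exact_permutation_p(rx, ry, rho)
        method = "exact-permutation"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
        method = "t-approximation"
    return SpearmanResult(rho=rho, p=p, n=n, method=method)


# ---------------------------------------------------------------------------
# Multiple comparisons and outcome dichotomisation


@dataclass(frozen=True)
class BonferroniResult:
    threshold: float
    flags: tuple[bool, ...]
    m: int
    alpha: float


def bonferroni(
    p_values, m: int | None = None, alpha: float = 0.05
) -> BonferroniResult:
    """Flag each test significant iff ``p < alpha / m``.

    ``m`` defaults to the EEG-parameter family size (6): each outcome is
    tested against the six spectral parameters, forming one family.
    """
    if m is None:
        m = DEFAULT_FAMILY_SIZE
    if m < 1:
        raise ValueError("family size m must be ≥ 1")
    threshold = alpha / m
    flags = tuple(float(p) < threshold for p in p_values)
    return BonferroniResult(threshold=threshold, flags=flags, m=m, alpha=alpha)


def dichotomize_mrs(mrs_12m: int, mrs3_is_bad: bool = True) -> bool | None:
    """Good (True) vs bad (False) 12-month outcome from the mRS.

    Good outcome is mRS ≤ 2.  Under the default convention mRS ≥ 3 is bad
    (two-class partition of the cohort).  With ``mrs3_is_bad=False`` the
    literal "bad is mRS > 3" reading applies and mRS = 3 is unassigned
    (returns ``None``).
    """
    if not 0 <= mrs_12m <= 6:
        raise ValueError(f"mRS {mrs_12m} outside the 0–6 scale")
    if mrs_12m <= 2:
        return True
    if mrs_12m == 3 and not mrs3_is_bad:
        return None
    return False


# ---------------------------------------------------------------------------
# Logistic regression


def _is_separated(z: np.ndarray, good: np.ndarray) -> bool:
    """Complete separation: a threshold on z splits the classes perfectly."""
    return float(np.max(z[~good])) < float(np.min(z[good])) or float(
        np.max(z[good])
    ) < float(np.min(z[~good]))


def logistic_univariate(
    feature_values: np.ndarray,
    good: np.ndarray,
    feature_name: str = "feature",
    ln_transform: bool = True,
) -> LogisticResult:
    """Binary logistic regression of good outcome on ln(feature).

    Fit by IRLS (binomial GLM); reports the odds ratio per unit increase of
    the ln-feature with a 95% Wald confidence interval.  Complete separation
    is detected before fitting and reported as a non-converged result with
    the (diverging) point estimates from a capped fit.
    """
    x = np.asarray(feature_values, dtype=float)
    good = np.asarray(good, dtype=bool)
    if x.shape != good.shape or x.ndim != 1:
        raise ValueError("feature_values and good must be 1-D of equal length")
    if ln_transform:
        if np.any(x <= 0):
            raise ValueError("ln-transform requires strictly positive feature values")
        z = np.log(x)
    else:
        z = x
    if good.all() or (~good).all():
        raise ValueError("both outcome classes must be present")
    if np.ptp(z) == 0:
        raise ConstantInputError(
            f"{feature_name} is identical for all patients; odds ratio undefined"
        )
    separated = _is_separated(z, good)
    design = sm.add_constant(z)
    model = sm.GLM(good.astype(float), design, family=sm.families.Binomial())
    with warnings.catch_warnings():
        # a separated fit is reported as non-converged, not warned about
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=25 if separated else 100)
    beta = float(res.params[1])
    se = float(res.bse[1])
    converged = bool(res.converged) and not separated and se < 1e3
    ci_low, ci_high = beta - 1.96 * se, beta + 1.96 * se

    def _exp(v: float) -> float:  # overflow-safe for diverging separated fits
        return math.inf if v > 700 else math.exp(v)

    return LogisticResult(
        feature_name=feature_name,
        beta=beta,
        or_=_exp(beta),
        ci_low=_exp(ci_low),
        ci_high=_exp(ci_high),
        p=float(res.pvalues[1]),
        converged=converged,
        separated=separated,
        n=len(x),
    )


# ---------------------------------------------------------------------------
# The full association study


def run_association_study(
    features: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: StatsConfig = StatsConfig(),
) -> CorrelationReport:
    """Spearman grid (6 EEG features × 4 outcomes, Bonferroni-corrected) plus
    the 6 univariate logistic fits for good 12-month outcome (mRS ≤ 2).

    Both tables must be indexed (or carry an ``id`` column) with matching
    patient identifiers; missing outcome values are dropped pairwise and the
    per-cell n recorded.
    """
    features = _indexed(features)
    outcomes = _indexed(outcomes)
    unmatched = sorted(set(features.index).symmetric_difference(outcomes.index))
    if unmatched:
        raise ValueError(f"patient ids do not match across tables: {unmatched}")
    if len(features) < 3:
        raise ValueError("need at least 3 matched patients")
    outcomes = outcomes.loc[features.index]

    correlations: list[CorrelationResult] = []
    pairwise_n: dict[str, int] = {}
    for outcome in CORRELATION_OUTCOMES:
        y_all = outcomes[outcome].astype(float)
        results = []
        for feat in EEG_FEATURES:
            x_all = features[feat].astype(float)
            ok = x_all.notna() & y_all.notna()
            pairwise_n[f"{feat}:{outcome}"] = int(ok.sum())
            try:
                r = spearman(x_all[ok].to_numpy(), y_all[ok].to_numpy())
            except ConstantInputError as err:
                raise ConstantInputError(
                    f"degenerate input for ({feat}, {outcome}): {err}"
                ) from err
            results.append((feat, r))
        corr = bonferroni(
            [r.p for _, r in results], m=config.bonferroni_m, alpha=config.alpha
        )
        for (feat, r), sig in zip(results, corr.flags):
            correlations.append(
                CorrelationResult(
                    feature_name=feat,
                    outcome_name=outcome,
                    rho=r.rho,
                    p_raw=r.p,
                    alpha_adjusted=corr.threshold,
                    significant=sig,
                    n=r.n,
                )
            )

    classes = outcomes["mrs_12m"].map(
        lambda v: dichotomize_mrs(int(v), mrs3_is_bad=config.mrs3_is_bad)
    )
    assigned = classes.notna()
    logistic: list[LogisticResult] = []
    for feat in EEG_FEATURES:
        x_all = features[feat].astype(float)
        ok = assigned & x_all.notna()
        logistic.append(
            logistic_univariate(
                x_all[ok].to_numpy(),
                classes[ok].astype(bool).to_numpy(),
                feature_name=feat,
            )
        )
    return CorrelationReport(
        correlations=tuple(correlations),
        logistic=tuple(logistic),
        n_patients=len(features),
        pairwise_n=pairwise_n,
    )


def _indexed(df: pd.DataFrame) -> pd.DataFrame:
    if "id" in df.columns:
        df = df.set_index("id")
    return df
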