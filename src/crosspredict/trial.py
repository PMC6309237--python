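"""Field-trial analysis and validation statistics for cross predictions.

The multi-location trial is analysed with the mixed linear model

    value ~ entry (fixed) + location (random) + location:block (random) + error

fitted by restricted maximum likelihood.  Adjusted entry means are the
generalized-least-squares fixed-effect solutions and their standard errors
come from the diagonal of the inverse coefficient matrix (X' V^-1 X)^-1.
The masking variance — the non-genetic part of the phenotypic variance an
entry mean carries — is estimated as the square of the average standard
error of the adjusted means.  Model errors are homoscedastic by default;
per-location error variances are available behind a flag.

Validation of cross predictions against observed families uses:

* the predicted phenotypic distribution N(mu_g, sigma2_g + s_m2),
* a fully-specified (case-0) Anderson-Darling goodness-of-fit test with
  p-values from the Marsaglia & Marsaglia (2004) evaluation of the A2
  distribution,
* equal-tailed chi-square confidence intervals for observed variances,
* Pearson correlations of observed vs predicted means and variances, and
* the top-half overlap between observed and predicted cross rankings.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .crosspred import CrossPrediction, CrossRanking, UsefulnessConfig, rank_crosses

__all__ = [
    "FieldTrialTable",
    "TrialAnalysis",
    "FamilyObservation",
    "PhenotypeDistribution",
    "ADTestResult",
    "fit_trial_model",
    "predicted_phenotype_distribution",
    "anderson_darling_normal",
    "variance_confidence_interval",
    "family_observations",
    "prediction_correlations",
    "ranking_overlap",
    "validate_families",
    "read_trial",
    "write_trial",
    "read_families",
    "write_families",
]


@dataclasses.dataclass
class FieldTrialTable:
    """Plot records (entry, location, block, value) of an augmented trial."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"entry", "location", "block", "value"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"trial table needs columns {sorted(required)}")
        t = self.table.copy()
        for col in ("entry", "location", "block"):
            t[col] = t[col].astype(str)
        t["value"] = t["value"].astype(float)
        if t.duplicated(["entry", "location", "block"]).any():
            dupes = t[t.duplicated(["entry", "location", "block"])]
            raise ValueError(
                f"duplicate (entry, location, block) plots: "
                f"{dupes[['entry', 'location', 'block']].iloc[0].tolist()}"
            )
        if not np.isfinite(t["value"]).all():
            raise ValueError("plot values must be finite")
        self.table = t.reset_index(drop=True)

    @property
    def entries(self) -> list[str]:
        return sorted(self.table["entry"].unique())

    @property
    def locations(self) -> list[str]:
        return sorted(self.table["location"].unique())


@dataclasses.dataclass
class TrialAnalysis:
    """REML fit summary: adjusted means, SEs and variance components."""

    entry_ids: list[str]
    adjusted_means: np.ndarray
    standard_errors: np.ndarray
    variance_components: dict
    reml_loglik: float
    converged: bool

    def __post_init__(self) -> None:
        self.adjusted_means = np.asarray(self.adjusted_means, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        if np.any(self.standard_errors <= 0):
            raise ValueError("standard errors must be > 0")

    @property
    def masking_variance(self) -> float:
        """s_m2 = (arithmetic mean of the per-entry SEs) squared."""
        return float(np.mean(self.standard_errors) ** 2)

    @property
    def masking_variance_mean_squared_se(self) -> float:
        """Alternative reading: the mean of the squared SEs."""
        return float(np.mean(self.standard_errors**2))

    def mean_of(self, entry: str) -> float:
        return float(self.adjusted_means[self.entry_ids.index(entry)])

    def means_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "entry": self.entry_ids,
                "adjusted_mean": self.adjusted_means,
                "standard_error": self.standard_errors,
            }
        )


@dataclasses.dataclass
class _TrialDesign:
    """Integer-coded plot structure for the REML evaluations."""

    y: np.ndarray
    entry_idx: np.ndarray  # (n,) in [0, m)
    loc_idx: np.ndarray  # (n,) in [0, n_loc)
    lb_idx: np.ndarray  # (n,) in [0, n_lb); location:block level
    loc_of_lb: np.ndarray  # (n_lb,) parent location of each block level
    m: int
    n_loc: int
    n_lb: int


def _reml_objective(log_params: np.ndarray, des: _TrialDesign, heteroscedastic: bool):
    """-2 * restricted log-likelihood (up to a constant) and the GLS solution.

    Parameters are log variances (sigma2_L, sigma2_LB, sigma2_e) — or one
    error variance per location when heteroscedastic.  The fixed-effect
    design is a pure entry indicator and the random design indicators are
    nested, so every matrix product reduces to grouped sums; with
    ``q = n_loc + n_lb`` random levels the evaluation is O(n q + m q^2) via
    two applications of the Woodbury identity / matrix-determinant lemma
    (once for V^-1, once for (X' V^-1 X)^-1), never forming an n x n or
    m x m matrix.
    """
    n = des.y.size
    q = des.n_loc + des.n_lb
    s2_L, s2_LB = np.exp(log_params[0]), np.exp(log_params[1])
    if heteroscedastic:
        d = np.exp(log_params[2:])[des.loc_idx]
    else:
        d = np.full(n, np.exp(log_params[2]))
    g = np.concatenate([np.full(des.n_loc, s2_L), np.full(des.n_lb, s2_LB)])
    w = 1.0 / d
    wy = w * des.y

    locw = np.bincount(des.loc_idx, w, minlength=des.n_loc)
    lbw = np.bincount(des.lb_idx, w, minlength=des.n_lb)
    # M = G^-1 + U' D^-1 U; blocks nest in locations, so the off-diagonal
    # block has one entry per block level
    M = np.diag(1.0 / g)
    M[np.arange(des.n_loc), np.arange(des.n_loc)] += locw
    rows_lb = des.n_loc + np.arange(des.n_lb)
    M[rows_lb, rows_lb] += lbw
    M[des.loc_of_lb, rows_lb] += lbw
    M[rows_lb, des.loc_of_lb] += lbw

    uty = np.concatenate(
        [np.bincount(des.loc_idx, wy, minlength=des.n_loc),
         np.bincount(des.lb_idx, wy, minlength=des.n_lb)]
    )
    a = np.bincount(des.entry_idx, w, minlength=des.m)
    xty = np.bincount(des.entry_idx, wy, minlength=des.m)
    B = np.zeros((des.m, q))
    np.add.at(B, (des.entry_idx, des.loc_idx), w)
    np.add.at(B, (des.entry_idx, des.n_loc + des.lb_idx), w)

    cM = np.linalg.cholesky(M)
    Minv_uty = np.linalg.solve(cM.T, np.linalg.solve(cM, uty))
    xvy = xty - B @ Minv_uty  # X' V^-1 y
    yvy = float(wy @ des.y - uty @ Minv_uty)  # y' V^-1 y

    # S = M - B' diag(1/a) B is the Schur complement giving W = X' V^-1 X
    S = M - B.T @ (B / a[:, None])
    cS = np.linalg.cholesky(S)

    def winv(v: np.ndarray) -> np.ndarray:
        va = v / a
        return va + (B @ np.linalg.solve(cS.T, np.linalg.solve(cS, B.T @ va))) / a

    tau = winv(xvy)
    yPy = yvy - float(xvy @ tau)
    logdet_M = 2.0 * float(np.sum(np.log(np.diag(cM))))
    logdet_S = 2.0 * float(np.sum(np.log(np.diag(cS))))
    logdet_V = float(np.sum(np.log(d)) + np.sum(np.log(g))) + logdet_M
    logdet_W = float(np.sum(np.log(a))) + logdet_S - logdet_M
    obj = logdet_V + logdet_W + yPy

    T = np.linalg.solve(cS.T, np.linalg.solve(cS, B.T))  # S^-1 B'
    diag_Winv = 1.0 / a + np.einsum("jq,qj->j", B, T) / a**2
    return obj, tau, diag_Winv


def fit_trial_model(
    t: FieldTrialTable,
    heteroscedastic: bool = False,
    entries: Sequence[str] | None = None,
) -> TrialAnalysis:
    """REML fit of the trial mixed model; entries fixed, design random.

    Parameters
    ----------
    t
        Plot table.  Unreplicated entries are fine as long as replicated
        checks connect the locations/blocks (augmented design).
    heteroscedastic
        Estimate a separate error variance per location instead of a single
        sigma2_e.
    entries
        Optional explicit entry list; entries without any plot raise an
        error naming them.
    """
    tab = t.table
    entry_ids = list(entries) if entries is not None else t.entries
    present = set(tab["entry"])
    orphans = [e for e in entry_ids if e not in present]
    if orphans:
        raise ValueError(f"entries with no plots (not estimable): {orphans[:5]}")
    locations = t.locations
    if len(locations) < 2 and len(tab["block"].unique()) < 2:
        # degenerate single-location single-block design: still fit, the
        # variance components collapse to their bounds
        pass

    e_idx = {e: i for i, e in enumerate(entry_ids)}
    l_idx = {l: i for i, l in enumerate(locations)}
    lb_levels = sorted(set(zip(tab["location"], tab["block"])))
    lb_map = {lb: i for i, lb in enumerate(lb_levels)}

    n = len(tab)
    y_raw = tab["value"].to_numpy()
    # centring makes the fit exactly translation-equivariant and avoids
    # cancellation noise in y'Py for data far from zero
    y_center = float(y_raw.mean())
    y = y_raw - y_center
    des = _TrialDesign(
        y=y,
        entry_idx=np.array([e_idx[e] for e in tab["entry"]]),
        loc_idx=np.array([l_idx[l] for l in tab["location"]]),
        lb_idx=np.array(
            [lb_map[lb] for lb in zip(tab["location"], tab["block"])]
        ),
        loc_of_lb=np.array([l_idx[loc] for loc, _ in lb_levels]),
        m=len(entry_ids),
        n_loc=len(locations),
        n_lb=len(lb_levels),
    )

    vy = float(np.var(y)) or 1.0
    lo, hi = math.log(vy * 1e-6), math.log(vy * 1e4)
    n_err = len(locations) if heteroscedastic else 1

    def vc_dict(s2: np.ndarray) -> dict:
        return {
            "sigma2_location": float(s2[0]),
            "sigma2_location_block": float(s2[1]),
            "sigma2_error": (
                {loc: float(v) for loc, v in zip(locations, s2[2:])}
                if heteroscedastic else float(s2[2])
            ),
        }

    if n == len(entry_ids):
        # saturated design (every entry observed exactly once overall): the
        # restricted likelihood carries no information on any variance
        # component; by convention the components collapse to the floor, so
        # adjusted means equal plot values and SEs are numerically ~0
        x_floor = np.full(2 + n_err, lo)
        obj, tau, diag_winv = _reml_objective(x_floor, des, heteroscedastic)
        return TrialAnalysis(
            entry_ids, tau + y_center, np.sqrt(diag_winv), vc_dict(np.exp(x_floor)),
            -0.5 * float(obj), True,
        )

    x0 = np.log(np.concatenate([[vy / 4.0, vy / 4.0], np.full(n_err, vy / 2.0)]))
    x0 = np.clip(x0, lo, hi)

    def f(lp: np.ndarray) -> float:
        try:
            return _reml_objective(lp, des, heteroscedastic)[0]
        except np.linalg.LinAlgError:
            return 1e12

    res = optimize.minimize(
        f, x0, method="L-BFGS-B", bounds=[(lo, hi)] * len(x0),
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success:
        # numeric-gradient line searches can stall near the bounds;
        # a derivative-free polish is robust for this small parameter count
        res2 = optimize.minimize(
            f, res.x if np.isfinite(res.fun) else x0, method="Powell",
            bounds=[(lo, hi)] * len(x0),
            options={"maxiter": 2000, "xtol": 1e-10, "ftol": 1e-12},
        )
        if res2.fun <= res.fun or not np.isfinite(res.fun):
            res = res2
        if not res.success and not np.isfinite(res.fun):
            raise RuntimeError(f"REML did not converge: {res.message}")

    obj, tau, diag_winv = _reml_objective(res.x, des, heteroscedastic)
    se = np.sqrt(diag_winv)
    s2 = np.exp(res.x)
    return TrialAnalysis(
        entry_ids=entry_ids,
        adjusted_means=tau + y_center,
        standard_errors=se,
        variance_components=vc_dict(s2),
        reml_loglik=-0.5 * float(obj),
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# predicted phenotypic distribution and goodness of fit


@dataclasses.dataclass
class PhenotypeDistribution:
    """Normal distribution N(mu_g, sigma2_g + s_m2) of observable values."""

    mu: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("phenotype distribution is degenerate (variance <= 0)")


def predicted_phenotype_distribution(
    cp: CrossPrediction, ta: "TrialAnalysis | float"
) -> PhenotypeDistribution:
    """Widen the genetic distribution by the trial's masking variance."""
    s_m2 = ta.masking_variance if isinstance(ta, TrialAnalysis) else float(ta)
    if s_m2 < 0:
        raise ValueError("masking variance must be >= 0")
    return PhenotypeDistribution(cp.mu_hat, cp.sigma2_hat + s_m2)


@dataclasses.dataclass
class ADTestResult:
    A2: float
    p_value: float
    n: int


def _ad_cdf_asymptotic(z: float) -> float:
    """Asymptotic CDF of the Anderson-Darling A2 statistic (case 0).

    Marsaglia & Marsaglia (2004) two-branch series; |error| < 2e-6.
    """
    if z < 0.01:
        return 0.0
    if z >= 32.0:
        # beyond the series' fitted range; the tail mass is < 1e-8
        return 1.0
    if z < 2.0:
        return math.exp(-1.2337141 / z) / math.sqrt(z) * (
            2.00012
            + (0.247105 - (0.0649821 - (0.0347962 - (0.011672 - 0.00168691 * z) * z) * z) * z) * z
        )
    return math.exp(
        -math.exp(1.0776 - (2.30695 - (0.43424 - (0.082433 - (0.008056 - 0.0003146 * z) * z) * z) * z) * z)
    )


def _ad_cdf(n: int, z: float) -> float:
    """Finite-n CDF of A2: asymptotic value plus the errfix(n, x) correction."""
    x = _ad_cdf_asymptotic(z)
    if x > 1.0 - 1e-6:
        # the correction polynomial's own fit error dominates this close to 1
        return x
    if x > 0.8:
        v = (-130.2137 + (745.2337 - (1705.091 - (1950.646 - (1116.360 - 255.7844 * x) * x) * x) * x) * x) / n
        return min(max(x + v, 0.0), 1.0)
    c = 0.01265 + 0.1757 / n
    if x < c:
        v = x / c
        v = math.sqrt(v) * (1.0 - v) * (49.0 * v - 102.0)
        return min(max(x + v * (0.0037 / n**2 + 0.00078 / n + 0.00006) / n, 0.0), 1.0)
    v = (x - c) / (0.8 - c)
    v = -0.00022633 + (6.54034 - (14.6538 - (14.458 - (8.259 - 1.91864 * v) * v) * v) * v) * v
    return min(max(x + v * (0.04213 + 0.01365 / n) / n, 0.0), 1.0)


def anderson_darling_normal(x: np.ndarray, mu: float, sigma2: float) -> ADTestResult:
    """Case-0 Anderson-Darling test of x ~ N(mu, sigma2), both given.

    The null is fully specified (parameters come from the marker-based
    prediction and the trial model, not from the tested sample), so the
    case-0 distribution of A2 applies.  Tail probabilities are computed in
    log space, so extreme observations do not overflow; a warning is
    emitted when a CDF value underflows the double representation.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("need a non-empty 1-D sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample must be finite")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    n = x.size
    s = np.sort((x - mu) / math.sqrt(sigma2))
    log_z = stats.norm.logcdf(s)
    log_1mz = stats.norm.logsf(s)
    cdf = stats.norm.cdf(s)
    if np.any(cdf == 0.0) or np.any(cdf == 1.0):
        warnings.warn(
            "sample point(s) far in the null tail; using log-tail safeguards",
            RuntimeWarning,
        )
    i = np.arange(1, n + 1)
    A2 = float(-n - np.sum((2 * i - 1) * (log_z + log_1mz[::-1])) / n)
    p = min(max(1.0 - _ad_cdf(n, A2), 0.0), 1.0)
    return ADTestResult(A2=A2, p_value=p, n=n)


def variance_confidence_interval(
    s2: float, n: int, alpha: float = 0.05
) -> tuple[float, float]:
    """Equal-tailed chi-square CI for the variance of a normal sample.

    lower = (n-1) s2 / chi2_{1-alpha/2, n-1},
    upper = (n-1) s2 / chi2_{alpha/2, n-1}.
    """
    if n < 2:
        raise ValueError("variance CI needs n >= 2")
    if s2 < 0:
        raise ValueError("s2 must be >= 0")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    lower = df * s2 / stats.chi2.ppf(1.0 - alpha / 2.0, df)
    upper = df * s2 / stats.chi2.ppf(alpha / 2.0, df)
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# family-level observations and comparison with predictions


@dataclasses.dataclass
class FamilyObservation:
    """Observed summary of one DH family from the trial's adjusted means."""

    cross_id: str
    entry_ids: list[str]
    n: int
    observed_mean: float
    observed_variance: float | None  # None for n = 1 (sample variance undefined)
    best_line_value: float


def family_observations(
    ta: TrialAnalysis, family_map: Mapping[str, Sequence[str]]
) -> list[FamilyObservation]:
    """Per-family mean, sample variance (n-1 divisor) and best-line value."""
    out = []
    for cross_id in sorted(family_map):
        members = list(family_map[cross_id])
        if not members:
            raise ValueError(f"family {cross_id} has no members")
        vals = np.array([ta.mean_of(e) for e in members])
        out.append(
            FamilyObservation(
                cross_id=cross_id,
                entry_ids=members,
                n=len(members),
                observed_mean=float(vals.mean()),
                observed_variance=float(vals.var(ddof=1)) if len(vals) > 1 else None,
                best_line_value=float(vals.max()),
            )
        )
    return out


def _match(
    obs: Sequence[FamilyObservation],
    pred: Sequence[CrossPrediction],
    exclude: Sequence[str] | None,
) -> list[tuple[FamilyObservation, CrossPrediction]]:
    excluded = set(exclude or ())
    pred_by_id = {p.cross_id: p for p in pred}
    pairs = []
    for o in obs:
        if o.cross_id in excluded:
            continue
        if o.cross_id not in pred_by_id:
            raise KeyError(f"no prediction for family {o.cross_id}")
        pairs.append((o, pred_by_id[o.cross_id]))
    return pairs


def prediction_correlations(
    obs: Sequence[FamilyObservation],
    pred: Sequence[CrossPrediction],
    exclude: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Pearson r of observed vs predicted means, and variances.

    The variance correlation uses only families with a defined sample
    variance (n >= 2); families may be excluded by cross id (e.g. outlier
    families).
    """
    pairs = _match(obs, pred, exclude)
    if len(pairs) < 3:
        raise ValueError("need >= 3 paired families after exclusion")
    means_obs = np.array([o.observed_mean for o, _ in pairs])
    means_pred = np.array([p.mu_hat for _, p in pairs])
    var_pairs = [(o, p) for o, p in pairs if o.observed_variance is not None]
    if len(var_pairs) < 3:
        raise ValueError("need >= 3 families with defined variances")
    var_obs = np.array([o.observed_variance for o, _ in var_pairs])
    var_pred = np.array([p.sigma2_hat for _, p in var_pairs])
    r_means = float(stats.pearsonr(means_obs, means_pred).statistic)
    r_vars = float(stats.pearsonr(var_obs, var_pred).statistic)
    return r_means, r_vars


def ranking_overlap(
    observed: CrossRanking, predicted: CrossRanking
) -> tuple[int, int, float]:
    """Overlap of the top halves of two rankings of the same crosses.

    Returns (k, matched, fraction) with k = floor(m/2) and matched the size
    of the intersection of the two top-k sets.
    """
    if set(observed.cross_ids) != set(predicted.cross_ids):
        raise ValueError("rankings cover different cross sets")
    m = len(observed.cross_ids)
    if m < 2:
        raise ValueError("need at least 2 crosses to compare rankings")
    k = m // 2
    matched = len(observed.top(k) & predicted.top(k))
    return k, matched, matched / k


def observed_ranking(obs: Sequence[FamilyObservation]) -> CrossRanking:
    """Rank families by the adjusted mean of their best line, best first."""
    scored = sorted(
        ((o.cross_id, o.best_line_value) for o in obs), key=lambda t: (-t[1], t[0])
    )
    return CrossRanking(list(scored), "best_line_value")


def validate_families(
    ta: TrialAnalysis,
    family_map: Mapping[str, Sequence[str]],
    predictions: Sequence[CrossPrediction],
    alpha: float = 0.05,
    cfg: UsefulnessConfig | None = None,
    exclude: Sequence[str] | None = None,
) -> dict:
    """Full validation report comparing predictions with trial observations.

    Per cross: observed n, mean, variance with its chi-square CI, predicted
    mu_g / sigma2_g, the predicted phenotypic variance sigma2_g + s_m2, and
    the Anderson-Darling test of the family's adjusted means against
    N(mu_g, sigma2_g + s_m2).  Globally: s_m2, observed-vs-predicted
    correlations and the top-half ranking overlap.  Families of size 1 are
    excluded from variance statistics and AD testing but kept for the mean
    correlation and the ranking.
    """
    cfg = cfg or UsefulnessConfig()
    obs = family_observations(ta, family_map)
    s_m2 = ta.masking_variance
    pred_by_id = {p.cross_id: p for p in predictions}
    per_cross = []
    for o in obs:
        if o.cross_id not in pred_by_id:
            raise KeyError(f"no prediction for family {o.cross_id}")
        p = pred_by_id[o.cross_id]
        dist = predicted_phenotype_distribution(p, s_m2)
        row: dict = {
            "cross_id": o.cross_id,
            "n": o.n,
            "observed_mean": o.observed_mean,
            "observed_variance": o.observed_variance,
            "best_line_value": o.best_line_value,
            "mu_hat": p.mu_hat,
            "sigma2_hat": p.sigma2_hat,
            "sigma_hat": p.sigma_hat,
            "predicted_phenotypic_variance": dist.variance,
            "variance_ci": None,
            "A2": None,
            "p_value": None,
        }
        if o.n >= 2:
            row["variance_ci"] = list(
                variance_confidence_interval(o.observed_variance, o.n, alpha)
            )
            vals = np.array([ta.mean_of(e) for e in o.entry_ids])
            ad = anderson_darling_normal(vals, dist.mu, dist.variance)
            row["A2"], row["p_value"] = ad.A2, ad.p_value
        per_cross.append(row)

    matched_pred = [pred_by_id[o.cross_id] for o in obs]
    r_means, r_vars = prediction_correlations(obs, matched_pred, exclude)
    obs_rank = observed_ranking(obs)
    pred_rank = rank_crosses(matched_pred, cfg)
    k, matched, fraction = ranking_overlap(obs_rank, pred_rank)
    return {
        "alpha": alpha,
        "masking_variance": s_m2,
        "variance_components": ta.variance_components,
        "crosses": per_cross,
        "r_means": r_means,
        "r_variances": r_vars,
        "excluded_from_correlations": sorted(exclude) if exclude else [],
        "ranking": {
            "k": k,
            "matched": matched,
            "fraction": fraction,
            "observed_order": obs_rank.cross_ids,
            "predicted_order": pred_rank.cross_ids,
        },
    }


# ---------------------------------------------------------------------------
# IO


def read_trial(path: str | Path) -> FieldTrialTable:
    """Read a trial TSV: ``entry<TAB>location<TAB>block<TAB>value``."""
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype={0: str, 1: str, 2: str})
    df.columns = ["entry", "location", "block", "value"] + list(df.columns[4:])
    return FieldTrialTable(df[["entry", "location", "block", "value"]])


def write_trial(t: FieldTrialTable, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        fh.write("entry\tlocation\tblock\tvalue\n")
        for row in t.table.itertuples(index=False):
            fh.write(f"{row.entry}\t{row.location}\t{row.block}\t{float(row.value)!r}\n")


def read_families(path: str | Path) -> dict[str, list[str]]:
    """Read a families TSV (``cross_id<TAB>entry_id``) into a mapping."""
    df = pd.read_csv(
        Path(path), sep="\t", comment="#", dtype=str,
        header=None, names=["cross_id", "entry_id"],
    )
    if len(df) and df.iloc[0, 0] == "cross_id":
        df = df.iloc[1:]
    out: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.cross_id, []).append(row.entry_id)
    return out


def write_families(family_map: Mapping[str, Sequence[str]], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("cross_id\tentry_id\n")
        for cross_id in sorted(family_map):
            for entry in family_map[cross_id]:
                fh.write(f"{cross_id}\t{entry}\n")
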