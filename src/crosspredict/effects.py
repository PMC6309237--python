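"""Genome-wide additive marker effects by ridge-regression BLUP.

The model is ``y = 1*mu + Z*beta + e`` with ``beta ~ N(0, sigma2_beta I)``
and ``e ~ N(0, sigma2_e I)``; the single fixed effect is the intercept.
When the ridge parameter ``lambda = sigma2_e / sigma2_beta`` is not given it
is estimated by restricted maximum likelihood, profiling the REML likelihood
over lambda via the spectral decomposition of Z Z' — the standard efficient
route for p >> n, costing one O(n^3) eigendecomposition plus a bounded 1-D
search.

Effect estimates come from the dual (n x n) ridge form
``beta_hat = Z'(ZZ' + lambda I)^{-1}(y - 1 mu_hat)`` with the generalized
least squares intercept; this equals the primal (p x p) form
``(Z'Z + lambda I)^{-1} Z'(y - 1 mu_hat)`` exactly, which the tests verify.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .core_io import GenotypeMatrix, PhenotypeTable

__all__ = ["MarkerEffects", "fit_rrblup", "predict_gebv", "read_effects", "write_effects"]


class REMLDegeneracyError(ValueError):
    """Raised when REML cannot separate signal from noise (e.g. constant y)."""


@dataclasses.dataclass
class MarkerEffects:
    """Intercept plus per-marker additive effects (trait units per allele unit)."""

    marker_ids: list[str]
    intercept: float
    beta: np.ndarray
    lam: float
    variance_components: tuple[float, float] | None = None  # (sigma2_beta, sigma2_e)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.marker_ids),):
            raise ValueError("beta length must equal marker count")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    def aligned_beta(self, marker_ids: list[str]) -> np.ndarray:
        index = {m: i for i, m in enumerate(self.marker_ids)}
        missing = [m for m in marker_ids if m not in index]
        if missing:
            raise KeyError(
                f"{len(missing)} markers lack effect estimates (first: {missing[:5]})"
            )
        return self.beta[[index[m] for m in marker_ids]]


def _reml_lambda(xi: np.ndarray, eta2: np.ndarray, log_bounds=(-10.0, 10.0)) -> float:
    """Maximise the profiled REML log-likelihood over log(lambda).

    ``xi`` are the eigenvalues of the intercept-projected ZZ', ``eta2`` the
    squared projections of y on the corresponding eigenvectors.
    """
    m = xi.size  # = n - 1 error contrasts

    def neg_restricted_ll(log_lam: float) -> float:
        denom = xi + np.exp(log_lam)
        return m * np.log(eta2 @ (1.0 / denom)) + np.sum(np.log(denom))

    res = minimize_scalar(
        neg_restricted_ll, bounds=log_bounds, method="bounded",
        options={"xatol": 1e-8},
    )
    return float(np.exp(res.x))


def fit_rrblup(
    Z: GenotypeMatrix, y: PhenotypeTable, lam: float | None = None
) -> MarkerEffects:
    """Fit RR-BLUP marker effects on a complete training genotype matrix.

    Parameters
    ----------
    Z
        Training genotypes, no missing calls (impute first).
    y
        Phenotypes covering every training sample.
    lam
        Ridge parameter sigma2_e / sigma2_beta.  If omitted it is estimated
        by REML and the variance components are reported.
    """
    if Z.has_missing:
        raise ValueError("training genotypes contain missing calls; impute first")
    if Z.n_samples < 2:
        raise ValueError("need at least 2 training samples")
    yv = y.aligned_to(Z.sample_ids)
    if np.isnan(yv).any():
        raise ValueError("phenotypes contain missing values for training samples")
    n = Z.n_samples
    X = Z.calls
    K = X @ X.T

    variance_components = None
    if lam is None:
        if np.ptp(yv) == 0.0:
            raise REMLDegeneracyError(
                "phenotype is constant; REML for lambda is degenerate — "
                "pass an explicit lambda"
            )
        # project out the intercept, then eigendecompose the projected kernel
        S = np.eye(n) - np.full((n, n), 1.0 / n)
        w, U = np.linalg.eigh(S @ (K + np.eye(n)) @ S)
        # smallest eigenvalue (~0) belongs to the constant direction
        keep = np.argsort(w)[1:]
        xi = np.maximum(w[keep] - 1.0, 0.0)
        eta2 = (U[:, keep].T @ yv) ** 2
        lam = _reml_lambda(xi, eta2)
        sigma2_beta = float(eta2 @ (1.0 / (xi + lam)) / (n - 1))
        variance_components = (sigma2_beta, lam * sigma2_beta)
    elif lam <= 0:
        raise ValueError("lambda must be positive")

    V = K + lam * np.eye(n)
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular ridge system (lambda={lam})") from exc
    Vinv_y = np.linalg.solve(c.T, np.linalg.solve(c, yv))
    Vinv_1 = np.linalg.solve(c.T, np.linalg.solve(c, np.ones(n)))
    mu = float(np.ones(n) @ Vinv_y / (np.ones(n) @ Vinv_1))
    resid = yv - mu
    alpha = np.linalg.solve(c.T, np.linalg.solve(c, resid))
    beta = X.T @ alpha
    return MarkerEffects(list(Z.marker_ids), mu, beta, float(lam), variance_components)


def predict_gebv(g: GenotypeMatrix, effects: MarkerEffects) -> PhenotypeTable:
    """Genomic estimated breeding values: intercept + sum_i g_i beta_i."""
    if g.has_missing:
        raise ValueError("genotypes contain missing calls; impute first")
    beta = effects.aligned_beta(g.marker_ids)
    values = effects.intercept + g.calls @ beta
    return PhenotypeTable(list(g.sample_ids), values, "gebv")


def write_effects(effects: MarkerEffects, path: str | Path, header: str | None = None) -> None:
    """Effects TSV with intercept/lambda in ``#`` header lines (repr precision)."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        fh.write(f"# intercept\t{float(effects.intercept)!r}\n")
        fh.write(f"# lambda\t{float(effects.lam)!r}\n")
        if effects.variance_components is not None:
            sb, se = effects.variance_components
            fh.write(f"# sigma2_beta\t{float(sb)!r}\n")
            fh.write(f"# sigma2_e\t{float(se)!r}\n")
        fh.write("marker_id\tbeta\n")
        for m, b in zip(effects.marker_ids, effects.beta):
            fh.write(f"{m}\t{float(b)!r}\n")


def read_effects(path: str | Path) -> MarkerEffects:
    path = Path(path)
    intercept = lam = None
    vc: dict[str, float] = {}
    markers: list[str] = []
    betas: list[float] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2 and parts[0] in {
                    "intercept", "lambda", "sigma2_beta", "sigma2_e"
                }:
                    vc[parts[0]] = float(parts[1])
                continue
            fields = line.split("\t")
            if fields[0] == "marker_id":
                continue
            markers.append(fields[0])
            betas.append(float(fields[1]))
    intercept = vc.get("intercept")
    lam = vc.get("lambda")
    if intercept is None or lam is None:
        raise ValueError(f"effects file {path} lacks intercept/lambda header lines")
    variance_components = None
    if "sigma2_beta" in vc and "sigma2_e" in vc:
        variance_components = (vc["sigma2_beta"], vc["sigma2_e"])
    return MarkerEffects(markers, intercept, np.array(betas), lam, variance_components)
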