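"""Analytical prediction of progeny means and genetic variances of crosses.

For two fully homozygous parents with genotype vectors in {-1, +1} and
additive marker effects beta, the progeny of the cross segregate only at
loci where the parents differ.  Writing ``delta_i = (p1_i - p2_i)/2`` (so
``delta_i`` is 0 at fixed loci and +-1 at segregating loci, the sign
recording linkage phase relative to parent 1), the genetic mean and
variance of the derived family are

    mu_g      = intercept + sum_i beta_i (p1_i + p2_i) / 2
    sigma2_g  = sum_i sum_j beta_i beta_j delta_i delta_j c(r_ij)

where ``r_ij`` is the recombination fraction between markers i and j and
``c(r)`` is the mating-system disequilibrium factor:

    DH from F1 gametes:        c(r) = 1 - 2 r
    RIL by repeated selfing:   c(r) = (1 - 2 r) / (1 + 2 r)

Both factors equal 1 at complete linkage and 0 for unlinked loci, so the
double sum reduces to per-chromosome blocks over segregating loci —
``O(sum_c s_c^2)`` instead of ``O(p^2)``.  The Monte-Carlo meiosis
simulator in :mod:`crosspredict.synth` is the correctness oracle for these
closed forms.

The usefulness criterion ``U = mu + i * h * sigma_g`` scores a cross by the
expected mean of its selected progeny fraction (selection intensity ``i``,
prediction accuracy ``h``); the defaults i = h = 1 give the plain
``mu_g + sigma_g`` ranking criterion.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix
from .effects import MarkerEffects
from .linkage import RecombinationMatrix

__all__ = [
    "CrossPrediction",
    "UsefulnessConfig",
    "CrossRanking",
    "segregation_indicators",
    "covariance_factor",
    "predict_cross_mean",
    "predict_cross_variance",
    "predict_cross",
    "predict_crosses",
    "usefulness",
    "rank_crosses",
    "read_predictions",
    "write_predictions",
]

ProgenyType = Literal["DH_from_F1", "RIL_selfing"]

#: numerical floor below which a (theoretically >= 0) variance is clamped to 0
_VARIANCE_DUST = 1e-12


@dataclasses.dataclass
class UsefulnessConfig:
    """Selection intensity ``i`` and accuracy ``h`` for the usefulness score."""

    intensity: float = 1.0
    accuracy: float = 1.0

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("selection intensity must be >= 0")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy h must lie in [0, 1]")


@dataclasses.dataclass
class CrossPrediction:
    """Predicted genetic mean and variance of one biparental family."""

    parent1_id: str
    parent2_id: str
    progeny_type: str
    mu_hat: float
    sigma2_hat: float
    n_segregating: int

    def __post_init__(self) -> None:
        if self.sigma2_hat < 0:
            raise ValueError("sigma2_hat must be >= 0")

    @property
    def sigma_hat(self) -> float:
        return float(np.sqrt(self.sigma2_hat))

    @property
    def cross_id(self) -> str:
        return f"{self.parent1_id}x{self.parent2_id}"


@dataclasses.dataclass
class CrossRanking:
    """Crosses ordered by a score, best first; ties broken by cross id."""

    entries: list[tuple[str, float]]
    criterion: str

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("ranking scores must be non-increasing")

    @property
    def cross_ids(self) -> list[str]:
        return [c for c, _ in self.entries]

    def top(self, k: int) -> set[str]:
        return set(self.cross_ids[:k])


def segregation_indicators(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-locus segregation/phase indicator delta = (p1 - p2) / 2.

    0 at loci fixed in the cross, +1/-1 at segregating loci with the sign
    encoding which parent carries the +1 allele.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError(f"parent vectors differ in length: {p1.shape} vs {p2.shape}")
    for v, name in ((p1, "p1"), (p2, "p2")):
        if np.isnan(v).any():
            raise ValueError(f"{name} has missing calls")
        if not np.isin(v, (-1.0, 1.0)).all():
            raise ValueError(f"{name} has calls outside {{-1, +1}}")
    return (p1 - p2) / 2.0


def covariance_factor(r, progeny_type: ProgenyType = "DH_from_F1"):
    """Disequilibrium factor c(r) linking marker pairs within a family.

    ``1 - 2r`` for DH lines made from F1 gametes (one meiosis), and
    ``(1 - 2r)/(1 + 2r)`` for recombinant inbred lines derived by repeated
    selfing (linkage decays over the extra generations).
    """
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 0.5)):
        raise ValueError("recombination fraction must lie in [0, 0.5]")
    if progeny_type == "DH_from_F1":
        c = 1.0 - 2.0 * r
    elif progeny_type == "RIL_selfing":
        c = (1.0 - 2.0 * r) / (1.0 + 2.0 * r)
    else:
        raise ValueError(f"unknown progeny type {progeny_type!r}")
    return float(c) if c.ndim == 0 else c


def _parent_vectors(
    g: GenotypeMatrix, parent1: str, parent2: str, marker_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    sub = g.subset(samples=[parent1, parent2], markers=list(marker_ids))
    return sub.calls[0], sub.calls[1]


def predict_cross_mean(p1: np.ndarray, p2: np.ndarray, effects: MarkerEffects) -> float:
    """Mid-parent genomic value: the expected mean of the derived family.

    Under additivity the expected allele dosage of a DH (or RIL) progeny is
    the parental average, so mu_g is the mean of the two parental GEBVs.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != (len(effects.marker_ids),) or p2.shape != p1.shape:
        raise ValueError("parent vectors must match the effects' marker set")
    return float(effects.intercept + effects.beta @ ((p1 + p2) / 2.0))


def predict_cross_variance(
    p1: np.ndarray,
    p2: np.ndarray,
    effects: MarkerEffects,
    R: RecombinationMatrix,
    progeny_type: ProgenyType = "DH_from_F1",
) -> float:
    """Genetic variance of the family from the pairwise covariance sum.

    Only segregating loci contribute, and cross-chromosome pairs vanish
    (c(0.5) = 0), so the sum is evaluated chromosome-block-wise on the
    segregating subset.  Tiny negative round-off is clamped to 0 with a
    warning; the implied covariance matrix is positive semidefinite for any
    valid recombination structure, so true negatives cannot occur.
    """
    if R.marker_ids != effects.marker_ids:
        raise ValueError("recombination matrix and effects marker sets differ")
    delta = segregation_indicators(p1, p2)
    v = effects.beta * delta
    seg = np.nonzero(delta != 0.0)[0]
    total = 0.0
    chroms = R.chromosome[seg]
    for chrom in np.unique(chroms):
        idx = seg[chroms == chrom]
        C = covariance_factor(R.block(idx), progeny_type)
        np.fill_diagonal(C, 1.0)
        vc = v[idx]
        total += float(vc @ C @ vc)
    if total < 0.0:
        if total < -_VARIANCE_DUST:
            raise ValueError(f"negative cross variance {total}: invalid R?")
        warnings.warn("clamping negative round-off variance to 0", RuntimeWarning)
        total = 0.0
    return total


def usefulness(mu: float, sigma2: float, cfg: UsefulnessConfig | None = None) -> float:
    """Usefulness score U = mu + i * h * sigma_g (defaults: mu + sigma_g)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    cfg = cfg or UsefulnessConfig()
    return float(mu + cfg.intensity * cfg.accuracy * np.sqrt(sigma2))


def predict_cross(
    g: GenotypeMatrix,
    parent1: str,
    parent2: str,
    effects: MarkerEffects,
    R: RecombinationMatrix,
    progeny_type: ProgenyType = "DH_from_F1",
) -> CrossPrediction:
    """Predict mean and variance for one parent pair from a genotype matrix."""
    p1, p2 = _parent_vectors(g, parent1, parent2, effects.marker_ids)
    delta = segregation_indicators(p1, p2)
    return CrossPrediction(
        parent1_id=parent1,
        parent2_id=parent2,
        progeny_type=progeny_type,
        mu_hat=predict_cross_mean(p1, p2, effects),
        sigma2_hat=predict_cross_variance(p1, p2, effects, R, progeny_type),
        n_segregating=int(np.count_nonzero(delta)),
    )


def predict_crosses(
    g: GenotypeMatrix,
    pairs: Sequence[tuple[str, str]],
    effects: MarkerEffects,
    R: RecombinationMatrix,
    progeny_type: ProgenyType = "DH_from_F1",
) -> list[CrossPrediction]:
    return [predict_cross(g, a, b, effects, R, progeny_type) for a, b in pairs]


def rank_crosses(
    predictions: Sequence[CrossPrediction], cfg: UsefulnessConfig | None = None
) -> CrossRanking:
    """Rank crosses by usefulness, descending; ties broken by cross id."""
    if not predictions:
        raise ValueError("no predictions to rank")
    cfg = cfg or UsefulnessConfig()
    ids = [p.cross_id for p in predictions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cross ids in predictions")
    scored = [(p.cross_id, usefulness(p.mu_hat, p.sigma2_hat, cfg)) for p in predictions]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return CrossRanking(
        scored, f"usefulness(i={cfg.intensity}, h={cfg.accuracy})"
    )


def write_predictions(
    predictions: Sequence[CrossPrediction],
    path: str | Path,
    cfg: UsefulnessConfig | None = None,
    header: str | None = None,
) -> None:
    cfg = cfg or UsefulnessConfig()
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        fh.write(
            "parent1\tparent2\tmu_hat\tsigma2_hat\tsigma_hat\tusefulness\tn_segregating\n"
        )
        for p in predictions:
            u = usefulness(p.mu_hat, p.sigma2_hat, cfg)
            fh.write(
                f"{p.parent1_id}\t{p.parent2_id}\t{p.mu_hat!r}\t{p.sigma2_hat!r}\t"
                f"{p.sigma_hat!r}\t{u!r}\t{p.n_segregating}\n"
            )


def read_predictions(path: str | Path, progeny_type: str = "DH_from_F1") -> list[CrossPrediction]:
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype={0: str, 1: str})
    return [
        CrossPrediction(
            parent1_id=row.parent1,
            parent2_id=row.parent2,
            progeny_type=progeny_type,
            mu_hat=float(row.mu_hat),
            sigma2_hat=float(row.sigma2_hat),
            n_segregating=int(row.n_segregating),
        )
        for row in df.itertuples(index=False)
    ]
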