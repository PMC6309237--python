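"""Synthetic breeding program and the Monte-Carlo meiosis oracle.

Emulates the data structure of a small applied barley-type program: a
handful of inbred parents (donor x elite factorial), biparental DH families
of very unequal sizes, a dense SNP map on 7 chromosomes, an additive
genetic architecture, and an augmented multi-location yield trial with the
parents as replicated checks.

The meiosis simulator is the package's correctness oracle: gametes are
generated under the Markov no-interference model (crossover between
adjacent markers with probability given by the Haldane map function,
independently per interval), which is exactly the stochastic process whose
expectations the analytical cross-variance formula integrates.  Empirical
moments of large simulated DH families therefore converge to the analytical
mu_g and sigma2_g.

Default dimensions mirror the emulated program: 7 chromosomes of 140 cM,
9 parents, 14 families with sizes 1-37 totalling 200 DH lines, a 5-location
trial with 5 blocks per location.  Marker density defaults to 200 per
chromosome (1,400 genome-wide) so that full pipelines run in seconds; the
variance components and effect scale are chosen so that per-cross genetic
variances fall in ~1-15 trait-units^2 while the masking variance is ~30 —
the regime where trial noise, not genetics, dominates the phenotypic
variance of family means.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import GenotypeMatrix, PhenotypeTable, qc_filter
from .crosspred import CrossPrediction, predict_crosses
from .effects import MarkerEffects, fit_rrblup, predict_gebv
from .linkage import LinkageMap, haldane_r, recombination_matrix
from .trial import FieldTrialTable, TrialAnalysis, fit_trial_model, validate_families

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "ScenarioResult",
    "default_cross_plan",
    "simulate_map",
    "simulate_parents",
    "simulate_effects",
    "simulate_gamete",
    "simulate_dh_family",
    "simulate_trial",
    "end_to_end_scenario",
]


def default_cross_plan() -> list[tuple[str, str, int]]:
    """Donor x elite factorial with the emulated program's family sizes.

    14 families, sizes between 4 and 37, 200 DH lines in total; not every
    factorial cell produced viable offspring.
    """
    return [
        ("D1", "E1", 13), ("D1", "E2", 7), ("D1", "E3", 10),
        ("D1", "E4", 10), ("D1", "E5", 10),
        ("D2", "E1", 18), ("D2", "E3", 16), ("D2", "E4", 4), ("D2", "E5", 12),
        ("D3", "E1", 20), ("D3", "E3", 22), ("D3", "E5", 8),
        ("D4", "E4", 13), ("D4", "E5", 37),
    ]


@dataclasses.dataclass
class SimulationConfig:
    """Dimensions, genetic architecture and trial design of a scenario."""

    n_chromosomes: int = 7
    markers_per_chromosome: int = 200
    chromosome_length_cM: float = 140.0
    parent_ids: tuple[str, ...] = ("D1", "D2", "D3", "D4", "E1", "E2", "E3", "E4", "E5")
    cross_plan: list[tuple[str, str, int]] = dataclasses.field(
        default_factory=default_cross_plan
    )
    allele_freq_range: tuple[float, float] = (0.1, 0.9)
    effect_sd: float = 0.1206  # trait units per allele unit; gives sigma2_g ~ 1-15
    intercept: float = 90.0  # trait units (e.g. dt/ha for yield)
    n_locations: int = 5
    n_blocks: int = 5
    sigma2_location: float = 40.0
    sigma2_location_block: float = 20.0
    sigma2_error: float = 150.0
    mapping_function: str = "haldane"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.markers_per_chromosome < 1:
            raise ValueError("need >= 1 chromosome and >= 1 marker per chromosome")
        if self.chromosome_length_cM <= 0:
            raise ValueError("chromosome length must be > 0")
        if min(self.n_locations, self.n_blocks) < 1:
            raise ValueError("trial design sizes must be >= 1")
        for p1, p2, n in self.cross_plan:
            if n < 1:
                raise ValueError(f"family size must be >= 1 ({p1}x{p2}: {n})")
            if p1 not in self.parent_ids or p2 not in self.parent_ids:
                raise ValueError(f"cross plan references unknown parent: {p1}x{p2}")
        if min(self.sigma2_location, self.sigma2_location_block, self.sigma2_error) < 0:
            raise ValueError("variance components must be >= 0")


@dataclasses.dataclass
class TruthRecord:
    """Ground truth of a simulated scenario, for recovery tests."""

    effects: MarkerEffects
    genotypic_values: dict[str, float]
    variance_components: dict[str, float]


def simulate_map(cfg: SimulationConfig) -> LinkageMap:
    """Evenly spaced markers named ``c<chrom>_m<idx>`` on each chromosome."""
    rows = []
    m = cfg.markers_per_chromosome
    for c in range(1, cfg.n_chromosomes + 1):
        if m == 1:
            positions = [0.0]
        else:
            positions = np.linspace(0.0, cfg.chromosome_length_cM, m)
        for i, pos in enumerate(positions):
            rows.append((f"c{c}_m{i:04d}", str(c), float(pos)))
    return LinkageMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"]))


def simulate_parents(
    cfg: SimulationConfig, rng: np.random.Generator, lmap: LinkageMap | None = None
) -> GenotypeMatrix:
    """Independent inbred parents with per-marker +1 allele frequencies
    drawn uniformly from ``cfg.allele_freq_range``."""
    lmap = lmap if lmap is not None else simulate_map(cfg)
    markers = lmap.marker_ids
    lo, hi = cfg.allele_freq_range
    p = rng.uniform(lo, hi, size=len(markers))
    calls = np.where(
        rng.random((len(cfg.parent_ids), len(markers))) < p[None, :], 1.0, -1.0
    )
    return GenotypeMatrix(list(cfg.parent_ids), markers, calls)


def simulate_effects(
    cfg: SimulationConfig, rng: np.random.Generator, marker_ids: Sequence[str]
) -> MarkerEffects:
    """True additive effects beta ~ N(0, effect_sd^2) plus the intercept."""
    beta = rng.normal(0.0, cfg.effect_sd, size=len(marker_ids))
    return MarkerEffects(
        list(marker_ids), cfg.intercept, beta, lam=0.0,
        variance_components=(cfg.effect_sd**2, 0.0),
    )


def _chromosome_blocks(lmap: LinkageMap) -> list[tuple[np.ndarray, np.ndarray]]:
    """(index array, adjacent-interval r vector) per chromosome, map order."""
    t = lmap.table
    blocks = []
    for chrom in lmap.chromosomes:
        idx = np.nonzero((t["chromosome"] == chrom).to_numpy())[0]
        pos = t["position_cM"].to_numpy(float)[idx]
        r_adj = haldane_r(np.diff(pos)) if len(idx) > 1 else np.empty(0)
        blocks.append((idx, np.asarray(r_adj)))
    return blocks


def _simulate_dh_calls(
    p1: np.ndarray, p2: np.ndarray, lmap: LinkageMap, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n doubled gametes of the (virtual) F1 of two inbred parents.

    Per chromosome the parental origin starts at parent 1 or 2 with
    probability 1/2 and switches between adjacent markers with probability
    ``haldane_r(interval)``, independently per interval — the Markov
    no-interference crossover model.  The F1 never needs materialising:
    for inbred parents its two haplotypes are the parental genotypes, and
    doubling the gamete reproduces +-1 calls.
    """
    if n < 1:
        raise ValueError("family size must be >= 1")
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    if p1.shape != (len(lmap.marker_ids),) or p2.shape != p1.shape:
        raise ValueError("parent vectors must align with the map's markers")
    out = np.empty((n, p1.size))
    for idx, r_adj in _chromosome_blocks(lmap):
        m = idx.size
        start = rng.integers(0, 2, size=(n, 1))
        if m > 1:
            switches = rng.random((n, m - 1)) < r_adj[None, :]
            origin = (start + np.concatenate(
                [np.zeros((n, 1), dtype=int), np.cumsum(switches, axis=1)], axis=1
            )) % 2
        else:
            origin = start
        out[:, idx] = np.where(origin == 0, p1[idx][None, :], p2[idx][None, :])
    return out


def simulate_gamete(
    p1: np.ndarray, p2: np.ndarray, lmap: LinkageMap, rng: np.random.Generator
) -> np.ndarray:
    """One doubled gamete (DH genotype vector) of the cross p1 x p2."""
    return _simulate_dh_calls(p1, p2, lmap, 1, rng)[0]


def simulate_dh_family(
    p1: np.ndarray,
    p2: np.ndarray,
    lmap: LinkageMap,
    n: int,
    rng: np.random.Generator,
    prefix: str = "DH",
) -> GenotypeMatrix:
    """n independent DH lines from one cross, one simulated meiosis each."""
    calls = _simulate_dh_calls(p1, p2, lmap, n, rng)
    ids = [f"{prefix}_{i:05d}" for i in range(n)]
    return GenotypeMatrix(ids, lmap.marker_ids, calls)


def simulate_trial(
    genotypic_values: PhenotypeTable,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    checks: Sequence[str] = (),
) -> FieldTrialTable:
    """Augmented-design plot table around the given genotypic values.

    plot = genotypic value + location effect + block-within-location effect
    + residual.  Check entries appear in every block of every location;
    all other entries appear once per location in a uniformly assigned
    block.
    """
    check_set = set(checks)
    unknown = check_set - set(genotypic_values.sample_ids)
    if unknown:
        raise ValueError(f"checks without genotypic values: {sorted(unknown)[:5]}")
    gv = dict(zip(genotypic_values.sample_ids, genotypic_values.values))
    loc_ids = [f"L{i+1}" for i in range(cfg.n_locations)]
    blk_ids = [f"B{i+1}" for i in range(cfg.n_blocks)]
    loc_eff = rng.normal(0.0, np.sqrt(cfg.sigma2_location), size=cfg.n_locations)
    blk_eff = rng.normal(
        0.0, np.sqrt(cfg.sigma2_location_block), size=(cfg.n_locations, cfg.n_blocks)
    )
    rows = []
    test_entries = [s for s in genotypic_values.sample_ids if s not in check_set]
    for li, loc in enumerate(loc_ids):
        blocks_of = rng.integers(0, cfg.n_blocks, size=len(test_entries))
        for entry, bi in zip(test_entries, blocks_of):
            rows.append((entry, loc, blk_ids[bi], li, int(bi)))
        for entry in sorted(check_set):
            for bi, blk in enumerate(blk_ids):
                rows.append((entry, loc, blk, li, bi))
    resid = rng.normal(0.0, np.sqrt(cfg.sigma2_error), size=len(rows))
    records = [
        (entry, loc, blk, gv[entry] + loc_eff[li] + blk_eff[li, bi] + e)
        for (entry, loc, blk, li, bi), e in zip(rows, resid)
    ]
    return FieldTrialTable(
        pd.DataFrame(records, columns=["entry", "location", "block", "value"])
    )


@dataclasses.dataclass
class ScenarioResult:
    """All artifacts of one synthetic end-to-end run."""

    config: SimulationConfig
    linkage_map: LinkageMap
    parents: GenotypeMatrix
    truth: TruthRecord
    dh_lines: GenotypeMatrix
    family_map: dict[str, list[str]]
    trial: FieldTrialTable
    analysis: TrialAnalysis
    effects_used: MarkerEffects
    predictions: list[CrossPrediction]
    report: dict

    def report_json(self) -> str:
        return json.dumps(self.report, indent=2, sort_keys=True)

    def write(self, outdir: str | Path, header: str | None = None) -> None:
        from .core_io import write_genotypes, write_phenotypes
        from .crosspred import write_predictions
        from .effects import write_effects
        from .linkage import write_map
        from .trial import write_families, write_trial

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genotypes(self.parents, outdir / "parents.tsv", header)
        write_genotypes(self.dh_lines, outdir / "dh_lines.tsv", header)
        write_map(self.linkage_map, outdir / "map.tsv", header)
        write_trial(self.trial, outdir / "trial.tsv", header)
        write_families(self.family_map, outdir / "families.tsv")
        write_effects(self.truth.effects, outdir / "truth_effects.tsv", header)
        write_phenotypes(
            PhenotypeTable(
                list(self.truth.genotypic_values),
                np.array(list(self.truth.genotypic_values.values())),
                "true_genotypic_value",
            ),
            outdir / "truth_values.tsv",
            header,
        )
        write_effects(self.effects_used, outdir / "effects.tsv", header)
        write_predictions(self.predictions, outdir / "predictions.tsv", header=header)
        (outdir / "report.json").write_text(self.report_json() + "\n")


def end_to_end_scenario(
    cfg: SimulationConfig,
    seed: int | None = None,
    use_true_effects: bool = False,
) -> ScenarioResult:
    """Simulate a breeding program and run the full prediction pipeline.

    Stages: simulate (map, parents, true effects, DH families, trial) ->
    QC filter -> marker-effect estimation by RR-BLUP on the pooled DH lines'
    adjusted means (or the simulated true effects when
    ``use_true_effects``) -> per-cross mean/variance prediction from the
    parental genotypes -> trial mixed-model analysis -> validation report.
    Deterministic under the seed.
    """
    if seed is None:
        seed = cfg.seed
    if seed is None:
        raise ValueError("a seed is required for a stochastic scenario run")
    rng = np.random.default_rng(seed)

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"scenario stage '{name}' failed: {exc}") from exc

    lmap = stage("map", lambda: simulate_map(cfg))
    parents = stage("parents", lambda: simulate_parents(cfg, rng, lmap))
    true_effects = stage(
        "effects_truth", lambda: simulate_effects(cfg, rng, lmap.marker_ids)
    )

    family_map: dict[str, list[str]] = {}
    blocks = []
    for p1, p2, n in cfg.cross_plan:
        cross_id = f"{p1}x{p2}"
        fam = stage(
            f"family {cross_id}",
            lambda p1=p1, p2=p2, n=n, cross_id=cross_id: simulate_dh_family(
                parents.row(p1), parents.row(p2), lmap, n, rng, prefix=cross_id
            ),
        )
        family_map[cross_id] = fam.sample_ids
        blocks.append(fam)
    dh = GenotypeMatrix(
        [s for f in blocks for s in f.sample_ids],
        lmap.marker_ids,
        np.vstack([f.calls for f in blocks]),
    )

    gv_all = stage(
        "genotypic_values",
        lambda: predict_gebv(
            GenotypeMatrix(
                dh.sample_ids + parents.sample_ids,
                lmap.marker_ids,
                np.vstack([dh.calls, parents.calls]),
            ),
            true_effects,
        ),
    )
    truth = TruthRecord(
        effects=true_effects,
        genotypic_values=dict(zip(gv_all.sample_ids, map(float, gv_all.values))),
        variance_components={
            "sigma2_location": cfg.sigma2_location,
            "sigma2_location_block": cfg.sigma2_location_block,
            "sigma2_error": cfg.sigma2_error,
        },
    )

    trial_tab = stage(
        "trial", lambda: simulate_trial(gv_all, cfg, rng, checks=parents.sample_ids)
    )
    analysis = stage("trial_model", lambda: fit_trial_model(trial_tab))

    pooled = GenotypeMatrix(
        dh.sample_ids + parents.sample_ids,
        lmap.marker_ids,
        np.vstack([dh.calls, parents.calls]),
    )
    filtered, qc_report = stage("qc", lambda: qc_filter(pooled))
    kept_markers = filtered.marker_ids
    lmap_kept = lmap.subset(kept_markers)

    if use_true_effects:
        idx = [true_effects.marker_ids.index(m) for m in kept_markers]
        effects_used = MarkerEffects(
            kept_markers, true_effects.intercept, true_effects.beta[idx], lam=0.0,
            variance_components=true_effects.variance_components,
        )
    else:
        train = filtered.subset(
            samples=[s for s in filtered.sample_ids if s in set(dh.sample_ids)]
        )
        y_train = PhenotypeTable(
            train.sample_ids,
            np.array([analysis.mean_of(s) for s in train.sample_ids]),
            "adjusted_mean",
        )
        effects_used = stage("rrblup", lambda: fit_rrblup(train, y_train))

    R = stage(
        "recombination",
        lambda: recombination_matrix(lmap_kept, cfg.mapping_function),
    )
    parents_kept = parents.subset(markers=kept_markers)
    pairs = [(p1, p2) for p1, p2, _ in cfg.cross_plan]
    predictions = stage(
        "predict", lambda: predict_crosses(parents_kept, pairs, effects_used, R)
    )
    report = stage(
        "validate", lambda: validate_families(analysis, family_map, predictions)
    )
    report["qc"] = qc_report.to_dict()
    report["seed"] = seed
    return ScenarioResult(
        config=cfg,
        linkage_map=lmap,
        parents=parents,
        truth=truth,
        dh_lines=dh,
        family_map=family_map,
        trial=trial_tab,
        analysis=analysis,
        effects_used=effects_used,
        predictions=predictions,
        report=report,
    )
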