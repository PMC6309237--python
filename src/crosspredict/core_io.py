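"""Data model and IO for inbred-line genotypes, phenotypes and QC.

Genotypes of fully homozygous material (inbred parents, DH lines) are coded
-1/+1 per marker, with missing values allowed before quality control.  The
-1/+1 coding is deliberate: a locus segregating in a DH family then has a
per-locus genotypic variance of exactly 1, which keeps the cross-variance
formula free of coding constants.  Heterozygous calls are rejected at import
(TSV) or mapped to missing (VCF), since the material is assumed inbred.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "QCReport",
    "read_genotypes",
    "write_genotypes",
    "read_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "gene_diversity",
    "qc_filter",
    "impute_missing",
]


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed or contains bad calls."""


class EmptyResultError(ValueError):
    """Raised when a filter removes every marker; carries the QC report."""

    def __init__(self, message: str, report: "QCReport"):
        super().__init__(message)
        self.report = report


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dupes))[:5]}")


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x markers matrix of homozygous calls.

    Parameters
    ----------
    sample_ids, marker_ids
        Ordered unique identifiers for rows and columns.
    calls
        Float array of shape ``(n_samples, n_markers)``; entries are -1.0,
        +1.0 or NaN (missing).
    """

    sample_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray
    #: imputed matrices carry fractional mean dosages in [-1, 1]
    dosage: bool = False

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        _check_unique(self.sample_ids, "sample_ids")
        _check_unique(self.marker_ids, "marker_ids")
        finite = self.calls[~np.isnan(self.calls)]
        if self.dosage:
            if finite.size and (np.abs(finite) > 1.0).any():
                raise GenotypeParseError("dosage calls must lie in [-1, 1]")
        else:
            bad = finite[(finite != -1.0) & (finite != 1.0)]
            if bad.size:
                raise GenotypeParseError(
                    f"calls outside {{-1, +1, NA}}: first offending value {bad[0]!r}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.calls).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.sample_ids, columns=self.marker_ids)

    def subset(
        self,
        samples: Iterable[str] | None = None,
        markers: Iterable[str] | None = None,
    ) -> "GenotypeMatrix":
        """Return a new matrix restricted (and reordered) to the given ids."""
        s_ids = list(samples) if samples is not None else self.sample_ids
        m_ids = list(markers) if markers is not None else self.marker_ids
        s_index = {s: i for i, s in enumerate(self.sample_ids)}
        m_index = {m: j for j, m in enumerate(self.marker_ids)}
        missing_s = [s for s in s_ids if s not in s_index]
        missing_m = [m for m in m_ids if m not in m_index]
        if missing_s:
            raise KeyError(f"unknown sample ids: {missing_s[:5]}")
        if missing_m:
            raise KeyError(f"unknown marker ids: {missing_m[:5]}")
        rows = [s_index[s] for s in s_ids]
        cols = [m_index[m] for m in m_ids]
        return GenotypeMatrix(s_ids, m_ids, self.calls[np.ix_(rows, cols)], self.dosage)

    def row(self, sample_id: str) -> np.ndarray:
        return self.calls[self.sample_ids.index(sample_id)]


@dataclasses.dataclass
class PhenotypeTable:
    """Per-sample trait values (one record per sample)."""

    sample_ids: list[str]
    values: np.ndarray
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids),):
            raise ValueError("values must be a vector matching sample_ids")
        _check_unique(self.sample_ids, "sample_ids")
        if not np.all(np.isfinite(self.values) | np.isnan(self.values)):
            raise ValueError("phenotype values must be finite where present")

    def aligned_to(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Values reordered to ``sample_ids``; error if any id is missing."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return self.values[[index[s] for s in sample_ids]]
        except KeyError as exc:
            raise KeyError(f"sample {exc} has no phenotype record") from exc

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, self.trait: self.values})


@dataclasses.dataclass
class QCReport:
    """Bookkeeping of the marker and individual quality-control filters."""

    markers_removed_multiallelic: int = 0
    markers_removed_missing: int = 0
    markers_removed_diversity: int = 0
    samples_removed_missing: int = 0
    kept_marker_ids: list[str] = dataclasses.field(default_factory=list)
    kept_sample_ids: list[str] = dataclasses.field(default_factory=list)

    def reconciles(self, n_markers_in: int, n_samples_in: int) -> bool:
        ok_m = (
            len(self.kept_marker_ids)
            + self.markers_removed_missing
            + self.markers_removed_diversity
            == n_markers_in
        )
        ok_s = len(self.kept_sample_ids) + self.samples_removed_missing == n_samples_in
        return ok_m and ok_s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# readers / writers


def read_genotypes(path: str | Path, fmt: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from TSV or VCF.

    TSV layout: header ``sample_id<TAB>m1<TAB>m2...``, one sample per row,
    cells ``-1``, ``1`` or ``NA``.  VCF: biallelic SNPs only; ``0/0`` maps to
    -1, ``1/1`` to +1, heterozygous or partially missing calls to NA.
    """
    if fmt == "tsv":
        return _read_genotypes_tsv(path)
    if fmt == "vcf":
        gm, _ = read_vcf(path)
        return gm
    raise ValueError(f"unknown genotype format {fmt!r} (expected 'tsv' or 'vcf')")


def _read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, comment="#", na_values=["NA"], dtype=str
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeParseError(f"cannot parse {path}: {exc}") from exc
    try:
        calls = df.astype(float).to_numpy()
    except ValueError as exc:
        raise GenotypeParseError(f"non-numeric genotype call in {path}: {exc}") from exc
    return GenotypeMatrix(list(df.index), list(df.columns), calls)


def write_genotypes(g: GenotypeMatrix, path: str | Path, header: str | None = None) -> None:
    """Write TSV with integer-formatted calls and NA for missing."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        fh.write("sample_id\t" + "\t".join(g.marker_ids) + "\n")
        for sid, row in zip(g.sample_ids, g.calls):
            cells = ["NA" if np.isnan(v) else str(int(v)) for v in row]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_vcf(path: str | Path) -> tuple[GenotypeMatrix, int]:
    """Read homozygous calls from a biallelic-SNP VCF.

    Returns the matrix and the number of records dropped for having more
    than two recorded alleles.  Requires cyvcf2 (``pip install
    crosspredict[vcf]``).
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("VCF import requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    n_multiallelic = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multiallelic += 1
            continue
        col = np.full(len(samples), np.nan)
        # genotypes: [allele_a, allele_b, phased]
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a == 0 and b == 0:
                col[i] = -1.0
            elif a == 1 and b == 1:
                col[i] = 1.0
            # het or any missing allele stays NaN
        marker_ids.append(rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}")
        columns.append(col)
    calls = (
        np.column_stack(columns) if columns else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(samples, marker_ids, calls), n_multiallelic


def read_phenotypes(path: str | Path, trait: str | None = None) -> PhenotypeTable:
    """Read a two-column phenotype TSV (``sample_id<TAB>trait``)."""
    df = pd.read_csv(Path(path), sep="\t", comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"phenotype table {path} needs >=2 columns")
    trait_col = trait if trait is not None else df.columns[1]
    return PhenotypeTable(list(df.iloc[:, 0]), df[trait_col].to_numpy(float), trait_col)


def write_phenotypes(p: PhenotypeTable, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        fh.write(f"sample_id\t{p.trait}\n")
        for sid, val in zip(p.sample_ids, p.values):
            fh.write(f"{sid}\t{'NA' if np.isnan(val) else repr(float(val))}\n")


# ---------------------------------------------------------------------------
# QC


def gene_diversity(calls: np.ndarray) -> float:
    """Nei gene diversity 2*p*(1-p) of one biallelic marker.

    ``p`` is the frequency of the +1 allele among non-missing calls.
    Ranges from 0 (monomorphic) to 0.5 (balanced).
    """
    calls = np.asarray(calls, dtype=float)
    nonmiss = calls[~np.isnan(calls)]
    if nonmiss.size == 0:
        raise ValueError("gene diversity undefined: all calls missing")
    p = float(np.mean(nonmiss == 1.0))
    return 2.0 * p * (1.0 - p)


def qc_filter(
    g: GenotypeMatrix,
    max_marker_missing: float = 0.10,
    min_gene_diversity: float = 0.10,
    max_sample_missing: float = 0.15,
    markers_removed_multiallelic: int = 0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the marker and individual QC filters.

    Markers are filtered first: missing fraction strictly above
    ``max_marker_missing``, then gene diversity strictly below
    ``min_gene_diversity`` (computed on non-missing calls).  Samples with a
    missing fraction strictly above ``max_sample_missing`` *on the retained
    markers* are removed afterwards.  The order matters on edge cases and is
    fixed.  ``markers_removed_multiallelic`` lets a VCF importer's count flow
    into the report.
    """
    isnan = np.isnan(g.calls)
    marker_missing = isnan.mean(axis=0)
    drop_missing = marker_missing > max_marker_missing

    diversity = np.zeros(g.n_markers)
    for j in range(g.n_markers):
        if drop_missing[j] and isnan[:, j].all():
            continue  # all-missing marker already dropped by the missing rule
        diversity[j] = gene_diversity(g.calls[:, j])
    drop_div = (~drop_missing) & (diversity < min_gene_diversity)

    keep_m = ~(drop_missing | drop_div)
    report = QCReport(
        markers_removed_multiallelic=markers_removed_multiallelic,
        markers_removed_missing=int(drop_missing.sum()),
        markers_removed_diversity=int(drop_div.sum()),
    )
    if not keep_m.any():
        report.kept_sample_ids = list(g.sample_ids)
        raise EmptyResultError("qc_filter removed every marker", report)

    kept_calls = g.calls[:, keep_m]
    sample_missing = np.isnan(kept_calls).mean(axis=1)
    keep_s = sample_missing <= max_sample_missing
    report.samples_removed_missing = int((~keep_s).sum())
    report.kept_marker_ids = [m for m, k in zip(g.marker_ids, keep_m) if k]
    report.kept_sample_ids = [s for s, k in zip(g.sample_ids, keep_s) if k]
    filtered = GenotypeMatrix(
        report.kept_sample_ids, report.kept_marker_ids, kept_calls[keep_s]
    )
    return filtered, report


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker mean over non-missing calls.

    The output has no missing cells and is suitable for RR-BLUP; run
    :func:`qc_filter` first so every marker has at least one call.
    """
    calls = g.calls.copy()
    isnan = np.isnan(calls)
    if not isnan.any():
        return GenotypeMatrix(list(g.sample_ids), list(g.marker_ids), calls, g.dosage)
    all_missing = isnan.all(axis=0)
    if all_missing.any():
        bad = [m for m, a in zip(g.marker_ids, all_missing) if a]
        raise ValueError(
            f"markers with no observed calls (run qc_filter first): {bad[:5]}"
        )
    col_means = np.nanmean(calls, axis=0)
    rows, cols = np.nonzero(isnan)
    calls[rows, cols] = col_means[cols]
    return GenotypeMatrix(list(g.sample_ids), list(g.marker_ids), calls, dosage=True)
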