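"""Linkage maps and map-distance to recombination-fraction conversion.

Positions are centimorgans (cM) throughout the user-facing API; the /100
Morgan conversion is internal to the mapping functions.  Markers on
different chromosomes are treated as unlinked (r = 0.5), so their
contribution to cross-variance covariance terms vanishes.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LinkageMap",
    "RecombinationMatrix",
    "haldane_r",
    "kosambi_r",
    "recombination_matrix",
    "read_map",
    "write_map",
]


def haldane_r(d) -> np.ndarray | float:
    """Haldane mapping function: r = (1 - exp(-2 d / 100)) / 2 for d in cM.

    Assumes crossovers form a Poisson process (no interference); this is
    exactly the meiosis model of the Monte-Carlo simulator, so analytical
    and simulated recombination agree in expectation.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0 cM")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def kosambi_r(d) -> np.ndarray | float:
    """Kosambi mapping function: r = tanh(2 d / 100) / 2 for d in cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0 cM")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


MAPPING_FUNCTIONS: dict[str, Callable] = {"haldane": haldane_r, "kosambi": kosambi_r}


@dataclasses.dataclass
class LinkageMap:
    """Marker order and cM positions on named chromosomes.

    Rows are sorted by (chromosome, position) on construction, so positions
    are non-decreasing within each chromosome.
    """

    table: pd.DataFrame  # columns: marker, chromosome, position_cM

    def __post_init__(self) -> None:
        t = self.table
        required = {"marker", "chromosome", "position_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"linkage map needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dupes = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate markers in map: {dupes[:5]}")
        if (t["position_cM"] < 0).any():
            raise ValueError("map positions must be >= 0 cM")
        self.table = (
            t.assign(
                marker=t["marker"].astype(str), chromosome=t["chromosome"].astype(str)
            )
            .sort_values(["chromosome", "position_cM"], kind="stable")
            .reset_index(drop=True)
        )

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker"].tolist()

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chromosome"]))

    def positions(self) -> np.ndarray:
        return self.table["position_cM"].to_numpy(float)

    def subset(self, markers: Sequence[str]) -> "LinkageMap":
        markers = set(map(str, markers))
        return LinkageMap(self.table[self.table["marker"].isin(markers)].copy())

    def check_covers(self, marker_ids: Sequence[str], drop_unmapped: bool = False) -> list[str]:
        """Verify every genotype marker has a map position.

        Returns the covered marker list.  Unmapped markers are an error
        unless ``drop_unmapped`` is set — silently dropping them would
        change variance predictions invisibly.
        """
        mapped = set(self.marker_ids)
        missing = [m for m in marker_ids if m not in mapped]
        if missing and not drop_unmapped:
            raise KeyError(
                f"{len(missing)} markers missing from the linkage map "
                f"(first: {missing[:5]}); pass drop_unmapped=True to discard them"
            )
        return [m for m in marker_ids if m in mapped]


@dataclasses.dataclass
class RecombinationMatrix:
    """Pairwise recombination fractions, materialised lazily.

    Stores the map geometry and the mapping function; dense blocks are
    produced on demand so that genome-sized marker sets never allocate a
    p x p array.  Cross-chromosome pairs have r = 0.5 exactly.
    """

    marker_ids: list[str]
    chromosome: np.ndarray  # per-marker chromosome label
    position_cM: np.ndarray
    mapping_function: str = "haldane"

    def __post_init__(self) -> None:
        if self.mapping_function not in MAPPING_FUNCTIONS:
            raise ValueError(f"unknown mapping function {self.mapping_function!r}")
        self.chromosome = np.asarray(self.chromosome)
        self.position_cM = np.asarray(self.position_cM, dtype=float)
        n = len(self.marker_ids)
        if self.chromosome.shape != (n,) or self.position_cM.shape != (n,):
            raise ValueError("chromosome/position arrays must match marker_ids")
        if len(set(self.marker_ids)) != n:
            raise ValueError("duplicate marker_ids")
        self._index = {m: i for i, m in enumerate(self.marker_ids)}

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def block(self, indices: np.ndarray) -> np.ndarray:
        """Dense r submatrix for the given marker indices."""
        f = MAPPING_FUNCTIONS[self.mapping_function]
        pos = self.position_cM[indices]
        chrom = self.chromosome[indices]
        r = f(np.abs(pos[:, None] - pos[None, :]))
        r = np.where(chrom[:, None] == chrom[None, :], r, 0.5)
        np.fill_diagonal(r, 0.0)
        return r

    def dense(self) -> np.ndarray:
        return self.block(np.arange(self.n_markers))

    def r(self, marker_i: str, marker_j: str) -> float:
        i, j = self._index[marker_i], self._index[marker_j]
        if i == j:
            return 0.0
        if self.chromosome[i] != self.chromosome[j]:
            return 0.5
        f = MAPPING_FUNCTIONS[self.mapping_function]
        return float(f(abs(self.position_cM[i] - self.position_cM[j])))

    def indices_of(self, markers: Sequence[str]) -> np.ndarray:
        return np.array([self._index[m] for m in markers], dtype=int)


def recombination_matrix(
    lmap: LinkageMap, mapping_function: str = "haldane"
) -> RecombinationMatrix:
    """Build the pairwise recombination structure for a linkage map."""
    return RecombinationMatrix(
        lmap.marker_ids,
        lmap.table["chromosome"].to_numpy(),
        lmap.positions(),
        mapping_function,
    )


def read_map(path: str | Path) -> LinkageMap:
    """Read a map TSV: ``marker_id<TAB>chromosome<TAB>position_cM``.

    A header row is optional; lines starting with ``#`` are comments.
    """
    df = pd.read_csv(
        Path(path),
        sep="\t",
        comment="#",
        header=None,
        names=["marker", "chromosome", "position_cM"],
        dtype={0: str, 1: str},
    )
    # tolerate a header row: drop it if the position column is non-numeric there
    first_pos = pd.to_numeric(df["position_cM"].iloc[:1], errors="coerce")
    if len(df) and np.isnan(first_pos.iloc[0]):
        df = df.iloc[1:].reset_index(drop=True)
    df["position_cM"] = pd.to_numeric(df["position_cM"])
    return LinkageMap(df)


def write_map(lmap: LinkageMap, path: str | Path, header: str | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        for _, row in lmap.table.iterrows():
            fh.write(f"{row.marker}\t{row.chromosome}\t{float(row.position_cM)!r}\n")
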