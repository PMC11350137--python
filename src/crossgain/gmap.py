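"""Genetic maps and recombination-fraction arithmetic.

Positions are genetic (centiMorgan). Distances are converted to
recombination fractions with Haldane's mapping function (no crossover
interference), the assumption underlying both the meiosis simulator and
the analytic recombinant-inbred-line disequilibrium used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GeneticMap", "haldane_c", "MapError"]


class MapError(ValueError):
    """Raised for malformed or inconsistent genetic maps."""


def haldane_c(d_cm):
    """Recombination fraction for a genetic distance in cM (Haldane).

    c = 0.5 * (1 - exp(-2d)) with d in Morgans. Vectorized.
    """
    d = np.asarray(d_cm, dtype=float) / 100.0
    if np.any(d < 0):
        raise ValueError("genetic distance must be non-negative")
    return 0.5 * (1.0 - np.exp(-2.0 * d))


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker map: unique ids, integer chromosome, cM position.

    Markers are stored sorted by (chromosome, position); all genotype
    matrices in the package are column-aligned to this order.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        mid = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=int)
        pos = np.asarray(self.position, dtype=float)
        if not (mid.shape == chrom.shape == pos.shape) or mid.ndim != 1:
            raise MapError("marker_id, chromosome, position must be equal-length 1-D")
        if len(set(mid)) != mid.size:
            raise MapError("duplicate marker ids in map")
        if not np.all(np.isfinite(pos)):
            raise MapError("non-finite map positions")
        if np.any(pos < 0):
            raise MapError("negative map positions")
        if np.any(chrom < 1):
            raise MapError("chromosome numbers must be >= 1")
        order = np.lexsort((pos, chrom))
        mid, chrom, pos = mid[order], chrom[order], pos[order]
        for c in np.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):  # cannot happen after lexsort
                raise MapError(f"unsorted positions on chromosome {c}")
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "_index", {m: i for i, m in enumerate(mid)})

    def __len__(self):
        return self.marker_id.size

    @property
    def n_markers(self) -> int:
        return self.marker_id.size

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def index_of(self, marker) -> int:
        try:
            return self._index[marker]
        except KeyError:
            raise MapError(f"unknown marker: {marker!r}") from None

    def chromosome_slices(self) -> list[slice]:
        """Contiguous column slice per chromosome, in sorted chromosome order."""
        out = []
        start = 0
        for c in self.chromosomes:
            n = int(np.sum(self.chromosome == c))
            out.append(slice(start, start + n))
            start += n
        return out

    def interval_recomb(self) -> np.ndarray:
        """Per-marker switch probabilities for gamete simulation.

        Entry i is the recombination fraction between marker i-1 and i
        when both lie on the same chromosome, and 0.5 at the first marker
        of every chromosome (independent assortment / random start phase).
        """
        c = np.empty(self.n_markers)
        if self.n_markers == 0:
            return c
        d = np.diff(self.position)
        same = np.diff(self.chromosome) == 0
        c[0] = 0.5
        c[1:] = np.where(same, haldane_c(np.maximum(d, 0.0)), 0.5)
        return c

    def recomb_fraction(self, i, j) -> float:
        """Pairwise recombination fraction between markers i and j.

        Accepts integer column indices or marker ids; 0.5 across
        chromosomes, Haldane of the cM distance within a chromosome.
        """
        i = i if isinstance(i, (int, np.integer)) else self.index_of(i)
        j = j if isinstance(j, (int, np.integer)) else self.index_of(j)
        if not (0 <= i < self.n_markers and 0 <= j < self.n_markers):
            raise MapError("marker index out of range")
        if self.chromosome[i] != self.chromosome[j]:
            return 0.5
        return float(haldane_c(abs(self.position[i] - self.position[j])))

    def recomb_matrix(self, indices) -> np.ndarray:
        """Pairwise recombination fractions for a set of column indices."""
        idx = np.asarray(indices, dtype=int)
        pos = self.position[idx]
        chrom = self.chromosome[idx]
        c = haldane_c(np.abs(pos[:, None] - pos[None, :]))
        c[chrom[:, None] != chrom[None, :]] = 0.5
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_id,
                "chromosome": self.chromosome,
                "position_cM": self.position,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        required = {"marker", "chromosome", "position_cM"}
        missing = required - set(df.columns)
        if missing:
            raise MapError(f"map is missing columns: {sorted(missing)}")
        return cls(
            df["marker"].to_numpy(object),
            df["chromosome"].to_numpy(int),
            df["position_cM"].to_numpy(float),
        )

    @classmethod
    def uniform(cls, n_chromosomes: int, markers_per_chromosome: int,
                length_cm: float) -> "GeneticMap":
        """Evenly spaced synthetic map (marker ids ``c{chrom}_m{k}``)."""
        ids, chroms, pos = [], [], []
        for c in range(1, n_chromosomes + 1):
            p = np.linspace(0.0, length_cm, markers_per_chromosome)
            for k in range(markers_per_chromosome):
                ids.append(f"c{c}_m{k + 1}")
            chroms.extend([c] * markers_per_chromosome)
            pos.extend(p.tolist())
        return cls(np.array(ids, object), np.array(chroms), np.array(pos))
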