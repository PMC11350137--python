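"""Line-by-marker dosage matrices aligned to a genetic map."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "GenotypeError"]


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """Lines x markers dosages in {-1, 0, +1}, NaN for missing calls.

    Column order must match the :class:`~crossgain.gmap.GeneticMap` the
    matrix was built against; readers enforce this.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray  # float array, values in {-1, 0, 1} or NaN

    def __post_init__(self):
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be 2-D (lines x markers)")
        n, m = self.dosages.shape
        if self.line_ids.size != n:
            raise GenotypeError("line_ids length does not match dosage rows")
        if self.marker_ids.size != m:
            raise GenotypeError("marker_ids length does not match dosage columns")
        if len(set(self.line_ids)) != n:
            raise GenotypeError("duplicate line ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        bad = ~np.isin(vals, (-1.0, 0.0, 1.0))
        if np.any(bad):
            raise GenotypeError(
                f"dosages outside {{-1,0,1}}: e.g. {vals[bad][:3].tolist()}"
            )
        self._row = {l: i for i, l in enumerate(self.line_ids)}

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def row(self, line_id) -> np.ndarray:
        try:
            return self.dosages[self._row[line_id]]
        except KeyError:
            raise GenotypeError(f"unknown line: {line_id!r}") from None

    def has_line(self, line_id) -> bool:
        return line_id in self._row

    def subset(self, line_ids) -> "GenotypeMatrix":
        idx = [self._row[l] for l in line_ids]
        return GenotypeMatrix(
            np.asarray(line_ids, object), self.marker_ids, self.dosages[idx]
        )

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the column mean (0 if all missing)."""
        Z = self.dosages.copy()
        if np.isnan(Z).any():
            col_mean = np.nanmean(np.where(np.isnan(Z), np.nan, Z), axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            nr, nc = np.nonzero(np.isnan(Z))
            Z[nr, nc] = col_mean[nc]
        return Z

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.dosages, columns=self.marker_ids)
        df.insert(0, "line_id", self.line_ids)
        return df
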