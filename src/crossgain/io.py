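"""Readers/writers for the plain-text pipeline formats.

All tables are TSV/CSV with documented headers; files written by this
package start with a ``#`` provenance comment line (seed, config hash)
which the readers skip. Readers validate rather than coerce: out-of-range
dosages, duplicate keys and unknown references raise with row/column
context instead of silently passing through.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, GenotypeError
from .gmap import GeneticMap, MapError

log = logging.getLogger(__name__)

__all__ = [
    "read_genotypes", "write_genotypes",
    "read_map", "write_map",
    "read_phenotypes", "write_phenotypes",
    "read_pedigree", "write_pedigree",
    "read_blues", "write_blues",
    "write_dataset", "provenance_line", "config_hash",
]

PHENO_COLUMNS = ["line_id", "family_id", "env_id", "set_id", "is_check",
                 "trait", "value"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_line(seed=None, config=None) -> str:
    parts = ["# crossgain"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config is not None:
        parts.append(f"config_hash={config_hash(config)}")
    return " ".join(parts)


def _write_table(df: pd.DataFrame, path, sep, seed=None, config=None,
                 float_format="%.10g"):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_line(seed, config) + "\n")
        df.to_csv(fh, sep=sep, index=False, float_format=float_format)


def _read_table(path, sep) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#")


# -- genotypes ---------------------------------------------------------------

def write_genotypes(geno: GenotypeMatrix, path, seed=None, config=None):
    _write_table(geno.to_frame(), path, sep="\t", seed=seed, config=config)


def read_genotypes(path, gmap: GeneticMap | None = None) -> GenotypeMatrix:
    """TSV with line_id first column, one dosage column per marker.

    Dosages must be -1/0/1 or empty (missing). When a map is given, the
    column order must match it exactly.
    """
    df = _read_table(path, sep="\t")
    if df.columns[0] != "line_id":
        raise GenotypeError(f"{path}: first column must be line_id")
    markers = df.columns[1:].to_numpy(object)
    dosages = df.iloc[:, 1:].to_numpy(float)
    vals = dosages[~np.isnan(dosages)]
    bad = ~np.isin(vals, (-1.0, 0.0, 1.0))
    if bad.any():
        r, c = np.argwhere(~np.isin(np.nan_to_num(dosages, nan=0.0),
                                    (-1.0, 0.0, 1.0)))[0]
        raise GenotypeError(
            f"{path}: dosage {dosages[r, c]!r} out of range at line "
            f"{df.iloc[r, 0]!r}, marker {markers[c]!r}")
    geno = GenotypeMatrix(df["line_id"].to_numpy(object), markers, dosages)
    if gmap is not None:
        if not np.array_equal(markers, gmap.marker_id):
            extra = set(markers) - set(gmap.marker_id)
            if extra:
                raise GenotypeError(
                    f"{path}: markers absent from map: {sorted(extra)[:5]}")
            raise GenotypeError(f"{path}: marker columns not in map order")
    log.info("read %d lines x %d markers from %s", geno.n_lines,
             geno.n_markers, path)
    return geno


# -- map ---------------------------------------------------------------------

def write_map(gmap: GeneticMap, path, seed=None, config=None):
    _write_table(gmap.to_frame(), path, sep=",", seed=seed, config=config)


def read_map(path) -> GeneticMap:
    df = _read_table(path, sep=",")
    try:
        return GeneticMap.from_frame(df)
    except MapError as exc:
        raise MapError(f"{path}: {exc}") from None


# -- phenotypes --------------------------------------------------------------

def write_phenotypes(phenos: pd.DataFrame, path, seed=None, config=None):
    _write_table(phenos[PHENO_COLUMNS], path, sep=",", seed=seed, config=config)


def read_phenotypes(path, known_lines=None) -> pd.DataFrame:
    df = _read_table(path, sep=",")
    missing = set(PHENO_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if known_lines is not None:
        known = set(known_lines)
        unknown = set(df.loc[df["is_check"] != 1, "line_id"]) - known
        if unknown:
            raise ValueError(
                f"{path}: phenotype rows reference unknown lines: "
                f"{sorted(unknown)[:5]}")
    return df


# -- pedigree ----------------------------------------------------------------

def write_pedigree(ped: pd.DataFrame, path, seed=None, config=None):
    _write_table(ped[["family_id", "parent1", "parent2"]], path, sep=",",
                 seed=seed, config=config)


def read_pedigree(path, known_parents=None) -> pd.DataFrame:
    df = _read_table(path, sep=",")
    missing = {"family_id", "parent1", "parent2"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["family_id"].duplicated().any():
        dups = df.loc[df["family_id"].duplicated(), "family_id"].tolist()
        raise ValueError(f"{path}: duplicate families {dups[:5]}")
    if known_parents is not None:
        known = set(known_parents)
        orphans = (set(df["parent1"]) | set(df["parent2"])) - known
        if orphans:
            raise ValueError(
                f"{path}: parents without genotypes: {sorted(orphans)[:5]}")
    return df


# -- BLUEs -------------------------------------------------------------------

def write_blues(blues: pd.DataFrame, path, seed=None, config=None):
    _write_table(blues[["line_id", "trait", "blue", "se"]], path, sep=",",
                 seed=seed, config=config)


def read_blues(path) -> pd.DataFrame:
    df = _read_table(path, sep=",")
    missing = {"line_id", "trait", "blue"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# -- bundles -----------------------------------------------------------------

def write_dataset(ds, outdir, seed=None):
    """Write a simulated NAM bundle (genotypes, map, phenos, pedigree, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = ds.config.to_dict()
    write_map(ds.gmap, outdir / "map.csv", seed=seed, config=cfg)
    all_geno = GenotypeMatrix(
        np.concatenate([ds.parents.line_ids, ds.genotypes.line_ids]),
        ds.gmap.marker_id,
        np.vstack([ds.parents.dosages, ds.genotypes.dosages]),
    )
    write_genotypes(all_geno, outdir / "genotypes.tsv", seed=seed, config=cfg)
    write_phenotypes(ds.phenotypes, outdir / "phenos.csv", seed=seed, config=cfg)
    write_pedigree(ds.pedigree, outdir / "pedigree.csv", seed=seed, config=cfg)
    fam_map = pd.DataFrame({"line_id": ds.genotypes.line_ids,
                            "family_id": ds.families})
    _write_table(fam_map, outdir / "families.csv", sep=",", seed=seed, config=cfg)
    truth = {"seed": seed, "config": cfg, "families": ds.truth.to_dict()}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
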