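"""Data containers and file I/O for dominant binary marker studies.

The raw material of the analysis is a binary marker matrix: one genotyped
individual per row, labelled with its species and its census plot, and one
dominant locus per column scored 1 (band present, the dominant phenotype)
or 0 (band absent, i.e. only recessive allelic variants at that position).
Missing scores are kept explicit — they reduce the per-locus sample size
and are never imputed or coerced to 0.

Alongside the marker matrix live two small community tables: a plot x
species abundance table (the input to the species-diversity profiles) and
a census table of adult stems per plot and species (the input to the
abundance covariations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerFormatError",
    "BinaryMarkerMatrix",
    "AbundanceTable",
    "read_marker_matrix",
    "write_marker_matrix",
    "read_abundance_table",
    "write_abundance_table",
    "read_census",
    "write_census",
    "locus_frequencies",
    "filter_loci",
]

META_COLUMNS = ("individual_id", "species", "plot")

#: String used for missing calls in the on-disk TSV/CSV representation.
MISSING_TOKEN = "NA"


class MarkerFormatError(ValueError):
    """Raised when a marker matrix file or object violates the format contract."""


def _infer_sep(path: Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if path.suffix.lower() == ".csv" else "\t"


@dataclass
class BinaryMarkerMatrix:
    """Individuals x dominant loci with 0/1/missing calls.

    Parameters
    ----------
    meta
        One row per individual with columns ``individual_id``, ``species``
        and ``plot``.  Individual ids must be unique.
    calls
        Float frame aligned row-wise with *meta*; values are 0.0, 1.0 or
        NaN (missing).  Column labels are the locus ids.
    """

    meta: pd.DataFrame
    calls: pd.DataFrame

    def __post_init__(self) -> None:
        meta = self.meta.reset_index(drop=True)
        calls = self.calls.reset_index(drop=True)
        missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
        if missing_cols:
            raise MarkerFormatError(f"meta is missing columns {missing_cols}")
        if len(meta) != len(calls):
            raise MarkerFormatError(
                f"meta has {len(meta)} rows but calls has {len(calls)}"
            )
        dup = meta["individual_id"][meta["individual_id"].duplicated()]
        if len(dup):
            raise MarkerFormatError(
                f"duplicate individual ids: {sorted(set(dup))[:5]}"
            )
        if calls.columns.duplicated().any():
            raise MarkerFormatError("locus ids are not unique")
        values = calls.to_numpy(dtype=float)
        bad = ~(np.isnan(values) | (values == 0.0) | (values == 1.0))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise MarkerFormatError(
                "non-binary call value "
                f"{values[r, c]!r} for individual "
                f"{meta['individual_id'].iloc[r]!r} at locus {calls.columns[c]!r}"
            )
        self.meta = meta
        self.calls = calls.astype(float)

    # -- convenience accessors -------------------------------------------------

    @property
    def locus_ids(self) -> list[str]:
        return [str(c) for c in self.calls.columns]

    @property
    def n_individuals(self) -> int:
        return len(self.meta)

    @property
    def plots(self) -> list[str]:
        return sorted(self.meta["plot"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.meta["species"].unique())

    def subset(
        self, *, species: str | None = None, plots: list[str] | None = None
    ) -> "BinaryMarkerMatrix":
        """Rows restricted to one species and/or a set of plots."""
        mask = pd.Series(True, index=self.meta.index)
        if species is not None:
            mask &= self.meta["species"] == species
        if plots is not None:
            mask &= self.meta["plot"].isin(plots)
        if not mask.any():
            raise MarkerFormatError(
                f"subset (species={species!r}, plots={plots!r}) selects no individuals"
            )
        return BinaryMarkerMatrix(self.meta[mask], self.calls[mask])

    def select_loci(self, locus_ids: list[str]) -> "BinaryMarkerMatrix":
        missing = [l for l in locus_ids if l not in self.calls.columns]
        if missing:
            raise MarkerFormatError(f"unknown loci: {missing[:5]}")
        return BinaryMarkerMatrix(self.meta, self.calls[list(locus_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinaryMarkerMatrix):
            return NotImplemented
        return self.meta.equals(other.meta) and self.calls.equals(other.calls)


@dataclass
class AbundanceTable:
    """Plot x species counts of stems; rows are plots, columns species."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.columns.duplicated().any():
            raise MarkerFormatError("species ids are not unique")
        if counts.index.duplicated().any():
            raise MarkerFormatError("plot labels are not unique")
        values = counts.to_numpy()
        if (values < 0).any() or not np.allclose(values, np.round(values)):
            raise MarkerFormatError("abundance counts must be nonnegative integers")
        empty = counts.sum(axis=1) == 0
        if empty.any():
            raise MarkerFormatError(
                f"plots with zero total abundance: {list(counts.index[empty])}"
            )
        self.counts = counts.astype(int)

    @property
    def plots(self) -> list[str]:
        return [str(p) for p in self.counts.index]

    @property
    def species_ids(self) -> list[str]:
        return [str(s) for s in self.counts.columns]

    def frequencies(self, plot: str) -> np.ndarray:
        """Within-plot relative species frequencies (zeros dropped)."""
        row = self.counts.loc[plot].to_numpy(dtype=float)
        total = row.sum()
        if total <= 0:
            raise MarkerFormatError(f"plot {plot!r} has zero total abundance")
        return row[row > 0] / total

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return self.counts.equals(other.counts)


# -- file readers / writers ----------------------------------------------------


def read_marker_matrix(path: str | Path, sep: str | None = None) -> BinaryMarkerMatrix:
    """Read a marker matrix from TSV/CSV.

    Expected header: ``individual_id, species, plot, <locus_1 ... locus_L>``;
    calls are ``0``/``1`` with missing values written as ``NA``.  Any other
    call value is rejected with the offending individual and locus named.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep=_infer_sep(path, sep), dtype=str, na_values=[MISSING_TOKEN]
    )
    missing_cols = [c for c in META_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise MarkerFormatError(f"{path}: missing required columns {missing_cols}")
    meta = frame[list(META_COLUMNS)]
    raw = frame.drop(columns=list(META_COLUMNS))
    if raw.shape[1] == 0:
        raise MarkerFormatError(f"{path}: no locus columns found")
    calls = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        column = raw[col]
        ok = column.isna() | column.isin(["0", "1"])
        if not ok.all():
            row = int(np.argmax(~ok.to_numpy()))
            raise MarkerFormatError(
                f"{path}: invalid call {column.iloc[row]!r} for individual "
                f"{meta['individual_id'].iloc[row]!r} at locus {col!r}"
            )
        calls[col] = column.astype(float)
    return BinaryMarkerMatrix(meta, calls)


def write_marker_matrix(
    m: BinaryMarkerMatrix, path: str | Path, sep: str | None = None
) -> None:
    path = Path(path)
    calls = m.calls.map(lambda v: MISSING_TOKEN if pd.isna(v) else str(int(v)))
    out = pd.concat([m.meta.reset_index(drop=True), calls.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep=_infer_sep(path, sep), index=False)


def read_abundance_table(path: str | Path, sep: str | None = None) -> AbundanceTable:
    """Read a plot x species table: first column holds plot labels."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_infer_sep(path, sep), index_col=0)
    return AbundanceTable(frame)


def write_abundance_table(
    t: AbundanceTable, path: str | Path, sep: str | None = None
) -> None:
    path = Path(path)
    t.counts.to_csv(path, sep=_infer_sep(path, sep), index_label="plot")


def read_census(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a long-format census table with columns ``plot, species, N``."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_infer_sep(path, sep))
    required = {"plot", "species", "N"}
    if not required.issubset(frame.columns):
        raise MarkerFormatError(f"{path}: census needs columns {sorted(required)}")
    if (frame["N"] < 0).any():
        raise MarkerFormatError(f"{path}: negative census counts")
    frame["N"] = frame["N"].astype(int)
    return frame


def write_census(census: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    census.to_csv(path, sep=_infer_sep(path, sep), index=False)


# -- locus frequencies and the frequency filter --------------------------------


def locus_frequencies(
    m: BinaryMarkerMatrix,
    *,
    species: str | None = None,
    plots: list[str] | None = None,
    scale: str = "phenotype",
) -> pd.DataFrame:
    """Per-locus variant frequencies over an optional species/plot subset.

    By default frequencies are phenotype ("genetic variant") frequencies:
    ``f_v1`` is the share of non-missing individuals carrying the band
    (variant '1'), ``f_vr = 1 - f_v1`` the share without it (variant '2',
    only recessive alleles).  ``scale="allele"`` instead estimates allele
    frequencies under Hardy-Weinberg equilibrium — the recessive-allele
    frequency is the square root of the band-absence share — which is only
    meaningful for randomly mating, non-inbred populations and is therefore
    off by default.

    ``n`` counts non-missing calls only.  A locus with no non-missing call
    in the subset gets ``n = 0`` and NaN frequencies — undefined, flagged
    rather than silently dropped.

    Returns a frame indexed by locus id with columns ``n, f_v1, f_vr``.
    """
    if scale not in ("phenotype", "allele"):
        raise ValueError(f"scale must be 'phenotype' or 'allele', got {scale!r}")
    if species is not None or plots is not None:
        m = m.subset(species=species, plots=plots)
    values = m.calls.to_numpy(dtype=float)
    n = np.sum(~np.isnan(values), axis=0)
    with np.errstate(invalid="ignore"):
        f1 = np.where(n > 0, np.nansum(values, axis=0) / np.maximum(n, 1), np.nan)
    if scale == "allele":
        q = np.sqrt(1.0 - f1)
        f1 = 1.0 - q
    return pd.DataFrame(
        {"n": n.astype(int), "f_v1": f1, "f_vr": 1.0 - f1},
        index=pd.Index(m.locus_ids, name="locus_id"),
    )


def filter_loci(
    freqs: pd.DataFrame, lower: float = 0.05, upper: float = 0.95
) -> tuple[list[str], pd.DataFrame]:
    """Apply the low/high frequency exclusion filter.

    Loci whose variant-'1' frequency is below *lower* or above *upper* are
    excluded, as are loci whose frequency is undefined (all calls missing).
    Boundary values are retained: the exclusion is strict (< lower or
    > upper), so a locus at exactly 0.05 or 0.95 survives.

    Returns ``(retained_ids, exclusion_log)`` where the log has one row per
    excluded locus with its frequency and a reason.
    """
    if not 0.0 <= lower < upper <= 1.0:
        raise ValueError(f"need 0 <= lower < upper <= 1, got {lower}, {upper}")
    records = []
    retained: list[str] = []
    for locus_id, row in freqs.iterrows():
        f1 = row["f_v1"]
        if np.isnan(f1):
            records.append((locus_id, f1, "undefined (all calls missing)"))
        elif f1 < lower:
            records.append((locus_id, f1, f"f_v1 < {lower}"))
        elif f1 > upper:
            records.append((locus_id, f1, f"f_v1 > {upper}"))
        else:
            retained.append(str(locus_id))
    log = pd.DataFrame(records, columns=["locus_id", "f_v1", "reason"])
    if not retained:
        warnings.warn(
            "locus frequency filter retained no loci; downstream stages will refuse "
            "to run",
            UserWarning,
            stacklevel=2,
        )
    return retained, log
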