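"""Spectral preprocessing: region exclusion, normalization, column scaling."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BinnedSpectra",
    "ColumnScaler",
    "DEFAULT_WATER_REGION",
    "exclude_regions",
    "normalize_total_area",
    "scale_columns",
    "read_binned_spectra",
    "write_binned_spectra",
]

#: Conventional water-suppression residual window (ppm).
DEFAULT_WATER_REGION = (4.7, 5.1)


@dataclass(frozen=True)
class BinnedSpectra:
    """Samples x chemical-shift-bin intensity matrix with group labels.

    ``bin_centers`` are in ppm and strictly monotone; the package convention
    is descending ppm (left-to-right as an NMR spectrum is plotted).
    """

    sample_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    bin_centers: tuple[float, ...]
    intensities: np.ndarray

    def __post_init__(self) -> None:
        intens = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", intens)
        if intens.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if len(self.sample_ids) != len(self.group_labels):
            raise ValueError("sample_ids and group_labels must be parallel")
        if intens.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal number of samples")
        if intens.shape[1] != len(self.bin_centers):
            raise ValueError("column count must equal bin_centers length")
        centers = np.asarray(self.bin_centers)
        if len(centers) > 1:
            diffs = np.diff(centers)
            if not ((diffs > 0).all() or (diffs < 0).all()):
                raise ValueError("bin_centers must be strictly monotone")

    @property
    def groups(self) -> tuple[str, ...]:
        out: list[str] = []
        for g in self.group_labels:
            if g not in out:
                out.append(g)
        return tuple(out)

    def subset_groups(self, groups: Sequence[str]) -> "BinnedSpectra":
        keep = np.asarray([g in set(groups) for g in self.group_labels])
        if not keep.any():
            raise ValueError(f"no samples in groups {list(groups)!r}")
        return BinnedSpectra(
            sample_ids=tuple(s for s, k in zip(self.sample_ids, keep) if k),
            group_labels=tuple(g for g, k in zip(self.group_labels, keep) if k),
            bin_centers=self.bin_centers,
            intensities=self.intensities[keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.intensities, columns=[f"{c:.6g}" for c in self.bin_centers]
        )
        df.insert(0, "group", list(self.group_labels))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df


def exclude_regions(
    spectra: BinnedSpectra, regions: Sequence[tuple[float, float]]
) -> BinnedSpectra:
    """Drop bins whose centers fall inside any ``(lo, hi)`` ppm interval.

    Overlapping intervals are handled as a set union; the order of the
    remaining bins is preserved.
    """
    centers = np.asarray(spectra.bin_centers)
    drop = np.zeros(len(centers), dtype=bool)
    for lo, hi in regions:
        lo, hi = min(lo, hi), max(lo, hi)
        drop |= (centers >= lo) & (centers <= hi)
    if drop.all():
        raise ValueError("exclusion regions would remove all bins")
    keep = ~drop
    return replace(
        spectra,
        bin_centers=tuple(centers[keep]),
        intensities=spectra.intensities[:, keep],
    )


def normalize_total_area(spectra: BinnedSpectra, target: float = 1.0) -> BinnedSpectra:
    """Scale every row so its total intensity equals ``target``."""
    sums = spectra.intensities.sum(axis=1)
    bad = np.flatnonzero(sums <= 0)
    if bad.size:
        names = [spectra.sample_ids[i] for i in bad]
        raise ValueError(f"non-positive total intensity for sample(s): {names}")
    scaled = spectra.intensities * (target / sums)[:, None]
    return replace(spectra, intensities=scaled)


@dataclass(frozen=True)
class ColumnScaler:
    """Stored column statistics from :func:`scale_columns`.

    ``kept`` marks the columns that survived the zero-variance filter; the
    inverse transform maps a scaled matrix back onto those columns.
    """

    method: str
    means: np.ndarray
    sds: np.ndarray
    kept: np.ndarray

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        x = np.asarray(matrix, dtype=float)[:, self.kept]
        x = x - self.means
        if self.method == "unit_variance":
            x = x / self.sds
        elif self.method == "pareto":
            x = x / np.sqrt(self.sds)
        return x

    def inverse_transform(self, scaled: np.ndarray) -> np.ndarray:
        x = np.asarray(scaled, dtype=float)
        if self.method == "unit_variance":
            x = x * self.sds
        elif self.method == "pareto":
            x = x * np.sqrt(self.sds)
        return x + self.means


_METHODS = ("center", "unit_variance", "pareto")


def scale_columns(matrix: np.ndarray, method: str = "pareto"):
    """Center (and optionally variance- or Pareto-scale) each column.

    Returns ``(scaled_matrix, ColumnScaler)``.  For the variance-based
    methods, zero-variance columns are dropped with a warning — they carry
    no discriminant information and would otherwise divide by zero.
    """
    if method not in _METHODS:
        raise ValueError(f"unknown scaling method {method!r}; choose from {_METHODS}")
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D")
    sds = x.std(axis=0, ddof=1)
    kept = np.ones(x.shape[1], dtype=bool)
    if method in ("unit_variance", "pareto"):
        zero = sds == 0
        if zero.any():
            logger.warning(
                "dropping %d zero-variance column(s) before %s scaling",
                int(zero.sum()),
                method,
            )
            kept = ~zero
    means = x[:, kept].mean(axis=0)
    scaler = ColumnScaler(method=method, means=means, sds=sds[kept], kept=kept)
    return scaler.transform(x), scaler


# ---------------------------------------------------------------------------
# Text I/O (column layout mirrors synthgen tables; bin centers as headers)
# ---------------------------------------------------------------------------


def write_binned_spectra(spectra: BinnedSpectra, path) -> None:
    """TSV export; header bin centers are ppm values (descending by default)."""
    spectra.to_dataframe().to_csv(path, sep="\t", index=False)


def read_binned_spectra(path) -> BinnedSpectra:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected columns sample_id, group, <bin centers...>")
    return BinnedSpectra(
        sample_ids=tuple(df["sample_id"].astype(str)),
        group_labels=tuple(df["group"].astype(str)),
        bin_centers=tuple(float(c) for c in df.columns[2:]),
        intensities=df.iloc[:, 2:].to_numpy(dtype=float),
    )
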