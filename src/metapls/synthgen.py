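"""Synthetic study bundles with known ground truth.

Generates metabolite concentration tables for a multi-group design with
planted mean shifts and block-correlation structure, renders them into
binned Lorentzian spectra, and builds structural-similarity matrices.
Every generator is deterministic given its seed, so downstream stages can
be tested end-to-end without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StudyDesign",
    "MetaboliteTable",
    "SpectralParams",
    "generate_metabolite_table",
    "render_binned_spectra",
    "generate_similarity_matrix",
    "default_design",
    "default_spectral_params",
    "read_metabolite_table",
    "write_metabolite_table",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Multi-group study layout with planted effects.

    Parameters
    ----------
    groups
        Ordered group names; the first entry is the reference group.
    n_per_group
        Samples per group (> 0).
    metabolites
        Unique metabolite names.
    effect_table
        Mapping ``(metabolite, group) -> standardized mean shift`` relative
        to the reference group.  Omitted entries default to 0.
    correlation_blocks
        ``(members, level)`` pairs; members of a block share pairwise
        correlation ``level`` (on the latent scale).  Blocks must be
        disjoint and ``level`` must lie in [0, 1).
    noise_sd
        Within-group standard deviation on the latent (log) scale.
    seed
        Root seed for all randomness.
    """

    groups: tuple[str, ...]
    n_per_group: int
    metabolites: tuple[str, ...]
    effect_table: Mapping[tuple[str, str], float] = field(default_factory=dict)
    correlation_blocks: tuple[tuple[tuple[str, ...], float], ...] = ()
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group <= 0:
            raise ValueError("n_per_group must be positive")
        if not self.metabolites:
            raise ValueError("metabolite list must not be empty")
        if len(set(self.metabolites)) != len(self.metabolites):
            raise ValueError("metabolite names must be unique")
        if len(self.groups) < 2:
            raise ValueError("at least two groups required")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        known = set(self.metabolites)
        ref = self.reference_group
        for (met, grp), shift in self.effect_table.items():
            if met not in known:
                raise ValueError(f"effect_table references unknown metabolite {met!r}")
            if grp not in self.groups:
                raise ValueError(f"effect_table references unknown group {grp!r}")
            if grp == ref and shift != 0:
                raise ValueError("reference group shifts must all be 0")
        seen: set[str] = set()
        for members, level in self.correlation_blocks:
            if not 0 <= level < 1:
                raise ValueError("block correlation level must be in [0, 1)")
            for met in members:
                if met not in known:
                    raise ValueError(f"block references unknown metabolite {met!r}")
                if met in seen:
                    raise ValueError(f"metabolite {met!r} appears in multiple blocks")
                seen.add(met)

    @property
    def reference_group(self) -> str:
        return self.groups[0]

    def shift(self, metabolite: str, group: str) -> float:
        return float(self.effect_table.get((metabolite, group), 0.0))


@dataclass(frozen=True)
class MetaboliteTable:
    """Per-sample metabolite concentrations (arbitrary units, non-negative)."""

    sample_ids: tuple[str, ...]
    group_labels: tuple[str, ...]
    metabolite_names: tuple[str, ...]
    values: np.ndarray  # (n_samples, n_metabolites)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.sample_ids) != len(self.group_labels):
            raise ValueError("sample_ids and group_labels must be parallel")
        if values.shape[0] != len(self.sample_ids):
            raise ValueError("row count must equal number of samples")
        if values.shape[1] != len(self.metabolite_names):
            raise ValueError("column count must equal number of metabolites")
        if len(set(self.metabolite_names)) != len(self.metabolite_names):
            raise ValueError("metabolite names must be unique")
        if np.isnan(values).any():
            raise ValueError("values must not contain missing entries")

    @property
    def groups(self) -> tuple[str, ...]:
        out: list[str] = []
        for g in self.group_labels:
            if g not in out:
                out.append(g)
        return tuple(out)

    def group_mask(self, group: str) -> np.ndarray:
        return np.asarray([g == group for g in self.group_labels])

    def subset_groups(self, groups: Sequence[str]) -> "MetaboliteTable":
        keep = np.asarray([g in set(groups) for g in self.group_labels])
        if not keep.any():
            raise ValueError(f"no samples in groups {list(groups)!r}")
        return MetaboliteTable(
            sample_ids=tuple(s for s, k in zip(self.sample_ids, keep) if k),
            group_labels=tuple(g for g, k in zip(self.group_labels, keep) if k),
            metabolite_names=self.metabolite_names,
            values=self.values[keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.metabolite_names))
        df.insert(0, "group", list(self.group_labels))
        df.insert(0, "sample_id", list(self.sample_ids))
        return df


@dataclass(frozen=True)
class SpectralParams:
    """Lorentzian peak library for spectral rendering.

    ``peaks`` maps metabolite name to a list of
    ``(ppm_center, relative_amplitude, half_width_at_half_maximum)``.
    """

    ppm_range: tuple[float, float]
    points: int
    peaks: Mapping[str, Sequence[tuple[float, float, float]]]
    baseline_sd: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.ppm_range
        if not lo < hi:
            raise ValueError("ppm_range must be an increasing interval")
        if self.points <= 0:
            raise ValueError("points must be positive")
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be non-negative")
        for met, plist in self.peaks.items():
            for center, amp, hwhm in plist:
                if not lo <= center <= hi:
                    raise ValueError(
                        f"peak of {met!r} at {center} ppm outside range [{lo}, {hi}]"
                    )
                if amp <= 0 or hwhm <= 0:
                    raise ValueError("peak amplitudes and widths must be positive")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------


def _latent_correlation(design: StudyDesign) -> np.ndarray:
    p = len(design.metabolites)
    idx = {m: j for j, m in enumerate(design.metabolites)}
    corr = np.eye(p)
    for members, level in design.correlation_blocks:
        cols = [idx[m] for m in members]
        for a in cols:
            for b in cols:
                if a != b:
                    corr[a, b] = level
    return corr


def generate_metabolite_table(
    design: StudyDesign, scale: str = "log"
) -> MetaboliteTable:
    """Draw a concentration table from the design's generative model.

    On the default ``scale="log"`` the latent variables are multivariate
    normal with per-group means ``shift * noise_sd``, block correlation from
    the design, and are exponentiated — this guarantees positivity and gives
    the right-skewed marginals typical of concentration data.  With
    ``scale="linear"`` the latent draw (offset to a baseline of 1) is used
    directly and negative values are truncated at 0.
    """
    if scale not in ("log", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    rng = np.random.default_rng(design.seed)
    p = len(design.metabolites)
    sd = design.noise_sd
    cov = _latent_correlation(design) * sd**2
    chol = np.linalg.cholesky(cov)

    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    group_labels: list[str] = []
    for group in design.groups:
        mu = np.asarray([design.shift(m, group) * sd for m in design.metabolites])
        z = rng.standard_normal((design.n_per_group, p))
        latent = mu + z @ chol.T
        if scale == "log":
            block = np.exp(latent)
        else:
            block = np.maximum(1.0 + latent, 0.0)
        rows.append(block)
        for i in range(design.n_per_group):
            sample_ids.append(f"{group}_{i + 1:02d}")
            group_labels.append(group)

    return MetaboliteTable(
        sample_ids=tuple(sample_ids),
        group_labels=tuple(group_labels),
        metabolite_names=tuple(design.metabolites),
        values=np.vstack(rows),
    )


def _lorentzian_bin_integrals(
    edges: np.ndarray, center: float, amplitude: float, hwhm: float
) -> np.ndarray:
    # antiderivative of A * hwhm^2 / ((x - c)^2 + hwhm^2) is A*hwhm*atan((x-c)/hwhm)
    prim = amplitude * hwhm * np.arctan((edges - center) / hwhm)
    return np.diff(prim)


def render_binned_spectra(
    table: MetaboliteTable,
    sp: SpectralParams,
    bin_width: float,
    seed: int = 0,
):
    """Render each sample into a binned spectrum.

    Each sample's spectrum is the sum over metabolites of
    ``value * amplitude`` weighted Lorentzian peaks, integrated analytically
    into contiguous bins of ``bin_width`` ppm, plus i.i.d. Gaussian baseline
    noise of ``sp.baseline_sd`` per bin.  Bin centers are reported in
    descending ppm (NMR plotting convention).
    """
    from metapls.preprocess import BinnedSpectra

    lo, hi = sp.ppm_range
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if bin_width >= hi - lo:
        raise ValueError("bin_width must be smaller than the ppm range")
    n_bins = int(np.floor((hi - lo) / bin_width + 1e-9))
    edges = lo + bin_width * np.arange(n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2.0

    n = len(table.sample_ids)
    intensities = np.zeros((n, n_bins))
    for j, met in enumerate(table.metabolite_names):
        peaks = sp.peaks.get(met, ())
        if not peaks:
            continue
        profile = np.zeros(n_bins)
        for center, amp, hwhm in peaks:
            profile += _lorentzian_bin_integrals(edges, center, amp, hwhm)
        intensities += np.outer(table.values[:, j], profile)

    if sp.baseline_sd > 0:
        rng = np.random.default_rng(seed)
        intensities = intensities + rng.normal(0.0, sp.baseline_sd, intensities.shape)

    # descending ppm
    return BinnedSpectra(
        sample_ids=table.sample_ids,
        group_labels=table.group_labels,
        bin_centers=tuple(centers[::-1]),
        intensities=intensities[:, ::-1],
    )


def generate_similarity_matrix(
    metabolites: Sequence[str],
    related_pairs: Sequence[tuple[str, str]],
    high: float = 0.9,
    low_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Symmetric structural-similarity matrix in [0, 1].

    Related pairs are set to ``high``; every other off-diagonal entry is
    ``|Normal(0, low_sd)|`` clipped below ``high / 2``; the diagonal is 1.
    """
    if not 0 < high <= 1:
        raise ValueError("high must be in (0, 1]")
    mets = list(metabolites)
    known = set(mets)
    for a, b in related_pairs:
        if a not in known or b not in known:
            raise ValueError(f"related pair ({a!r}, {b!r}) references unknown metabolite")
    rng = np.random.default_rng(seed)
    p = len(mets)
    raw = np.abs(rng.normal(0.0, low_sd, (p, p)))
    limit = np.nextafter(high / 2.0, 0.0)
    mat = np.clip((raw + raw.T) / 2.0, 0.0, limit)
    idx = {m: j for j, m in enumerate(mets)}
    for a, b in related_pairs:
        mat[idx[a], idx[b]] = high
        mat[idx[b], idx[a]] = high
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=mets, columns=mets)


# ---------------------------------------------------------------------------
# Presets mirroring a six-group intervention-study shape
# ---------------------------------------------------------------------------

GROUPS = ("NC", "M", "HD", "Ber", "Bai", "Jas")

_SERUM_N_METABOLITES = 26
_BRAIN_N_METABOLITES = 42


def _metabolite_names(n: int) -> tuple[str, ...]:
    return tuple(f"met{j + 1:02d}" for j in range(n))


def default_design(
    tissue: str = "brain",
    n_per_group: int = 8,
    n_markers: int = 10,
    effect_size: float = 2.0,
    block_level: float = 0.6,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[StudyDesign, dict]:
    """Six-group design (NC reference, M model, four treatments).

    The first ``n_markers`` metabolites are perturbed in the model group M
    (alternating sign) and partially restored by treatments; returns the
    design plus a ground-truth dict for test harnesses.
    """
    n_mets = _BRAIN_N_METABOLITES if tissue == "brain" else _SERUM_N_METABOLITES
    if tissue not in ("brain", "serum"):
        raise ValueError("tissue must be 'brain' or 'serum'")
    mets = _metabolite_names(n_mets)
    markers = mets[:n_markers]
    effect: dict[tuple[str, str], float] = {}
    for k, met in enumerate(markers):
        sign = 1.0 if k % 2 == 0 else -1.0
        effect[(met, "M")] = sign * effect_size
        # treatments partially restore toward the reference level
        for grp, recovery in (("HD", 0.2), ("Ber", 0.3), ("Bai", 0.5), ("Jas", 0.5)):
            effect[(met, grp)] = sign * effect_size * recovery
    blocks = (
        ((mets[0], mets[2], mets[4]), block_level),
        ((mets[n_markers], mets[n_markers + 1], mets[n_markers + 2]), block_level),
    )
    design = StudyDesign(
        groups=GROUPS,
        n_per_group=n_per_group,
        metabolites=mets,
        effect_table=effect,
        correlation_blocks=blocks,
        noise_sd=noise_sd,
        seed=seed,
    )
    truth = {
        "markers": list(markers),
        "effect_size": effect_size,
        "up_in_model": [m for k, m in enumerate(markers) if k % 2 == 0],
        "down_in_model": [m for k, m in enumerate(markers) if k % 2 == 1],
        "blocks": [list(b[0]) for b in blocks],
    }
    return design, truth


def default_spectral_params(
    metabolites: Sequence[str], baseline_sd: float = 0.002, seed: int = 12345
) -> SpectralParams:
    """Fictional but ppm-plausible peak library (0.5–9.5 ppm).

    Peak positions are drawn once from a fixed seed so the library is stable
    across runs; it makes no attempt to reproduce real chemical shifts.
    """
    rng = np.random.default_rng(seed)
    peaks: dict[str, list[tuple[float, float, float]]] = {}
    for met in metabolites:
        n_peaks = int(rng.integers(1, 4))
        plist = []
        for _ in range(n_peaks):
            center = float(rng.uniform(0.6, 9.4))
            amp = float(rng.uniform(0.5, 2.0))
            hwhm = float(rng.uniform(0.005, 0.02))
            plist.append((center, amp, hwhm))
        peaks[met] = plist
    return SpectralParams(
        ppm_range=(0.5, 9.5), points=9000, peaks=peaks, baseline_sd=baseline_sd
    )


# ---------------------------------------------------------------------------
# Text I/O (first column sample id, second column group, rest metabolites)
# ---------------------------------------------------------------------------


def write_metabolite_table(table: MetaboliteTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index=False)


def read_metabolite_table(path) -> MetaboliteTable:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3 or list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected columns sample_id, group, <metabolites...>")
    return MetaboliteTable(
        sample_ids=tuple(df["sample_id"].astype(str)),
        group_labels=tuple(df["group"].astype(str)),
        metabolite_names=tuple(df.columns[2:]),
        values=df.iloc[:, 2:].to_numpy(dtype=float),
    )


def write_ground_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
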