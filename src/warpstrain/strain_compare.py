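"""Strain extraction, HARP-style sampling, and comparison statistics.

Strains are Green-Lagrange, E = 1/2 (F^T F - I), projected onto the local
cardiac directions (d.E d for unit d).  Sampling mirrors a 2D HARP tagged-
MRI analysis: per short-axis slice, strains are averaged in 4 anatomical
regions (anterior, posterior, septal, lateral) x 3 transmural depths
(epicardial, midwall, endocardial), giving 12 circumferential and 12
radial values per slice.

Two strain tables (a reference, e.g. truth or tagged MRI, and a
prediction, e.g. warping) are compared with the coefficient of
determination R^2, the percent root-mean-square error normalized per
entry by the reference strain, a Bland-Altman agreement analysis with a
trend regression of differences on means, and a two-sided paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lvmesh import HexMesh, LocalFrame

__all__ = [
    "DEPTH_LABELS",
    "green_lagrange",
    "project_strain",
    "sample_harp_grid",
    "percent_rmse",
    "r_squared",
    "bland_altman",
    "paired_ttest",
    "BlandAltman",
    "ComparisonStats",
    "compare_tables",
]

# wall_depth bands: [0, 1/3) epicardial, [1/3, 2/3) midwall, [2/3, 1] endocardial
DEPTH_LABELS = ("epicardial", "midwall", "endocardial")

TABLE_COLUMNS = ("slice", "region", "depth", "direction", "value")


class MetricError(ValueError):
    """A comparison statistic is undefined for the given inputs."""


@dataclass(frozen=True)
class BlandAltman:
    """Agreement summary: mean difference (bias), 1.96-sd limits of
    agreement, sd of differences, and the slope of differences on means
    (trend / proportional-error detector)."""

    mean_difference: float
    lower_limit: float
    upper_limit: float
    sd_difference: float
    slope: float


@dataclass(frozen=True)
class ComparisonStats:
    """Full two-method comparison for one strain direction."""

    r_squared: float
    percent_rmse: float
    bland_altman: BlandAltman
    t_test_p: float
    n: int
    n_excluded: int = 0


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green-Lagrange strain E = 1/2 (F^T F - I); rigid-motion invariant.

    Accepts a single 3x3 gradient or any (..., 3, 3) stack.
    """
    F = np.asarray(F, dtype=float)
    C = np.einsum("...kx,...ky->...xy", F, F)
    return 0.5 * (C - np.eye(3))


def project_strain(E: np.ndarray, direction: np.ndarray) -> float | np.ndarray:
    """Directional strain d.E d along a unit direction d."""
    d = np.asarray(direction, dtype=float)
    if not np.allclose(np.linalg.norm(d, axis=-1), 1.0, atol=1e-8):
        raise ValueError("direction must be unit length")
    out = np.einsum("...x,...xy,...y->...", d, E, d)
    return float(out) if out.ndim == 0 else out


def sample_harp_grid(
    E_gauss: np.ndarray,
    frames: LocalFrame,
    mesh: HexMesh,
) -> pd.DataFrame:
    """Average projected strains on the slice x region x depth layout.

    ``E_gauss`` is (n_elems, 8, 3, 3) Green-Lagrange tensors at the mesh
    Gauss points.  Every (slice, region, depth) cell averages the
    circumferential and radial projections over its Gauss points; the
    output has exactly 12 circumferential + 12 radial rows per slice.
    Raises if a cell contains no Gauss points.
    """
    ecc = np.einsum("egx,egxy,egy->eg", frames.circumferential, E_gauss,
                    frames.circumferential)
    err = np.einsum("egx,egxy,egy->eg", frames.radial, E_gauss, frames.radial)
    depth = mesh.depth_at_gauss()
    depth_band = np.minimum((depth * 3).astype(int), 2)  # (E, G)

    rows = []
    for sl in np.unique(mesh.slice_index):
        for region in ("anterior", "posterior", "septal", "lateral"):
            emask = (mesh.slice_index == sl) & (mesh.region == region)
            for ib, dlabel in enumerate(DEPTH_LABELS):
                gmask = emask[:, None] & (depth_band == ib)
                if not np.any(gmask):
                    raise ValueError(
                        f"empty sampling cell: slice {sl}, {region}, {dlabel}"
                    )
                for direction, field in (("circumferential", ecc), ("radial", err)):
                    rows.append(
                        (int(sl), region, dlabel, direction, float(field[gmask].mean()))
                    )
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def strain_table_from_displacements(
    mesh: HexMesh,
    displacements: np.ndarray,
    frames: LocalFrame | None = None,
) -> pd.DataFrame:
    """HARP-layout strain table of a recovered nodal displacement field.

    Computes F at the mesh Gauss points from the displacement field,
    converts to Green-Lagrange strain and samples it on the standard
    slice x region x depth layout.
    """
    from .lvmesh import local_frames
    from .mechanics import FEAssembly

    fr = frames if frames is not None else local_frames(mesh)
    F = FEAssembly(mesh).deformation_gradients(displacements)
    return sample_harp_grid(green_lagrange(F), fr, mesh)


def percent_rmse(
    reference: np.ndarray,
    predicted: np.ndarray,
    exclusion_floor: float = 0.01,
    ratio_of_sums: bool = False,
) -> tuple[float, int]:
    """%RMSE with the reference as gold standard.

    Default: sqrt(mean over entries of (ref - pred)^2 / ref^2), i.e. the
    root mean squared per-entry relative error.  ``ratio_of_sums`` selects
    the variant sqrt(sum (ref - pred)^2 / sum ref^2).  Reference entries
    with magnitude below ``exclusion_floor`` are excluded (near-zero
    denominators make the per-entry form unstable); the excluded count is
    returned alongside the metric.
    """
    ref = np.asarray(reference, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted must have equal length")
    keep = np.abs(ref) >= exclusion_floor
    n_excl = int(np.sum(~keep))
    if not np.any(keep):
        raise MetricError("all reference entries below the exclusion floor")
    ref, pred = ref[keep], pred[keep]
    if ratio_of_sums:
        val = np.sqrt(np.sum((ref - pred) ** 2) / np.sum(ref**2))
    else:
        val = np.sqrt(np.mean((ref - pred) ** 2 / ref**2))
    return float(val), n_excl


def r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """Coefficient of determination: squared Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise MetricError("need >= 3 paired samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise MetricError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r**2)


def bland_altman(x: np.ndarray, y: np.ndarray) -> BlandAltman:
    """Bland-Altman agreement of method y against method x.

    Differences d = y - x against means m = (x + y)/2; limits of agreement
    at mean(d) +/- 1.96 sd(d); the least-squares slope of d on m flags
    magnitude-dependent bias (e.g. proportional underestimation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise MetricError("need >= 3 paired samples")
    d = y - x
    m = (x + y) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.std(m) > 0:
        # centered fit for conditioning; the slope is unaffected
        slope = float(np.polyfit(m - m.mean(), d, 1)[0])
    else:
        slope = 0.0
    return BlandAltman(
        mean_difference=bias,
        lower_limit=bias - 1.96 * sd,
        upper_limit=bias + 1.96 * sd,
        sd_difference=sd,
        slope=slope,
    )


def paired_ttest(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired t-test p-value for equal means.

    Zero-variance differences: p = 1 when the methods agree exactly,
    otherwise a 0 sentinel (a constant nonzero shift is unambiguous).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise MetricError("need >= 3 paired samples")
    d = y - x
    scale = max(np.abs(d).max(), 1e-300)
    if np.std(d) <= 1e-12 * scale:
        return 1.0 if np.allclose(d, 0) else 0.0
    return float(stats.ttest_rel(x, y).pvalue)


def compare_tables(
    reference: pd.DataFrame,
    predicted: pd.DataFrame,
    exclusion_floor: float = 0.01,
) -> dict[str, ComparisonStats]:
    """Per-direction comparison of two strain sample tables.

    Tables must share the (slice, region, depth, direction) layout; rows
    are aligned on those keys.  Returns {direction: ComparisonStats}.
    R^2 of a degenerate (zero-variance) comparison is reported as NaN
    rather than raising, so identical-input reports stay well defined.
    """
    keys = ["slice", "region", "depth", "direction"]
    merged = reference.merge(predicted, on=keys, suffixes=("_ref", "_pred"))
    if len(merged) != len(reference):
        raise ValueError("strain tables do not share a common sampling layout")
    out: dict[str, ComparisonStats] = {}
    for direction, grp in merged.groupby("direction"):
        ref = grp["value_ref"].to_numpy()
        pred = grp["value_pred"].to_numpy()
        try:
            r2 = r_squared(ref, pred)
        except MetricError:
            r2 = float("nan")
        try:
            prmse, n_excl = percent_rmse(ref, pred, exclusion_floor)
        except MetricError:
            prmse, n_excl = float("nan"), len(ref)
        out[direction] = ComparisonStats(
            r_squared=r2,
            percent_rmse=prmse,
            bland_altman=bland_altman(ref, pred),
            t_test_p=paired_ttest(ref, pred),
            n=len(ref),
            n_excluded=n_excl,
        )
    return out
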