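"""Microstructure along streamline tracts: DTI scalars and weighted FVF.

Covers the quantification steps between preprocessed diffusion data and
per-tract summary metrics:

* log-linear least-squares diffusion tensor fit restricted to the low-b
  shell (the tensor model breaks down at high b);
* scalar maps from the sorted eigenvalues — FA, MD (mean), AD (λ1),
  RD ((λ2+λ3)/2);
* the occupancy-weighted fiber volume fraction of two crossing fascicles,
  ``wFVF = (ν1·fvf1 + ν2·fvf2) / (ν1 + ν2)`` (per-fascicle ν/fvf maps are
  inputs from a multi-compartment fit, not recomputed here);
* seed-mask dilation, streamline length filtering (default 30–300 mm),
  voxelization of streamlines, and unweighted mean of each scalar map over
  the traversed voxels.

Streamline coordinates are physical mm on the same axis convention as
:class:`~lcmri.volume.Volume`; a point maps to voxel ``floor(p / voxel_size)``
(half-open voxel boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from lcmri.volume import Volume

__all__ = [
    "TensorFit",
    "TractSet",
    "fit_dti",
    "dti_scalars",
    "compute_wfvf",
    "dilate_mask",
    "streamline_length",
    "filter_streamlines",
    "voxelize_streamlines",
    "tract_mean_metrics",
]


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass
class TensorFit:
    """Per-voxel tensor estimates within a brain mask.

    ``tensors`` holds full symmetric 3x3 tensors (mm^2/s); ``evals`` their
    eigenvalues sorted descending (λ1 ≥ λ2 ≥ λ3).  Voxels outside the mask
    are NaN.  Negative eigenvalues are kept (a noise indicator) and flagged.
    """

    tensors: np.ndarray      # (X, Y, Z, 3, 3)
    evals: np.ndarray        # (X, Y, Z, 3) descending
    s0: np.ndarray           # (X, Y, Z)
    mask: np.ndarray         # fitted voxels
    n_negative_evals: int = 0


@dataclass
class TractSet:
    """Filtered streamlines with lengths and (optionally) traversed voxels."""

    streamlines: list[np.ndarray]
    lengths_mm: np.ndarray
    n_removed: int = 0
    voxels: set[tuple[int, int, int]] = field(default_factory=set)

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)


# --------------------------------------------------------------------------
# tensor fitting
# --------------------------------------------------------------------------

def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz) to ln S."""
    gx, gy, gz = bvecs[:, 0], bvecs[:, 1], bvecs[:, 2]
    b = bvals
    return np.column_stack(
        [
            np.ones_like(b),
            -b * gx * gx,
            -b * gy * gy,
            -b * gz * gz,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )


def fit_dti(
    dwi: Volume,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    mask: np.ndarray | None = None,
    shell_max_b: float = 1000.0,
) -> TensorFit:
    """Log-linear least-squares tensor fit per voxel.

    Only measurements with ``b <= shell_max_b`` (plus all b0s) enter the fit.
    Requires at least 6 non-zero-b directions and one b0 in that range.
    """
    if not dwi.is_4d:
        raise ValueError("DWI volume must be 4D")
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if len(bvals) != dwi.shape[3] or bvecs.shape != (len(bvals), 3):
        raise ValueError("gradient table does not match DWI volume")
    use = bvals <= shell_max_b
    n_b0 = int(np.sum(bvals[use] == 0))
    n_dw = int(np.sum((bvals > 0) & use))
    if n_b0 < 1 or n_dw < 6:
        raise ValueError(
            f"need >= 1 b0 and >= 6 diffusion-weighted measurements at "
            f"b <= {shell_max_b}, got {n_b0} and {n_dw}"
        )
    spatial = dwi.spatial_shape
    if mask is None:
        mask = np.ones(spatial, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != spatial:
        raise ValueError("mask grid does not match DWI volume")

    signal = dwi.data[mask][:, use].astype(float)
    # guard non-positive magnitudes (possible under heavy noise) before log
    tiny = np.finfo(float).tiny
    logs = np.log(np.clip(signal, tiny, None))
    design = _design_matrix(bvals[use], bvecs[use])
    coef, *_ = np.linalg.lstsq(design, logs.T, rcond=None)   # (7, nvox)

    nvox = coef.shape[1]
    d = np.empty((nvox, 3, 3))
    d[:, 0, 0] = coef[1]
    d[:, 1, 1] = coef[2]
    d[:, 2, 2] = coef[3]
    d[:, 0, 1] = d[:, 1, 0] = coef[4]
    d[:, 0, 2] = d[:, 2, 0] = coef[5]
    d[:, 1, 2] = d[:, 2, 1] = coef[6]
    evals = np.linalg.eigvalsh(d)[:, ::-1]                   # descending

    tensors = np.full((*spatial, 3, 3), np.nan)
    ev = np.full((*spatial, 3), np.nan)
    s0 = np.full(spatial, np.nan)
    tensors[mask] = d
    ev[mask] = evals
    s0[mask] = np.exp(coef[0])
    return TensorFit(
        tensors=tensors,
        evals=ev,
        s0=s0,
        mask=mask,
        n_negative_evals=int(np.sum(np.any(evals < 0, axis=1))),
    )


def dti_scalars(evals: np.ndarray) -> dict[str, np.ndarray]:
    """FA/MD/AD/RD maps from eigenvalue triples (last axis, descending).

    Voxels with all-zero (or all-NaN) eigenvalues get NaN FA — the
    anisotropy of a zero tensor is undefined.
    """
    ev = np.asarray(evals, dtype=float)
    if ev.shape[-1] != 3:
        raise ValueError("expected eigenvalue triples on the last axis")
    md = ev.mean(axis=-1)
    ad = ev[..., 0]
    rd = (ev[..., 1] + ev[..., 2]) / 2.0
    num = np.linalg.norm(ev - md[..., None], axis=-1)
    den = np.linalg.norm(ev, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den == 0, np.nan, fa)
    return {"FA": fa, "MD": md, "AD": ad, "RD": rd}


def compute_wfvf(nu1, fvf1, nu2, fvf2) -> np.ndarray:
    """Occupancy-weighted fiber volume fraction of two crossing fascicles.

    ``(ν1·fvf1 + ν2·fvf2) / (ν1 + ν2)``; where both occupancies vanish the
    value is NaN (missing), never zero.  Inputs must lie in [0, 1].
    """
    arrs = [np.asarray(a, dtype=float) for a in (nu1, fvf1, nu2, fvf2)]
    for name, a in zip(("nu1", "fvf1", "nu2", "fvf2"), arrs):
        finite = a[np.isfinite(a)]
        if np.any(finite < 0) or np.any(finite > 1):
            raise ValueError(f"{name} must lie in [0, 1]")
    nu1, fvf1, nu2, fvf2 = arrs
    denom = nu1 + nu2
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (nu1 * fvf1 + nu2 * fvf2) / denom
    return np.where(denom == 0, np.nan, w)


# --------------------------------------------------------------------------
# masks and streamlines
# --------------------------------------------------------------------------

def dilate_mask(mask: np.ndarray, radius_voxels: int = 1, connectivity: int = 26) -> np.ndarray:
    """Morphological dilation, 26-connected by default ("every direction")."""
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius_voxels == 0:
        return mask.copy()
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    return ndimage.binary_dilation(mask, structure=structure, iterations=radius_voxels)


def streamline_length(points: np.ndarray) -> float:
    """Polyline arc length in mm."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or len(points) < 2:
        raise ValueError("streamline needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(points, axis=0), axis=1)))


def filter_streamlines(
    streamlines,
    min_mm: float = 30.0,
    max_mm: float = 300.0,
) -> TractSet:
    """Keep streamlines whose arc length lies in ``[min_mm, max_mm]``."""
    if min_mm > max_mm:
        raise ValueError(f"min length {min_mm} exceeds max length {max_mm}")
    kept, lengths = [], []
    removed = 0
    for s in streamlines:
        ln = streamline_length(s)
        if min_mm <= ln <= max_mm:
            kept.append(np.asarray(s, dtype=float))
            lengths.append(ln)
        else:
            removed += 1
    return TractSet(
        streamlines=kept,
        lengths_mm=np.asarray(lengths, dtype=float),
        n_removed=removed,
    )


def voxelize_streamlines(
    streamlines,
    shape: tuple[int, int, int],
    voxel_size,
    step_mm: float | None = None,
) -> set[tuple[int, int, int]]:
    """Set of voxels visited by any streamline.

    Each segment is supersampled at a step no larger than ``step_mm``
    (default: half the smallest voxel edge), so no traversed voxel is
    skipped.  Segments are split into a power-of-two number of pieces, which
    nests the sample points under step halving: refining the step can only
    add voxels, never remove them.
    """
    vs = np.asarray(voxel_size, dtype=float)
    extent = np.asarray(shape) * vs
    step = float(vs.min()) / 2.0 if step_mm is None else float(step_mm)
    if step <= 0:
        raise ValueError("step_mm must be positive")
    voxels: set[tuple[int, int, int]] = set()
    for idx, s in enumerate(streamlines):
        pts = np.atleast_2d(np.asarray(s, dtype=float))
        if np.any(pts < 0) or np.any(pts >= extent):
            raise ValueError(
                f"streamline {idx} has points outside the grid "
                f"(extent {extent.tolist()} mm)"
            )
        samples = [pts[:1]]
        for a, b in zip(pts[:-1], pts[1:]):
            seg = np.linalg.norm(b - a)
            n = 1 << max(int(np.ceil(np.log2(max(seg / step, 1.0)))), 0)
            t = np.linspace(0.0, 1.0, n + 1)[1:]
            samples.append(a + t[:, None] * (b - a))
        allpts = np.vstack(samples)
        idx3 = np.floor(allpts / vs).astype(int)
        voxels.update(map(tuple, idx3))
    return voxels


def tract_mean_metrics(
    voxels,
    scalar_maps: dict[str, Volume | np.ndarray],
) -> dict[str, dict]:
    """Unweighted mean of each scalar map over the traversed voxel set.

    NaN (missing) voxels are excluded per metric, with exclusion counts
    reported: ``{metric: {"mean": .., "n_voxels": .., "n_missing": ..}}``.
    """
    voxels = sorted(set(map(tuple, voxels)))
    if not voxels:
        raise ValueError("empty traversed-voxel set")
    idx = np.asarray(voxels)
    out: dict[str, dict] = {}
    for name, vmap in scalar_maps.items():
        data = vmap.data if isinstance(vmap, Volume) else np.asarray(vmap)
        vals = data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
        good = np.isfinite(vals)
        out[name] = {
            "mean": float(vals[good].mean()) if good.any() else float("nan"),
            "n_voxels": int(good.sum()),
            "n_missing": int((~good).sum()),
        }
    return out
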