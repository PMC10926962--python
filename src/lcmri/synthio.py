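"""Seed-controlled synthetic fixtures with known ground truth.

Every generator here is a pure function of its spec (seed included) and
emulates the statistical structure one analysis stage assumes:

* ``generate_lc_phantom`` — a hyperintense tubular locus coeruleus (the real
  nucleus is roughly 2.5 mm in diameter and 15 mm long) over a uniform
  pontine background at MT-slab geometry, with additive Gaussian noise
  (magnitude-MRI high-SNR regime);
* ``perturb_rater_masks`` — two imperfect manual delineations of the true
  tube, for the two-rater intersection step;
* ``generate_bold`` — an ROI time course with oddball-locked responses,
  slow sinusoidal drift, motion leakage and Gaussian noise;
* ``generate_dwi`` — multi-shell diffusion signals from prescribed diffusion
  tensors under the single-tensor forward model, with Rician noise;
* ``generate_tract_fixture`` — jittered streamline bundles traversing scalar
  maps of known value.

Units: mm for geometry, seconds for time, s/mm^2 for b-values, mm^2/s for
diffusivities, arbitrary units for intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from lcmri import oddball_glm
from lcmri.volume import Volume

__all__ = [
    "PhantomSpec",
    "BoldSpec",
    "DwiSpec",
    "generate_lc_phantom",
    "rasterize_tube",
    "perturb_rater_masks",
    "generate_bold",
    "generate_dwi",
    "generate_tract_fixture",
    "make_gradient_table",
    "random_spd_tensor",
]

# MT-TFL-like slab geometry: high in-plane resolution, thick axial slices
DEFAULT_VOXEL_SIZE = (0.39, 0.39, 1.7)


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry and signal model of the LC phantom.

    ``lc_centerlines`` holds one polyline per side (left, right) in mm
    coordinates; the tube of radius ``lc_radius`` around each polyline is
    the true LC.  LC voxels have expected intensity
    ``contrast_ratio * pons_mean``; everything else sits at ``pons_mean``.
    """

    shape: tuple[int, int, int] = (64, 64, 16)
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    lc_centerlines: tuple[np.ndarray, np.ndarray] | None = None
    lc_radius: float = 1.25
    contrast_ratio: float = 1.15
    pons_mean: float = 100.0
    noise_sd: float = 5.0          # image SNR 20 relative to the pons
    seed: int = 0

    def __post_init__(self) -> None:
        if self.contrast_ratio <= 0:
            raise ValueError("contrast_ratio must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pons_mean <= 0:
            raise ValueError("pons_mean must be > 0")
        if self.lc_centerlines is None:
            self.lc_centerlines = _default_centerlines(self.shape, self.voxel_size)
        self.lc_centerlines = tuple(
            np.atleast_2d(np.asarray(c, dtype=float)) for c in self.lc_centerlines
        )
        extent = np.asarray(self.shape) * np.asarray(self.voxel_size)
        for c in self.lc_centerlines:
            if np.any(c < 0) or np.any(c >= extent):
                raise ValueError(
                    f"centerline leaves the grid (extent {extent.tolist()} mm)"
                )


def _default_centerlines(shape, voxel_size, length_mm: float = 15.0, sep_mm: float = 7.0):
    """Two vertical tubes, bilaterally symmetric, centered in the slab.

    The rostro-caudal extent is a free parameter of the phantom; 15 mm
    matches the textbook length of the nucleus.
    """
    extent = np.asarray(shape) * np.asarray(voxel_size)
    cx, cy = extent[0] / 2.0, extent[1] * 0.6   # slightly posterior
    z_mid = extent[2] / 2.0
    length = min(length_mm, extent[2] * 0.9)
    z = np.linspace(z_mid - length / 2.0, z_mid + length / 2.0, 9)
    left = np.column_stack([np.full_like(z, cx - sep_mm / 2.0), np.full_like(z, cy), z])
    right = np.column_stack([np.full_like(z, cx + sep_mm / 2.0), np.full_like(z, cy), z])
    return left, right


@dataclass
class BoldSpec:
    """ROI BOLD series: oddball response + drift + motion leakage + noise.

    ``beta`` is the injected effect size expressed on the z-scored task
    regressor (the convention the GLM fits in), so a noiseless, drift-free
    series returns exactly ``beta``.
    """

    n_volumes: int = 335
    tr_s: float = 1.7
    paradigm: oddball_glm.OddballParadigm | None = None
    beta: float = 2.0
    drift_amplitude: float = 0.0
    drift_cycles: int = 2
    motion: np.ndarray | None = None
    motion_leak: float = 0.0
    noise_sd: float = 0.0
    baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes < 10:
            raise ValueError("need at least 10 volumes")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.paradigm is None:
            # study-like defaults: 220 stimuli, 46 targets, ISI 2.5 s
            self.paradigm = oddball_glm.generate_paradigm(
                220, 46, isi_ms=2500.0, seed=self.seed
            )
        if np.any(self.paradigm.target_onsets_s >= self.n_volumes * self.tr_s):
            raise ValueError("paradigm onset beyond scan end")


@dataclass
class DwiSpec:
    """Diffusion signals from a prescribed tensor field.

    ``tensors`` is a ``(X, Y, Z, 3, 3)`` field of symmetric positive-definite
    diffusion tensors in mm^2/s.  Noiseless signal per voxel and direction:
    ``S0 * exp(-b g^T D g)``; Rician noise of scale ``sigma`` is applied to
    the magnitude.
    """

    tensors: np.ndarray = None
    bvals: np.ndarray = None
    bvecs: np.ndarray = None
    s0: float = 1000.0
    sigma: float = 0.0
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bvals is None or self.bvecs is None:
            self.bvals, self.bvecs = make_gradient_table(seed=self.seed)
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.tensors is None:
            self.tensors = np.broadcast_to(
                np.diag([1.7e-3, 0.3e-3, 0.3e-3]), (4, 4, 4, 3, 3)
            ).copy()
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[-2:] != (3, 3):
            raise ValueError("tensors must be a (X, Y, Z, 3, 3) field")
        if np.any(self.bvals < 0) or not np.any(self.bvals == 0):
            raise ValueError("b-values must be >= 0 with at least one b=0 entry")
        nz = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[nz], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("gradient directions must be unit vectors")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        evals = np.linalg.eigvalsh(self.tensors.reshape(-1, 3, 3))
        if np.any(evals <= 0):
            raise ValueError("all tensors must be positive definite")


# --------------------------------------------------------------------------
# phantom
# --------------------------------------------------------------------------

def _point_segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to segment [a, b]."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def rasterize_tube(
    polyline: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size,
    radius_mm: float,
) -> np.ndarray:
    """Boolean mask of voxels whose center lies within ``radius_mm`` of the polyline."""
    polyline = np.atleast_2d(np.asarray(polyline, dtype=float))
    vs = np.asarray(voxel_size, dtype=float)
    lo = np.maximum(np.floor((polyline.min(axis=0) - radius_mm) / vs).astype(int), 0)
    hi = np.minimum(
        np.ceil((polyline.max(axis=0) + radius_mm) / vs).astype(int) + 1,
        np.asarray(shape),
    )
    mask = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return mask
    grids = np.meshgrid(
        *[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij"
    )
    idx = np.stack([g.ravel() for g in grids], axis=1)
    centers = (idx + 0.5) * vs
    dmin = np.full(len(centers), np.inf)
    if len(polyline) == 1:
        dmin = np.linalg.norm(centers - polyline[0], axis=1)
    else:
        for a, b in zip(polyline[:-1], polyline[1:]):
            np.minimum(dmin, _point_segment_distances(centers, a, b), out=dmin)
    inside = idx[dmin <= radius_mm]
    mask[inside[:, 0], inside[:, 1], inside[:, 2]] = True
    return mask


def generate_lc_phantom(
    spec: PhantomSpec,
) -> tuple[Volume, np.ndarray, tuple[int, int]]:
    """Render the LC phantom.

    Returns the intensity volume, the true LC mask (both tubes), and the
    in-plane voxel coordinate of a pontine reference center situated
    anteriorly to (smaller y than) the LC, midway between the two tubes.
    """
    mask = np.zeros(spec.shape, dtype=bool)
    for line in spec.lc_centerlines:
        mask |= rasterize_tube(line, spec.shape, spec.voxel_size, spec.lc_radius)
    data = np.full(spec.shape, float(spec.pons_mean))
    data[mask] = spec.contrast_ratio * spec.pons_mean
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vs = np.asarray(spec.voxel_size)
    mid = np.mean([line.mean(axis=0) for line in spec.lc_centerlines], axis=0)
    # anterior offset ~half the distance from LC to the front of the grid
    ref_y_mm = mid[1] / 2.0
    ref_center = (int(mid[0] / vs[0]), int(ref_y_mm / vs[1]))
    return Volume(data, spec.voxel_size), mask, ref_center


def _inplane_boundary(mask2d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(add candidates, remove candidates) for one axial slice, 4-connectivity."""
    from scipy import ndimage

    grown = ndimage.binary_dilation(mask2d, structure=ndimage.generate_binary_structure(2, 1))
    shrunk = ndimage.binary_erosion(mask2d, structure=ndimage.generate_binary_structure(2, 1))
    add = np.argwhere(grown & ~mask2d)
    remove = np.argwhere(mask2d & ~shrunk)
    return add, remove


def perturb_rater_masks(
    true_mask: np.ndarray,
    jitter_voxels: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Two simulated manual delineations of the true mask.

    Each rater's mask is the truth with up to ``jitter_voxels`` boundary
    voxels per axial slice randomly added or removed.  Returns
    ``(mask_a, mask_b, dice)`` where ``dice`` is the Dice overlap of the two
    rater masks.  Raises if the jitter empties any originally occupied slice.
    """
    true_mask = np.asarray(true_mask, dtype=bool)
    if not true_mask.any():
        raise ValueError("true mask is empty")
    if jitter_voxels < 0:
        raise ValueError("jitter_voxels must be >= 0")
    rng = np.random.default_rng(seed)
    masks = []
    for _ in range(2):
        m = true_mask.copy()
        for z in range(m.shape[2]):
            if not true_mask[:, :, z].any():
                continue
            add, remove = _inplane_boundary(true_mask[:, :, z])
            candidates = [("add", tuple(v)) for v in add] + [
                ("remove", tuple(v)) for v in remove
            ]
            if not candidates or jitter_voxels == 0:
                continue
            k = int(rng.integers(0, jitter_voxels + 1))
            picks = rng.choice(len(candidates), size=min(k, len(candidates)), replace=False)
            for p in picks:
                action, (x, y) = candidates[int(p)]
                m[x, y, z] = action == "add"
            if not m[:, :, z].any():
                raise ValueError(
                    f"jitter {jitter_voxels} emptied slice {z}; reduce jitter"
                )
        masks.append(m)
    a, b = masks
    dice = 2.0 * np.sum(a & b) / (np.sum(a) + np.sum(b))
    return a, b, float(dice)


# --------------------------------------------------------------------------
# BOLD
# --------------------------------------------------------------------------

def generate_bold(spec: BoldSpec) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthesize an ROI BOLD time course.

    Returns ``(series, motion, truth)`` where ``motion`` is the
    ``(n_volumes, 6)`` nuisance table actually mixed into the series and
    ``truth`` records the injected parameters.
    """
    rng = np.random.default_rng(spec.seed)
    n, tr = spec.n_volumes, spec.tr_s
    raw = oddball_glm.task_regressor(spec.paradigm, n, tr)
    task = (raw - raw.mean()) / raw.std()
    series = spec.baseline + spec.beta * task

    if spec.motion is not None:
        motion = np.asarray(spec.motion, dtype=float)
        if motion.shape != (n, 6):
            raise ValueError(f"motion must be ({n}, 6), got {motion.shape}")
    else:
        # smooth random-walk realignment traces (mm / radians scale ~0.1)
        steps = rng.normal(0.0, 0.02, size=(n, 6))
        motion = np.cumsum(steps, axis=0)
    if spec.motion_leak != 0:
        series = series + spec.motion_leak * motion.sum(axis=1)

    if spec.drift_amplitude != 0:
        k = np.arange(n)
        for c in range(1, spec.drift_cycles + 1):
            phase = rng.uniform(0, 2 * np.pi)
            series = series + spec.drift_amplitude * np.sin(
                2 * np.pi * c * k / n + phase
            )
    if spec.noise_sd > 0:
        series = series + rng.normal(0.0, spec.noise_sd, size=n)
    truth = {
        "beta": spec.beta,
        "noise_sd": spec.noise_sd,
        "drift_amplitude": spec.drift_amplitude,
        "drift_cycles": spec.drift_cycles,
        "motion_leak": spec.motion_leak,
        "seed": spec.seed,
    }
    return series, motion, truth


def bold_volume_from_series(
    series: np.ndarray,
    roi_shape: tuple[int, int, int] = (4, 4, 2),
    voxel_size=(1.7, 1.7, 2.0),
) -> tuple[Volume, np.ndarray]:
    """Tile one ROI series into a small 4D volume plus its full mask."""
    series = np.asarray(series, dtype=float)
    data = np.broadcast_to(series, (*roi_shape, len(series))).copy()
    return Volume(data, voxel_size), np.ones(roi_shape, dtype=bool)


# --------------------------------------------------------------------------
# DWI
# --------------------------------------------------------------------------

def make_gradient_table(
    n_dirs: int = 64,
    b: float = 1000.0,
    n_b0: int = 7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-shell FSL-style gradient table: ``n_b0`` b0s then ``n_dirs`` at b.

    Directions are drawn uniformly on the sphere (seeded); adequate for
    testing tensor estimation, which needs spread rather than optimality.
    """
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_dirs, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), v])
    return bvals, bvecs


def random_spd_tensor(rng, scale: float = 1e-3) -> np.ndarray:
    """Random symmetric positive-definite diffusion tensor (mm^2/s)."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    evals = rng.uniform(0.2, 2.5, size=3) * scale
    return q @ np.diag(evals) @ q.T


def dwi_forward_signal(tensors: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray, s0: float) -> np.ndarray:
    """Noiseless single-tensor signal ``S0 exp(-b g^T D g)`` per voxel/direction."""
    quad = np.einsum("nd,...de,ne->...n", bvecs, tensors, bvecs)
    return s0 * np.exp(-bvals * quad)


def generate_dwi(spec: DwiSpec) -> tuple[Volume, tuple[np.ndarray, np.ndarray]]:
    """Synthesize a 4D DWI volume and its gradient table.

    Rician noise: the noiseless signal is taken as the real channel and two
    independent Gaussian deviates of scale ``sigma`` corrupt the complex
    signal before the magnitude is taken.
    """
    clean = dwi_forward_signal(spec.tensors, spec.bvals, spec.bvecs, spec.s0)
    if spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        n1 = rng.normal(0.0, spec.sigma, size=clean.shape)
        n2 = rng.normal(0.0, spec.sigma, size=clean.shape)
        data = np.sqrt((clean + n1) ** 2 + n2**2)
    else:
        data = clean
    return Volume(data, spec.voxel_size), (spec.bvals.copy(), spec.bvecs.copy())


# --------------------------------------------------------------------------
# tracts
# --------------------------------------------------------------------------

def generate_tract_fixture(
    path_mm: np.ndarray,
    shape: tuple[int, int, int],
    voxel_size,
    scalar_values: dict[str, float] | None = None,
    n_streamlines: int = 20,
    jitter_mm: float = 0.5,
    seed: int = 0,
) -> tuple[list[np.ndarray], dict[str, Volume]]:
    """Jittered copies of a path polyline plus constant-valued scalar maps.

    Each streamline is the input path shifted by a random lateral offset of
    magnitude up to ``jitter_mm`` (clipped inside the grid).  Scalar maps are
    constant at the requested value on the whole grid.
    """
    path = np.atleast_2d(np.asarray(path_mm, dtype=float))
    if path.size == 0:
        raise ValueError("empty path polyline")
    vs = np.asarray(voxel_size, dtype=float)
    extent = np.asarray(shape) * vs
    if np.any(path < 0) or np.any(path >= extent):
        raise ValueError("path polyline leaves the grid")
    rng = np.random.default_rng(seed)
    streamlines = []
    eps = 1e-6
    for _ in range(n_streamlines):
        offset = rng.uniform(-jitter_mm, jitter_mm, size=3)
        s = np.clip(path + offset, 0.0, extent - eps)
        streamlines.append(s)
    maps = {}
    for name, value in (scalar_values or {}).items():
        maps[name] = Volume(np.full(shape, float(value)), tuple(vs))
    return streamlines, maps


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def save_streamlines(streamlines, path, shape=None, voxel_size=None) -> None:
    """Write streamlines (mm coordinates) as .tck or .trk by extension."""
    import nibabel as nib
    from nibabel import streamlines as nibsl

    path = str(path)
    tractogram = nibsl.Tractogram(
        [np.asarray(s, dtype=np.float32) for s in streamlines],
        affine_to_rasmm=np.eye(4),
    )
    if path.endswith(".trk"):
        if shape is None or voxel_size is None:
            raise ValueError("TRK output needs grid shape and voxel_size")
        header = {
            nibsl.trk.Field.VOXEL_SIZES: tuple(float(v) for v in voxel_size),
            nibsl.trk.Field.DIMENSIONS: tuple(int(s) for s in shape),
            nibsl.trk.Field.VOXEL_TO_RASMM: np.diag([*voxel_size, 1.0]).astype(
                np.float32
            ),
            nibsl.trk.Field.VOXEL_ORDER: "RAS",
        }
        nib.streamlines.save(tractogram, path, header=header)
    elif path.endswith(".tck"):
        nib.streamlines.save(tractogram, path)
    else:
        raise ValueError(f"unsupported streamline format: {path}")


def load_streamlines(path) -> list[np.ndarray]:
    """Read .tck/.trk streamlines in mm (RAS) coordinates."""
    import nibabel as nib

    obj = nib.streamlines.load(str(path))
    return [np.asarray(s, dtype=float) for s in obj.tractogram.streamlines]


def save_events_tsv(paradigm: oddball_glm.OddballParadigm, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"onset_s": paradigm.onsets_s, "type": paradigm.types}
    ).to_csv(path, sep="\t", index=False)


def load_events_tsv(path, **paradigm_kwargs) -> oddball_glm.OddballParadigm:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return oddball_glm.OddballParadigm(
        df["onset_s"].to_numpy(), list(df["type"]), **paradigm_kwargs
    )


def save_motion_tsv(motion: np.ndarray, path) -> None:
    import pandas as pd

    cols = ["tx", "ty", "tz", "rx", "ry", "rz"]
    pd.DataFrame(np.asarray(motion), columns=cols).to_csv(path, sep="\t", index=False)


def load_motion_tsv(path) -> np.ndarray:
    import pandas as pd

    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def save_gradient_table(bvals: np.ndarray, bvecs: np.ndarray, prefix) -> None:
    """FSL convention: one-line .bval; .bvec with one row per axis."""
    np.savetxt(f"{prefix}.bval", np.asarray(bvals)[None, :], fmt="%.1f")
    np.savetxt(f"{prefix}.bvec", np.asarray(bvecs).T, fmt="%.8f")


def load_gradient_table(prefix) -> tuple[np.ndarray, np.ndarray]:
    bvals = np.loadtxt(f"{prefix}.bval").ravel()
    bvecs = np.loadtxt(f"{prefix}.bvec").T
    return bvals, bvecs


def save_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True, default=float)
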