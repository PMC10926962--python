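"""Locus coeruleus MT-contrast extraction.

Pipeline, per side:

1. upsample the volume (default factor 3, nearest-neighbor, so a 1 mm grid
   becomes 0.33 mm);
2. intersect the two raters' LC masks;
3. order the occupied axial slices caudal-to-rostral and split them into
   caudal 25 % / medial 50 % / rostral 25 % subparts (slice counts, floor
   rule, remainder to the medial subpart);
4. on each slice, center a 5-voxel in-plane cross on the highest-intensity
   mask voxel and average the 5 intensities (LC̄_i);
5. average a slice-matched square pontine reference region (default 15x15
   voxels, i.e. 4.95 mm per side at 0.33 mm resolution) anterior to the LC
   (pons̄_i);
6. contrast per subpart = mean over its slices of (LC̄_i / pons̄_i − 1).

The ratio normalization makes every contrast value invariant to global
intensity scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lcmri.volume import Volume

__all__ = [
    "LCRegion",
    "SliceSample",
    "ReferenceSpec",
    "ContrastResult",
    "upsample_volume",
    "intersect_masks",
    "subdivide_rostrocaudal",
    "peak_cross_mean",
    "reference_mean",
    "compute_contrast",
    "extract_contrast",
]

SUBPARTS = ("caudal", "medial", "rostral")


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass
class LCRegion:
    """One side's LC: intersection mask, ordered slices, subpart labels."""

    side: str
    mask: np.ndarray                       # boolean, (x, y, z)
    slices: list[int] = field(init=False)  # caudal -> rostral (ascending z)
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        self.mask = np.asarray(self.mask, dtype=bool)
        occupied = sorted(int(z) for z in np.unique(np.argwhere(self.mask)[:, 2]))
        if occupied and occupied != list(range(occupied[0], occupied[-1] + 1)):
            raise ValueError(f"mask slices are not contiguous: {occupied}")
        self.slices = occupied

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def subpart_slices(self, subpart: str) -> list[int]:
        return [z for z in self.slices if self.labels.get(z) == subpart]


@dataclass(frozen=True)
class SliceSample:
    """Per-slice measurement: peak voxel, 5-voxel cross mean, reference mean."""

    slice_index: int
    peak: tuple[int, int]
    cross_mean: float        # LC̄_i
    reference_mean: float    # pons̄_i
    reference_center: tuple[int, int]

    @property
    def normalized(self) -> float:
        return self.cross_mean / self.reference_mean - 1.0


@dataclass
class ReferenceSpec:
    """Placement of the square pontine reference region.

    Either explicit per-slice in-plane centers (mimicking manual placement)
    or a rule-based center at ``(peak_x, peak_y - anterior_offset)`` —
    anterior is the smaller-y direction.  ``size`` is the odd region edge in
    voxels (default 15).
    """

    size: int = 15
    centers: dict[int, tuple[int, int]] | None = None
    anterior_offset: int = 30

    def __post_init__(self) -> None:
        if self.size < 3 or self.size % 2 == 0:
            raise ValueError("reference size must be odd and >= 3")

    def center_for(self, slice_index: int, peak: tuple[int, int] | None) -> tuple[int, int]:
        if self.centers is not None:
            if slice_index not in self.centers:
                raise ValueError(f"no reference center given for slice {slice_index}")
            return tuple(self.centers[slice_index])
        if peak is None:
            raise ValueError("rule-based reference placement needs the slice peak")
        return (peak[0], peak[1] - self.anterior_offset)


@dataclass
class SubpartContrast:
    contrast: float
    n_slices: int
    samples: list[SliceSample]


@dataclass
class ContrastResult:
    """Contrast per subpart (plus whole-LC) for one side, with audit samples."""

    side: str
    subparts: dict[str, SubpartContrast]

    def contrast(self, subpart: str) -> float:
        return self.subparts[subpart].contrast


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def upsample_volume(vol: Volume, factor: int, method: str = "nearest") -> Volume:
    """Upsample each spatial axis by an integer factor.

    Nearest-neighbor replication by default (keeps intensities and mask
    provenance exact); trilinear available via ``method='linear'``.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ValueError(f"upsampling factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return vol.copy()
    if method == "nearest":
        data = vol.data
        for ax in range(3):
            data = np.repeat(data, factor, axis=ax)
    elif method == "linear":
        from scipy import ndimage

        zoom = [factor] * 3 + [1] * (vol.data.ndim - 3)
        data = ndimage.zoom(vol.data, zoom, order=1, grid_mode=True, mode="nearest")
    else:
        raise ValueError(f"unknown upsampling method: {method}")
    new_vs = tuple(v / factor for v in vol.voxel_size)
    return Volume(data, new_vs)


def upsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor upsampling of a boolean mask."""
    out = np.asarray(mask, dtype=bool)
    if int(factor) == 1:
        return out.copy()
    for ax in range(3):
        out = np.repeat(out, int(factor), axis=ax)
    return out


def intersect_masks(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxelwise intersection of the two raters' masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    inter = a & b
    if not inter.any():
        raise ValueError(
            f"rater masks do not intersect (sizes {int(a.sum())} and {int(b.sum())})"
        )
    return inter


def subdivide_rostrocaudal(mask: np.ndarray, side: str = "left") -> LCRegion:
    """Partition the mask's axial slices into caudal/medial/rostral subparts.

    Slices are ordered caudal (low z) to rostral (high z); the caudal and
    rostral subparts each take ``floor(n/4)`` slices and the medial subpart
    the remainder, so the 25/50/25 split holds exactly when 4 | n and the
    medial subpart absorbs rounding otherwise.
    """
    region = LCRegion(side=side, mask=mask)
    n = region.n_slices
    if n < 4:
        raise ValueError(
            f"need at least 4 occupied slices to form three subparts, got {n}"
        )
    quarter = n // 4
    for rank, z in enumerate(region.slices):
        if rank < quarter:
            region.labels[z] = "caudal"
        elif rank >= n - quarter:
            region.labels[z] = "rostral"
        else:
            region.labels[z] = "medial"
    return region


# in-plane: center + anterior/posterior (±y) + left/right (±x)
_CROSS_IN_PLANE = ((0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0))
# through-plane: center + left/right (±x) + rostral/caudal (±z)
_CROSS_THROUGH_PLANE = ((0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 0, 1), (0, 0, -1))


def peak_cross_mean(
    vol: Volume,
    mask: np.ndarray,
    slice_index: int,
    mode: str = "in-plane",
) -> tuple[tuple[int, int], float]:
    """Peak-centered 5-voxel cross mean on one axial slice.

    The peak is the highest-intensity voxel of the mask on that slice; ties
    break to the lexicographically smallest ``(x, y)`` for determinism.
    Returns ``(peak_xy, cross_mean)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.spatial_shape:
        raise ValueError("mask grid does not match volume")
    sl = mask[:, :, slice_index]
    if not sl.any():
        raise ValueError(f"mask has no voxels on slice {slice_index}")
    coords = np.argwhere(sl)                      # already sorted by (x, y)
    vals = vol.data[coords[:, 0], coords[:, 1], slice_index]
    # ties (flat plateaus): take the tied voxel nearest the plateau centroid
    # so the cross samples plateau interior; remaining ties break to the
    # lexicographically smallest (x, y).  For a two-voxel tie both are
    # equidistant from the centroid, so the smaller (x, y) wins.
    tied = coords[vals == vals.max()]
    d2 = ((tied - tied.mean(axis=0)) ** 2).sum(axis=1)
    best = tied[d2 == d2.min()]
    peak_xy = tuple(int(c) for c in min(map(tuple, best)))
    offsets = _CROSS_IN_PLANE if mode == "in-plane" else _CROSS_THROUGH_PLANE
    if mode not in ("in-plane", "through-plane"):
        raise ValueError(f"unknown cross mode: {mode}")
    total = 0.0
    for dx, dy, dz in offsets:
        x, y, z = peak_xy[0] + dx, peak_xy[1] + dy, slice_index + dz
        if not (
            0 <= x < vol.shape[0] and 0 <= y < vol.shape[1] and 0 <= z < vol.n_slices
        ):
            raise ValueError(
                f"5-voxel cross at peak {peak_xy} exceeds volume bounds on slice "
                f"{slice_index}"
            )
        total += float(vol.data[x, y, z])
    return peak_xy, total / 5.0


def reference_mean(
    vol: Volume,
    slice_index: int,
    spec: ReferenceSpec,
    peak: tuple[int, int] | None = None,
) -> tuple[float, tuple[int, int]]:
    """Mean of the square pontine reference region on one axial slice."""
    cx, cy = spec.center_for(slice_index, peak)
    half = spec.size // 2
    x0, x1 = cx - half, cx + half + 1
    y0, y1 = cy - half, cy + half + 1
    if x0 < 0 or y0 < 0 or x1 > vol.shape[0] or y1 > vol.shape[1]:
        raise ValueError(
            f"reference region out of bounds on slice {slice_index} "
            f"(center ({cx}, {cy}), size {spec.size})"
        )
    region = vol.data[x0:x1, y0:y1, slice_index]
    return float(region.mean()), (cx, cy)


def compute_contrast(
    vol: Volume,
    region: LCRegion,
    ref_spec: ReferenceSpec | None = None,
    cross_mode: str = "in-plane",
) -> ContrastResult:
    """Contrast per subpart: mean over slices of (LC̄_i / pons̄_i − 1).

    Also reports ``"whole"`` — the mean over every occupied slice, which by
    construction is unchanged by how the subpart boundaries fall.
    """
    ref_spec = ref_spec or ReferenceSpec()
    samples: dict[int, SliceSample] = {}
    for z in region.slices:
        peak, lc_mean = peak_cross_mean(vol, region.mask, z, mode=cross_mode)
        pons_mean, center = reference_mean(vol, z, ref_spec, peak=peak)
        if pons_mean <= 0:
            raise ValueError(f"non-positive reference mean on slice {z}")
        samples[z] = SliceSample(z, peak, lc_mean, pons_mean, center)
    subparts: dict[str, SubpartContrast] = {}
    for part in SUBPARTS:
        zs = region.subpart_slices(part)
        if not zs:
            raise ValueError(f"subpart '{part}' has no slices (n={region.n_slices})")
        vals = [samples[z].normalized for z in zs]
        subparts[part] = SubpartContrast(
            contrast=float(np.mean(vals)),
            n_slices=len(zs),
            samples=[samples[z] for z in zs],
        )
    whole = [samples[z].normalized for z in region.slices]
    subparts["whole"] = SubpartContrast(
        contrast=float(np.mean(whole)),
        n_slices=region.n_slices,
        samples=[samples[z] for z in region.slices],
    )
    return ContrastResult(side=region.side, subparts=subparts)


def extract_contrast(
    vol: Volume,
    mask_rater1: np.ndarray,
    mask_rater2: np.ndarray,
    side: str = "left",
    factor: int = 3,
    ref_spec: ReferenceSpec | None = None,
    cross_mode: str = "in-plane",
    upsample_method: str = "nearest",
) -> ContrastResult:
    """Full single-side pipeline: upsample, intersect, subdivide, contrast."""
    up = upsample_volume(vol, factor, method=upsample_method)
    m1 = upsample_mask(mask_rater1, factor)
    m2 = upsample_mask(mask_rater2, factor)
    inter = intersect_masks(m1, m2)
    region = subdivide_rostrocaudal(inter, side=side)
    return compute_contrast(up, region, ref_spec=ref_spec, cross_mode=cross_mode)


def result_to_frame(result: ContrastResult):
    """Tabulate a ContrastResult: one row per subpart."""
    import pandas as pd

    rows = [
        {
            "side": result.side,
            "subpart": part,
            "n_slices": sc.n_slices,
            "contrast": sc.contrast,
        }
        for part, sc in result.subparts.items()
    ]
    return pd.DataFrame(rows)
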