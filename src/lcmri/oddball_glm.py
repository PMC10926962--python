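"""Auditory-oddball paradigm construction and event-related ROI GLM.

The paradigm is a stream of frequent standard tones with rare targets
(~20 % of stimuli) at a fixed interstimulus interval; the subject presses a
button at each target.  The ROI analysis convolves the target-onset vector
with a two-gamma hemodynamic response function (HRF), adds six head-motion
nuisance regressors and a Fourier basis modelling slow drift (all sine and
cosine pairs with fewer cycles per run than the cut-off, default 3), z-scores
every non-intercept predictor, and fits ordinary least squares to the mean
ROI time course.  The quantity of interest is the beta of the target
regressor.

Because predictors are z-scored before fitting, an injected effect expressed
on the z-scored task regressor is recovered as the same number: betas are in
units of one standard deviation of the task regressor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from lcmri.volume import Volume

__all__ = [
    "HRFParams",
    "OddballParadigm",
    "DesignMatrix",
    "GLMResult",
    "generate_paradigm",
    "two_gamma_hrf",
    "build_design",
    "fit_glm",
    "extract_roi_beta",
    "score_accuracy",
]


# --------------------------------------------------------------------------
# types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma HRF parameters (seconds).

    The kernel is ``g(t; peak_delay, peak_disp) - g(t; under_delay,
    under_disp) / ratio`` with ``g`` a gamma density of shape
    ``delay / disp`` and scale ``disp``; the positive lobe peaks near
    ``peak_delay - peak_disp`` (~5 s with the defaults).
    """

    peak_delay: float = 6.0
    under_delay: float = 16.0
    peak_disp: float = 1.0
    under_disp: float = 1.0
    ratio: float = 6.0


@dataclass
class OddballParadigm:
    """Stimulus stream: onsets in seconds with a type per stimulus."""

    onsets_s: np.ndarray          # strictly increasing, seconds
    types: list[str]              # "standard" | "target", parallel to onsets
    isi_ms: float = 2500.0
    target_hz: float = 1000.0
    standard_hz: float = 500.0
    tone_duration_ms: float = 100.0

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if len(self.onsets_s) != len(self.types):
            raise ValueError("onsets and types must have equal length")
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("onsets must be strictly increasing")
        bad = set(self.types) - {"standard", "target"}
        if bad:
            raise ValueError(f"unknown stimulus types: {sorted(bad)}")

    @property
    def target_onsets_s(self) -> np.ndarray:
        return self.onsets_s[[t == "target" for t in self.types]]

    @property
    def n_targets(self) -> int:
        return sum(t == "target" for t in self.types)

    @property
    def target_fraction(self) -> float:
        return self.n_targets / len(self.types)


@dataclass
class DesignMatrix:
    """Column matrix (volumes x regressors) with named columns.

    All non-intercept columns are z-scored (mean 0, SD 1); the intercept is
    the last column.
    """

    matrix: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.names):
            raise ValueError("matrix/names shape mismatch")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]


@dataclass
class GLMResult:
    betas: dict[str, float]
    se: dict[str, float]
    residual_variance: float
    df: int

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Two-sided t confidence interval for one coefficient."""
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.df)
        b, s = self.betas[name], self.se[name]
        return (b - tcrit * s, b + tcrit * s)


# --------------------------------------------------------------------------
# paradigm
# --------------------------------------------------------------------------

def generate_paradigm(
    n_total: int,
    n_target: int,
    isi_ms: float = 2500.0,
    seed: int = 0,
    min_gap: int = 1,
    **tone_kwargs,
) -> OddballParadigm:
    """Pseudorandom oddball sequence with a minimum standard-gap rule.

    Exactly ``n_target`` targets are placed among ``n_total`` stimuli with at
    least ``min_gap`` standards between any two consecutive targets.
    Deterministic given ``seed``.
    """
    if not 0 < n_target < n_total:
        raise ValueError(f"need 0 < n_target < n_total, got {n_target}/{n_total}")
    if min_gap < 1:
        raise ValueError("min_gap must be >= 1")
    # spacing feasibility: targets consume n_target slots plus min_gap
    # standards between each consecutive pair
    if n_target + (n_target - 1) * min_gap > n_total:
        raise ValueError(
            f"cannot place {n_target} targets with min_gap={min_gap} "
            f"among {n_total} stimuli"
        )
    rng = np.random.default_rng(seed)
    # classic stars-and-bars trick: sample positions in the compressed
    # sequence, then re-expand so consecutive targets are >= min_gap+1 apart
    m = n_total - (n_target - 1) * min_gap
    compressed = np.sort(rng.choice(m, size=n_target, replace=False))
    positions = compressed + min_gap * np.arange(n_target)
    types = ["standard"] * n_total
    for p in positions:
        types[int(p)] = "target"
    onsets = np.arange(n_total) * (isi_ms / 1000.0)
    return OddballParadigm(onsets, types, isi_ms=isi_ms, **tone_kwargs)


# --------------------------------------------------------------------------
# HRF and design matrix
# --------------------------------------------------------------------------

def two_gamma_hrf(
    tr_s: float,
    length_s: float = 32.0,
    params: HRFParams | None = None,
) -> np.ndarray:
    """Two-gamma HRF sampled at the volume grid, peak normalized to 1."""
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    if length_s < 0:
        raise ValueError("length_s must be non-negative")
    p = params or HRFParams()
    t = np.arange(0.0, length_s + 1e-9, tr_s)
    peak = stats.gamma.pdf(t, a=p.peak_delay / p.peak_disp, scale=p.peak_disp)
    under = stats.gamma.pdf(t, a=p.under_delay / p.under_disp, scale=p.under_disp)
    h = peak - under / p.ratio
    m = np.max(np.abs(h))
    if m == 0:
        raise ValueError("degenerate HRF (all zero); increase length_s")
    return h / m


def zscore_columns(x: np.ndarray) -> np.ndarray:
    """Z-transform each column to mean 0, SD 1 (population SD)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a constant column")
    return (x - mu) / sd


def task_regressor(
    paradigm: OddballParadigm,
    n_volumes: int,
    tr_s: float,
    hrf_params: HRFParams | None = None,
) -> np.ndarray:
    """HRF-convolved target indicator sampled on the volume grid (raw units).

    Each target onset is assigned to the volume whose acquisition window
    contains it; no slice-level microtiming.
    """
    onsets = paradigm.target_onsets_s
    if np.any(onsets >= n_volumes * tr_s):
        raise ValueError("target onset beyond scan end")
    indicator = np.zeros(n_volumes)
    vols = np.floor(onsets / tr_s).astype(int)
    np.add.at(indicator, vols, 1.0)
    kernel = two_gamma_hrf(tr_s, params=hrf_params)
    return np.convolve(indicator, kernel)[:n_volumes]


def fourier_drift_basis(n_volumes: int, hp_cycles: int) -> tuple[np.ndarray, list[str]]:
    """Sine/cosine pairs for every whole cycle count below the cut-off."""
    cols, names = [], []
    k = np.arange(n_volumes)
    for c in range(1, hp_cycles):
        cols.append(np.sin(2 * np.pi * c * k / n_volumes))
        cols.append(np.cos(2 * np.pi * c * k / n_volumes))
        names += [f"drift_sin{c}", f"drift_cos{c}"]
    if not cols:
        return np.empty((n_volumes, 0)), []
    return np.column_stack(cols), names


def build_design(
    paradigm: OddballParadigm,
    n_volumes: int,
    tr_s: float,
    motion: np.ndarray | None = None,
    hp_cycles: int = 3,
    hrf_params: HRFParams | None = None,
) -> DesignMatrix:
    """Assemble the oddball design matrix.

    Columns: HRF-convolved target regressor, six motion parameters, Fourier
    drift pairs for cycles ``1 .. hp_cycles-1``, and an intercept.  Every
    non-intercept column is z-scored.

    Raises on rank deficiency, naming the offending columns.
    """
    cols = [task_regressor(paradigm, n_volumes, tr_s, hrf_params)]
    names = ["target"]
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_volumes, 6):
            raise ValueError(
                f"motion table must be {n_volumes} rows x 6 columns, got {motion.shape}"
            )
        cols.append(motion)
        names += [f"motion_{ax}" for ax in ("tx", "ty", "tz", "rx", "ry", "rz")]
    drift, drift_names = fourier_drift_basis(n_volumes, hp_cycles)
    if drift.shape[1]:
        cols.append(drift)
        names += drift_names
    x = zscore_columns(np.column_stack(cols))
    x = np.column_stack([x, np.ones(n_volumes)])
    names.append("intercept")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # report which columns are linearly dependent on their predecessors
        dep = []
        for j in range(1, x.shape[1]):
            if np.linalg.matrix_rank(x[:, : j + 1]) == np.linalg.matrix_rank(x[:, :j]):
                dep.append(names[j])
        raise ValueError(f"design matrix is rank deficient; collinear columns: {dep}")
    return DesignMatrix(x, names)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

def fit_glm(series: np.ndarray, design: DesignMatrix) -> GLMResult:
    """Ordinary least squares fit of one time series against the design."""
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or len(y) != design.n_volumes:
        raise ValueError(
            f"series length {y.shape} does not match design rows {design.n_volumes}"
        )
    x = design.matrix
    df = design.n_volumes - np.linalg.matrix_rank(x)
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    resvar = float(resid @ resid) / df
    cov = resvar * np.linalg.inv(x.T @ x)
    se = np.sqrt(np.diag(cov))
    return GLMResult(
        betas=dict(zip(design.names, map(float, beta))),
        se=dict(zip(design.names, map(float, se))),
        residual_variance=resvar,
        df=int(df),
    )


def extract_roi_beta(
    bold: Volume,
    roi_mask: np.ndarray,
    design: DesignMatrix,
    regressor: str = "target",
) -> float:
    """Mean ROI time course, then OLS; returns the named regressor's beta."""
    if not bold.is_4d:
        raise ValueError("BOLD volume must be 4D")
    mask = np.asarray(roi_mask, dtype=bool)
    if mask.shape != bold.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match BOLD grid {bold.spatial_shape}"
        )
    if not mask.any():
        raise ValueError("ROI mask is empty")
    series = bold.data[mask].mean(axis=0)
    return fit_glm(series, design).betas[regressor]


def score_accuracy(
    paradigm: OddballParadigm,
    response_times_s,
    window_ms: float = 2000.0,
) -> float:
    """Percent of targets with at least one button press within the window."""
    if window_ms < 0:
        raise ValueError("window_ms must be non-negative")
    targets = paradigm.target_onsets_s
    if len(targets) == 0:
        raise ValueError("paradigm has no targets")
    responses = np.sort(np.asarray(response_times_s, dtype=float))
    w = window_ms / 1000.0
    hit = [
        bool(np.any((responses >= t) & (responses <= t + w))) for t in targets
    ]
    return 100.0 * sum(hit) / len(targets)
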