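"""Aggregate quantification from fluorescence micrographs.

The central readout is the per-pixel brightness standard deviation of a
micrograph: a uniform field (no aggregates) has an SD close to the camera
read noise, while bright puncta or filaments on that background raise the
SD in proportion to the amount of aggregate.  On top of that single-image
statistic this module builds replicate time-course summaries (mean +/-
SEM), Boltzmann-sigmoid kinetics fits (t50, lag), four-parameter-logistic
half-max dose-response fits (the EC50 analogue on the seed-fraction
axis), z-stack thickness maps, dotted/mesh morphology classification and
species activity ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import closing, disk, skeletonize

from .containers import Micrograph, ZStack

__all__ = [
    "TimeCourse", "DoseResponse", "SigmoidFit", "HalfMaxFit",
    "MorphologyReport", "MorphologyCutoffs",
    "sd_statistic", "summarize_timecourse", "fit_sigmoid", "fit_half_max",
    "thickness_profile", "classify_morphology", "rank_activity",
]


# --------------------------------------------------------------------------
# SD statistic

def sd_statistic(img) -> float:
    """Population standard deviation of pixel brightness.

    The raw grid is used: no background subtraction or flat-fielding.
    Color images are converted to grayscale by channel mean (handled by
    the :class:`Micrograph` container).  Population (divide-by-N) SD is
    used; on full frames the difference from sample SD is negligible but
    fixing it makes outputs bit-reproducible.
    """
    if isinstance(img, Micrograph):
        px = img.pixels
    else:
        px = np.asarray(img)
        if px.ndim == 3:
            px = px.astype(np.float64).mean(axis=-1)
    if px.size == 0:
        raise ValueError("empty image")
    px = px.astype(np.float64)
    if not np.all(np.isfinite(px)):
        raise ValueError("non-finite pixel values")
    return float(np.std(px, ddof=0))


# --------------------------------------------------------------------------
# Time course

@dataclass(frozen=True)
class TimeCoursePoint:
    time_h: float
    sd_mean: float
    sd_sem: float  # NaN when n_replicates == 1
    n_replicates: int


@dataclass(frozen=True)
class TimeCourse:
    """Replicate-summarised SD readout versus incubation time."""

    points: tuple[TimeCoursePoint, ...]

    def __post_init__(self) -> None:
        t = [p.time_h for p in self.points]
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("time points must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_h for p in self.points])

    @property
    def means(self) -> np.ndarray:
        return np.array([p.sd_mean for p in self.points])


def summarize_timecourse(images) -> TimeCourse:
    """Summarise per-replicate image SDs into a mean +/- SEM time course.

    `images` is an iterable of :class:`Micrograph` whose metadata carries
    ``time_h`` and ``replicate_id``.  For each time point the SD statistic
    of each replicate image is computed, and the replicate values are
    summarised as mean and SEM (sample SD over replicates / sqrt(n)).
    With a single replicate the SEM is reported as NaN.
    """
    by_time: dict[float, dict[int, list[float]]] = {}
    for img in images:
        t, r = img.meta.time_h, img.meta.replicate_id
        by_time.setdefault(t, {}).setdefault(r, []).append(sd_statistic(img))
    points = []
    for t in sorted(by_time):
        reps = np.array([np.mean(v) for _, v in sorted(by_time[t].items())])
        n = reps.size
        sem = float(np.std(reps, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        points.append(TimeCoursePoint(t, float(reps.mean()), sem, int(n)))
    if not points:
        raise ValueError("no images supplied")
    return TimeCourse(points=tuple(points))


# --------------------------------------------------------------------------
# Sigmoid kinetics fit

@dataclass(frozen=True)
class SigmoidFit:
    baseline: float
    plateau: float
    t50: float
    slope: float          # 1/hours
    lag_time: float       # hours, = max(0, t50 - 2/slope)
    rss: float
    extrapolated: bool    # t50 outside the observed time range


def _boltzmann(t, baseline, plateau, t50, slope):
    return baseline + (plateau - baseline) / (1.0 + np.exp(-slope * (t - t50)))


def fit_sigmoid(tc: TimeCourse) -> SigmoidFit:
    """Least-squares Boltzmann sigmoid fit of an SD time course.

    Multistart initialisation over a deterministic grid of (t50, slope)
    guesses; the best (lowest residual sum of squares) fit wins, with ties
    broken by grid order, so the result is deterministic given the data.
    The lag time is the conventional tangent construction
    ``t50 - 2/slope`` floored at zero.
    """
    t, y = tc.times, tc.means
    if t.size < 5:
        raise ValueError("need >= 5 time points to fit a sigmoid")
    span = float(y.max() - y.min())
    t_range = float(t.max() - t.min())
    if span <= 1e-12 * max(1.0, abs(float(y.mean()))):
        # flat series: plateau == baseline, t50 unidentifiable
        return SigmoidFit(float(y.mean()), float(y.mean()), float(t.max()) + t_range,
                          0.0, 0.0, float(((y - y.mean()) ** 2).sum()), True)

    best = None
    for t50_0 in np.quantile(t, [0.25, 0.5, 0.75]):
        for slope_0 in (0.5 / t_range, 2.0 / t_range, 10.0 / t_range, 0.1):
            p0 = [float(y.min()), float(y.max()), float(t50_0), float(slope_0)]
            try:
                popt, _ = curve_fit(_boltzmann, t, y, p0=p0, maxfev=20000)
            except RuntimeError:
                continue
            rss = float(((y - _boltzmann(t, *popt)) ** 2).sum())
            if best is None or rss < best[0] - 1e-15:
                best = (rss, popt)
    if best is None:
        raise RuntimeError("sigmoid fit failed to converge from all starts")
    rss, (baseline, plateau, t50, slope) = best
    if plateau < baseline:  # mirror-symmetric parameterisation; normalise
        baseline, plateau, slope = plateau, baseline, -slope
    lag = max(0.0, t50 - 2.0 / slope) if slope > 0 else 0.0
    extrapolated = not (t.min() <= t50 <= t.max())
    return SigmoidFit(float(baseline), float(plateau), float(t50),
                      float(slope), float(lag), rss, bool(extrapolated))


# --------------------------------------------------------------------------
# Half-max (EC50-analogue) dose-response fit

@dataclass(frozen=True)
class DoseResponse:
    """Endpoint SD per replicate at each seed (AEF) fraction."""

    fractions: tuple[float, ...]
    endpoint_sds: tuple[tuple[float, ...], ...]  # replicates per fraction

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.endpoint_sds):
            raise ValueError("fractions and endpoint_sds must align")
        if len(set(self.fractions)) != len(self.fractions):
            raise ValueError("fractions must be unique")
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class HalfMaxFit:
    bottom: float
    top: float
    half_max_fraction: float
    hill: float
    rss: float
    unidentifiable: bool


def _logistic4(x, bottom, top, half, hill):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x > 0, (half / np.maximum(x, 1e-300)) ** hill, np.inf)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_half_max(dr: DoseResponse) -> HalfMaxFit:
    """Four-parameter-logistic fit of endpoint SD versus seed fraction.

    Rising form (promotion): response climbs from `bottom` toward `top`
    with increasing fraction, reaching halfway at ``half_max_fraction``.
    Deterministic multistart least squares, as in :func:`fit_sigmoid`.
    A constant response is flagged unidentifiable.
    """
    if len(dr.fractions) < 4:
        raise ValueError("need >= 4 distinct fractions")
    x = np.repeat(dr.fractions, [len(r) for r in dr.endpoint_sds]).astype(float)
    y = np.concatenate([np.asarray(r, dtype=float) for r in dr.endpoint_sds])
    span = float(y.max() - y.min())
    if span <= 1e-12 * max(1.0, abs(float(y.mean()))):
        return HalfMaxFit(float(y.mean()), float(y.mean()), math.nan, math.nan,
                          float(((y - y.mean()) ** 2).sum()), True)

    pos = x[x > 0]
    best = None
    for half_0 in np.quantile(pos, [0.2, 0.5, 0.8]):
        for hill_0 in (0.5, 1.0, 2.0, 4.0):
            p0 = [float(y.min()), float(y.max()), float(half_0), hill_0]
            bounds = ([-np.inf, -np.inf, 1e-6, 1e-3], [np.inf, np.inf, 10.0, 50.0])
            try:
                popt, _ = curve_fit(_logistic4, x, y, p0=p0, bounds=bounds,
                                    maxfev=20000)
            except RuntimeError:
                continue
            rss = float(((y - _logistic4(x, *popt)) ** 2).sum())
            if best is None or rss < best[0] - 1e-15:
                best = (rss, popt)
    if best is None:
        raise RuntimeError("half-max fit failed to converge from all starts")
    rss, (bottom, top, half, hill) = best
    return HalfMaxFit(float(bottom), float(top), float(half), float(hill),
                      rss, False)


# --------------------------------------------------------------------------
# Thickness from z-stacks

def _robust_floor(values: np.ndarray, k: float = 5.0) -> float:
    """Background mean + k sigma, estimated from the dark end of the
    histogram (10th/40th percentiles of a Gaussian), so the estimate stays
    valid even when aggregates elevate most of the frame."""
    q10, q40 = np.quantile(values, [0.10, 0.40])
    sigma = max(float(q40 - q10) / 1.0283, 1e-12)
    mu = float(q40) + 0.2533 * sigma
    return mu + k * sigma


def thickness_profile(zs: ZStack) -> tuple[float, np.ndarray]:
    """Per-pixel aggregate thickness and its mean over the footprint.

    A global threshold (Otsu, floored at median + 5 robust SD so pure
    noise yields an empty footprint) marks aggregate voxels; the thickness
    at each xy position is the number of above-threshold slices times
    ``z_step`` (micrometers).  The scalar summary is the mean thickness
    over the above-threshold footprint; an all-background stack gives 0.
    """
    data = zs.slices.astype(np.float64)
    thr = max(float(threshold_otsu(data)), _robust_floor(data.ravel()))
    counts = (data > thr).sum(axis=0)
    thickness = counts * zs.z_step
    footprint = counts > 0
    mean_th = float(thickness[footprint].mean()) if footprint.any() else 0.0
    return mean_th, thickness


# --------------------------------------------------------------------------
# Morphology classification

@dataclass(frozen=True)
class MorphologyCutoffs:
    """Decision boundaries for the dotted/mesh classifier.

    "mesh" requires both a dominant connected component and a dense
    skeleton; the values are calibrated on the synthetic renderer at its
    default parameters.
    """

    min_largest_component_fraction: float = 0.5
    min_skeleton_length_per_area: float = 0.01


@dataclass(frozen=True)
class MorphologyReport:
    label: str                        # "dotted" | "mesh" | "none"
    n_components: int
    largest_component_fraction: float
    skeleton_length_per_area: float
    threshold_used: float


def classify_morphology(img, cutoffs: MorphologyCutoffs | None = None
                        ) -> MorphologyReport:
    """Classify an aggregate image as dotted-like or mesh-like.

    Otsu threshold (floored at a robust background bound) -> connected
    components (8-connectivity) -> descriptors.  "mesh" when the largest
    component holds at least ``min_largest_component_fraction`` of the
    foreground AND the skeleton length per image area exceeds
    ``min_skeleton_length_per_area``; otherwise "dotted".  With no
    above-threshold pixels the label is "none" and descriptors are zero.
    """
    cutoffs = cutoffs or MorphologyCutoffs()
    px = (img.pixels if isinstance(img, Micrograph) else np.asarray(img)
          ).astype(np.float64)
    thr = max(float(threshold_otsu(px)), _robust_floor(px.ravel()))
    fg = px > thr
    if not fg.any():
        return MorphologyReport("none", 0, 0.0, 0.0, thr)
    # bridge 1-2 px threshold dropouts along thin filaments
    fg = closing(fg, disk(2))
    labels, n_comp = label(fg, connectivity=2, return_num=True)
    sizes = np.bincount(labels.ravel())[1:]
    lcf = float(sizes.max() / sizes.sum())
    skel = skeletonize(fg)
    density = float(skel.sum() / px.size)
    is_mesh = (lcf >= cutoffs.min_largest_component_fraction
               and density >= cutoffs.min_skeleton_length_per_area)
    return MorphologyReport("mesh" if is_mesh else "dotted", int(n_comp),
                            lcf, density, thr)


# --------------------------------------------------------------------------
# Species activity ranking

def rank_activity(endpoint_sds: dict[str, list[float]]
                  ) -> list[tuple[str, float, bool]]:
    """Rank species by mean endpoint SD, descending.

    Returns (species, mean_sd, tied) triples.  Exact ties are broken
    lexicographically and flagged on every member of the tie.
    """
    if not endpoint_sds:
        raise ValueError("no species supplied")
    means = {sp: float(np.mean(v)) for sp, v in endpoint_sds.items()}
    ordered = sorted(means, key=lambda sp: (-means[sp], sp))
    tied_values = {v for v in means.values()
                   if sum(1 for w in means.values() if w == v) > 1}
    return [(sp, means[sp], means[sp] in tied_values) for sp in ordered]
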