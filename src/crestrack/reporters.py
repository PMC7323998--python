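"""Reporter-intensity statistics and expression classification.

Covers the image-side measurements around the photoconvertible
(green→red) and Wnt reporters: background subtraction, multiply
colocalization, the expression-recovery classification that separates the
early (silenced-before-conversion) from the late (still-transcribing)
neural-crest wave, positive-cell fractions, intensity/time profiles,
in-region counting and Welch's two-sample t test from group summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .circular import TestResult
from .geometry import Region

__all__ = [
    "GroupSummary",
    "IntensityProfile",
    "background_subtract",
    "colocalize",
    "classify_expression_state",
    "positive_fraction",
    "mad_threshold",
    "intensity_profile",
    "count_cells_in_region",
    "welch_t_test",
    "welch_from_samples",
    "format_mean_sd",
]


@dataclass(frozen=True)
class GroupSummary:
    """mean ± SD (n): SD is the sample standard deviation (n−1)."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        v = np.asarray(values, float)
        return cls(mean=float(v.mean()), sd=float(v.std(ddof=1)), n=len(v))


@dataclass
class IntensityProfile:
    t_hpf: np.ndarray
    mean_intensity: np.ndarray      # NaN where no cells were present
    n_cells: np.ndarray


def format_mean_sd(s: GroupSummary) -> str:
    return f"{s.mean:.1f} ± {s.sd:.1f} (n = {s.n})"


# ---------------------------------------------------------------------------
# image operations
# ---------------------------------------------------------------------------


def background_subtract(image: np.ndarray) -> np.ndarray:
    """Subtract the per-z-slice median and clip negatives to zero."""
    img = np.asarray(image, float)
    if img.ndim == 2:
        img = img[None]
        squeeze = True
    else:
        squeeze = False
    med = np.median(img.reshape(img.shape[0], -1), axis=1)
    out = np.clip(img - med[:, None, None], 0, None)
    return out[0] if squeeze else out


def colocalize(
    channel_a: np.ndarray,
    channel_b: np.ndarray,
    detections=None,
    radius_vox: int = 3,
):
    """Pixelwise product of background-subtracted channels.

    Mirrors the multiply-colocalization recipe: subtract background in each
    channel, then multiply.  The raw product image (float) is returned; the
    rescaling to a display bit depth is applied only when images are
    written out.  When detections are given, a per-cell score (mean product
    within a small neighbourhood of each detection voxel) is returned too.
    """
    a = np.asarray(channel_a, float)
    b = np.asarray(channel_b, float)
    if a.shape != b.shape:
        raise ValueError(f"channel shapes differ: {a.shape} vs {b.shape}")
    prod = background_subtract(a) * background_subtract(b)
    if detections is None:
        return prod
    scores = []
    r = radius_vox
    for det in detections:
        idx = np.asarray(det, float) if not hasattr(det, "position_um") else None
        if idx is None:
            raise ValueError("pass voxel indices (z, y, x) for per-cell scores")
        z, y, x = (int(round(v)) for v in idx)
        sl = tuple(
            slice(max(c - rr, 0), c + rr + 1)
            for c, rr in zip((z, y, x), (max(r // 2, 1), r, r))
        )
        scores.append(float(prod[sl].mean()))
    return prod, np.asarray(scores)


# ---------------------------------------------------------------------------
# expression classification and fractions
# ---------------------------------------------------------------------------


def classify_expression_state(
    pool_green: float,
    pool_red: float,
    ratio_threshold: float = 0.1,
) -> str:
    """Classify a photoconverted cell as 'active' or 'silenced'.

    After conversion the red pool is inherited by every cell that existed
    at conversion time; green re-accumulates only under an active promoter.
    A cell is 'active' when G/(G+R) > ratio_threshold at evaluation time.
    Zero total fluorescence is 'unclassifiable'.
    """
    total = pool_green + pool_red
    if total <= 0:
        return "unclassifiable"
    return "active" if pool_green / total > ratio_threshold else "silenced"


def classify_truth_expression(
    truth, t_eval_hpf: float, ratio_threshold: float = 0.1
) -> dict[int, str]:
    """Expression state of every cell alive at t_eval in a converted truth."""
    if not truth.conversions:
        raise ValueError("truth has no photoconversion event")
    if t_eval_hpf <= max(truth.conversions):
        raise ValueError("t_eval must lie after the conversion")
    f = truth.frame_of_time(t_eval_hpf)
    out = {}
    for c in truth.cells:
        if c.alive_at(f):
            j = f - c.birth_frame
            out[c.cell_id] = classify_expression_state(
                float(c.pool_green[j]), float(c.pool_red[j]), ratio_threshold
            )
    return out


def positive_fraction(values, threshold: float):
    """Fraction of values above a threshold, with 'a/n' counts alongside."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("positive_fraction needs at least one value")
    a = int((v > threshold).sum())
    n = int(v.size)
    return a / n, a, n


def mad_threshold(values, k: float = 3.0) -> float:
    """Robust positivity threshold: median + k · 1.4826 · MAD."""
    v = np.asarray(values, float)
    med = np.median(v)
    return float(med + k * 1.4826 * np.median(np.abs(v - med)))


def intensity_profile(truth, channel: str = "wnt", sox10_only: bool = True) -> IntensityProfile:
    """Mean per-cell reporter intensity over time across the population.

    Computed from the tracked per-cell intensity series (no smoothing);
    timepoints with no alive cells carry NaN and n = 0.
    """
    attr = {
        "wnt": "wnt_intensity",
        "green": "pool_green",
        "red": "pool_red",
    }[channel]
    times = truth.frame_times
    total = np.zeros(len(times))
    n = np.zeros(len(times), dtype=int)
    for c in truth.cells:
        series = getattr(c, attr)
        sl = slice(c.birth_frame, c.end_frame + 1)
        total[sl] += series
        n[sl] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, total / np.maximum(n, 1), np.nan)
    return IntensityProfile(t_hpf=times, mean_intensity=mean, n_cells=n)


def count_cells_in_region(positions, region: Region) -> int:
    """Number of detections (one timepoint) satisfying a region predicate."""
    pts = np.atleast_2d(np.asarray(positions, float))
    if pts.size == 0:
        return 0
    return int(region(pts).sum())


# ---------------------------------------------------------------------------
# Welch's t test
# ---------------------------------------------------------------------------


def welch_t_test(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Welch's two-sample t test from group summaries.

    t = (m_a − m_b) / sqrt(s_a²/n_a + s_b²/n_b) with Welch–Satterthwaite
    degrees of freedom and a two-sided p from the t distribution.
    """
    va = a.sd**2 / a.n
    vb = b.sd**2 / b.n
    se2 = va + vb
    if se2 == 0:
        return TestResult(
            statistic=0.0, p_value=1.0, method="welch", df=float(a.n + b.n - 2),
            n=(a.n, b.n), degenerate=True,
        )
    t = (a.mean - b.mean) / np.sqrt(se2)
    df = se2**2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(
        statistic=float(t), p_value=float(min(p, 1.0)), method="welch",
        df=float(df), n=(a.n, b.n),
    )


def welch_from_samples(values_a, values_b) -> TestResult:
    return welch_t_test(
        GroupSummary.from_values(values_a), GroupSummary.from_values(values_b)
    )
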