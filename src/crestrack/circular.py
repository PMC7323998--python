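"""Circular migration statistics: stride-sampled angles, rose histograms,
circular median and the Wallraff test of angular dispersion.

Angle convention (documented prominently because medians depend on it):
displacements are projected onto the anteroposterior–mediolateral plane
(the dorsal-view plane); 0° is the anterior direction and angles increase
towards the tracked eye's distal (lateral) side, mapped to [0, 360).

The Wallraff test compares angular *dispersions*: each observation is
replaced by its circular distance to its own group's circular median, and
the two groups of distances are compared by a two-sided Mann–Whitney rank
test (midranks; exact enumeration of all rank splits for small samples,
tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "AngleSample",
    "AngleHistogram",
    "TestResult",
    "sample_displacement_angles",
    "pool_angle_samples",
    "angle_histogram",
    "circular_median",
    "circular_distance_deg",
    "wallraff_test",
    "center_tracks",
]

EXACT_MAX_N = 12


@dataclass
class TestResult:
    """Statistic / df / p contract shared by the rank and Welch tests."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    n: tuple[int, ...] = ()
    degenerate: bool = False

    def formatted_p(self, floor: float = 2.2e-16) -> str:
        if self.p_value < floor:
            return f"p < {floor:g}"
        return f"p = {self.p_value:.3g}"


@dataclass
class AngleSample:
    group: str
    angles_deg: np.ndarray                 # in [0, 360)
    cell_ids: np.ndarray | None = None     # parallel track ids for auditing

    def __post_init__(self) -> None:
        a = np.asarray(self.angles_deg, float) % 360.0
        object.__setattr__(self, "angles_deg", a)
        if self.cell_ids is not None:
            ids = np.asarray(self.cell_ids)
            if len(ids) != len(a):
                raise ValueError("cell_ids must parallel angles")

    @property
    def n(self) -> int:
        return len(self.angles_deg)


@dataclass
class AngleHistogram:
    bin_width_deg: float
    counts: np.ndarray
    median_deg: float | None            # None for an empty sample

    @property
    def bin_edges_deg(self) -> np.ndarray:
        return np.arange(0.0, 360.0 + self.bin_width_deg, self.bin_width_deg)


def circular_distance_deg(a, b) -> np.ndarray:
    """Shortest arc between angles in degrees: min(|a−b|, 360−|a−b|)."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % 360.0
    return np.minimum(d, 360.0 - d)


def displacement_angles_deg(
    positions: np.ndarray,
    stride_frames: int,
    min_step_um: float = 0.5,
    axis_ap: np.ndarray = (1.0, 0.0, 0.0),
    axis_distal: np.ndarray = (0.0, 1.0, 0.0),
) -> np.ndarray:
    """Angles of stride-sampled planar displacements for one track.

    Steps start at frames 0, stride, 2·stride, …; a step shorter than
    ``min_step_um`` in the plane is dropped (stationary-cell noise).
    """
    if stride_frames < 1:
        raise ValueError("stride_frames must be >= 1")
    pos = np.atleast_2d(np.asarray(positions, float))
    n = len(pos)
    if n <= stride_frames:
        return np.empty(0)
    starts = np.arange(0, n - stride_frames, stride_frames)
    delta = pos[starts + stride_frames] - pos[starts]
    e_ap = np.asarray(axis_ap, float)
    e_d = np.asarray(axis_distal, float)
    x = delta @ e_ap
    y = delta @ e_d
    norm = np.hypot(x, y)
    keep = norm >= min_step_um
    return np.degrees(np.arctan2(y[keep], x[keep])) % 360.0


def sample_displacement_angles(
    tracks,
    stride_frames: int,
    min_step_um: float = 0.5,
    group: str = "",
    axis_ap=(1.0, 0.0, 0.0),
    axis_distal=(0.0, 1.0, 0.0),
) -> AngleSample:
    """Pool stride-sampled angles over a set of tracks.

    ``tracks`` is a mapping track-id → (n, 3) position array (or a single
    array, treated as one anonymous track).  Per-angle track ids are kept so
    per-cell aggregations can be audited later.
    """
    if isinstance(tracks, np.ndarray):
        tracks = {0: tracks}
    angles, ids = [], []
    for tid in sorted(tracks):
        a = displacement_angles_deg(
            tracks[tid], stride_frames, min_step_um, axis_ap, axis_distal
        )
        angles.append(a)
        ids.append(np.full(len(a), tid))
    if angles:
        angles = np.concatenate(angles)
        ids = np.concatenate(ids)
    else:
        angles = np.empty(0)
        ids = np.empty(0, dtype=int)
    return AngleSample(group=group, angles_deg=angles, cell_ids=ids)


def pool_angle_samples(samples, group: str = "") -> AngleSample:
    angles = np.concatenate([s.angles_deg for s in samples]) if samples else np.empty(0)
    return AngleSample(group=group, angles_deg=angles)


def circular_median(angles_deg) -> float:
    """Data angle minimizing the summed circular distance to the sample.

    Ties are resolved to the smallest such angle.  Raises on empty input.
    """
    a = np.asarray(angles_deg, float) % 360.0
    if a.size == 0:
        raise ValueError("circular median of an empty sample")
    cands = np.unique(a)
    sums = circular_distance_deg(cands[:, None], a[None, :]).sum(axis=1)
    best = sums.min()
    return float(cands[np.flatnonzero(np.isclose(sums, best, rtol=0, atol=1e-9))[0]])


def angle_histogram(sample: AngleSample, bin_width_deg: float = 10.0) -> AngleHistogram:
    """Half-open binning [k·w, (k+1)·w) of an angle sample plus its median."""
    if 360.0 % bin_width_deg != 0:
        raise ValueError("bin width must divide 360")
    nbins = int(360.0 // bin_width_deg)
    idx = np.floor(sample.angles_deg / bin_width_deg).astype(int) % nbins
    counts = np.bincount(idx, minlength=nbins)
    med = circular_median(sample.angles_deg) if sample.n else None
    return AngleHistogram(bin_width_deg=bin_width_deg, counts=counts, median_deg=med)


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_ranksum_p(ranks: np.ndarray, n_a: int) -> float:
    """Two-sided p of the observed group-A rank sum under exhaustive
    enumeration of all C(n, n_a) assignments of the pooled midranks."""
    n = len(ranks)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    dev = abs(w_obs - mu) - 1e-9
    count = 0
    for idx in combinations(range(n), n_a):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev:
            count += 1
    return count / comb(n, n_a)


def wallraff_test(group_a: AngleSample, group_b: AngleSample) -> TestResult:
    """Wallraff test of angular distance (dispersion) between two groups.

    Distances of each observation to its *own* group's circular median are
    compared by a two-sided Mann–Whitney test.  Exact enumeration is used
    when n_A + n_B <= 12, otherwise the tie-corrected normal approximation.
    """
    if group_a.n < 2 or group_b.n < 2:
        raise ValueError("each group needs at least 2 angles")
    da = circular_distance_deg(group_a.angles_deg, circular_median(group_a.angles_deg))
    db = circular_distance_deg(group_b.angles_deg, circular_median(group_b.angles_deg))
    na, nb = len(da), len(db)
    pooled = np.concatenate([da, db])
    ranks = _midranks(pooled)
    w_a = ranks[:na].sum()
    u_a = w_a - na * (na + 1) / 2.0

    if np.ptp(pooled) == 0:
        return TestResult(
            statistic=float(u_a), p_value=1.0, method="wallraff-exact",
            n=(na, nb), degenerate=True,
        )
    if na + nb <= EXACT_MAX_N:
        p = _exact_ranksum_p(ranks, na)
        method = "wallraff-exact"
    else:
        res = sps.mannwhitneyu(
            da, db, alternative="two-sided", method="asymptotic"
        )
        p = float(res.pvalue)
        method = "wallraff-asymptotic"
    return TestResult(
        statistic=float(u_a), p_value=min(float(p), 1.0), method=method, n=(na, nb)
    )


def center_tracks(tracks: dict, frame0: int):
    """Subtract each track's position at ``frame0`` from its later positions.

    ``tracks`` maps id → (start_frame, (n, 3) positions).  Tracks absent at
    ``frame0`` are skipped; the skip count is returned alongside.
    Returns (dict id → centered positions from frame0 on, n_skipped).
    """
    out = {}
    skipped = 0
    for tid in sorted(tracks):
        start, pos = tracks[tid]
        pos = np.atleast_2d(np.asarray(pos, float))
        end = start + len(pos) - 1
        if not start <= frame0 <= end:
            skipped += 1
            continue
        k = frame0 - start
        out[tid] = pos[k:] - pos[k]
    return out, skipped
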