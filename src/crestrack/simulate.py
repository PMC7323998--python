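"""Ground-truth simulator for the two ocular neural-crest waves.

The simulator produces per-cell trajectories with divisions, reporter pools
and genotype-dependent behaviour on a fixed frame grid:

* the early wave (``1NC``) delaminates from the lateral stripe at 12–14 hpf,
  migrates onto the proximal hemisphere of the eye and crawls towards the
  equator, where a reflecting boundary halts it (wildtype);
* the late wave (``2NC``) appears mediodorsally at 16–17 hpf, is attracted
  to a periocular cluster point near the dorsal eye rim during 18–22 hpf,
  and at cluster dissolution up to ``n_entering_2nc`` cells are designated
  to enter: they migrate over the dorsal rim onto the distal hemisphere and
  settle there (wildtype);
* under ``pax6b_null`` and ``pax6_double_null`` the cluster never dissolves
  (cells stay periocular); ``pax6_double_null`` additionally sends the early
  wave across the equator deep into the distal half.

Motion is a per-frame guidance drift plus isotropic Gaussian jitter; the
cluster phase is a mean-reverting attraction.  Divisions are a per-cell
Poisson process; daughters appear one frame after the parent's last frame,
displaced symmetrically.  With probability ``mixing_fraction`` a lineage is
programmed mixed-destination: at its first division after destination
assignment one daughter subtree adopts the opposite eye compartment (a
mixed lineage that would never divide is forced to divide once, since a
mixed-destination program is unobservable without at least two branches).

Reporter pools follow promoter-gated synthesis with first-order decay,
``dG/dt = k_syn·a(t) − k_deg·G`` and ``dR/dt = −k_deg·R``; photoconversion
moves the whole green pool to red instantaneously.  The promoter hard-off
times are 16 hpf (1NC) and 20 hpf (2NC).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .config import SimulationConfig
from .geometry import EmbryoModel, default_embryo_model

__all__ = [
    "CellRecord",
    "GroundTruth",
    "build_embryo_model",
    "simulate_populations",
    "apply_photoconversion",
]

POP_1NC = "1NC"
POP_2NC = "2NC"

# destination programs
PROX, DIST, PERI, PENDING = 0, 1, 2, 3
PROGRAM_NAMES = {PROX: "proximal", DIST: "distal", PERI: "periocular", PENDING: "none"}

# route stages
ST_APPROACH_SHELL = 0   # 1NC: towards proximal eye surface
ST_CRAWL = 1            # 1NC: on-surface crawl towards the equator
ST_TO_CLUSTER = 2       # 2NC: towards the periocular cluster point
ST_CLUSTER = 3          # 2NC: mean-reverting cluster phase
ST_TO_RIM = 4           # 2NC: over the dorsal rim
ST_TO_TARGET = 5        # towards a settling point on the eye surface
ST_SETTLED = 6          # spring to the settling point

_DAUGHTER_EPS_UM = 3.5


@dataclass
class CellRecord:
    """One tracked cell segment of the ground truth."""

    cell_id: int
    parent_id: int | None
    lineage_id: int
    population: str
    birth_frame: int
    end_frame: int
    birth_hpf: float
    end_hpf: float
    positions: np.ndarray                 # (n_frames_alive, 3) μm
    destination_truth: str                # proximal / distal / periocular / none
    wnt_positive: bool
    pool_green: np.ndarray = field(default=None, repr=False)
    pool_red: np.ndarray = field(default=None, repr=False)
    wnt_intensity: np.ndarray = field(default=None, repr=False)
    promoter_state: np.ndarray = field(default=None, repr=False)   # bool

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.birth_frame + 1

    def position_at(self, frame: int) -> np.ndarray:
        if not self.birth_frame <= frame <= self.end_frame:
            raise IndexError(f"cell {self.cell_id} not alive at frame {frame}")
        return self.positions[frame - self.birth_frame]

    def alive_at(self, frame: int) -> bool:
        return self.birth_frame <= frame <= self.end_frame


@dataclass
class GroundTruth:
    """Simulated embryo: geometry, cells and the config that produced them."""

    model: EmbryoModel
    cells: list[CellRecord]
    config: SimulationConfig
    conversions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        by_id = {c.cell_id: c for c in self.cells}
        for c in self.cells:
            if c.parent_id is not None and c.parent_id not in by_id:
                raise ValueError(f"dangling parent_id {c.parent_id}")
        self._by_id = by_id

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: int) -> CellRecord:
        return self._by_id[cell_id]

    @property
    def frame_times(self) -> np.ndarray:
        return self.config.frame_times()

    def founders(self) -> list[CellRecord]:
        return [c for c in self.cells if c.parent_id is None]

    def children_of(self, cell_id: int) -> list[CellRecord]:
        return [c for c in self.cells if c.parent_id == cell_id]

    def terminal_cells(self) -> list[CellRecord]:
        has_child = {c.parent_id for c in self.cells if c.parent_id is not None}
        return [c for c in self.cells if c.cell_id not in has_child]

    def n_divisions(self) -> int:
        return sum(1 for c in self.cells if c.parent_id is not None) // 2

    def frame_of_time(self, t_hpf: float) -> int:
        cfg = self.config
        f = int(round((t_hpf - cfg.t_start_hpf) / cfg.dt_h))
        if not 0 <= f < cfg.n_frames:
            raise ValueError(f"t = {t_hpf} hpf outside simulated window")
        return f

    def detections_at(self, frame: int) -> tuple[np.ndarray, np.ndarray]:
        """(cell_ids, positions) of all cells alive at a frame."""
        ids, pos = [], []
        for c in self.cells:
            if c.alive_at(frame):
                ids.append(c.cell_id)
                pos.append(c.position_at(frame))
        if not ids:
            return np.empty(0, dtype=int), np.empty((0, 3))
        return np.asarray(ids), np.asarray(pos)


def build_embryo_model(config: SimulationConfig) -> EmbryoModel:
    """Embryo geometry for a simulation config (eye radius, body side)."""
    config.validate()
    return default_embryo_model(
        eye_radius=config.eye_radius_um, mirrored=config.mirrored
    )


# ---------------------------------------------------------------------------
# simulation core
# ---------------------------------------------------------------------------


def _unit_rows(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    n[n == 0] = 1.0
    return v / n


class _State:
    """Growable per-cell arrays for the frame-major simulation loop."""

    def __init__(self, n_frames: int, capacity: int) -> None:
        self.n_frames = n_frames
        self.traj = np.full((capacity, n_frames, 3), np.nan)
        self.pos = np.zeros((capacity, 3))
        self.alive = np.zeros(capacity, dtype=bool)
        self.pop = np.zeros(capacity, dtype=np.int8)        # 0 = 1NC, 1 = 2NC
        self.program = np.full(capacity, PENDING, dtype=np.int8)
        self.stage = np.zeros(capacity, dtype=np.int8)
        self.attract = np.zeros((capacity, 3))
        self.parent = np.full(capacity, -1, dtype=int)
        self.lineage = np.full(capacity, -1, dtype=int)
        self.birth_frame = np.zeros(capacity, dtype=int)
        self.end_frame = np.full(capacity, -1, dtype=int)
        self.mix_pending = np.zeros(capacity, dtype=bool)
        self.force_frame = np.full(capacity, -1, dtype=int)
        self.no_div = np.zeros(capacity, dtype=bool)
        self.wnt_pos = np.zeros(capacity, dtype=bool)
        self.n = 0

    def _grow(self, need: int) -> None:
        cap = len(self.alive)
        if self.n + need <= cap:
            return
        new = max(cap * 2, self.n + need)
        for name in (
            "pos", "alive", "pop", "program", "stage", "attract", "parent",
            "lineage", "birth_frame", "end_frame", "mix_pending",
            "force_frame", "no_div", "wnt_pos",
        ):
            arr = getattr(self, name)
            shape = (new,) + arr.shape[1:]
            out = np.zeros(shape, dtype=arr.dtype)
            if name in ("parent", "lineage", "end_frame", "force_frame"):
                out[:] = -1
            if name == "program":
                out[:] = PENDING
            out[: self.n] = arr[: self.n]
            setattr(self, name, out)
        t = np.full((new, self.n_frames, 3), np.nan)
        t[: self.n] = self.traj[: self.n]
        self.traj = t

    def add(self, **kw) -> int:
        self._grow(1)
        i = self.n
        self.n += 1
        for k, v in kw.items():
            getattr(self, k)[i] = v
        return i


def simulate_populations(
    model: EmbryoModel, config: SimulationConfig
) -> GroundTruth:
    """Simulate both neural-crest waves and return the ground truth.

    Deterministic given ``config.seed``.  Reporter pools are integrated for
    the no-photoconversion history; apply_photoconversion re-integrates
    them with a conversion event.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nF = config.n_frames
    times = config.frame_times()
    dt_h = config.dt_h
    dt_min = config.dt_s / 60.0
    R = model.eye_radius
    c = model.eye_center
    u = model.u
    ap = model.axis_ap
    dv = model.axis_dv
    genotype = config.genotype

    if config.n_1nc == 0 and config.n_2nc == 0:
        warnings.warn("both populations empty: returning empty GroundTruth")
        return _finalize(_State(nF, 1), model, config, times)

    st = _State(nF, capacity=4 * (config.n_1nc + config.n_2nc) + 8)

    # -- founders ---------------------------------------------------------
    def _founder_batch(n, window, zone, pop_code):
        if n == 0:
            return
        t_birth = rng.uniform(window[0], window[1], size=n)
        frames = np.clip(
            np.round((t_birth - config.t_start_hpf) / dt_h).astype(int), 0, nF - 2
        )
        starts = zone.sample(rng, n)
        for k in range(n):
            i = st.add(
                pos=starts[k],
                pop=pop_code,
                birth_frame=frames[k],
                parent=-1,
            )
            st.lineage[i] = i
            if pop_code == 0:
                # early wave: destination program known at birth
                st.program[i] = DIST if genotype == "pax6_double_null" else PROX
                st.stage[i] = ST_APPROACH_SHELL
            else:
                st.program[i] = PENDING
                st.stage[i] = ST_TO_CLUSTER
            st.wnt_pos[i] = (
                pop_code == 1 and rng.random() < config.wnt_wave2_fraction
            )

    _founder_batch(config.n_1nc, config.delamination_window_1nc, model.origin_zone_1nc, 0)
    _founder_batch(config.n_2nc, config.delamination_window_2nc, model.origin_zone_2nc, 1)

    # mixed-destination lineages (1NC programs exist from birth)
    for i in range(st.n):
        if st.pop[i] == 0 and rng.random() < config.mixing_fraction:
            st.mix_pending[i] = True
            st.force_frame[i] = _forced_frame(rng, config, times[st.birth_frame[i]])
    # 2NC mixing flags drawn now (seed stability) but armed at designation
    mix_2nc = {i: rng.random() < config.mixing_fraction
               for i in range(st.n) if st.pop[i] == 1}

    entry_start_frame = int(round((config.entry_window[0] - config.t_start_hpf) / dt_h))
    speed1 = config.speed_um_per_min[POP_1NC] * dt_min
    speed2 = config.speed_um_per_min[POP_2NC] * dt_min
    # diffusive jitter: noise_sigma_um is the per-axis sd over one minute
    sigma = config.noise_sigma_um * math.sqrt(dt_min)
    p_div = config.division_rate_per_h * dt_h
    kappa = min(0.4, 0.5 * dt_min)            # cluster mean reversion / frame
    k_rad = min(1.0, 0.9 * dt_min)            # radial spring to eye surface

    designated = False
    settle_taken: list = []

    for f in range(nF):
        # births scheduled for this frame
        newborn = (st.birth_frame[: st.n] == f) & (st.end_frame[: st.n] == -1)
        st.alive[: st.n][newborn] = True

        # --- 2NC cluster dissolution: destination designation ------------
        if not designated and f >= entry_start_frame:
            designated = True
            idx = [i for i in range(st.n)
                   if st.alive[i] and st.pop[i] == 1 and st.program[i] == PENDING]
            idx.sort()
            if genotype == "wildtype":
                enter = idx[: config.n_entering_2nc]
                stay = idx[config.n_entering_2nc:]
            else:
                enter, stay = [], idx
            for i in enter:
                st.program[i] = DIST
                st.stage[i] = ST_TO_RIM
                st.attract[i] = _rim_point(rng, model)
                if mix_2nc.get(st.lineage[i], False) and not _lineage_armed(st, i):
                    st.mix_pending[i] = True
                    st.force_frame[i] = _forced_frame(rng, config, times[f])
            for i in stay:
                st.program[i] = PERI
                st.stage[i] = ST_CLUSTER

        a = st.alive[: st.n]
        n_alive = int(a.sum())
        if n_alive:
            ids = np.flatnonzero(a)
            P = st.pos[ids]
            rel = P - c
            dist = np.linalg.norm(rel, axis=1)
            nhat = _unit_rows(rel)
            pd = rel @ u
            drift = np.zeros_like(P)
            stg = st.stage[ids]
            prg = st.program[ids]
            pop = st.pop[ids]
            spd = np.where(pop == 0, speed1, speed2)

            # approach the proximal eye surface (1NC)
            m = stg == ST_APPROACH_SHELL
            if m.any():
                target = c + R * nhat[m]
                drift[m] = _unit_rows(target - P[m]) * spd[m, None]
                arrived = np.abs(dist[m] - R) < 3.0
                st.stage[ids[m]] = np.where(arrived, ST_CRAWL, ST_APPROACH_SHELL)

            # on-surface crawl towards (and past, if distal-programmed) equator
            m = stg == ST_CRAWL
            if m.any():
                d = 1.0 * ap + 0.8 * u
                d_t = d - (nhat[m] @ d)[:, None] * nhat[m]
                d_t = _unit_rows(d_t)
                halt = np.where(
                    prg[m] == DIST,
                    np.clip((0.55 * R - pd[m]) / (0.10 * R), 0.0, 1.0),
                    np.clip(-pd[m] / (0.30 * R), 0.0, 1.0),
                )
                radial = k_rad * (R - dist[m])[:, None] * nhat[m]
                drift[m] = d_t * (halt * spd[m])[:, None] + radial
                # contact inhibition: anchor at the halt band or on touching
                # an already-anchored neighbour (monolayer crystallizes)
                band = np.where(prg[m] == DIST, pd[m] > 0.50 * R, pd[m] > -0.08 * R)
                anchored_sel = (
                    st.alive[: st.n]
                    & (st.stage[: st.n] == ST_SETTLED)
                    & (st.pop[: st.n] == 0)
                )
                if anchored_sel.any():
                    from scipy.spatial import cKDTree

                    tree = cKDTree(st.pos[: st.n][anchored_sel])
                    # freeze before entering the exclusion zone of an
                    # anchored neighbour (no perpetual spring/repulsion fight)
                    near = tree.query(P[m], k=1)[0] < 8.5
                    band = band | near
                sub = ids[m]
                rows = np.flatnonzero(m)
                for j in np.flatnonzero(band):
                    i = sub[j]
                    st.stage[i] = ST_SETTLED
                    st.attract[i] = P[rows[j]]

            # towards / inside the periocular cluster (2NC)
            m = (stg == ST_TO_CLUSTER) | (stg == ST_CLUSTER)
            if m.any():
                to_cc = model.cluster_center - P[m]
                d_cc = np.linalg.norm(to_cc, axis=1)
                appr = stg[m] == ST_TO_CLUSTER
                step = np.where(appr, spd[m], 0.0)[:, None] * _unit_rows(to_cc)
                ou = np.where(appr, 0.0, kappa)[:, None] * to_cc
                drift[m] = step + ou
                newly = appr & (d_cc < 8.0)
                sub = ids[m]
                st.stage[sub[newly]] = ST_CLUSTER

            # over the dorsal rim (2NC entering)
            m = stg == ST_TO_RIM
            if m.any():
                target = st.attract[ids[m]]
                gap = np.linalg.norm(target - P[m], axis=1)
                drift[m] = _unit_rows(target - P[m]) * spd[m, None]
                over = (gap < 5.0) | (pd[m] > 0.25 * R)
                sub = ids[m]
                for j in np.flatnonzero(over):
                    i = sub[j]
                    st.stage[i] = ST_TO_TARGET
                    st.attract[i] = _settle_point(rng, model, DIST, settle_taken)

            # towards the settling point on the eye surface; near the shell
            # the route bends tangentially around the sphere rather than
            # cutting through the eye interior
            m = stg == ST_TO_TARGET
            if m.any():
                target = st.attract[ids[m]]
                to_t = target - P[m]
                gap = np.linalg.norm(to_t, axis=1)
                near = np.abs(dist[m] - R) < 10.0
                tang = to_t - (np.sum(to_t * nhat[m], axis=1))[:, None] * nhat[m]
                radial = k_rad * (R - dist[m])[:, None] * nhat[m]
                step_near = _unit_rows(tang) * spd[m, None] + radial
                step_far = _unit_rows(to_t) * spd[m, None]
                drift[m] = np.where(near[:, None], step_near, step_far)
                st.stage[ids[m]] = np.where(gap < 3.0, ST_SETTLED, ST_TO_TARGET)

            # settled: spring to the settling point
            m = stg == ST_SETTLED
            if m.any():
                drift[m] += kappa * (st.attract[ids[m]] - P[m])

            # mitotic pause: freshly born cells re-spread before migrating
            young = (f - st.birth_frame[ids]) <= 1
            drift[young] = 0.0

            # epithelialized (settled/clustered) cells jiggle less than
            # migrating mesenchymal cells
            jit = np.where(
                np.isin(st.stage[ids], (ST_SETTLED, ST_CLUSTER)), 0.25 * sigma, sigma
            )
            P = P + drift + rng.normal(0.0, 1.0, size=P.shape) * jit[:, None]
            # nuclear exclusion at roughly one nucleus diameter
            for _ in range(2):
                P += _repulsion(P, radius=8.0, strength=min(0.5, 0.25 * dt_min))

            # hard schedule boundaries (reflecting clamps)
            rel = P - c
            pd = rel @ u
            # wildtype early wave never crosses the equator
            m = (
                (pop == 0)
                & (prg == PROX)
                & np.isin(st.stage[ids], (ST_CRAWL, ST_SETTLED))
            )
            over = m & (pd > -1.0)
            if over.any():
                P[over] -= (pd[over] + 1.0)[:, None] * u
            # 2NC stay outside the eye shell until they are sent in
            m2 = (pop == 1) & np.isin(st.stage[ids], (ST_TO_CLUSTER, ST_CLUSTER))
            if m2.any():
                rel2 = P[m2] - c
                d2 = np.linalg.norm(rel2, axis=1)
                lim = R + 7.0
                low = d2 < lim
                if low.any():
                    scale = lim / d2[low]
                    P[m2.nonzero()[0][low]] = c + rel2[low] * scale[:, None]

            st.pos[ids] = P
            st.traj[ids, f] = P

            # --- divisions ------------------------------------------------
            if f < nF - 1:
                div_draw = (rng.random(n_alive) < p_div) & ~st.no_div[ids]
                forced = st.force_frame[ids] == f
                dividing = np.flatnonzero(div_draw | forced)
                for j in dividing:
                    i = ids[j]
                    if st.birth_frame[i] == f:
                        if st.force_frame[i] == f:
                            st.force_frame[i] = f + 1
                        continue      # no zero-length segments
                    _divide(st, rng, i, f, times, config, model, settle_taken)

        # end of frame

    # close all still-alive cells at the final frame
    for i in range(st.n):
        if st.alive[i]:
            st.end_frame[i] = nF - 1

    return _finalize(st, model, config, times)


def _repulsion(P: np.ndarray, radius: float, strength: float) -> np.ndarray:
    """Soft pairwise exclusion: nuclei closer than ``radius`` push apart.

    Keeps settled populations at monolayer-like spacing instead of
    collapsing onto shared guidance attractors.
    """
    out = np.zeros_like(P)
    if len(P) < 2 or strength <= 0:
        return out
    from scipy.spatial import cKDTree

    tree = cKDTree(P)
    for i, j in tree.query_pairs(radius):
        d = P[i] - P[j]
        dist = np.linalg.norm(d)
        if dist < 1e-9:
            d = np.array([1.0, 0.0, 0.0])
            dist = 1e-9
        push = strength * (radius - dist) * d / dist
        out[i] += 0.5 * push
        out[j] -= 0.5 * push
    return out


def _lineage_armed(st: _State, i: int) -> bool:
    lin = st.lineage[i]
    return bool(np.any(st.mix_pending[: st.n] & (st.lineage[: st.n] == lin)))


def _forced_frame(rng: np.random.Generator, config: SimulationConfig, t_now: float) -> int:
    """Frame of the guaranteed division of a mixed lineage: well before t_end."""
    lo = t_now + 1.0
    hi = config.t_end_hpf - 3.0
    if hi <= lo:
        hi = lo + 0.5
    t = rng.uniform(lo, min(hi, config.t_end_hpf - config.dt_h))
    f = int(round((t - config.t_start_hpf) / config.dt_h))
    return min(max(f, 1), config.n_frames - 2)


def _rim_point(rng: np.random.Generator, model: EmbryoModel) -> np.ndarray:
    d = 0.15 * model.axis_ap + 0.35 * model.u + 0.93 * model.axis_dv
    d = d + rng.normal(0.0, 0.10, size=3)
    d /= np.linalg.norm(d)
    return model.eye_center + (model.eye_radius + 2.0) * d


def _settle_point(
    rng: np.random.Generator,
    model: EmbryoModel,
    program: int,
    taken: list | None = None,
    min_sep_um: float = 8.0,
) -> np.ndarray:
    """Random point on the target hemisphere of the eye surface.

    Settle points are kept at least ``min_sep_um`` apart (one nucleus
    diameter) so settled cells form a spaced monolayer, not a pile.
    """
    s = 1.0 if program == DIST else -1.0
    best, best_d = None, -1.0
    for _ in range(50):
        tangent = rng.normal(0.0, 1.0, size=3)
        tangent -= (tangent @ model.u) * model.u
        tangent /= max(np.linalg.norm(tangent), 1e-12)
        d = s * model.u + 0.45 * tangent
        d /= np.linalg.norm(d)
        p = model.eye_center + model.eye_radius * d
        if not taken:
            best = p
            break
        gap = min(np.linalg.norm(p - q) for q in taken)
        if gap >= min_sep_um:
            best = p
            break
        if gap > best_d:
            best, best_d = p, gap
    if taken is not None:
        taken.append(best)
    return best


def _divide(
    st: _State,
    rng: np.random.Generator,
    i: int,
    f: int,
    times: np.ndarray,
    config: SimulationConfig,
    model: EmbryoModel,
    settle_taken: list | None = None,
) -> None:
    st.alive[i] = False
    st.end_frame[i] = f
    eps = rng.normal(0.0, 1.0, size=3)
    eps /= max(np.linalg.norm(eps), 1e-12)
    offsets = (_DAUGHTER_EPS_UM * eps, -_DAUGHTER_EPS_UM * eps)

    diverge = (
        st.mix_pending[i]
        and st.program[i] in (PROX, DIST)
        and times[f] < config.t_end_hpf - 2.5
    )
    for k, off in enumerate(offsets):
        j = st.add(
            pos=st.pos[i] + off,
            pop=st.pop[i],
            birth_frame=f + 1,
            parent=i,
        )
        st.lineage[j] = st.lineage[i]
        # settled daughters take their own spot in the monolayer; anchors
        # of the proximal wave never cross the equatorial halt plane
        if st.stage[i] == ST_SETTLED:
            anchor = st.attract[i] + off
            if st.pop[i] == 0 and st.program[i] == PROX:
                pd_a = float((anchor - model.eye_center) @ model.u)
                if pd_a > -1.0:
                    anchor = anchor - (pd_a + 1.0) * model.u
            st.attract[j] = anchor
        else:
            st.attract[j] = st.attract[i]
        st.wnt_pos[j] = st.wnt_pos[i]
        st.stage[j] = st.stage[i]
        st.program[j] = st.program[i]
        st.no_div[j] = st.no_div[i]
        if diverge:
            st.mix_pending[j] = False
            st.force_frame[j] = -1
            if k == 1:
                # the stray branch: one non-dividing cell re-routed to the
                # opposite compartment (one mixed branch per lineage)
                other = DIST if st.program[i] == PROX else PROX
                st.program[j] = other
                st.stage[j] = ST_TO_TARGET
                # avoid spots already held by settled cells of either wave
                occupied = list(settle_taken or []) + [
                    st.pos[k]
                    for k in range(st.n)
                    if st.alive[k] and st.stage[k] == ST_SETTLED
                ]
                st.attract[j] = _settle_point(rng, model, other, occupied)
                if settle_taken is not None:
                    settle_taken.append(st.attract[j].copy())
                st.no_div[j] = True
        else:
            st.mix_pending[j] = st.mix_pending[i]
            st.force_frame[j] = st.force_frame[i]
            if st.mix_pending[j] and st.force_frame[j] <= f:
                st.force_frame[j] = min(f + 2, len(times) - 2)
        st.alive[j] = st.birth_frame[j] == f + 1


def _finalize(
    st: _State, model: EmbryoModel, config: SimulationConfig, times: np.ndarray
) -> GroundTruth:
    cells: list[CellRecord] = []
    for i in range(st.n):
        b, e = int(st.birth_frame[i]), int(st.end_frame[i])
        if e < 0:
            e = config.n_frames - 1
        traj = st.traj[i, b : e + 1].copy()
        cells.append(
            CellRecord(
                cell_id=i,
                parent_id=int(st.parent[i]) if st.parent[i] >= 0 else None,
                lineage_id=int(st.lineage[i]),
                population=POP_1NC if st.pop[i] == 0 else POP_2NC,
                birth_frame=b,
                end_frame=e,
                birth_hpf=float(times[b]),
                end_hpf=float(times[e]),
                positions=traj,
                destination_truth=PROGRAM_NAMES[int(st.program[i])],
                wnt_positive=bool(st.wnt_pos[i]),
            )
        )
    truth = GroundTruth(model=model, cells=cells, config=config)
    integrate_pools(truth)
    return truth


# ---------------------------------------------------------------------------
# reporter pools
# ---------------------------------------------------------------------------


def _silencing_hpf(config: SimulationConfig, population: str) -> float:
    return (
        config.silencing_1nc_hpf if population == POP_1NC else config.silencing_2nc_hpf
    )


def integrate_pools(truth: GroundTruth) -> None:
    """(Re)compute green/red pools, promoter state and Wnt intensity in place.

    Uses the conversion events stored on the truth.  Children inherit the
    parent's pool values at the division frame.
    """
    cfg = truth.config
    times = truth.frame_times
    dt_h = cfg.dt_h
    k_deg = math.log(2.0) / cfg.green_halflife_h
    k_syn = cfg.k_syn_per_h
    decay = math.exp(-k_deg * dt_h)
    gain = (k_syn / k_deg) * (1.0 - decay) if k_deg > 0 else k_syn * dt_h
    conversions = sorted(truth.conversions)

    order = sorted(truth.cells, key=lambda c: c.birth_frame)
    g_end: dict[int, float] = {}
    r_end: dict[int, float] = {}
    for cell in order:
        nfr = cell.n_frames
        t = times[cell.birth_frame : cell.end_frame + 1]
        silence = _silencing_hpf(cfg, cell.population)
        on = t < silence
        cell.promoter_state = on
        G = np.zeros(nfr)
        Rp = np.zeros(nfr)
        if cell.parent_id is not None:
            G[0] = g_end[cell.parent_id]
            Rp[0] = r_end[cell.parent_id]
        conv_frames = set()
        for tc in conversions:
            # event applies at the first frame with time >= tc
            f = int(np.searchsorted(times, tc - 1e-12))
            conv_frames.add(f)
        for k in range(nfr):
            f = cell.birth_frame + k
            if k > 0:
                G[k] = G[k - 1] * decay + (gain if on[k - 1] else 0.0)
                Rp[k] = Rp[k - 1] * decay
            if f in conv_frames:
                Rp[k] += G[k]
                G[k] = 0.0
        g_end[cell.cell_id] = float(G[-1])
        r_end[cell.cell_id] = float(Rp[-1])
        cell.pool_green = G
        cell.pool_red = Rp
        cell.wnt_intensity = _wnt_profile(cfg, t, cell)


def _wnt_profile(cfg: SimulationConfig, t: np.ndarray, cell: CellRecord) -> np.ndarray:
    """Two-wave Wnt-reporter intensity: transient wave in all NC, sustained
    second wave in the Wnt-positive subset of the late population."""
    w1 = 1.0 * np.exp(-0.5 * ((t - cfg.wnt_wave1_peak_hpf) / 0.8) ** 2)
    out = w1.copy()
    if cell.population == POP_2NC and cell.wnt_positive:
        out = out + 2.5 * np.exp(-0.5 * ((t - cfg.wnt_wave2_peak_hpf) / 3.0) ** 2)
    return out


def apply_photoconversion(truth: GroundTruth, t_convert_hpf: float) -> GroundTruth:
    """Return a new GroundTruth with a green→red conversion at ``t_convert``.

    For every cell alive at the conversion instant, R ← R + G and G ← 0;
    afterwards green re-accumulates only where the promoter is still active
    (the basis of the expression-recovery classification).
    """
    cfg = truth.config
    if not cfg.t_start_hpf <= t_convert_hpf <= cfg.t_end_hpf:
        raise ValueError(
            f"t_convert = {t_convert_hpf} hpf outside simulated window "
            f"[{cfg.t_start_hpf}, {cfg.t_end_hpf}]"
        )
    out = GroundTruth(
        model=truth.model,
        cells=[
            CellRecord(
                cell_id=c.cell_id,
                parent_id=c.parent_id,
                lineage_id=c.lineage_id,
                population=c.population,
                birth_frame=c.birth_frame,
                end_frame=c.end_frame,
                birth_hpf=c.birth_hpf,
                end_hpf=c.end_hpf,
                positions=c.positions,
                destination_truth=c.destination_truth,
                wnt_positive=c.wnt_positive,
            )
            for c in truth.cells
        ],
        config=cfg,
        conversions=tuple(sorted(truth.conversions + (t_convert_hpf,))),
    )
    integrate_pools(out)
    return out
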