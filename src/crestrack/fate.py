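"""Backward/forward fate propagation, destination labels, lineage
homogeneity and penetrance statistics.

Destination labelling follows the proximodistal dichotomy of the eye: a
terminal cell at position p is *inside the eye shell* when
``| ‖p − c‖ − R | <= shell_um``; inside the shell it is *distal* when its
proximodistal coordinate ``(p − c)·u`` exceeds ``margin_um``, *proximal*
when below ``−margin_um``, with the exact-equator tie broken to proximal;
outside the shell it is *periocular*.  A lineage is *homogeneous* when all
its labelled terminals share one compartment of the proximal/distal
dichotomy; periocular terminals do not enter the dichotomy.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .geometry import EmbryoModel, Region
from .lineage import LineageForest

__all__ = [
    "DestinationLabel",
    "HomogeneityReport",
    "PenetranceReport",
    "select_cells",
    "propagate_selection",
    "classify_destination",
    "lineage_homogeneity",
    "penetrance_table",
    "defect_call",
    "round_half_away",
]

PROXIMAL, DISTAL, PERIOCULAR, UNLABELLED = (
    "proximal",
    "distal",
    "periocular",
    "unlabelled",
)
DICHOTOMY = (PROXIMAL, DISTAL)


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (percentage convention)."""
    return int(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0


# ---------------------------------------------------------------------------
# selection and propagation
# ---------------------------------------------------------------------------


def select_cells(
    forest: LineageForest, region: Region, t_select_hpf: float
) -> set[int]:
    """Ids of segments alive at t_select whose position is in the region."""
    frame = forest.frame_of_time(t_select_hpf)
    lo, hi = forest.frame_span
    if not lo <= frame <= hi:
        raise ValueError(f"t_select = {t_select_hpf} hpf outside forest span")
    alive = forest.alive_at(frame)
    if not alive:
        warnings.warn(f"no cells alive at {t_select_hpf} hpf")
        return set()
    pts = np.array([s.position_at(frame) for s in alive])
    inside = region(pts)
    return {s.segment_id for s, ok in zip(alive, inside) if ok}


@dataclass
class PropagatedTracks:
    """Trajectories of a selection propagated through the forest."""

    segment_ids: set[int]
    frame_window: tuple[int, int]                     # inclusive
    tracks: dict[int, tuple[int, np.ndarray]]         # id -> (start_frame, positions)
    direction: str


def propagate_selection(
    forest: LineageForest,
    selection: set[int],
    t_from_hpf: float,
    t_to_hpf: float,
    direction: str,
) -> PropagatedTracks:
    """Propagate a cell selection backward (ancestors) or forward
    (descendants) in time and return the trajectories over the window.

    Backward: the unique ancestor path of each selected segment restricted
    to [t_to, t_from] (t_to < t_from).  Forward: the selected segments and
    all their descendants restricted to [t_from, t_to].
    """
    missing = sorted(set(selection) - set(forest.segments))
    if missing:
        raise ValueError(f"selection ids absent from forest: {missing}")
    if direction not in ("backward", "forward"):
        raise ValueError("direction must be 'backward' or 'forward'")
    if direction == "backward" and not t_to_hpf <= t_from_hpf:
        raise ValueError("backward propagation needs t_to <= t_from")
    if direction == "forward" and not t_from_hpf <= t_to_hpf:
        raise ValueError("forward propagation needs t_from <= t_to")

    f_from = forest.frame_of_time(t_from_hpf)
    f_to = forest.frame_of_time(t_to_hpf)
    f_lo, f_hi = min(f_from, f_to), max(f_from, f_to)

    members: set[int] = set()
    for sid in selection:
        members.add(sid)
        if direction == "backward":
            members.update(forest.ancestors(sid))
        else:
            members.update(forest.descendants(sid))

    tracks = {}
    for sid in sorted(members):
        seg = forest.segments[sid]
        a = max(seg.start_frame, f_lo)
        b = min(seg.end_frame, f_hi)
        if a > b:
            continue
        tracks[sid] = (a, seg.positions[a - seg.start_frame : b - seg.start_frame + 1])
    return PropagatedTracks(
        segment_ids={sid for sid in members if sid in tracks},
        frame_window=(f_lo, f_hi),
        tracks=tracks,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# destination labels
# ---------------------------------------------------------------------------


def classify_destination(
    forest: LineageForest,
    model: EmbryoModel,
    t_eval_hpf: float,
    shell_um: float = 6.0,
    margin_um: float = 0.0,
) -> dict[int, str]:
    """Destination label of every terminal segment at the evaluation time."""
    if np.linalg.norm(model.lens_center - model.eye_center) == 0:
        raise ValueError("degenerate proximodistal axis")
    frame = forest.frame_of_time(t_eval_hpf)
    labels: dict[int, str] = {}
    c = model.eye_center
    u = model.u
    R = model.eye_radius
    for seg in forest.terminals():
        # a terminal born after t_eval is represented by its ancestor alive
        # at t_eval; a terminal dead before t_eval stays unlabelled
        probe = seg
        while probe is not None and probe.start_frame > frame:
            probe = (
                forest.segments[probe.parent_id]
                if probe.parent_id is not None
                else None
            )
        if probe is None or not probe.alive_at(frame):
            labels[seg.segment_id] = UNLABELLED
            continue
        p = probe.position_at(frame)
        r = np.linalg.norm(p - c)
        if abs(r - R) > shell_um:
            labels[seg.segment_id] = PERIOCULAR
            continue
        pd = float((p - c) @ u)
        if pd > margin_um:
            labels[seg.segment_id] = DISTAL
        else:
            # includes the exact-equator tie, broken to proximal
            labels[seg.segment_id] = PROXIMAL
    return labels


def wave_terminals(
    forest: LineageForest, labels: dict[int, str], label: str
) -> list:
    """Terminal segments of the pure wave that settled in one compartment.

    The migration-angle comparison contrasts the two waves, so a terminal
    belongs to the group only when its whole lineage settled on that side
    (terminals of mixed lineages are excluded).
    """
    terminal_ids = {s.segment_id for s in forest.terminals()}
    out = []
    members = forest.lineage_members()
    opposite = {PROXIMAL: DISTAL, DISTAL: PROXIMAL}[label]
    for root, segs in members.items():
        term_labels = {labels.get(sid) for sid in segs if sid in terminal_ids}
        if label in term_labels and opposite not in term_labels:
            out.extend(
                forest.segments[sid]
                for sid in segs
                if sid in terminal_ids and labels.get(sid) == label
            )
    return sorted(out, key=lambda s: s.segment_id)


# ---------------------------------------------------------------------------
# homogeneity
# ---------------------------------------------------------------------------


@dataclass
class HomogeneityReport:
    n_lineages: int            # lineages with >= 1 labelled (prox/dist) terminal
    n_homogeneous: int
    n_mixed: int
    n_excluded: int = 0        # lineages with no in-dichotomy terminal
    per_lineage: dict[int, Counter] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_homogeneous + self.n_mixed != self.n_lineages:
            raise ValueError("homogeneous + mixed must equal analysed lineages")

    @property
    def fraction_homogeneous(self) -> float:
        return self.n_homogeneous / self.n_lineages if self.n_lineages else float("nan")

    @property
    def fraction_mixed(self) -> float:
        return self.n_mixed / self.n_lineages if self.n_lineages else float("nan")

    @property
    def percent_homogeneous(self) -> int:
        return round_half_away(100.0 * self.fraction_homogeneous)

    @property
    def percent_mixed(self) -> int:
        return round_half_away(100.0 * self.fraction_mixed)

    @classmethod
    def from_counts(cls, n_lineages: int, n_mixed: int) -> "HomogeneityReport":
        return cls(
            n_lineages=n_lineages,
            n_homogeneous=n_lineages - n_mixed,
            n_mixed=n_mixed,
        )

    def to_dict(self) -> dict:
        return {
            "n_lineages": self.n_lineages,
            "n_homogeneous": self.n_homogeneous,
            "n_mixed": self.n_mixed,
            "n_excluded": self.n_excluded,
            "fraction_homogeneous": self.fraction_homogeneous,
            "percent_homogeneous": self.percent_homogeneous,
            "percent_mixed": self.percent_mixed,
        }


def lineage_homogeneity(
    forest: LineageForest, labels: dict[int, str]
) -> HomogeneityReport:
    """Homogeneous vs mixed lineages from terminal destination labels.

    A lineage (tree rooted at a founder) is homogeneous when its labelled
    terminals all lie in one compartment of the proximal/distal dichotomy
    and mixed when both compartments occur; periocular and unlabelled
    terminals are ignored for the dichotomy, and lineages with no
    in-dichotomy terminal are excluded (counted separately).
    """
    terminal_ids = {s.segment_id for s in forest.terminals()}
    unknown = sorted(set(labels) - set(forest.segments))
    if unknown:
        raise ValueError(f"labels refer to unknown segments: {unknown}")
    missing = sorted(terminal_ids - set(labels))
    if missing:
        raise ValueError(f"labels missing for terminals: {missing}")

    per_lineage: dict[int, Counter] = {}
    for root, members in forest.lineage_members().items():
        cnt = Counter(
            labels[sid] for sid in members if sid in terminal_ids
        )
        per_lineage[root] = cnt

    n_hom = n_mix = n_exc = 0
    for cnt in per_lineage.values():
        kinds = [k for k in DICHOTOMY if cnt.get(k, 0) > 0]
        if not kinds:
            n_exc += 1
        elif len(kinds) == 1:
            n_hom += 1
        else:
            n_mix += 1
    return HomogeneityReport(
        n_lineages=n_hom + n_mix,
        n_homogeneous=n_hom,
        n_mixed=n_mix,
        n_excluded=n_exc,
        per_lineage=per_lineage,
    )


# ---------------------------------------------------------------------------
# penetrance
# ---------------------------------------------------------------------------


@dataclass
class PenetranceRow:
    genotype: str
    n_affected: int
    n_total: int

    @property
    def percent(self) -> int:
        return round_half_away(100.0 * self.n_affected / self.n_total)

    @property
    def formatted(self) -> str:
        return f"{self.percent}% ({self.n_affected}/{self.n_total})"


@dataclass
class PenetranceReport:
    rows: dict[str, PenetranceRow]

    def formatted(self, genotype: str) -> str:
        return self.rows[genotype].formatted

    def to_dict(self) -> dict:
        return {
            g: {
                "n_affected": r.n_affected,
                "n_total": r.n_total,
                "percent": r.percent,
                "formatted": r.formatted,
            }
            for g, r in self.rows.items()
        }


def penetrance_table(embryo_outcomes) -> PenetranceReport:
    """Per-genotype migration-defect penetrance, formatted "x% (a/n)".

    ``embryo_outcomes`` is an iterable of (genotype, affected) pairs or of
    dicts with those keys, one entry per embryo.
    """
    rows: dict[str, list[bool]] = {}
    for item in embryo_outcomes:
        if isinstance(item, dict):
            g, a = item["genotype"], bool(item["affected"])
        else:
            g, a = item[0], bool(item[1])
        rows.setdefault(g, []).append(a)
    if not rows:
        raise ValueError("at least one embryo outcome required")
    return PenetranceReport(
        rows={
            g: PenetranceRow(genotype=g, n_affected=sum(v), n_total=len(v))
            for g, v in rows.items()
        }
    )


# ---------------------------------------------------------------------------
# defect call
# ---------------------------------------------------------------------------


def defect_call(
    forest: LineageForest,
    labels: dict[int, str],
    min_2nc_distal: int = 1,
    max_1nc_distal: int = 0,
) -> tuple[bool, dict]:
    """Call an embryo's migration phenotype affected or not.

    Affected when too few late-wave (2NC) derivatives reach the distal eye
    (< min_2nc_distal) and/or early-wave (1NC) derivatives invade it
    (> max_1nc_distal).  Requires population truth on the forest segments.
    An empty forest is called affected, flagged.
    """
    terms = forest.terminals() if len(forest) else []
    if not terms:
        return True, {"flag": "empty forest", "n_2nc_distal": 0, "n_1nc_distal": 0}
    n2 = n1 = 0
    for seg in terms:
        if labels.get(seg.segment_id) != DISTAL:
            continue
        if seg.population == "2NC":
            n2 += 1
        elif seg.population == "1NC":
            n1 += 1
    affected = (n2 < min_2nc_distal) or (n1 > max_1nc_distal)
    return affected, {"n_2nc_distal": n2, "n_1nc_distal": n1}
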