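"""Division-aware lineage forest.

A :class:`LineageForest` is the object the fate and homogeneity statistics
operate on: a set of trees whose nodes are *segments* (maximal cell tracks
between birth/appearance and division/disappearance) and whose child links
are divisions.  It can be built directly from simulated ground truth (one
segment per simulated cell) or from a linked track graph (linear chains
contracted into segments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = ["Segment", "LineageForest"]


@dataclass
class Segment:
    """One cell segment: contiguous positions from birth to end."""

    segment_id: int
    parent_id: int | None
    start_frame: int
    end_frame: int
    positions: np.ndarray            # (n, 3) μm, frame-aligned
    children: list[int] = field(default_factory=list)
    population: str | None = None    # truth label when known
    destination_truth: str | None = None

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def alive_at(self, frame: int) -> bool:
        return self.start_frame <= frame <= self.end_frame

    def position_at(self, frame: int) -> np.ndarray:
        if not self.alive_at(frame):
            raise IndexError(
                f"segment {self.segment_id} not alive at frame {frame}"
            )
        return self.positions[frame - self.start_frame]

    def duration_h(self, dt_h: float) -> float:
        return self.n_frames * dt_h


class LineageForest:
    """Forest of division-aware lineage trees over cell segments."""

    def __init__(self, segments: Iterable[Segment], dt_h: float, t_start_hpf: float):
        self.segments: dict[int, Segment] = {}
        self.dt_h = float(dt_h)
        self.t_start_hpf = float(t_start_hpf)
        for seg in segments:
            if seg.segment_id in self.segments:
                raise ValueError(f"duplicate segment id {seg.segment_id}")
            self.segments[seg.segment_id] = seg
        # rebuild child links deterministically
        for seg in self.segments.values():
            seg.children = []
        for seg in self.segments.values():
            if seg.parent_id is not None:
                parent = self.segments.get(seg.parent_id)
                if parent is None:
                    raise ValueError(f"dangling parent id {seg.parent_id}")
                parent.children.append(seg.segment_id)
        for seg in self.segments.values():
            if len(seg.children) > 2:
                raise ValueError(
                    f"segment {seg.segment_id} has {len(seg.children)} children"
                )
            seg.children.sort()
            for cid in seg.children:
                child = self.segments[cid]
                if child.start_frame != seg.end_frame + 1:
                    raise ValueError(
                        f"child {cid} does not start adjacent to parent "
                        f"{seg.segment_id} end"
                    )

    # -- structure --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments.values())

    def roots(self) -> list[Segment]:
        return sorted(
            (s for s in self.segments.values() if s.parent_id is None),
            key=lambda s: s.segment_id,
        )

    def terminals(self) -> list[Segment]:
        return sorted(
            (s for s in self.segments.values() if not s.children),
            key=lambda s: s.segment_id,
        )

    def root_of(self, segment_id: int) -> int:
        seg = self.segments[segment_id]
        while seg.parent_id is not None:
            seg = self.segments[seg.parent_id]
        return seg.segment_id

    def ancestors(self, segment_id: int) -> list[int]:
        """Path root→...→parent of the segment (excluding itself)."""
        out = []
        seg = self.segments[segment_id]
        while seg.parent_id is not None:
            out.append(seg.parent_id)
            seg = self.segments[seg.parent_id]
        return out[::-1]

    def descendants(self, segment_id: int) -> list[int]:
        out, stack = [], [segment_id]
        while stack:
            sid = stack.pop()
            for cid in self.segments[sid].children:
                out.append(cid)
                stack.append(cid)
        return sorted(out)

    def subtree(self, segment_id: int) -> list[int]:
        return sorted([segment_id] + self.descendants(segment_id))

    def lineage_members(self) -> dict[int, list[int]]:
        """root segment id → all segment ids of that tree."""
        return {r.segment_id: self.subtree(r.segment_id) for r in self.roots()}

    def n_divisions(self) -> int:
        return sum(1 for s in self.segments.values() if len(s.children) == 2)

    # -- time -------------------------------------------------------------
    def time_of_frame(self, frame: int) -> float:
        return self.t_start_hpf + frame * self.dt_h

    def frame_of_time(self, t_hpf: float) -> int:
        return int(round((t_hpf - self.t_start_hpf) / self.dt_h))

    @property
    def frame_span(self) -> tuple[int, int]:
        lo = min(s.start_frame for s in self.segments.values())
        hi = max(s.end_frame for s in self.segments.values())
        return lo, hi

    def alive_at(self, frame: int) -> list[Segment]:
        return sorted(
            (s for s in self.segments.values() if s.alive_at(frame)),
            key=lambda s: s.segment_id,
        )

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_truth(cls, truth) -> "LineageForest":
        """One segment per simulated cell record, labels carried over."""
        segs = [
            Segment(
                segment_id=c.cell_id,
                parent_id=c.parent_id,
                start_frame=c.birth_frame,
                end_frame=c.end_frame,
                positions=np.asarray(c.positions, float),
                population=c.population,
                destination_truth=c.destination_truth,
            )
            for c in truth.cells
        ]
        return cls(segs, dt_h=truth.config.dt_h, t_start_hpf=truth.config.t_start_hpf)
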