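"""File formats: track CSV, Newick lineages, TIFF stacks and run manifests.

The track table is a flat CSV with one row per (cell, frame):
``embryo_id, cell_id, parent_id, lineage_id, frame, t_hpf, x_um, y_um,
z_um, ch_green, ch_red, ch_wnt, population_truth, destination``.
Coordinates are physical μm, frames 0-based, times hpf; UTF-8, comma
separator, "." decimal, header mandatory.  Reading validates the table and
reports offending row numbers.
"""

from __future__ import annotations

import io as _io
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Phylo

from .lineage import LineageForest, Segment

__all__ = [
    "TRACK_COLUMNS",
    "tracks_from_truth",
    "write_tracks",
    "read_tracks",
    "forest_from_tracks",
    "write_lineage_newick",
    "read_lineage_newick",
    "export_truth",
    "write_frame_tiffs",
    "write_manifest",
]

TRACK_COLUMNS = [
    "embryo_id",
    "cell_id",
    "parent_id",
    "lineage_id",
    "frame",
    "t_hpf",
    "x_um",
    "y_um",
    "z_um",
    "ch_green",
    "ch_red",
    "ch_wnt",
    "population_truth",
    "destination",
]


class TrackTableError(ValueError):
    pass


# ---------------------------------------------------------------------------
# track CSV
# ---------------------------------------------------------------------------


def tracks_from_truth(truth, embryo_id: str = "sim0") -> pd.DataFrame:
    """Flatten a GroundTruth into the track table."""
    times = truth.frame_times
    parts = []
    for c in truth.cells:
        n = c.n_frames
        frames = np.arange(c.birth_frame, c.end_frame + 1)
        parts.append(
            pd.DataFrame(
                {
                    "embryo_id": embryo_id,
                    "cell_id": c.cell_id,
                    "parent_id": c.parent_id if c.parent_id is not None else pd.NA,
                    "lineage_id": c.lineage_id,
                    "frame": frames,
                    "t_hpf": times[frames],
                    "x_um": c.positions[:, 0],
                    "y_um": c.positions[:, 1],
                    "z_um": c.positions[:, 2],
                    "ch_green": c.pool_green,
                    "ch_red": c.pool_red,
                    "ch_wnt": c.wnt_intensity,
                    "population_truth": c.population,
                    "destination": c.destination_truth,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRACK_COLUMNS)
    df = pd.concat(parts, ignore_index=True)
    return df[TRACK_COLUMNS]


def write_tracks(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise TrackTableError(f"missing columns: {missing}")
    table.to_csv(path, index=False, float_format="%.6g")


def _validate_tracks(df: pd.DataFrame) -> None:
    missing = [c for c in TRACK_COLUMNS[:12] if c not in df.columns]
    if missing:
        raise TrackTableError(f"missing columns: {missing}")
    dup = df.duplicated(subset=["cell_id", "frame"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]   # +2: header + 0-base
        raise TrackTableError(f"duplicate (cell_id, frame) at file rows {rows}")
    ids = set(df["cell_id"].unique().tolist())
    parents = df.loc[df["parent_id"].notna(), ["parent_id"]]
    dangling = parents[~parents["parent_id"].isin(ids)]
    if len(dangling):
        rows = (dangling.index + 2).tolist()[:10]
        bad = sorted(set(int(v) for v in dangling["parent_id"]))
        raise TrackTableError(
            f"dangling parent_id {bad} at file rows {rows}"
        )
    for cid, grp in df.groupby("cell_id", sort=False):
        t = grp.sort_values("frame")["t_hpf"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise TrackTableError(
                f"t_hpf not strictly increasing for cell {cid}"
            )


def read_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"parent_id": "Int64"})
    if len(df) == 0:
        return df
    _validate_tracks(df)
    return df


def forest_from_tracks(table: pd.DataFrame) -> LineageForest:
    """Reassemble a LineageForest (one segment per cell id) from the table."""
    if len(table) == 0:
        return LineageForest([], dt_h=1.0, t_start_hpf=0.0)
    df = table.sort_values(["cell_id", "frame"])
    t = df["t_hpf"].to_numpy()
    f = df["frame"].to_numpy()
    # infer the frame grid
    spans = df.groupby("cell_id")
    dt_candidates = []
    for _, grp in spans:
        tt = grp["t_hpf"].to_numpy()
        if len(tt) > 1:
            dt_candidates.append(np.diff(tt).min())
    dt_h = float(min(dt_candidates)) if dt_candidates else 1.0
    t_start = float((t - f * dt_h).min())
    segs = []
    for cid, grp in spans:
        frames = grp["frame"].to_numpy()
        pos = grp[["x_um", "y_um", "z_um"]].to_numpy(float)
        parent = grp["parent_id"].iloc[0]
        segs.append(
            Segment(
                segment_id=int(cid),
                parent_id=None if pd.isna(parent) else int(parent),
                start_frame=int(frames[0]),
                end_frame=int(frames[-1]),
                positions=pos,
                population=(
                    str(grp["population_truth"].iloc[0])
                    if "population_truth" in grp and grp["population_truth"].notna().iloc[0]
                    else None
                ),
                destination_truth=(
                    str(grp["destination"].iloc[0])
                    if "destination" in grp and grp["destination"].notna().iloc[0]
                    else None
                ),
            )
        )
    return LineageForest(segs, dt_h=dt_h, t_start_hpf=t_start)


# ---------------------------------------------------------------------------
# Newick lineages
# ---------------------------------------------------------------------------


def _newick_of(forest: LineageForest, seg_id: int) -> str:
    seg = forest.segments[seg_id]
    label = f"s{seg.segment_id}"
    length = seg.duration_h(forest.dt_h)
    if seg.children:
        inner = ",".join(_newick_of(forest, c) for c in seg.children)
        return f"({inner}){label}:{length:.6g}"
    return f"{label}:{length:.6g}"


def write_lineage_newick(forest: LineageForest, path: str | Path) -> None:
    """One Newick string per lineage tree: labels are segment ids, branch
    lengths are segment durations in hours."""
    with open(path, "w", encoding="utf-8") as fh:
        for root in forest.roots():
            fh.write(_newick_of(forest, root.segment_id) + ";\n")


def read_lineage_newick(path: str | Path):
    """Parse lineage trees back to (label, duration_h, children) tuples.

    Topology and durations round-trip; positions do not live in Newick.
    Raises on malformed input with the parser's position message.
    """
    trees = []
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    for line in filter(None, (ln.strip() for ln in text.splitlines())):
        tree = Phylo.read(_io.StringIO(line), "newick")

        def conv(clade):
            children = [conv(ch) for ch in clade.clades]
            return (
                clade.name,
                float(clade.branch_length) if clade.branch_length is not None else None,
                children,
            )

        trees.append(conv(tree.root))
    return trees


# ---------------------------------------------------------------------------
# bundles
# ---------------------------------------------------------------------------


def export_truth(truth, out_dir: str | Path, embryo_id: str = "sim0") -> dict[str, Path]:
    """Write the track CSV and the Newick lineage file for a simulation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tracks": out / f"{embryo_id}_tracks.csv",
        "lineages": out / f"{embryo_id}_lineages.nwk",
    }
    write_tracks(tracks_from_truth(truth, embryo_id), paths["tracks"])
    write_lineage_newick(LineageForest.from_truth(truth), paths["lineages"])
    return paths


def write_frame_tiffs(
    stacks: dict[str, np.ndarray],
    out_dir: str | Path,
    embryo_id: str,
    frame: int,
    imaging,
    dt_s: float,
) -> list[Path]:
    """One multi-page TIFF per channel: {embryo}_t{frame:04d}_c{channel}.tif
    plus a sidecar JSON with voxel size and channel names."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for ch, img in stacks.items():
        p = out / f"{embryo_id}_t{frame:04d}_c{ch}.tif"
        dtype = np.uint16 if imaging.bit_depth == 16 else np.uint8
        tifffile.imwrite(p, np.asarray(img).astype(dtype))
        written.append(p)
    sidecar = out / f"{embryo_id}_t{frame:04d}.json"
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "embryo_id": embryo_id,
                "frame": frame,
                "voxel_size_um": list(imaging.voxel_size_um),
                "dt_s": dt_s,
                "channels": sorted(stacks),
            },
            fh,
            indent=2,
        )
    written.append(sidecar)
    return written


def write_manifest(path: str | Path, command: str, params: dict, seed: int | None) -> None:
    """Machine-readable record of a pipeline run."""
    import crestrack

    manifest = {
        "command": command,
        "parameters": params,
        "seed": seed,
        "versions": {
            "crestrack": getattr(crestrack, "__version__", "unknown"),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
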