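"""Result files: five-category trajectory spreadsheets and lineage
exports.

Each trajectory category (all cells, dividing, non-dividing, daughters,
dividing daughters) is written as one XLSX workbook with two sheets —
migration measures and x–y coordinates — plus mirrored CSV pairs for
pipeline use.  Lineage trees are exported as nested JSON-able dicts with
per-edge time-to-division and a dividing-daughter flag per vertex, and
can be drawn as a static plot.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from fuccitrack.image_io import tracks_to_table
from fuccitrack.metrics import MeasureRow
from fuccitrack.tracking import CATEGORY_NAMES, LineageTree, Track, categorize

__all__ = ["write_results", "export_lineage_tree", "lineage_graph", "plot_lineage"]

_MEASURE_COLUMNS = [
    "Cell_ID",
    "Trajectory_Time_h",
    "Total_Distance_um",
    "Displacement_um",
    "Directionality",
    "Avg_Speed_um_h",
]


def _measures_frame(tracks: list[Track], measures: dict[str, MeasureRow]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        m = measures.get(t.id)
        if m is None:
            continue
        rows.append(
            (m.cell_id, m.trajectory_time_h, m.total_distance_um, m.displacement_um,
             m.directionality, m.avg_speed_um_h)
        )
    return pd.DataFrame(rows, columns=_MEASURE_COLUMNS)


def write_results(
    lineage: LineageTree,
    measures: dict[str, MeasureRow],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the five category workbooks (and CSV mirrors) to ``out_dir``.

    Per category: ``<Category>.xlsx`` with sheets ``Measures`` and
    ``Coordinates``, plus ``<Category>_measures.csv`` and
    ``<Category>_coordinates.csv``.  Empty categories produce files with
    headers only.  Returns the workbook path per category.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cats = categorize(lineage)
    written: dict[str, Path] = {}
    for name in CATEGORY_NAMES:
        tracks = cats[name]
        mdf = _measures_frame(tracks, measures)
        cdf = tracks_to_table(tracks)
        xlsx = out_dir / f"{name}.xlsx"
        with pd.ExcelWriter(xlsx) as writer:
            mdf.to_excel(writer, sheet_name="Measures", index=False)
            cdf.to_excel(writer, sheet_name="Coordinates", index=False)
        mdf.to_csv(out_dir / f"{name}_measures.csv", index=False)
        cdf.to_csv(out_dir / f"{name}_coordinates.csv", index=False)
        written[name] = xlsx
    return written


def lineage_graph(lineage: LineageTree) -> nx.DiGraph:
    """Directed lineage forest; edges parent→daughter carry the
    daughter's time-to-division in frames where it divides."""
    g = nx.DiGraph()
    for t in lineage:
        g.add_node(t.id, divides=t.division_frame is not None, generation=LineageTree.generation(t.id))
    for t in lineage:
        for d in t.daughter_ids:
            if d in lineage.tracks:
                g.add_edge(t.id, d)
    return g


def export_lineage_tree(
    lineage: LineageTree,
    root_id: str,
    frame_interval_min: float,
    path: str | Path | None = None,
) -> dict:
    """Hierarchical export of one ancestor's subtree.

    Each vertex records its generation, lifetime, whether it divides and
    whether it is a dividing daughter; each parent→daughter edge is
    implied by nesting, with ``time_to_division_h`` on vertices that
    divide (the quantity the arrow length encodes in a lineage drawing).
    Optionally written to ``path`` as JSON.
    """
    if root_id not in lineage.tracks:
        raise ValueError(f"unknown root {root_id!r}")

    def node(tid: str) -> dict:
        t = lineage[tid]
        divides = t.division_frame is not None
        d = {
            "id": tid,
            "generation": LineageTree.generation(tid),
            "birth_frame": t.birth_frame,
            "last_frame": t.last_frame,
            "divides": divides,
            "dividing_daughter": divides and t.parent_id is not None,
            "time_to_division_h": (
                (t.division_frame - t.birth_frame) * frame_interval_min / 60.0 if divides else None
            ),
            "daughters": [node(d_) for d_ in t.daughter_ids if d_ in lineage.tracks],
        }
        return d

    tree = node(root_id)
    if path is not None:
        Path(path).write_text(json.dumps(tree, indent=2))
    return tree


def plot_lineage(lineage: LineageTree, root_id: str, frame_interval_min: float, path: str | Path) -> None:
    """Static lineage-tree drawing: x = time (h), one horizontal line per
    cell, vertical connectors at divisions; dividing daughters in blue."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if root_id not in lineage.tracks:
        raise ValueError(f"unknown root {root_id!r}")
    step_h = frame_interval_min / 60.0

    rows: dict[str, float] = {}

    def assign(tid: str, next_row: list[int]) -> float:
        t = lineage[tid]
        kids = [d for d in t.daughter_ids if d in lineage.tracks]
        if not kids:
            rows[tid] = next_row[0]
            next_row[0] += 1
        else:
            ys = [assign(k, next_row) for k in kids]
            rows[tid] = sum(ys) / len(ys)
        return rows[tid]

    assign(root_id, [0])
    fig, ax = plt.subplots(figsize=(8, 4))

    def draw(tid: str) -> None:
        t = lineage[tid]
        y = rows[tid]
        dividing_daughter = t.division_frame is not None and t.parent_id is not None
        color = "tab:blue" if dividing_daughter else "0.3"
        ax.plot([t.birth_frame * step_h, t.last_frame * step_h], [y, y], color=color, lw=2)
        kids = [d for d in t.daughter_ids if d in lineage.tracks]
        if kids:
            x = (t.division_frame + 1) * step_h
            ys = [rows[k] for k in kids]
            ax.plot([x, x], [min(ys), max(ys)], color="0.6", lw=1)
            for k in kids:
                draw(k)
        ax.text(t.birth_frame * step_h, y + 0.12, tid, fontsize=7)

    draw(root_id)
    ax.set_xlabel("time (h)")
    ax.set_yticks([])
    ax.set_title(f"lineage of {root_id}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
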