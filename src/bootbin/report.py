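"""Static visual report: 2D scatterplot with cluster hulls plus counts.

Produces a self-contained HTML file (inline SVG figures and inline JSON
data) and a machine-readable JSON with everything that is plotted: point
coordinates, roles, cluster/bin/annotation labels, convex hull vertices
per non-noise cluster, and per-cluster / per-bin sequence counts.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def _ccw(points: np.ndarray) -> list[tuple[float, float]]:
    hull = ConvexHull(points)
    return [(float(points[v, 0]), float(points[v, 1])) for v in hull.vertices]


def convex_hulls(
    coords: dict[str, tuple[float, float]], labels: dict[str, int]
) -> dict[int, list[tuple[float, float]]]:
    """Convex hull vertices (CCW) per non-noise cluster.

    Clusters of one or two points, or collinear clusters, yield the
    degenerate hull (the point, or the two extreme points).
    """
    groups: dict[int, list[tuple[float, float]]] = {}
    for rid, lab in labels.items():
        if lab == -1 or rid not in coords:
            continue
        groups.setdefault(int(lab), []).append(coords[rid])
    hulls: dict[int, list[tuple[float, float]]] = {}
    for lab, pts in groups.items():
        arr = np.asarray(pts, dtype=float)
        uniq = np.unique(arr, axis=0)
        if len(uniq) == 1:
            hulls[lab] = [tuple(map(float, uniq[0]))]
        elif len(uniq) == 2:
            hulls[lab] = [tuple(map(float, p)) for p in uniq]
        else:
            try:
                hulls[lab] = _ccw(arr)
            except QhullError:  # collinear: keep the two extremes
                order = np.lexsort((uniq[:, 1], uniq[:, 0]))
                hulls[lab] = [
                    tuple(map(float, uniq[order[0]])),
                    tuple(map(float, uniq[order[-1]])),
                ]
    return hulls


@dataclass
class ReportBundle:
    """Everything the report renders, in plain Python containers."""

    coords: dict[str, tuple[float, float]]
    roles: dict[str, str]
    clusters: dict[str, int]
    bins: dict[str, int]
    annotations: dict[str, str] = field(default_factory=dict)

    def point_table(self) -> list[dict]:
        rows = []
        for rid in sorted(self.coords):
            x, y = self.coords[rid]
            rows.append(
                {
                    "id": rid,
                    "x": round(float(x), 6),
                    "y": round(float(y), 6),
                    "role": self.roles.get(rid, ""),
                    "cluster": self.clusters.get(rid),
                    "bin": self.bins.get(rid),
                    "annotation": self.annotations.get(rid),
                }
            )
        return rows

    def counts(self) -> dict[str, dict[str, int]]:
        per_cluster: dict[str, int] = {}
        for lab in self.clusters.values():
            key = "noise" if lab == -1 else str(lab)
            per_cluster[key] = per_cluster.get(key, 0) + 1
        per_bin: dict[str, int] = {}
        for lab in self.bins.values():
            per_bin[str(lab)] = per_bin.get(str(lab), 0) + 1
        return {"per_cluster": per_cluster, "per_bin": per_bin}


def _scatter_svg(bundle: ReportBundle, hulls, color_by: str) -> str:
    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    pts = bundle.point_table()
    labs = []
    for p in pts:
        v = p[color_by]
        labs.append(-1 if v is None else v)
    uniq = sorted(set(labs), key=str)
    cmap = plt.get_cmap("tab20")
    for j, lab in enumerate(uniq):
        xs = [p["x"] for p, l in zip(pts, labs) if l == lab]
        ys = [p["y"] for p, l in zip(pts, labs) if l == lab]
        color = "0.6" if lab == -1 else cmap(j % 20)
        name = "noise/none" if lab == -1 else str(lab)
        ax.scatter(xs, ys, s=8, color=color, label=name, linewidths=0)
    for lab, verts in hulls.items():
        if len(verts) >= 2:
            poly = verts + [verts[0]]
            ax.plot([v[0] for v in poly], [v[1] for v in poly], "k-", lw=0.8)
    ax.set_title(f"2D embedding, colored by {color_by}")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    if len(uniq) <= 20:
        ax.legend(fontsize=6, markerscale=1.5, loc="best")
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def _bars_svg(counts: dict[str, int], title: str) -> str:
    fig, ax = plt.subplots(figsize=(6.5, 2.5))
    keys = sorted(counts, key=lambda k: (k == "noise", k.zfill(8)))
    ax.bar(range(len(keys)), [counts[k] for k in keys], color="#4878a8")
    ax.set_xticks(range(len(keys)))
    ax.set_xticklabels(keys, fontsize=7)
    ax.set_title(title)
    ax.set_ylabel("sequences")
    buf = io.StringIO()
    fig.savefig(buf, format="svg", metadata={"Date": None})
    plt.close(fig)
    return buf.getvalue()


def render(bundle: ReportBundle, out_dir: str | os.PathLike) -> tuple[str, str]:
    """Write report.html and report.json; returns their paths.

    The JSON is deterministic for a fixed binning result (sorted keys,
    rounded coordinates); the HTML inlines the same data plus SVG
    figures.
    """
    os.makedirs(out_dir, exist_ok=True)
    hulls = convex_hulls(bundle.coords, bundle.clusters)
    data = {
        "points": bundle.point_table(),
        "hulls": {str(k): v for k, v in sorted(hulls.items())},
        "counts": bundle.counts(),
    }
    json_path = os.path.join(out_dir, "report.json")
    with open(json_path, "w") as out:
        json.dump(data, out, indent=2, sort_keys=True)
        out.write("\n")

    matplotlib.rcParams["svg.hashsalt"] = "bootbin"
    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<title>Binning report</title>"
        "<style>body{font-family:sans-serif;max-width:900px;margin:auto}"
        "h2{border-bottom:1px solid #ccc}</style></head><body>",
        "<h1>Binning report</h1>",
        "<h2>2D embedding</h2>",
        _scatter_svg(bundle, hulls, "cluster"),
        _scatter_svg(bundle, hulls, "bin"),
    ]
    if bundle.annotations:
        parts.append(_scatter_svg(bundle, hulls, "annotation"))
    counts = bundle.counts()
    parts.append("<h2>Sequences per cluster and per bin</h2>")
    parts.append(_bars_svg(counts["per_cluster"], "sequences per cluster"))
    parts.append(_bars_svg(counts["per_bin"], "sequences per bin"))
    parts.append("<h2>Data</h2><script type='application/json' id='report-data'>")
    parts.append(json.dumps(data, sort_keys=True))
    parts.append("</script></body></html>")
    html_path = os.path.join(out_dir, "report.html")
    with open(html_path, "w") as out:
        out.write("\n".join(parts))
    return html_path, json_path
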