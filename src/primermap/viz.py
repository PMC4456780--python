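"""Raster rendering of per-primer alignment panels and per-target
primer-distribution maps.

Each image gets a JSON sidecar describing its geometry (ruler extent,
glyph list, title).  Pixel-level golden-image comparison is brittle
across rasterizer versions, so the sidecar is the machine-testable
surface; the raster is for humans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
from PIL import Image, ImageDraw, ImageFont

from .design import PrimerSet
from .mapping import AlignmentView

__all__ = ["DistributionMap", "render_alignment_panel",
           "render_distribution_map", "pack_rows", "SUPPORTED_FORMATS"]

SUPPORTED_FORMATS = ("png", "jpeg", "gif")
_PIL_FORMAT = {"png": "PNG", "jpeg": "JPEG", "jpg": "JPEG", "gif": "GIF"}


@dataclass
class DistributionMap:
    """Geometry of one primer-distribution figure.

    The target is drawn as a number line in nucleotide units spanning
    [1, target_length]; each accepted primer becomes one arrowed glyph
    whose horizontal extent is its span under that scale and whose
    arrowhead points in the direction of synthesis (right for forward,
    left for reverse).  ``glyphs`` entries are (name, start, end,
    direction, row) with the row assigned by first-fit packing so
    overlapping primers never collide.
    """

    target_id: str
    target_length: int
    title: str
    glyphs: list[tuple[str, int, int, str, int]] = field(default_factory=list)

    def to_sidecar(self) -> dict:
        return {
            "title": self.title,
            "target_id": self.target_id,
            "ruler": {"start": 1, "end": self.target_length, "units": "nt"},
            "glyphs": [
                {"name": n, "start": s, "end": e, "direction": d, "row": r}
                for n, s, e, d, r in self.glyphs
            ],
        }


def pack_rows(spans: list[tuple[int, int]], gap: int = 1) -> list[int]:
    """Greedy first-fit row assignment for possibly overlapping spans.

    Spans are processed in the order given (callers sort by start);
    each goes to the lowest row whose last occupied end lies at least
    ``gap`` before the span's start.
    """
    row_ends: list[int] = []
    rows: list[int] = []
    for start, end in spans:
        for r, occupied_end in enumerate(row_ends):
            if start > occupied_end + gap:
                row_ends[r] = end
                rows.append(r)
                break
        else:
            row_ends.append(end)
            rows.append(len(row_ends) - 1)
    return rows


def _write_sidecar(image_path: Path, payload: dict) -> Path:
    sidecar = image_path.with_suffix(image_path.suffix + ".json")
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sidecar


def render_alignment_panel(view: AlignmentView, out_path: str | Path,
                           format: str = "jpeg") -> Path:
    """Render one primer/target alignment panel to a raster file.

    The panel shows the sequence name, the primer name with its span
    and direction, coordinate ticks, and the target/primer text rows.
    Supported formats: png, jpeg, gif (selected by ``format``, not by
    the path extension).
    """
    fmt = format.lower()
    if fmt not in _PIL_FORMAT:
        raise ValueError(
            f"unsupported format {format!r}; supported: {', '.join(SUPPORTED_FORMATS)}"
        )
    out_path = Path(out_path)
    font = ImageFont.load_default()
    char_w, char_h = 7, 12
    n = len(view.target_line)
    width = max(480, 40 + char_w * (n + 24))
    height = 120
    img = Image.new("RGB", (width, height), "white")
    draw = ImageDraw.Draw(img)
    arrow = "->" if view.direction == "forward" else "<-"
    draw.text((20, 10),
              f"{view.target_id}   primer {view.primer_name} "
              f"[{view.primer_start}..{view.primer_end}] {arrow}",
              fill="black", font=font)
    x0, y0 = 20, 45
    # coordinate ticks above the target row
    for tick in view.tick_positions:
        x = x0 + (tick - view.window_start) * char_w
        draw.text((x, y0 - char_h - 2), str(tick), fill="gray", font=font)
        draw.line([(x + 2, y0 - 2), (x + 2, y0 + 1)], fill="gray")
    draw.text((x0, y0), view.target_line, fill="black", font=font)
    color = "blue" if view.direction == "forward" else "red"
    draw.text((x0, y0 + char_h + 4), view.primer_line, fill=color, font=font)
    img.save(out_path, _PIL_FORMAT[fmt])
    _write_sidecar(out_path, {
        "kind": "alignment_panel",
        "target_id": view.target_id,
        "primer": {
            "name": view.primer_name,
            "start": view.primer_start,
            "end": view.primer_end,
            "direction": view.direction,
        },
        "window": {"start": view.window_start, "end": view.window_end},
        "ticks": list(view.tick_positions),
        "format": fmt,
    })
    return out_path


def build_distribution_map(primer_set: PrimerSet, title: str | None = None) -> DistributionMap:
    """Lay out the glyphs for one target's primer-distribution map."""
    primers = sorted(
        primer_set.primers,
        key=lambda p: (p.start, 0 if p.direction == "forward" else 1, p.length),
    )
    rows = pack_rows([(p.start, p.end) for p in primers])
    glyphs = [
        (p.name or str(p.start), p.start, p.end, p.direction, row)
        for p, row in zip(primers, rows)
    ]
    return DistributionMap(
        target_id=primer_set.target_id,
        target_length=primer_set.target_length,
        title=title or primer_set.target_id,
        glyphs=glyphs,
    )


def render_distribution_map(primer_set: PrimerSet, out_path: str | Path) -> Path:
    """Render the primer-distribution map for one target as PNG.

    An empty primer set still produces a valid ruler-only image.  The
    JSON sidecar written next to the image lists every glyph with its
    coordinates, direction, and packed row.
    """
    out_path = Path(out_path)
    dmap = build_distribution_map(primer_set)
    n_rows = 1 + max((g[4] for g in dmap.glyphs), default=0)
    fig_h = 1.6 + 0.4 * n_rows
    fig, ax = plt.subplots(figsize=(10, fig_h))
    L = dmap.target_length
    ax.set_xlim(-0.02 * L, 1.02 * L)
    ax.set_ylim(-1.2, n_rows + 0.5)
    # the target as a number line
    ax.hlines(-0.6, 1, L, color="black", lw=2)
    ax.set_title(dmap.title, fontsize=11)
    for name, start, end, direction, row in dmap.glyphs:
        y = row
        color = "tab:blue" if direction == "forward" else "tab:red"
        if direction == "forward":
            ax.annotate("", xy=(end, y), xytext=(start, y),
                        arrowprops=dict(arrowstyle="-|>", color=color, lw=2))
        else:
            ax.annotate("", xy=(start, y), xytext=(end, y),
                        arrowprops=dict(arrowstyle="-|>", color=color, lw=2))
        ax.text((start + end) / 2, y + 0.18, name, ha="center",
                va="bottom", fontsize=7)
    ax.spines[["left", "right", "top"]].set_visible(False)
    ax.get_yaxis().set_visible(False)
    ax.set_xlabel("position (nt)")
    fig.tight_layout()
    fig.savefig(out_path, format="png", dpi=100)
    plt.close(fig)
    _write_sidecar(out_path, {"kind": "distribution_map", **dmap.to_sidecar()})
    return out_path
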