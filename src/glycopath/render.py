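"""SVG rendering of pathway maps with SNFG monosaccharide glyphs.

Arrows follow the expression semantics of the scoring module: black solid
arrows (width scaling with expression) for expressed reactions, red for
limited, pink for absent and gray dashed for reactions whose gene is
unknown.  Comparison maps color arrows dark pink (increased), green
(decreased) or black (unchanged).  Every arrow embeds its gene-requirement
expression as a ``data-requirement`` attribute and an SVG ``<title>``
(tooltip), the offline analogue of an interactive hover.

Output is deterministic: identical inputs produce byte-identical documents.
Glyph shapes/colors follow the SNFG standard for the codes the standard
covers; other codes fall back to a white hexagon.
"""

from __future__ import annotations

import logging
import math
from xml.sax.saxutils import escape, quoteattr

from .pathway_model import GlycanStructure, Pathway, requirement_to_string
from .scoring import ComparisonState, ReactionState

__all__ = [
    "CLASS_STYLE",
    "COMPARISON_STYLE",
    "SNFG_GLYPHS",
    "FALLBACK_GLYPH",
    "render_structure",
    "render_pathway",
    "render_html_report",
]

logger = logging.getLogger(__name__)

#: reaction class -> (stroke hex, dash array or None)
CLASS_STYLE: dict[str, tuple[str, str | None]] = {
    "expressed": ("#000000", None),
    "limited": ("#ED1C24", None),
    "absent": ("#F7A8C4", None),
    "unknown": ("#9D9D9C", "6,4"),
}

#: comparison status -> (stroke hex, dash array or None)
COMPARISON_STYLE: dict[str, tuple[str, str | None]] = {
    "increased": ("#E75480", None),
    "decreased": ("#00A651", None),
    "unchanged": ("#000000", None),
    "undefined": ("#9D9D9C", "6,4"),
}

#: monosaccharide code -> (shape, fill hex); SNFG shape/color assignments
SNFG_GLYPHS: dict[str, tuple[str, str]] = {
    "Glc": ("circle", "#0072BC"),
    "Gal": ("circle", "#FFD400"),
    "Man": ("circle", "#00A651"),
    "GlcNAc": ("square", "#0072BC"),
    "GalNAc": ("square", "#FFD400"),
    "Fuc": ("triangle", "#ED1C24"),
    "Neu5Ac": ("diamond", "#A54399"),
    "Neu5Gc": ("diamond", "#BFDDF5"),
    "Xyl": ("star", "#F47920"),
    "GlcA": ("diamond-half", "#0072BC"),
}

FALLBACK_GLYPH = ("hexagon", "#FFFFFF")

_GLYPH = 11.0   # glyph cell size, px
_NODE_W = 96.0  # layout cell, px per layer
_NODE_H = 64.0
_MARGIN = 48.0
_R_NODE = 16.0  # arrow endpoint clearance around a node


def _polygon(points: list[tuple[float, float]], fill: str) -> str:
    pts = " ".join(f"{x:.2f},{y:.2f}" for x, y in points)
    return f'<polygon points="{pts}" fill="{fill}" stroke="#000000" stroke-width="0.6"/>'


def _glyph_element(code: str, cx: float, cy: float) -> str:
    shape, fill = SNFG_GLYPHS.get(code, FALLBACK_GLYPH)
    if code not in SNFG_GLYPHS:
        logger.warning("no SNFG glyph for code %r; using fallback hexagon", code)
    r = _GLYPH / 2.0
    if shape == "circle":
        return (
            f'<circle class="glyph" cx="{cx:.2f}" cy="{cy:.2f}" r="{r:.2f}" '
            f'fill="{fill}" stroke="#000000" stroke-width="0.6"/>'
        )
    if shape == "square":
        return (
            f'<rect class="glyph" x="{cx - r:.2f}" y="{cy - r:.2f}" '
            f'width="{2 * r:.2f}" height="{2 * r:.2f}" '
            f'fill="{fill}" stroke="#000000" stroke-width="0.6"/>'
        )
    if shape == "triangle":
        pts = [(cx, cy - r), (cx + r, cy + r), (cx - r, cy + r)]
        return _polygon(pts, fill).replace("<polygon", '<polygon class="glyph"', 1)
    if shape == "diamond":
        pts = [(cx, cy - r), (cx + r, cy), (cx, cy + r), (cx - r, cy)]
        return _polygon(pts, fill).replace("<polygon", '<polygon class="glyph"', 1)
    if shape == "diamond-half":
        top = [(cx, cy - r), (cx + r, cy), (cx - r, cy)]
        bottom = [(cx - r, cy), (cx + r, cy), (cx, cy + r)]
        return (
            '<g class="glyph">'
            + _polygon(top, fill)
            + _polygon(bottom, "#FFFFFF")
            + "</g>"
        )
    if shape == "star":
        pts = []
        for k in range(10):
            rad = r if k % 2 == 0 else r * 0.45
            ang = -math.pi / 2 + k * math.pi / 5
            pts.append((cx + rad * math.cos(ang), cy + rad * math.sin(ang)))
        return _polygon(pts, fill).replace("<polygon", '<polygon class="glyph"', 1)
    # hexagon fallback
    pts = [
        (cx + r * math.cos(math.pi / 6 + k * math.pi / 3),
         cy + r * math.sin(math.pi / 6 + k * math.pi / 3))
        for k in range(6)
    ]
    return _polygon(pts, fill).replace("<polygon", '<polygon class="glyph"', 1)


def render_structure(structure: GlycanStructure, cx: float = 0.0, cy: float = 0.0) -> str:
    """SVG fragment for one structure: stacked SNFG glyph rows plus label.

    One row per monosaccharide code (alphabetical, top to bottom), with the
    residue count drawn left to right.
    """
    if not structure.composition:
        raise ValueError(f"structure {structure.id!r} has an empty composition")
    codes = sorted(structure.composition)
    rows = len(codes)
    parts = [f'<g id="str:{escape(structure.id)}" class="structure">']
    parts.append(
        f"<title>{escape(structure.name)} "
        f"({escape(str(dict(sorted(structure.composition.items()))))})</title>"
    )
    for row, code in enumerate(codes):
        count = structure.composition[code]
        y = cy + (row - (rows - 1) / 2.0) * (_GLYPH + 2.0)
        for k in range(count):
            x = cx + (k - (count - 1) / 2.0) * (_GLYPH + 2.0)
            parts.append(_glyph_element(code, x, y))
    label_y = cy + rows * (_GLYPH + 2.0) / 2.0 + 9.0
    parts.append(
        f'<text x="{cx:.2f}" y="{label_y:.2f}" text-anchor="middle" '
        f'font-size="8" font-family="sans-serif">{escape(structure.id)}</text>'
    )
    parts.append("</g>")
    return "".join(parts)


def _node_xy(pathway: Pathway, sid: str) -> tuple[float, float]:
    x, y = pathway.layout[sid]
    return _MARGIN + x * _NODE_W, _MARGIN + y * _NODE_H


def _arrow_element(
    pathway: Pathway,
    rid: str,
    color: str,
    width: float,
    dash: str | None,
    tooltip: str,
) -> str:
    r = pathway.reactions[rid]
    x1, y1 = _node_xy(pathway, r.substrate_id)
    x2, y2 = _node_xy(pathway, r.product_id)
    dx, dy = x2 - x1, y2 - y1
    length = math.hypot(dx, dy) or 1.0
    ux, uy = dx / length, dy / length
    sx, sy = x1 + ux * _R_NODE, y1 + uy * _R_NODE
    ex, ey = x2 - ux * _R_NODE, y2 - uy * _R_NODE
    head = 4.0 + width
    bx, by = ex - ux * head, ey - uy * head
    px, py = -uy, ux
    requirement = "?" if r.requirement is None else requirement_to_string(r.requirement)
    dash_attr = f' stroke-dasharray="{dash}"' if dash else ""
    tip = [
        f'<g id="rxn:{escape(rid)}" class="arrow" '
        f"data-requirement={quoteattr(requirement)}>",
        f"<title>{escape(tooltip)}</title>",
        f'<line x1="{sx:.2f}" y1="{sy:.2f}" x2="{bx:.2f}" y2="{by:.2f}" '
        f'stroke="{color}" stroke-width="{width:.3f}"{dash_attr}/>',
        _polygon(
            [
                (ex, ey),
                (bx + px * head / 2.0, by + py * head / 2.0),
                (bx - px * head / 2.0, by - py * head / 2.0),
            ],
            color,
        ).replace('stroke="#000000"', f'stroke="{color}"'),
        "</g>",
    ]
    return "".join(tip)


def render_pathway(
    pathway: Pathway,
    states: dict[str, ReactionState] | None = None,
    comparison: dict[str, ComparisonState] | None = None,
) -> str:
    """Complete SVG document for a pathway map.

    Exactly one of ``states`` (expression map) or ``comparison``
    (two-sample map) may be given; with neither, all arrows are plain
    black.  Every reaction must have a state.  The document contains one
    ``<g class="arrow">`` per reaction and one ``<g class="structure">``
    per structure.
    """
    if states is not None and comparison is not None:
        raise ValueError("pass either states or comparison, not both")
    mode = states if states is not None else comparison
    if mode is not None:
        missing = sorted(set(pathway.reactions) - set(mode))
        if missing:
            raise KeyError(f"missing state for reactions {missing}")

    xs = [xy[0] for xy in pathway.layout.values()] or [0.0]
    ys = [xy[1] for xy in pathway.layout.values()] or [0.0]
    canvas_w = 2 * _MARGIN + (max(xs) + 0.5) * _NODE_W
    canvas_h = 2 * _MARGIN + (max(ys) + 0.8) * _NODE_H

    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{canvas_w:.0f}" height="{canvas_h:.0f}" '
        f'viewBox="0 0 {canvas_w:.0f} {canvas_h:.0f}">',
        f"<title>{escape(pathway.name)}</title>",
        '<rect width="100%" height="100%" fill="#FFFFFF"/>',
    ]

    for rid in sorted(pathway.reactions):
        reaction = pathway.reactions[rid]
        if states is not None:
            st = states[rid]
            color, dash = CLASS_STYLE[st.klass]
            width = st.width
            tooltip = (
                f"{rid}: {st.klass}"
                + (f", score={st.score:.4g} TPM" if st.score is not None else "")
            )
        elif comparison is not None:
            st = comparison[rid]
            color, dash = COMPARISON_STYLE[st.status]
            width = 2.5 if st.status in ("increased", "decreased") else 1.0
            tooltip = (
                f"{rid}: {st.status}"
                + (f", fold={st.fold:.4g}" if st.fold is not None else "")
            )
        else:
            color, dash, width = "#000000", None, 1.0
            tooltip = rid
        if reaction.step_label:
            tooltip = f"{reaction.step_label} — {tooltip}"
        parts.append(_arrow_element(pathway, rid, color, width, dash, tooltip))

    for sid in sorted(pathway.structures):
        cx, cy = _node_xy(pathway, sid)
        parts.append(render_structure(pathway.structures[sid], cx, cy))

    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def render_html_report(svg: str, score_table_json: str, title: str = "pathway report") -> str:
    """Standalone HTML wrapping the SVG map and the JSON score table."""
    return (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'/>"
        f"<title>{escape(title)}</title></head><body>\n"
        f"<h1>{escape(title)}</h1>\n"
        + svg
        + "\n<h2>scores</h2>\n<pre>"
        + escape(score_table_json)
        + "</pre>\n</body></html>\n"
    )
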