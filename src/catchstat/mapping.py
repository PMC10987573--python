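"""Choropleth rendering of a table variable over region boundaries.

Numeric variables get a continuous gradient (default light lavender to
dark purple — darker means higher); categorical variables get distinct
colors from a fixed palette; missing values get a neutral grey and a
legend entry.  The primary output is a self-contained SVG built
deterministically (byte-identical for identical inputs); an HTML wrapper
embedding the same SVG is written for convenient panning/zooming in a
browser.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_LIGHT = "#EFEDF5"   # light lavender
DEFAULT_DARK = "#3F007D"    # dark purple
DEFAULT_MISSING = "#BDBDBD"

#: fixed categorical palette, cycled in category order
CATEGORICAL_PALETTE = (
    "#1B9E77", "#D95F02", "#7570B3", "#E7298A",
    "#66A61E", "#E6AB02", "#A6761D", "#666666",
)


@dataclass
class ChoroplethSpec:
    """What to draw and how to color it."""

    variable: str
    scale: str = "gradient"            # "gradient" | "categorical"
    light_color: str = DEFAULT_LIGHT
    dark_color: str = DEFAULT_DARK
    missing_color: str = DEFAULT_MISSING
    title: str = ""

    def __post_init__(self) -> None:
        if self.scale not in ("gradient", "categorical"):
            raise ValueError("scale must be 'gradient' or 'categorical'")
        if self.scale == "gradient" and self.light_color == self.dark_color:
            raise ValueError("gradient endpoints must be distinct")


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    return int(c[0:2], 16), int(c[2:4], 16), int(c[4:6], 16)


def _rgb_to_hex(rgb) -> str:
    return "#{:02X}{:02X}{:02X}".format(*(int(round(v)) for v in rgb))


def luminance(color: str) -> float:
    """Perceptual luminance (ITU-R BT.601 weights), 0 = black."""
    r, g, b = _hex_to_rgb(color)
    return 0.299 * r + 0.587 * g + 0.114 * b


def color_for_value(value, spec: ChoroplethSpec, domain) -> str:
    """Fill color for one region's value.

    For a gradient scale ``domain`` is (min, max) and the color is a
    linear RGB interpolation between the endpoints; out-of-domain values
    are clamped with a logged warning.  For a categorical scale ``domain``
    is the ordered category list and colors cycle through a fixed palette.
    Missing values map to ``spec.missing_color``.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return spec.missing_color
    if spec.scale == "categorical":
        cats = list(domain)
        if value not in cats:
            logger.warning("category %r outside the legend domain", value)
            return spec.missing_color
        return CATEGORICAL_PALETTE[cats.index(value) % len(CATEGORICAL_PALETTE)]
    vmin, vmax = float(domain[0]), float(domain[1])
    if vmax == vmin:
        raise ValueError("degenerate gradient domain")
    v = float(value)
    if v < vmin or v > vmax:
        logger.warning("value %g outside domain [%g, %g]; clamped", v, vmin, vmax)
        v = min(max(v, vmin), vmax)
    frac = (v - vmin) / (vmax - vmin)
    lo = _hex_to_rgb(spec.light_color)
    hi = _hex_to_rgb(spec.dark_color)
    return _rgb_to_hex(tuple(l + frac * (h - l) for l, h in zip(lo, hi)))


def _mid_color(spec: ChoroplethSpec) -> str:
    lo = _hex_to_rgb(spec.light_color)
    hi = _hex_to_rgb(spec.dark_color)
    return _rgb_to_hex(tuple((l + h) / 2 for l, h in zip(lo, hi)))


def _ring_path(coords, project) -> str:
    pts = [project(x, y) for x, y in coords]
    body = " L ".join(f"{px:.2f},{py:.2f}" for px, py in pts)
    return f"M {body} Z"


def _geometry_path(geom, project) -> str:
    if geom.geom_type == "Polygon":
        polys = [geom]
    else:
        polys = list(geom.geoms)
    parts = []
    for poly in polys:
        parts.append(_ring_path(poly.exterior.coords, project))
        for ring in poly.interiors:
            parts.append(_ring_path(ring.coords, project))
    return " ".join(parts)


def _fmt(v: float) -> str:
    return f"{v:.3g}"


def render_choropleth(joined, geometries: dict, spec: ChoroplethSpec,
                      out_path, *, width: int = 800) -> str:
    """Write a choropleth of ``spec.variable`` and return the SVG text.

    ``joined`` is the region-indexed DataFrame and ``geometries`` the
    matching id -> shapely geometry map (both as produced by
    ``join_table_boundaries``).  A ``.svg`` path gets the bare SVG; a
    ``.html`` path gets a minimal wrapper embedding it.  Rendering is
    pure: identical inputs give byte-identical output.
    """
    if len(joined) == 0:
        raise ValueError("joined dataset is empty")
    if spec.variable not in joined.columns:
        raise ValueError(f"variable {spec.variable!r} not in table")
    values = joined[spec.variable]

    degenerate = False
    if spec.scale == "gradient":
        finite = values.to_numpy(dtype=float)
        finite = finite[np.isfinite(finite)]
        if len(finite) == 0:
            raise ValueError("no non-missing values to map")
        domain = (float(finite.min()), float(finite.max()))
        if domain[0] == domain[1]:
            degenerate = True
            logger.warning("degenerate range: constant variable %r",
                           spec.variable)
    else:
        seen = []
        for v in values:
            if v is not None and not (isinstance(v, float) and math.isnan(v)):
                if v not in seen:
                    seen.append(v)
        domain = seen

    minx = min(g.bounds[0] for g in geometries.values())
    miny = min(g.bounds[1] for g in geometries.values())
    maxx = max(g.bounds[2] for g in geometries.values())
    maxy = max(g.bounds[3] for g in geometries.values())
    span_x = maxx - minx or 1.0
    span_y = maxy - miny or 1.0
    height = int(round(width * span_y / span_x))
    pad = 10

    def project(x, y):
        px = pad + (x - minx) / span_x * (width - 2 * pad)
        py = pad + (maxy - y) / span_y * (height - 2 * pad)  # flip y
        return px, py

    has_missing = False
    shapes = []
    for rid in joined.index:
        value = values.loc[rid]
        if value is None or (isinstance(value, float) and math.isnan(value)):
            fill = spec.missing_color
            has_missing = True
        elif degenerate:
            fill = _mid_color(spec)
        else:
            fill = color_for_value(value, spec, domain)
        path = _geometry_path(geometries[rid], project)
        shapes.append(
            f'<path d="{path}" fill="{fill}" stroke="#FFFFFF" '
            f'stroke-width="1"><title>{rid}: {value}</title></path>')

    legend = ['<g font-family="sans-serif" font-size="12">']
    ly = 20
    if spec.title:
        legend.append(f'<text x="{pad}" y="{ly}" font-size="14" '
                      f'font-weight="bold">{spec.title}</text>')
        ly += 20
    if spec.scale == "gradient" and not degenerate:
        steps = 8
        for i, frac_val in enumerate(np.linspace(domain[0], domain[1], steps)):
            c = color_for_value(float(frac_val), spec, domain)
            legend.append(f'<rect x="{pad + i * 18}" y="{ly}" width="18" '
                          f'height="12" fill="{c}"/>')
        legend.append(f'<text x="{pad}" y="{ly + 26}">{_fmt(domain[0])}</text>')
        legend.append(f'<text x="{pad + steps * 18}" y="{ly + 26}" '
                      f'text-anchor="end">{_fmt(domain[1])}</text>')
        ly += 40
    elif spec.scale == "gradient" and degenerate:
        legend.append(f'<rect x="{pad}" y="{ly}" width="18" height="12" '
                      f'fill="{_mid_color(spec)}"/>')
        legend.append(f'<text x="{pad + 24}" y="{ly + 10}">constant '
                      f'({_fmt(domain[0])})</text>')
        ly += 20
    else:
        for i, cat in enumerate(domain):
            c = CATEGORICAL_PALETTE[i % len(CATEGORICAL_PALETTE)]
            legend.append(f'<rect x="{pad}" y="{ly}" width="18" height="12" '
                          f'fill="{c}"/>')
            legend.append(f'<text x="{pad + 24}" y="{ly + 10}">{cat}</text>')
            ly += 16
    if has_missing:
        legend.append(f'<rect x="{pad}" y="{ly}" width="18" height="12" '
                      f'fill="{spec.missing_color}"/>')
        legend.append(f'<text x="{pad + 24}" y="{ly + 10}">missing</text>')
    legend.append("</g>")

    svg = (
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height + 70}" viewBox="0 0 {width} {height + 70}">\n'
        f'<g transform="translate(0,70)">\n' + "\n".join(shapes) + "\n</g>\n"
        + "\n".join(legend) + "\n</svg>\n"
    )

    out_path = str(out_path)
    if out_path.endswith(".html"):
        doc = ("<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
               f"<title>{spec.title or spec.variable}</title></head>"
               "<body style='margin:0'>\n" + svg + "</body></html>\n")
        with open(out_path, "w") as fh:
            fh.write(doc)
    else:
        with open(out_path, "w") as fh:
            fh.write(svg)
    return svg
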