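"""Rendering pain frequency maps: opacity coding, SVG overlay, HTML wrapper.

Each disjoint output rectangle is drawn on the blank body template as an
SVG ``<rect>`` in a single colour; the participant overlap is coded by
the element's opacity, so more commonly painful locations appear more
saturated and undrawn template areas stay white.
"""

from __future__ import annotations

import copy
import html
import os
from dataclasses import dataclass, field
from typing import IO

from lxml import etree

from .model import ContractError, FrequencyMap, Layout

__all__ = ["RenderConfig", "opacity", "render_svg", "render_html", "blank_template"]

SVG_NS = "http://www.w3.org/2000/svg"

_HTML_PAGE = """<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Pain frequency map</title>
<style>
body {{ font-family: sans-serif; margin: 1.5em; }}
.map {{ border: 1px solid #ccc; display: inline-block; }}
.controls {{ margin-top: 0.8em; max-width: 40em; }}
.gradient {{ height: 1em; background: linear-gradient(to right, #fff, {color}); border: 1px solid #999; }}
input[type=range] {{ width: 100%; }}
</style>
</head>
<body>
<h1>Pain frequency map{region_title}</h1>
<div class="map">
{svg}
</div>
<div class="controls">
<div class="gradient"></div>
<input type="range" id="threshold" min="0" max="1" step="0.0001" value="1">
<label for="threshold">show locations with overlap proportion &le;
<span id="threshold-value">1.0000</span></label>
</div>
<script>
var slider = document.getElementById("threshold");
function applyThreshold() {{
  var t = parseFloat(slider.value);
  document.getElementById("threshold-value").textContent = t.toFixed(4);
  var rects = document.querySelectorAll("g.pain-frequency-map rect");
  rects.forEach(function (r) {{
    var p = parseFloat(r.getAttribute("data-overlap-proportion"));
    r.style.visibility = p <= t ? "visible" : "hidden";
  }});
}}
slider.addEventListener("input", applyThreshold);
applyThreshold();
</script>
</body>
</html>
"""


def _validate_color(color: str) -> str:
    from matplotlib.colors import is_color_like

    if not is_color_like(color):
        raise ContractError(f"{color!r} is not a valid CSS color name or hex code")
    return color


@dataclass
class RenderConfig:
    """Rendering options.

    ``color`` is a CSS colour name or hex code (default ``#ff0000``,
    red). ``clip_shapes`` optionally maps a region label to an SVG
    fragment (e.g. a ``<path>``) used as a clip path so rectangles
    overflowing the region outline are hidden; off by default.
    """

    color: str = "#ff0000"
    layout: Layout = Layout.HORIZONTAL
    clip_shapes: dict[str, str] | None = None

    def __post_init__(self) -> None:
        _validate_color(self.color)
        self.layout = Layout(self.layout)


def opacity(frequency: int, max_frequency: int) -> float:
    """Opacity coding a rectangle's overlap frequency.

    ``frequency / (max_frequency + 1)``: strictly increasing in the
    frequency and strictly inside (0, 1) for every valid input, so even
    the most common location never fully saturates and the least common
    is never invisible.
    """
    if max_frequency < 1 or not 1 <= frequency <= max_frequency:
        raise ContractError(
            f"frequency {frequency} outside [1, {max_frequency}]"
        )
    return frequency / (max_frequency + 1)


def _parse_template(template) -> etree._Element:
    if isinstance(template, etree._Element):
        return copy.deepcopy(template)
    if isinstance(template, bytes):
        return etree.fromstring(template)
    if isinstance(template, str) and template.lstrip().startswith("<"):
        return etree.fromstring(template.encode("utf-8"))
    return etree.parse(str(template)).getroot()


def blank_template(width: float = 1000, height: float = 1000) -> bytes:
    """A minimal blank template: a white plane with a thin border, for
    rendering simulated data or maps without a digitized body outline."""
    root = etree.Element("{%s}svg" % SVG_NS, nsmap={None: SVG_NS})
    root.set("width", str(width))
    root.set("height", str(height))
    root.set("viewBox", f"0 0 {width} {height}")
    border = etree.SubElement(root, "{%s}rect" % SVG_NS)
    border.set("x", "0")
    border.set("y", "0")
    border.set("width", str(width))
    border.set("height", str(height))
    border.set("fill", "white")
    border.set("stroke", "#333333")
    return etree.tostring(root)


def render_svg(
    fm: FrequencyMap,
    template,
    cfg: RenderConfig | None = None,
) -> etree._Element:
    """Overlay a frequency map on the body template.

    Adds one ``<rect>`` per output rectangle inside a
    ``<g class="pain-frequency-map">`` group, filled with the configured
    colour at the opacity coding its overlap frequency; geometry
    attributes reproduce the rectangle fields exactly as decimal
    strings. Untouched template areas remain blank.
    """
    cfg = cfg or RenderConfig()
    root = _parse_template(template)
    group = etree.SubElement(root, "{%s}g" % SVG_NS)
    group.set("class", "pain-frequency-map")
    if cfg.clip_shapes and fm.region in cfg.clip_shapes:
        clip_id = f"region-clip-{fm.region}"
        clip = etree.SubElement(root, "{%s}clipPath" % SVG_NS)
        clip.set("id", clip_id)
        clip.append(etree.fromstring(cfg.clip_shapes[fm.region]))
        group.set("clip-path", f"url(#{clip_id})")
    fmax = fm.max_frequency
    for rect in fm.rects:
        el = etree.SubElement(group, "{%s}rect" % SVG_NS)
        el.set("x", str(rect.x))
        el.set("y", str(rect.y))
        el.set("width", str(rect.width))
        el.set("height", str(rect.height))
        el.set("fill", cfg.color)
        el.set("opacity", str(opacity(rect.overlap_frequency, fmax)))
        el.set("data-overlap-frequency", str(rect.overlap_frequency))
        el.set("data-overlap-proportion", f"{rect.overlap_proportion:.4f}")
    return root


def render_html(
    svg: etree._Element | bytes | str,
    fm: FrequencyMap,
    cfg: RenderConfig | None = None,
) -> str:
    """Wrap a rendered SVG in a self-contained HTML page with a slider
    that hides rectangles whose overlap proportion exceeds the chosen
    cutoff (at the maximum every rectangle is visible)."""
    cfg = cfg or RenderConfig()
    if isinstance(svg, (bytes, str)):
        svg_text = svg.decode("utf-8") if isinstance(svg, bytes) else svg
    else:
        svg_text = etree.tostring(svg, pretty_print=True).decode("utf-8")
    region_title = f" — {html.escape(fm.region)}" if fm.region else ""
    return _HTML_PAGE.format(color=cfg.color, region_title=region_title, svg=svg_text)


def write_svg(root: etree._Element, path_or_buf) -> None:
    data = etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    if isinstance(path_or_buf, (str, os.PathLike)):
        with open(path_or_buf, "wb") as fh:
            fh.write(data)
    else:
        path_or_buf.write(data)
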