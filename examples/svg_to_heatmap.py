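"""Full pipeline: SVG drawings -> recordings CSV -> overlap -> heat map.

Builds two small SVG pain drawings in a temporary directory (including
a drawn-then-erased mark), extracts the recordings, computes the
overlap decomposition and writes a self-contained HTML pain frequency
map. Run:

    python examples/svg_to_heatmap.py
"""

import tempfile
from pathlib import Path

from painmap import (
    blank_template,
    compute_overlap,
    load_drawing_set,
    render_html,
    render_svg,
)

DRAWING_A = """<svg xmlns="http://www.w3.org/2000/svg" width="200" height="200">
  <rect x="0" y="0" width="200" height="100" fill="white"/>
  <rect x="40" y="40" width="30" height="30" data-region="front"/>
  <rect x="60" y="60" width="30" height="30" data-region="front"/>
  <rect x="120" y="20" width="10" height="10" data-region="front" visibility="hidden"/>
</svg>"""

DRAWING_B = """<svg xmlns="http://www.w3.org/2000/svg" width="200" height="200">
  <rect x="50" y="50" width="60" height="60" data-region="front"/>
</svg>"""

with tempfile.TemporaryDirectory() as tmp:
    root = Path(tmp)
    (root / "patient-a.svg").write_text(DRAWING_A)
    (root / "patient-b.svg").write_text(DRAWING_B)

    ds = load_drawing_set(root, region_filter="front")
    print(f"extracted {len(ds.recordings)} visible unique recordings "
          f"from {ds.total_drawings} drawings "
          "(the erased 10x10 mark was dropped, the template rect skipped)")

    fm = compute_overlap(ds)
    print(f"\n{len(fm)} disjoint rectangles; "
          f"max overlap frequency {fm.max_frequency} of T={ds.total_drawings}")
    print(fm.to_frame().to_string(index=False))

    page = render_html(render_svg(fm, blank_template(200, 200)), fm)
    out = Path("scratch")
    out.mkdir(exist_ok=True)
    (out / "example_map.html").write_text(page)
    print(f"\nwrote {out / 'example_map.html'}: the shared area renders in a "
          "deeper red (higher opacity); the slider hides locations above a "
          "chosen overlap proportion.")
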