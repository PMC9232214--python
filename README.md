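# painmap

Grid-free quantification of freehand pain drawings on a 2D body
template, and rendering of pain frequency (heat) maps.

## The problem

In pain research and clinical screening, participants shade where it
hurts on a body outline ("body map" or manikin). Digital capture tools
record each pencil click as a small axis-aligned square (an SVG
`<rect>`), so a participant's drawing is a pile of overlapping squares
at arbitrary coordinates — no predefined grid cells. To summarise a
cohort, one wants to know, for every location on the template, *how
many distinct participants* reported pain there.

`painmap` answers this by decomposing all participants' rectangles
into **maximal disjoint rectangles**, each a unique template location
annotated with its *overlap set* `o` (the distinct participants
covering it), *overlap frequency* `|o|`, and *overlap proportion*
`|o| / T`, where `T` is the total number of submitted drawings,
including empty ones. The result renders as a heat map in which more
commonly painful locations appear more saturated.

## The algorithm

Let `R` be the visible, unique rectangles from all drawings of one
body region, each with top-left corner `(x, y)` and size `(w, h)`
occupying the half-open box `[x, x+w) × [y, y+h)`:

1. **Decomposition** — collect all edge coordinates `{x, x+w}` and
   `{y, y+h}` along each axis.
2. **Partitions** — consecutive distinct edges become half-open
   interval windows; x- and y-windows cross into grid cells.
3. **Overlap grid** — each covered cell gets the set of distinct
   participants with a rectangle containing it (several marks by one
   participant count once).
4. **Merging** — adjacent cells with identical overlap sets are fused
   into maximal rectangles: first maximal runs along the layout axis
   (*horizontal* → wider, *vertical* → longer rectangles), then runs of
   equal-extent results across the other axis.

The output tiles the drawn area exactly: three strictly nested squares
from three participants decompose into 9 rectangles (centre + 4 per
nesting ring); the same squares from one participant collapse to 1.

## Worked example

```python
from painmap import compute_overlap, fixtures

ds = fixtures("concentric3")       # nested squares, participants A/B/C
fm = compute_overlap(ds, layout="horizontal")
print(fm.to_frame().to_string(index=False))
```

```
   x    y  width  height  area overlap  overlap_frequency  overlap_proportion
20.0 20.0   60.0    10.0 600.0       A                  1            0.333333
20.0 30.0   10.0    40.0 400.0       A                  1            0.333333
30.0 30.0   40.0    10.0 400.0     A;B                  2            0.666667
70.0 30.0   10.0    40.0 400.0       A                  1            0.333333
30.0 40.0   10.0    20.0 200.0     A;B                  2            0.666667
40.0 40.0   20.0    20.0 400.0   A;B;C                  3            1.000000
60.0 40.0   10.0    20.0 200.0     A;B                  2            0.666667
30.0 60.0   40.0    10.0 400.0     A;B                  2            0.666667
20.0 70.0   60.0    10.0 600.0       A                  1            0.333333
```

Nine disjoint rectangles: the 20×20 centre is covered by all three
participants (proportion 3/3), the middle ring by A and B (2/3), the
outer ring by A alone (1/3). See `examples/` for the full
SVG-to-heat-map pipeline and a synthetic workload benchmark.

## Command line

The analysis is also a chainable three-step shell workflow (``-`` means
standard streams):

```sh
painmap extract drawings/ -o recordings.csv        # SVG files -> CSV
painmap overlap recordings.csv -o rects.csv        # overlap decomposition
painmap heatmap rects.csv -o map.html              # pain frequency map

# or piped:
painmap simulate -n 500 --seed 7 | painmap overlap - | painmap heatmap - -o map.html
```

`painmap overlap` supports layout choice, frequency/size filtering and
null-drawing masking (`--null-id`); `painmap heatmap` takes a custom
body template SVG and map colour; `painmap simulate` generates the
synthetic single-click and participant-drawing workloads.

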