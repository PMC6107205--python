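"""Convert per-tile classifier probabilities into continuous Ashcroft scores.

Each probability vector is ordered (p0, p1, p3, p5, p7, p_ignore). A tile is
dropped when the ignore mass is the strictly largest component; otherwise the
score classes are renormalized to sum to 1 and the score is their
weight-weighted sum, interpolating between the discrete Ashcroft grades.
"""

from histoscore import ASHCROFT, slide_score, tile_score

vectors = {
    "undecided between 1 and 3": [0.0, 0.5, 0.5, 0.0, 0.0, 0.0],
    "confident class 7": [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
    "spread with some ignore mass": [0.1, 0.2, 0.3, 0.2, 0.1, 0.1],
    "dominant ignore (dropped)": [0.08, 0.08, 0.08, 0.08, 0.08, 0.6],
}

tiles = []
for name, p in vectors.items():
    ts = tile_score(p, ASHCROFT, row=0, col=len(tiles))
    tiles.append(ts)
    shown = "ignored" if ts.ignored else f"A = {ts.score:.3f}"
    print(f"{name:32s} -> {shown}")

sc = slide_score(tiles)
print(f"\nslide mean over scored tiles: {sc.mean:.3f} "
      f"({sc.n_scored} scored, {sc.n_ignored} ignored)")
print("The 50/50 tile scores exactly 2 (0.5*1 + 0.5*3); the slide mean "
      "averages only the non-ignored tiles.")
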