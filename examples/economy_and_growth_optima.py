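"""Locate the shell-economy and rapid-growth optima in Raup morphospace.

The economy surface scores internal volume per unit of shell material
(wall thickness 7.7% of the whorl-section radius, walls shared between
adjoining whorls charged half each); the growth surface scores how fast a
shell's diameter outruns its material budget.  Both are scanned on the
standard (D, W) grid at circular aperture (S = 1) and polished locally.
"""

from ammopareto import argmax_on_grid, economy_performance, growth_performance
from ammopareto.performance import DEFAULT_GRID_2D, GROWTH_GRID

econ = argmax_on_grid(economy_performance(), DEFAULT_GRID_2D)
print(f"economy optimum:  D = {econ.point['D']:.3f}, W = {econ.point['W']:.3f}"
      f"  (ratio {econ.value:.2f}, boundary axes: {econ.on_boundary})")

growth = argmax_on_grid(growth_performance(), GROWTH_GRID)
print(f"growth optimum:   D = {growth.point['D']:.3f}, W = {growth.point['W']:.3f}")

print(
    "\nThe economy task favours tightly coiled involute shells (high D, "
    "W near 1), where almost every new wall is shared with the previous "
    "whorl; the growth task favours evolute, fast-expanding shells "
    "(low D, W > 4), whose diameter grows quickest per unit of material."
)
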