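"""Build the Pareto front implied by the three shell tasks.

Evaluates economy, growth and (stand-in) hydrodynamic performance on a
(D, W) grid and keeps the non-dominated phenotypes: shells that cannot be
improved at all three tasks at once.  The three single-task optima are
the archetypes; the front spans the region between them.
"""

from ammopareto import (
    GridSpec,
    drag_performance,
    economy_performance,
    front_on_grid,
    growth_performance,
)

grid = GridSpec(axes={"D": (0.0, 0.95, 61), "W": (1 + 1e-6, 5.0, 61)},
                fixed={"S": 1.0})
front = front_on_grid(
    [economy_performance(), growth_performance(), drag_performance()], grid
)

n = len(front.points)
print(f"grid points: {n}, on the Pareto front: {front.mask.sum()} "
      f"({100 * front.mask.mean():.0f}%)")
print("\nsingle-task archetypes (always on the front):")
for _, row in front.archetypes.iterrows():
    print(f"  {row['task']:<8} D = {row['D']:.3f}  W = {row['W']:.3f}")
print(
    "\nEach genus's position relative to these archetypes indicates the "
    "relative weight of the tasks in its niche; points off the front are "
    "dominated (improvable at every task simultaneously)."
)
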