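"""Simulate exploration loops and look at their basic geometry.

A bumblebee leaves its nest, explores with smoothly varying turning rate,
and after an exponentially distributed time (30 s on average) steers back
home.  Each simulated loop starts at the nest and ends on re-entering the
13 m nest disc.
"""

import numpy as np
from numpy.random import default_rng

from beeloop import ModelParams, simulate_loop
from beeloop.observables import loop_extension, loop_length

params = ModelParams()  # calibrated defaults
rng = default_rng(42)

print("  dur (s)  tau (s)  length (m)  extension (m)")
shown = 0
while shown < 8:
    loop = simulate_loop(params, nest=(0.0, 0.0), rng=rng)
    if loop_extension(loop, (0.0, 0.0)) <= params.nest_radius:
        continue  # switch fired before leaving the disc: not a loop
    print(f"{loop.track.times[-1]:9.1f}{loop.switch_time:9.1f}"
          f"{loop_length(loop):12.1f}"
          f"{loop_extension(loop, (0.0, 0.0)):15.1f}")
    shown += 1

# Duration is always >= tau (the bee cannot turn home before deciding to);
# length is speed x duration exactly (constant-speed flight); extension is
# how far from the nest the loop reached.
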