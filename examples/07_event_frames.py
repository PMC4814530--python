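"""From event-camera streams to binary training vectors.

Synthesizes a DVS-style event stream from a binary digit-like image embedded
in a 128x128 sensor, accumulates per-pixel event counts over a time window,
crops the most active 28x28 patch, and thresholds it into a binary vector —
the preprocessing chain for training on real event recordings.
"""

import numpy as np

import dendritic as dn
from dendritic.data import synthesize_events

rng = np.random.default_rng(0)
glyph = np.zeros((28, 28), dtype=int)
glyph[4:24, 12:16] = 1          # a crude "1"
glyph[20:24, 8:20] = 1

stream = synthesize_events(glyph, rng, rate_on=40.0, rate_off=0.1,
                           duration=2000.0, width=128, height=128,
                           offset=(50, 60))
print(f"stream: {stream.t.size} events over {stream.duration:.0f} ms")

for window in [(0.0, 100.0), (0.0, 2000.0)]:
    frame = dn.events_to_frame(stream, window)
    patch, (r, c) = dn.crop_max_activity(frame, 28)
    x = dn.threshold_image(patch, threshold=patch.max() / 4)
    print(f"window {window}: {frame.sum()} events, hottest 28x28 patch at "
          f"({r},{c}), {int(x.sum())} active pixels after thresholding")
print("Longer accumulation windows give denser, cleaner frames; the cropped "
      "binary vector is what the classifier trains on.")
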