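"""Anchor an externally estimated Ne-per-generation table to calendar time.

Linkage-disequilibrium methods output Ne for a grid of generations before
sampling. Converting the breed's registry-recognition year to generations
(3.76 years per generation) splits the timeline, and the slopes on either
side say whether the breed lost breeding animals faster before or after
recognition.
"""

import numpy as np

import breedstruct as bs
from breedstruct.profiles import NeTimeline

# synthetic decline: steep loss long ago, slower in the registry era
gens = np.arange(13, 300, 1.0)
ne = 80 + 1.8 * (gens - 13) + 0.012 * (gens - 13) ** 2
tl = NeTimeline(generations_ago=gens, ne=ne, anchor_year=2015)

res = bs.ne_timeline_slopes(tl, recognition_year=1915)
print(f"recognition year 1915 = {res.gen_at_recognition:.1f} generations "
      f"before sampling")
print(f"Ne at recognition: {res.ne_at_recognition:.0f}")
print(f"slope after recognition:  {res.slope_post:+.2f} breeding dogs "
      "per generation")
print(f"slope before recognition: {res.slope_pre:+.2f}")
print(f"difference (pre - post):  {res.slope_difference:+.2f}")
# Positive slopes mean Ne was larger further back: the breed has been
# shrinking. A positive difference says the shrinkage per generation was
# faster before the registry recognized the breed.
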