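"""Strand-specific 5' count profiles reveal the nick as a one-nucleotide
Watson-strand spike facing a diffuse Crick-strand zone.

The 5' count at a position/strand is the number of read 5' ends mapping
there.  A persistent nick puts a 5' end at one exact Watson coordinate in
every imprinted chromatid; the weakened opposite strand instead breaks
anywhere in a ~20-nt zone, spreading its excess.
"""

import numpy as np

from nickscan import SonicationParams, build_mat_region, compute_five_prime_counts, simulate_library

genome = build_mat_region("M_donorless")
params = SonicationParams(n_molecules=30_000, imprint_fraction=0.3, seed=7)
profile = compute_five_prime_counts(simulate_library(genome, params), genome)
nick = genome.nick_sites[0][0]

print(f"library size {profile.library_size:,}; nick at {nick}")
print(f"Watson 5' count at nick: {profile.watson[nick]}  "
      f"(background median {int(np.median(profile.watson[1:-1]))})")
print("Crick 5' counts around the nick (nick-12 .. nick+9):")
print("  ", profile.crick[nick - 12 : nick + 10].tolist())
# The Watson spike is tens of standard deviations above background at one
# position; the Crick excess is ~1/20 as high per position, spread over the
# 20-nt weakened zone.
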