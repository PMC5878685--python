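"""Binned RPKM tracks and an IP/WCE enrichment ratio.

Emulates a chromatin-immunoprecipitation display: a whole-cell-extract
(WCE) library covering the locus uniformly and an IP library concentrated
around the nick, both reduced to 1-kb RPKM tracks and divided bin by bin.
"""

import numpy as np

from nickscan import (
    SonicationParams,
    build_mat_region,
    enrichment_track,
    rpkm_track,
    simulate_library,
)

genome = build_mat_region("M_donorless")
nick = genome.nick_sites[0][0]
wce_reads = simulate_library(genome, SonicationParams(n_molecules=10_000, imprint_fraction=0.3, seed=2))

# IP-like footprint: keep reads whose 5' end is within 1.5 kb of the nick
five = np.where(wce_reads.is_reverse, wce_reads.end - 1, wce_reads.start)
ip_reads = wce_reads[np.abs(five - nick) <= 1500]

ip = rpkm_track(ip_reads, genome, bin_size=1000)
wce = rpkm_track(wce_reads, genome, bin_size=1000)
ratio = enrichment_track(ip, wce)

print(f"bins: {len(ratio)} x {ratio.bin_size} nt; nick in bin {nick // 1000}")
print("enrichment ratio per bin:")
print("  ", np.round(ratio.values, 2).tolist())
# Bins inside the IP footprint show ratios near the inverse of the captured
# fraction; bins outside drop towards the pseudocount floor.
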