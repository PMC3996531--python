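"""Resolving expressed retrocopy junctions from RNA reads by k-mer mapping.

Reads that fail to map to known transcripts are shattered into 13-mers,
each placed at a unique genome position and extended base-by-base; the
boundary between adjacent uniquely extended fragments is the expressed
fusion breakpoint (e.g. a retrocopy transcribed from a host gene's UTR).
"""

import numpy as np

from retrocopy import GenomeKmerIndex, resolve_expressed_junction
from retrocopy.models import revcomp

rng = np.random.default_rng(11)
bases = np.array(list("ACGT"))
genome = {
    "chr1": "".join(bases[rng.integers(0, 4, 5000)]),
    "chr2": "".join(bases[rng.integers(0, 4, 5000)]),
}
index = GenomeKmerIndex(genome)

# a chimeric RNA read: 40 bp of retrocopy (chr1) then 35 bp of host UTR (chr2)
read = genome["chr1"][1200:1240] + genome["chr2"][3000:3035]
junctions = resolve_expressed_junction([read], {}, index)
print(f"chimeric read -> junction: {junctions[0][0]} | {junctions[0][1]}")

# an ordinary transcriptomic read is consumed by the known-junction database
tx = {"t1": genome["chr1"][1000:2000]}
print("fully transcriptomic read resolved junctions:",
      resolve_expressed_junction([genome['chr1'][1100:1175]], tx, index))

# antisense fragments are located on the minus strand
rc_read = revcomp(genome["chr1"][1200:1240]) + genome["chr2"][3000:3035]
print("reverse-strand fragment junction:",
      resolve_expressed_junction([rc_read], {}, index)[0])

# The printed coordinates are the last genome base of the upstream
# fragment and the first base of the downstream fragment — the expressed
# breakpoint at single-base resolution.
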