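"""Build phantomized, diluted fiber lattices and check the connectivity law.

The mean number of bonds at the cross-linked node of each site follows
z = pbond * (6*(1-pphan) + 4*pphan): dilution removes bonds, phantom
crossings remove cross-links without removing fibers.
"""

import numpy as np

from emtecm import LatticeSpec, average_connectivity, build_lattice

print(f"{'pbond':>6} {'pphan':>6} {'z (measured)':>13} {'z (mean-field)':>15}")
for pbond, pphan in [(1.0, 0.0), (1.0, 1.0), (0.8, 0.3), (0.9, 0.7)]:
    vals = [
        average_connectivity(build_lattice(LatticeSpec(20, 20, pbond, pphan, seed=s)))
        for s in range(20)
    ]
    z_mf = pbond * (6 * (1 - pphan) + 4 * pphan)
    print(f"{pbond:6.2f} {pphan:6.2f} {np.mean(vals):13.4f} {z_mf:15.4f}")

print()
print("Measured z is the per-site bond count at the primary node, averaged")
print("over 20 random 20x20 lattices; it matches the mean-field law to")
print("sampling error, and is exact (6 and 4) at the two deterministic corners.")
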