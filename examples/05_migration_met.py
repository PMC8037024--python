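"""EMT-to-MET transition of cells migrating away from the tumor.

Cells leave the tumor edge in a mesenchymal state and move radially at
constant speed through the static LOXL2 field.  The mechanosensing
signal falls with distance; where the total signal drops below the
mesenchymal fold, ZEB collapses (MET).  Tumors with higher LOXL2 output
(alpha*rho/lambda) support mesenchymal travel farther out.
"""

from emtecm import CircuitParams, FieldParams
from emtecm.migration import MigrationSetup, met_location, simulate_migration

p = CircuitParams()
print(f"{'alpha*rho/lambda':>17} {'MET radius':>11} {'decay length':>13}")
for c0 in (1e5, 2e5, 4e5, 8e5):
    field = FieldParams(alpha=c0 * 0.1, rho=1.0, lam=0.1, D=40.0, R=10.0)
    setup = MigrationSetup(field=field, circuit=p, v=0.05,
                           I_background=20_000.0, t_max=6000.0)
    r_met = met_location(simulate_migration(setup))
    print(f"{c0:17.0f} {r_met:11.1f} {field.decay_length:13.1f}")
print()
print("MET radius: first distance (lattice units) at which ZEB mRNA falls")
print("below 10% of its tumor-edge value.  It grows with tumor secretion;")
print("cells must reach vasculature before this radius to seed metastasis.")
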