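"""Waiting-time profiles W(s): how long each monomer spends in the pore.

For a semiflexible chain (kappa = 40) the trans-side subchain stays
stretched; when it first touches the far membrane it must start spreading
laterally, which shows up as an early peak (or cusp) in W(s). For a
flexible chain (kappa = 10) the profile is a smooth hump instead.
"""

import numpy as np

from poreslab import SimParams, peak_position
from poreslab.engine import run_ensemble

base = SimParams(n_bonds=25, e_field=5.0, r_sep=5.0, kappa=10.0,
                 max_mcs=2_000_000)

for kappa in (10.0, 40.0):
    ens = run_ensemble(base.replace(kappa=kappa), n_samples=30, base_seed=7)
    w = ens.w_mean
    peak = peak_position(w, (2, base.n_bonds - 2))
    print(f"kappa = {kappa:4.0f}:  W(s) in MCS, s = 0 (head) .. N (tail)")
    print("  ", np.array2string(np.round(w, 0), max_line_width=76))
    print(f"   early peak/cusp at s = {peak}"
          if peak >= 0 else "   no early peak (monotone rise)")
    print()

print("The peak position marks roughly how many monomers fit between the")
print("membranes before the trans-side subchain has to bend sideways.")
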