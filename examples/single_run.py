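"""Run a small ensemble at one parameter point and read off the basics.

A chain of N+1 = 26 charged monomers is equilibrated on the cis side,
released at t = 0, and driven through the pore by the field E = 5 into a
slab of width R = 5. Each sample reports its translocation time tau (in
Monte Carlo steps), how often the chain withdrew and restarted, and the
trial-move acceptance rate.
"""

from poreslab import SimParams
from poreslab.engine import run_ensemble

params = SimParams(n_bonds=25, kappa=10.0, e_field=5.0, r_sep=5.0,
                   max_mcs=2_000_000)
ens = run_ensemble(params, n_samples=20, base_seed=1)

print(f"N = {params.n_bonds}, kappa = {params.kappa}, "
      f"E = {params.e_field}, R = {params.r_sep}")
print(f"mean tau     = {ens.tau_mean:8.0f} +/- {ens.tau_se:.0f} MCS")
print(f"acceptance   = {100 * ens.acceptance_mean:8.1f} %")
print(f"mean retries = "
      f"{sum(r.attempts for r in ens.records) / ens.n_success:8.1f} "
      "attempts per success")
print()
print("tau is the time from releasing the head monomer until the whole")
print("chain has passed the pore exit plane; retries count how often the")
print("chain withdrew fully to the cis side and the attempt restarted.")
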