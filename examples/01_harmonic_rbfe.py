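"""End-to-end relative transfer free energy on the harmonic host-guest.

Builds the two-ligand toy system whose transfer free energy is known in
closed form (ligand A sits in a k = 4 binding-site well and moves to a
k = 1 bulk well; ligand B feels k = 1 everywhere), runs both ATM legs
with lambda replica exchange, and estimates the free energy with UWHAM.
"""

import atmkit as ak

system = ak.make_harmonic_host_guest(k_site=4.0, k_bulk=1.0, k_site_b=1.0,
                                     k_bulk_b=1.0, kT=1.0)
run = ak.RunSpec(seed=7, n_windows=11, n_steps=10000, exchange_interval=250,
                 sample_interval=250, friction=10.0, anneal_steps=2750,
                 equil_steps=1000, replicate_count=3)

result = ak.run_rbfe(system, run, mode="mm")

print(f"analytic   ddG = {system.analytic_ddg:+.4f} kcal/mol "
      "(= -(3/2) ln 4 at kT = 1)")
print(f"estimated  ddG = {result.ddg:+.4f} ± {result.sigma:.4f} kcal/mol "
      f"({run.replicate_count} replicates, SEM)")
for rep, (ddg, sigma) in enumerate(result.replicate_ddgs):
    print(f"  replicate {rep}: {ddg:+.4f} ± {sigma:.4f}")
print(f"mean neighbor exchange acceptance: "
      f"{result.mean_exchange_acceptance:.2f}")
print("The estimate should bracket the analytic value within ~2 SEM; the")
print("acceptance near 1 reflects the dense lambda ladder on this easy system.")
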