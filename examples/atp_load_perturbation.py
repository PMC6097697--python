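"""Catalytic-potential plots: step the ATP load and watch the three kinases.

A 50% increase (factor 1.5) in the ATP-hydrolysis rate constant drains the
adenylate pool; each kinase modulates its catalytically active fraction f_A
to bring the system back to a homeostatic state.  PFK responds inversely to
the energy charge (AMP activation / ATP inhibition), while HEX and PYK move
with it.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import catpot as cp

ref = cp.nominal_reference_state()
model = cp.build_rbc_model(ref, modules=("PFK", "HEX", "PYK"))

for factor in (1.5, 0.85):
    res = cp.perturb_atp_utilization(model, factor)
    ec = res.curve.energy_charge
    print(f"\nATP load x{factor}: energy charge {ec[0]:.3f} -> {ec[-1]:.3f}, "
          f"net-ATP SSE {res.sse:.3g}")
    for enzyme in ("PFK", "HEX", "PYK"):
        fa = res.curve.fa[enzyme]
        rho = cp.fa_ec_correlation(res, enzyme)
        rel = "inverse" if rho < 0 else "direct"
        print(f"  {enzyme}: f_A {fa[0]:.3f} -> {fa[-1]:.3f}  "
              f"corr(f_A, EC) = {rho:+.2f} ({rel} relation)")

res = cp.perturb_atp_utilization(model, 1.5)
fig, axes = plt.subplots(1, 3, figsize=(10, 3), constrained_layout=True)
for ax, enzyme in zip(axes, ("PFK", "HEX", "PYK")):
    cp.plot_catalytic_potential(res, enzyme, ax=ax)
fig.savefig("scratch_catalytic_potential.png", dpi=120)
print("\nwrote scratch_catalytic_potential.png "
      "(f_A vs energy charge; the dot marks the homeostatic reference)")
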