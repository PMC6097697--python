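"""Pairwise interplay of the kinases in the fully regulated model.

Phase portraits plot the active fraction of one kinase against another along
the response to an ATP-load step.  PFK moves opposite to HEX (as PFK
activates, HEX is driven into inactive complexes), while HEX and PYK move in
tandem - they sit at the boundaries of the system and are linked through the
adenylate pool.
"""

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

import catpot as cp

ref = cp.nominal_reference_state()
model = cp.build_rbc_model(ref, modules=("PFK", "HEX", "PYK"))
res = cp.perturb_atp_utilization(model, 1.5)

pairs = [("PFK", "HEX"), ("HEX", "PYK"), ("PFK", "PYK")]
fig, axes = plt.subplots(1, 3, figsize=(10, 3), constrained_layout=True)
for ax, pair in zip(axes, pairs):
    portrait = cp.phase_portrait(res, pair)
    cp.plot_phase_portrait(portrait, ax=ax)
    sign = "negative" if portrait.correlation < 0 else "positive"
    print(f"{pair[0]:>4s} vs {pair[1]}: {sign} association "
          f"(rank correlation {portrait.correlation:+.2f})")
fig.savefig("scratch_phase_portraits.png", dpi=120)
print("wrote scratch_phase_portraits.png")
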