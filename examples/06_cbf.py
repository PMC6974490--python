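"""Quantify CBF from the phantom's pCASL triplet and check the round trip.

The phantom encodes a known flow field (white matter 33.73, lesions 30.05,
grey matter 60 ml/100 g/min) through the inverse of the consensus
single-compartment pCASL equation; cbf_map must decode it exactly at zero
noise.
"""

import numpy as np

from myelinpet import PhantomSpec, build_phantom, cbf_map

res = build_phantom(PhantomSpec(seed=1))
cbf = cbf_map(res.asl["control"], res.asl["label"], res.asl["m0"], res.spec.asl_params)

for name, mask in (("grey matter", res.masks["gm"]),
                   ("white matter", res.truth.label_map == 2),
                   ("lesions", res.masks["t2_lesions"] != 0)):
    est = cbf.values[mask].mean()
    true = res.truth.cbf_map_true[mask].mean()
    print(f"{name:<13} CBF {est:6.2f} ml/100g/min (truth {true:6.2f})")
err = np.abs(cbf.values - res.truth.cbf_map_true)[res.masks["brain"]].max()
print(f"max absolute error in brain: {err:.2e} ml/100g/min")
print("Lesional flow ~11% below white matter reflects the hypoperfusion of "
      "demyelinated tissue the phantom emulates.")
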