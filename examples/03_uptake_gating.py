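"""Flow-cytometry-style uptake gating.

Simulates fluorescence intensities for a treated population (a mixture of
labelled and unlabelled cells) and an untreated control, places the gate at
the control's 99th percentile, and reports percent positive — the readout
used to compare folate-targeted against plain vesicles.
"""

import holoqpi as h

n = 10_000
for k, label in enumerate(("si-EV", "fol-si-EV", "DOX-EV", "fol-DOX-EV")):
    p = h.UPTAKE_FRACTIONS[label]
    treated = h.simulate_flow_events(p, n, seed=100 + 2 * k)
    control = h.simulate_flow_events(0.0, n, seed=101 + 2 * k)
    r = h.gate_positive(treated, control)
    print(f"{label:>11}: gated {r.percent_positive:5.2f} % positive "
          f"(generating fraction {100 * p:5.2f} %)")
print("-> folate conjugation roughly doubles siRNA-EV uptake; the gate "
      "admits ~1 % of negatives by construction.")
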