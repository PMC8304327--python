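"""Secretion quantification from capillary-western signals, plus the
ATP/ADP probe-binding readout.

Signals from conditioned medium (CM) and cell lysate are scaled to whole
samples, turned into absolute CM ratios, and corrected by the beta-actin
baseline of accidental release to estimate the regulated secreted
fraction of each construct.
"""

import pandas as pd

from hsp90cl import cwb
from hsp90cl import simulate as sim

meas, truth = sim.simulate_cwb_signals(
    sim.CwbTruth(secreted_fraction={"WT": 0.016, "AA": 0.045},
                 baseline_release=0.03, noise_sd=0.1), seed=5)
ratios = cwb.absolute_ratio_table(meas)
estimates, p = cwb.secreted_fraction(ratios[ratios["target"] == "HA"],
                                     ratios[ratios["target"] == "actin"])

print("simulated truth: WT secretes 1.6%, AA 4.5%, baseline release 3%\n")
for e in sorted(estimates, key=lambda e: e.construct):
    print(f"  {e.construct}: secreted fraction {e.mean:.1%} +/- {e.sd:.1%} "
          f"(n={e.n}, actin baseline {e.baseline:.1%})")
print(f"  WT vs AA Student t-test: p = {p:.3f}")
print("the estimate is the HA absolute CM ratio minus the mean actin "
      "ratio,\nso only regulated (non-accidental) release remains.\n")

# probe binding: desthiobiotin-ATP/-ADP signal normalized by bait amount;
# three replicates per construct and nucleotide
signals = {("WT", "ATP"): [43, 46, 49], ("AA", "ATP"): [48, 53, 58],
           ("WT", "ADP"): [30, 34, 38], ("AA", "ADP"): [29, 35, 41]}
rows = []
for (construct, nucleotide), values in signals.items():
    for rep, desthio in enumerate(values, start=1):
        rows.append(("desthiobiotin", construct, nucleotide, rep, desthio))
        rows.append(("HA", construct, nucleotide, rep, 100.0))
probe = pd.DataFrame(rows, columns=["target", "construct", "nucleotide",
                                    "replicate", "signal"])
per_rep, summary = cwb.probe_binding(probe)
print("probe binding (desthiobiotin / HA-tag signal):")
print(summary.to_string(index=False))
print("both constructs label more with the ATP probe than the ADP probe,"
      "\nand neither nucleotide shows a significant WT-vs-AA difference -"
      "\nthe linker mutations leave nucleotide-pocket occupancy intact.")
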