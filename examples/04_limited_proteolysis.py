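"""Limited-proteolysis readouts on simulated gel-band peptide intensities.

WT and the phospho-dead AA mutant are digested with 0/7/14 ng/uL trypsin;
peptide intensities per gel band report how much full-length protein
remains and where the dominant cleavage occurs (after K607 in the C
domain).
"""

from hsp90cl import proteolysis as pl
from hsp90cl import simulate as sim

matrix, truth = sim.simulate_proteolysis_bands(
    sim.ProteolysisTruth(noise_sd=0.05), seed=3)

ffl = pl.fraction_full_length(matrix)
print("fraction of full-length protein remaining (median over peptides):")
print(pl.summarize_ratios(ffl)[["genotype", "dose", "median", "n"]]
      .to_string(index=False))
print("\nconfigured truth for comparison:")
print(truth.to_string(index=False))

comparisons = pl.compare_genotypes(ffl)
print("\nWT vs AA per dose (Welch t on per-peptide ratios, BH over doses):")
print(comparisons.to_string(index=False))
print("\nAA loses full-length protein faster at every positive dose - the"
      "\nnon-phosphorylatable linker makes the C domain more accessible.")

bvl = pl.band_vs_lane_ratio(matrix)
sides = pl.assign_cleavage_side(
    matrix[["peptide", "start", "end"]].drop_duplicates())
merged = bvl.merge(sides, on="peptide")
at_dose = merged[(merged["dose"] == 7.0) & (merged["side"] != "spanning")]
print("\nband-A / lane ratio at 7 ng/uL by side of K607 (median):")
print(at_dose.groupby("side")["ratio"].median().to_string())
print("peptides after the cut keep their signal in band A because the"
      "\nsmall C-terminal fragment runs below the analyzed lane range.")
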