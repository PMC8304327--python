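"""Co-occupancy bounds and phosphate stoichiometry from site occupancies.

Given marginal occupancies of two sites, the Frechet bounds delimit the
fraction of protein monomers modified at both sites without any assumption
about coupling between the sites.
"""

from hsp90cl import co_occupancy_bounds, phosphate_stoichiometry

p_s226, p_s255 = 0.95, 0.95
lower, upper, independent = co_occupancy_bounds(p_s226, p_s255)

print(f"Marginal occupancies: S226 = {p_s226:.0%}, S255 = {p_s255:.0%}\n")
print(f"doubly phosphorylated monomers: {lower:.0%} to {upper:.0%}")
print(f"  lower bound ({lower:.0%}): sites anti-coupled as far as possible")
print(f"  upper bound ({upper:.0%}): phosphorylation fully coupled")
print(f"  independence point:         {independent:.2%}")

moles = phosphate_stoichiometry([p_s226, p_s255])
print(f"\nphosphate stoichiometry: {moles:.1f} mol phosphate / mol protein")
print("(the sum of site occupancies - what a bulk phosphate assay would see)")
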