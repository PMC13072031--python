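"""Resorption indices from published group mean concentrations.

Builds the four needle groups (apical/basal x healthy/chlorotic) from the
reference study's mean C/N/P concentrations and computes the resorption
efficiency of N and P plus the resorption priority index per condition.
"""

from needlestoich import ratios_from_concentrations, resorption_efficiency, resorption_priority

GROUP_MEANS = {  # mg/g dry mass
    "AH": {"c": 447.8, "n": 21.9, "p": 8.3},
    "BH": {"c": 481.8, "n": 12.8, "p": 4.3},
    "AC": {"c": 461.4, "n": 24.7, "p": 7.9},
    "BC": {"c": 472.4, "n": 7.2, "p": 1.6},
}

print("group  C:N     C:P     N:P")
for g, m in GROUP_MEANS.items():
    r = ratios_from_concentrations(m["c"], m["n"], m["p"])
    print(f"{g}    {r.c_n:6.2f}  {r.c_p:6.2f}  {r.n_p:5.2f}")

print()
for cond, (apical, basal) in (("healthy", ("AH", "BH")), ("chlorotic", ("AC", "BC"))):
    nre_n = resorption_efficiency(GROUP_MEANS[apical]["n"], GROUP_MEANS[basal]["n"])
    nre_p = resorption_efficiency(GROUP_MEANS[apical]["p"], GROUP_MEANS[basal]["p"])
    rpi, label = resorption_priority(nre_n, nre_p)
    print(f"{cond:9s}  NRE_N = {nre_n:5.2f}%   NRE_P = {nre_p:5.2f}%   RPI = {rpi:.3f} ({label})")

print(
    "\nNRE is the percent of the nutrient withdrawn from basal needles; the\n"
    "chlorotic trees withdraw far more N and P than healthy ones, and RPI\n"
    "near 1 means both nutrients are withdrawn together."
)
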