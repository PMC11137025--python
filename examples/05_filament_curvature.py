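"""Curvature analysis of synthetic buckled microtubule traces.

Generates the pinned wild-type and vimentin-null filament populations
(~100 filaments each, sinusoidal buckles plus tracing noise), measures
per-filament mean curvature by the smoothed three-point circumradius, and
compares the genotypes with an unpaired two-sided t test.
"""

from cytomech import genotype_filament_sets, population_compare

wt, ko = genotype_filament_sets(n_per_group=100, seed=0)
res = population_compare(wt, ko)

print(f"wild-type mean curvature     : {res['mean_a']:.4f} 1/um  ({len(wt)} filaments)")
print(f"vimentin-null mean curvature : {res['mean_b']:.4f} 1/um  ({len(ko)} filaments)")
print(f"t statistic = {res['t_statistic']:.2f}, two-sided p = {res['p_value']:.3g}")
print()
print("without lateral reinforcement by the vimentin network, compressed")
print("microtubules buckle with a larger amplitude-to-wavelength ratio, so")
print("vimentin-null filaments carry systematically higher curvature.")
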