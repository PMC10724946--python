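"""Generate a small synthetic multi-cohort panel and inspect its truth.

The generator plants co-expression modules (shared latent factors),
tumor-vs-normal shifts, proteome-specific shifts and hub regulators,
and returns the ground truth alongside the matrices.
"""

import pancanet as pc

specs = pc.reference_panel_specs(n_cohorts=3, n_tumor=30, n_normal=20)
plan = pc.reference_module_plan()  # one pan module (40), two specific (30)
panel = pc.generate_cohort_panel(specs, n_genes=300, module_plan=plan, seed=1)

print(f"cohorts: {panel.cohorts}")
for c in panel.cohorts:
    print(f"  {c}: proteome {panel.proteome[c].shape}, "
          f"{len(panel.truth.dep_genes[c])} differential genes, "
          f"{len(panel.truth.proteome_specific_genes[c])} proteome-specific, "
          f"regulators {sorted(panel.truth.regulators[c])}")

# The pan module is active everywhere; specific modules in one cohort each.
for m in panel.truth.modules:
    where = "all cohorts" if m.is_pan else ",".join(m.cohorts)
    print(f"module {m.module_id}: {len(m.member_genes)} genes in {where}, "
          f"hub {m.regulator}")
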