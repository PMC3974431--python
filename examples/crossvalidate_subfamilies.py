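"""Leave-one-out cross-validated discrimination of wing shapes by group.

Two demonstrations: (1) hit ratios recomputed from the reference bee
study's printed cross-validation counts; (2) a fresh LOO cross-validation
on synthetic wings at the same sample sizes, with strong group separation.
"""

from wingmorph import (
    SyntheticSpec,
    gpa,
    hit_ratios,
    loo_crossvalidate,
    project_to_tangent,
    reference_confusion,
    simulate_dataset,
)

# --- printed reference table, recomputed -----------------------------------
hr = hit_ratios(reference_confusion())
print("reference study's printed cross-validation counts, recomputed:")
print(f"  overall hit ratio {hr.overall:.2f}% ({hr.n_misclassified} of 360 misclassified)")
print(f"  Apinae {hr.per_group_display['Apinae']}%, Panurginae {hr.per_group_display['Panurginae']}%")

# --- fresh cross-validation on synthetic wings ------------------------------
spec = SyntheticSpec(seed=42, effect_size=0.1)  # 15 groups, 360 wings, clear separation
dataset = simulate_dataset(spec)
scores = project_to_tangent(gpa(dataset)).matrix
confusion = loo_crossvalidate(scores, list(dataset.labels()))
hr_syn = hit_ratios(confusion)
print("\nsynthetic 15-group study (separation well above noise):")
print(f"  overall hit ratio {hr_syn.overall:.2f}% ({hr_syn.n_misclassified} misclassified)")
print("  -> distinct mean shapes at these sample sizes are recovered near-perfectly;")
print("     each held-out wing is classified by refitting PCA+LDA without it")
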