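# wingmorph

Landmark-based geometric morphometrics for taxonomic assignment of insect
wings: generalized Procrustes superimposition, tangent-space statistics,
cross-validated linear discriminant analysis, and Mahalanobis/posterior
placement of unknown specimens — the workflow used to decide where a fossil
bee wing belongs among living subfamilies.

## The problem

Wing venation is one of the few characters a compression fossil preserves
well. The intersections of wing veins are homologous across bees, so a wing
can be reduced to *k* = 18 planar landmarks and compared quantitatively with
wings of living species. The questions this package answers:

1. Do wing shapes discriminate the candidate taxa at all (here: 15 bee
   subfamilies, 360 reference specimens)?
2. If so, to which taxon does an unknown wing — digitized several times by
   several people — belong, and with what confidence?

## The method

**Superimposition.** Each configuration is centred and scaled to unit
centroid size (CS = √Σᵢ‖xᵢ − x̄‖²), then all are iteratively rotated onto a
consensus by generalized Procrustes analysis (GPA). What remains is shape in
Kendall's sense. Aligned shapes are projected into the Euclidean space
tangent to shape space at the consensus; the adequacy of that linearization
is verified by the through-origin regression of tangent distances on
Procrustes ρ distances over all specimen pairs (slope ≈ 1 is required, and
obtained, in the small-variation regime).

**Discrimination.** Tangent coordinates for k planar landmarks span at most
2k − 4 dimensions, so the pooled covariance is singular on raw coordinates;
discrimination therefore runs on retained principal components. Linear
discriminant analysis with group priors π_g yields, for any specimen score
**x**, Mahalanobis distances to each group mean

  MD_g = √((**x** − **μ**_g)ᵀ Σ⁻¹ (**x** − **μ**_g)),  Σ = pooled within-group covariance,

and posterior probabilities PP_g ∝ π_g · exp(−MD_g²/2). Performance is
reported as leave-one-out cross-validated hit ratios (PCA + LDA refitted in
every fold).

**Assignment.** Reference and unknowns are superimposed jointly, the
discriminant space is fitted on the reference only, and unknowns are pushed
through the same maps *a posteriori*. Replicate digitizations of one
physical specimen stay independent rows and are summarized by a modal vote.

Because the reference study's raw coordinates were never deposited, the
package ships a synthetic generator (`simulate_dataset`) reproducing the
data's statistical structure — group-distinct mean shapes, isotropic
landmark noise, similarity-transform nuisance, replicate digitization error
— at the study's exact sample sizes, plus the study's printed tables
(`reference_confusion`, `study_design`) for worked examples.

## Worked example

```python
from wingmorph import (SyntheticSpec, simulate_dataset, simulate_replicates,
                       assign_unknowns, hit_ratios, reference_confusion)

# hit ratios recomputed from the reference study's printed counts
hr = hit_ratios(reference_confusion())
print(hr.overall, hr.n_misclassified)   # 98.61  5

# synthetic fossil placement at the study's sample sizes
spec = SyntheticSpec(seed=42, effect_size=0.1)
reference = simulate_dataset(spec)              # 360 wings, 15 subfamilies
replicates = simulate_replicates(spec, "Andreninae", 8)
report = assign_unknowns(reference, replicates,
                         replicate_of={r.specimen_id: "fossil" for r in replicates})
s = report.summaries[0]
print(s.assigned_group, s.agreement)    # Andreninae  1.0
print(s.md_range, s.pp_range)           # (6.56, 8.04)  (1.0000, 1.0000)
```

All eight replicate digitizations vote for the true source subfamily with
posterior probability ≈ 1; the Mahalanobis distances are reported in the
full retained-PC space (32 dimensions here). The `examples/` directory has
one narrative script per capability, and the `wingmorph` command exposes the
same pipeline from the shell (`wingmorph simulate`, `superimpose`,
`adequacy`, `crossvalidate`, `assign`, `run`).

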