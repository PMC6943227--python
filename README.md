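# fmt-engraft

Donor engraftment analysis for fecal microbiota transplantation (FMT)
cohorts, at three resolutions: community, species and strain.

After an FMT, a recipient's gut community is a mixture — species and
strains from the donor, survivors of the recipient's own baseline
community, and newcomers from the environment. `fmt_engraft` takes the
profiled outputs of a shotgun metagenomic study (an mOTU-style
relative-abundance table, a per-position SNV table, a cohort manifest and a
clinical-metadata table) and quantifies that mixture for cohorts of
inflammatory-bowel-disease (CD/UC) recipients and their donors:

* **Community** — Shannon diversity H = −Σ pᵢ ln pᵢ, Kruskal–Wallis
  multigroup comparison, Bray–Curtis on log-transformed abundances
  (pseudo-abundance x₀ = 10⁻⁶), cosine similarity, and the Euclidean
  geometry of the baseline→post-FMT shift relative to the donor.
* **Species** — every taxon detected (≥ 0.001) in a post-FMT sample is
  classified as donor-specific, recipient-specific, common or new by
  comparing detection in the donor and the recipient's baseline; per-sample
  count and abundance fractions summarise donor gain per disease subtype.
* **Strain** — determinant SNV positions (alleles that distinguish the
  donor strain from the recipient's baseline strain of the same species)
  are defined from baseline alone and tracked over visits: donor/recipient
  retention fractions, coexistence vs displacement classification, and the
  rate of newly arising SNVs. An autologous arm yields empty determinant
  sets and serves as the noise-floor control.
* **Prediction** — one bagged-tree presence classifier and abundance
  regressor per taxon, from donor profile + baseline profile + clinical
  metadata, evaluated strictly out-of-bag (OOB AUC, pooled Spearman ρ,
  OOB permutation importance with provenance labels).
* **Correlation** — Spearman screening of Δtaxon vs Δclinical-index across
  recipients with Benjamini–Hochberg control; the q < 0.05 pairs form a
  bipartite network exported as GraphML/SIF.

A synthetic cohort generator with exact ground-truth bookkeeping (mixture
fraction d, environmental gain g, strain displacement f, planted clinical
correlations) makes every stage testable without sequencing data. See
`docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a 15-pair cohort at the default study conditions and run the full
pipeline:

```sh
fmt-engraft simulate --seed 1 --out cohort/
fmt-engraft run-all --config examples/pipeline.yaml --seed 1 --out results/
```

or, in Python:

```python
import fmt_engraft as fe

spec = fe.CohortSimSpec(seed=1)           # 15 pairs (11 CD / 4 UC), 200 taxa
abundance, manifest, truth = fe.simulate_species_cohort(spec)

parts = fe.partition_cohort(abundance, manifest)
print(fe.donor_gain_summary((s, p) for s, _, p in parts))
```

```
     group      mean        sd   n  n_is_one
0       CD  0.143477  0.028904  33     False
1       UC  0.155121  0.035296  12     False
2  overall  0.146582   0.03076  45     False
```

About 15% of each post-FMT community's mass is donor-specific — taxa
detected in the donor but not at the recipient's baseline. (The generator
mixes 30% donor mass, but roughly half of it lands on taxa the recipient
already carried, which the partition counts as `common`; the truth record
confirms: `truth.per_sample.frac_donor_specific.mean() ≈ 0.148`.)

Strain tracking on the matching SNV table recovers the planted
subtype-specific displacement (CD 0.11, UC 0.63):

```python
snv, _ = fe.simulate_snv_cohort(fe.StrainSimSpec(seed=2, n_species=5), manifest)
series = fe.track_cohort(snv, manifest)
print(fe.cohort_retention_summary(series))
```

```
  subtype  day      mean        sd  n_recipients  pooled_mean
0      CD    3  0.121246  0.020088            11     0.121148
...
3      UC    3  0.638542  0.035599             4     0.638195
```

UC-like recipients retain ~64% of donor-specific alleles three days after
FMT versus ~12% in the CD-like arm — the colonisation-permissiveness
contrast the cohort was built to carry.

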