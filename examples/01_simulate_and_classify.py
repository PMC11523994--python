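"""Simulate a cohort and assign GS/CIN labels by nearest centroid.

Generates a synthetic 309-tumor cohort (binned log2 profiles with purity
admixture and Gaussian bin noise), builds GS/CIN centroids from a labeled
reference panel, classifies every sample by Euclidean distance over the
autosomal peak dimensions, and compares against the generator's truth.
"""

import cnsubtype as cs

cfg = cs.SimConfig(seed=7)
cohort = cs.simulate_cohort(cfg)

peaks, n_removed = cs.filter_autosomal_peaks(cfg.peaks())
print(f"peak catalog: {len(cfg.peaks())} peaks, {n_removed} on sex chromosomes removed")

peak_matrix = cs.summarize_peaks(cohort.profiles, peaks, cohort.grid)
reference, labels = cs.simulate_reference(cfg)
centroids = cs.build_centroids(reference, labels)
calls = cs.classify_samples(peak_matrix[centroids.peak_ids], centroids)

strata, composition, n_excluded = cs.stratify(calls, cohort.truth["lauren"])
print("\nfour-subgroup composition (n, % of included):")
print(composition)

recovery = (calls["label"] == cohort.truth["subtype"]).mean()
print(f"\nlabel recovery vs simulation truth: {recovery:.1%}")
# Each sample is assigned to the cluster centroid (mean reference peak
# profile) nearest in Euclidean distance; with the default well-separated
# templates essentially every tumor is recovered correctly.
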