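"""Harmonize two studies on different scales with percentile ranks.

Generates a two-study bulk cohort whose raw values differ 5-fold in scale,
rank-transforms each sample, and derives the housekeeping low/medium/high
thresholds that anchor every downstream high-expression call.
"""

from targetscape import default_spec, generate_bulk, hk_reference, \
    rank_percentile

spec = default_spec(seed=1)
em, ann, gt = generate_bulk(spec)

s1 = ann.loc[ann.study_id == "S1", "sample_id"]
s2 = ann.loc[ann.study_id == "S2", "sample_id"]
print(f"raw median, study S1: {em.values[s1].median(axis=1).median():8.2f}")
print(f"raw median, study S2: {em.values[s2].median(axis=1).median():8.2f}")
# S2 is ~5x S1: raw values are not comparable across studies.

pm = rank_percentile(em, seed=11)
print(f"percentile median, S1: {pm.values[s1].median(axis=1).median():.3f}")
print(f"percentile median, S2: {pm.values[s2].median(axis=1).median():.3f}")
# after the sample-wise rank transform both studies live on the same
# (0, 1] scale (each sample's values are a permutation of 1/G .. 1).

ref = hk_reference(pm, spec.hk_genes)
print(f"housekeeping thresholds (pooled): low={ref.pooled.p01:.3f} "
      f"medium={ref.pooled.p50:.3f} high={ref.pooled.p90:.3f}")
# a gene whose percentile exceeds the high threshold is expressed above
# 90% of housekeeping genes in its sample - the "high expression" call.
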