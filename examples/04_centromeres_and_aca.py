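"""Centromere localization from trans contacts, aggregate chromosomal
analysis (ACA), and the nuclear-configuration call.

Centromeres of different chromosomes cluster in the nucleus, so each
chromosome's centromere is found as the bin whose trans contacts with the
other candidates are maximal. The ACA rescales every chromosome to a common
pseudo-length with the centromere centered, averages the O/E maps, and scores
centromere-centromere (C-C), telomere-telomere (T-T) and Rabl-style arm
alignment enrichment.
"""

import kelpfold as kf

truth = kf.SyntheticTruth(seed=0)  # plants beta_c = 5, beta_t = 3, no Rabl band
m = kf.ice_balance(kf.mask_low_coverage(kf.simulate_contact_map(truth, 1_000_000)))

calls = kf.locate_centromeres_hic(m)
print(calls[["chrom", "midpoint", "score", "no_enrichment"]].to_string(index=False))
print("planted midpoints:", truth.centromeres())

centromeres = dict(zip(calls["chrom"], calls["midpoint"].astype(float)))
intra, inter = kf.aca(m, centromeres)
scores = kf.cluster_scores(inter)
print(f"C-C score: {scores.cc_score:.2f}  (planted boost {truth.beta_c})")
print(f"T-T score: {scores.tt_score:.2f}  (planted boost {truth.beta_t})")
print(f"arm alignment: {scores.arm_alignment_score:.2f}")
print("configuration:", kf.classify_configuration(scores))
# Strong C-C and T-T enrichment with no arm-alignment band is the
# clustered-non-Rabl configuration.
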