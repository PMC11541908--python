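"""Insulation profile, TAD assessment, and the insulated viral-insertion analog.

The default synthetic genome plants a single 400 kb insulated domain on chr4
(an analog of a large endogenous viral element) and no TADs. The insulation
track finds exactly that domain's boundaries; the genome-wide verdict
distinguishes compartment transitions from conspicuous TAD-like boundaries.
"""

import warnings

import kelpfold as kf

warnings.filterwarnings("ignore")

truth = kf.SyntheticTruth(seed=0, beta_q=4.0)  # EVE analog also contacts telomeres
m = kf.ice_balance(kf.mask_low_coverage(kf.simulate_contact_map(truth, 1_000_000)))
m.genome.gc = kf.simulate_feature_tracks(truth, with_sequences=False).gc

track = kf.insulation_track(m, window=100_000)
bounds = kf.detect_boundaries(track, min_strength=0.5)
strong = [b for b in bounds if b.strength >= 1.0]
print(f"{len(bounds)} boundaries, {len(strong)} strong (>= 1 log2):")
for b in strong:
    print(f"  {b.chrom}:{b.position}  strength {b.strength:.2f}")
print("planted domain:", truth.insulated_region)

comp = kf.call_compartments(m, mode="cis")
verdict = kf.assess_tad_presence(bounds, m.genome, compartment_borders=comp.borders)
print("TAD verdict:", verdict["verdict"],
      f"({verdict['n_compartment_transitions']} dips at compartment borders set aside)")

contrast = kf.region_insulation_contrast(m, truth.insulated_region)
print(f"domain insulation contrast: {contrast:.2f} (1 = not insulated)")

score, p = kf.region_to_telomere_contact(m, truth.insulated_region, n_perm=199, seed=0)
print(f"domain-telomere trans contact: score {score:.2f}, empirical p {p:.4f}")
# The two strong boundaries bracket the planted domain, the contrast shows
# ~3x within-domain enrichment, and the domain's telomere contact is
# significant against length-matched random controls.
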