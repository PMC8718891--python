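"""qPCR quantification and the kernel-density AAD risk model.

Triplicate Cq values are inverted through the published standard curves
(F. prausnitzii: Cq = 37.342 - 3.674 log10 copies), normalized by each
sample's 16S deviation factor, and scaled by the 100x template dilution.
A two-class Gaussian KDE on min-max-normalized concentrations then gives
P(AAD | x) and the low-vs-high region risk ratio.
"""

from aadrisk import fit_kde_model, generate_cohort, normalize_deviation, predict_p_aad, region_risk_ratio
from aadrisk.qpcr import DEFAULT_CURVES, quantify_plate

study = generate_cohort(seed=1)
conc = quantify_plate(study.qpcr, DEFAULT_CURVES)
norm = normalize_deviation(conc["FPRAU"], conc["16S"], dilution_factor=100)
norm.index = [s[:-2] for s in norm.index]  # sample id -> subject id

is_aad = study.truth["group"] == "AAD"
for g, mask in (("AAD", is_aad), ("non-AAD", ~is_aad)):
    vals = norm.loc[mask[mask].index, "fprau_final"]
    print(f"F. prausnitzii, {g}: median {vals.median():.2e} GC/uL")

model = fit_kde_model(norm.loc[is_aad, "fprau_final"],
                      norm.loc[~is_aad, "fprau_final"], bandwidth="auto")
print(f"KDE bandwidth (Silverman, normalized scale): {model.bandwidth:.3f}")

for x in (1e7, 3e7, 8e7):
    print(f"P(AAD | {x:.1e} GC/uL) = {predict_p_aad(model, x).p_aad:.2f}")

ratio = region_risk_ratio(model, low_threshold=2.4e7, high_threshold=8.0e7)
print(f"risk ratio, x < 2.4e7 vs x > 8.0e7 GC/uL: {ratio:.2f}")
# A ratio above 1 means subjects with low baseline F. prausnitzii carry a
# correspondingly higher posterior probability of developing diarrhea on
# amoxicillin-clavulanate than subjects with high baseline levels.
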