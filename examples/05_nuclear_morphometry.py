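"""Measure nuclear length:width ratios before and after dilation.

Stromal nuclei elongate strongly with pupil dilation (mean ratio ~2 -> ~5).
Nuclei are segmented by Otsu + watershed and measured by maximum Feret
diameter (length) with the perpendicular hull extent as width.
"""

from iriskit import morph, synthetic as syn

groups = {}
for condition, seed in [("untreated", 31), ("dilated", 32)]:
    preset = syn.default_nuclei_preset("stroma", condition, n_nuclei=300,
                                       seed=seed)
    img, truth = syn.generate_nuclei_field(preset)
    labels = morph.segment_nuclei(img)
    table = morph.measure_all(labels)
    groups[condition] = table["ratio"].to_numpy()
    print(f"{condition}: {len(table)} nuclei measured; planted mean ratio "
          f"{truth.ratio.mean():.2f}, measured {table['ratio'].mean():.2f}")

stats, comparison = morph.group_ratio_stats(groups)
for s in stats:
    print(f"{s.group}: mean ± SD = {s.mean_ratio:.2f} ± {s.sd:.2f} (n={s.n})")
print(f"Student's t: t = {comparison.statistic:.1f}, "
      f"p = {comparison.p_value:.2e} {comparison.stars}")
# **** means p < 0.0001: dilation elongates stromal nuclei far beyond what
# sampling noise could produce at these group sizes.
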