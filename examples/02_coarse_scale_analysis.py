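"""Coarse-scale analysis: does hitting zone 1 win fights?

Fits a binomial GLM of eviction on the zone-1/zone-2 strike proportions
(with interaction) plus relative weight difference, reports per-term
likelihood-ratio tests, and the four Kendall tau-b correlations between
spatial (zone proportions) and temporal (rap counts) performance.
Everything is run twice, with and without Tukey-fence outliers.
"""

from rapskill import (
    GeneratorConfig,
    build_report,
    generate_dataset,
    run_coarse_analysis,
)

dataset = generate_dataset(GeneratorConfig(n_fights=94, seed=42))
report = build_report(dataset.fights, dataset.pois)
result = run_coarse_analysis(
    dataset.fights, report.zone_summaries, report.outlier_flags
)

fit = result.without_outliers
print(f"fights analysed: {fit.n} ({result.n_flagged} outlier-flagged, removed here)")
print("\nGLM of eviction, per-term likelihood-ratio tests:")
for term, (chi2, df, p) in fit.lrt.items():
    print(f"  {term:24s} chi2({df}) = {chi2:6.3f}   p = {p:.3f}")
print("\nKendall tau-b, spatial vs temporal performance:")
for key, tau in fit.taus.items():
    print(f"  {key:34s} tau = {tau.tau:+.3f}   p = {tau.p:.3f}")
print(
    "\nA positive zone1~raps_per_bout tau means accurate attackers also rap"
    "\nvigorously; a positive zone-1 GLM term means accuracy predicts eviction."
)
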