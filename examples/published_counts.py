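"""Reproduce the published summary percentages from their counts.

The study behind this package reports its genome-wide results as
summary counts over a five-clone iPSC-derived neural stem cell panel.
This example feeds call matrices realizing those counts through the
package's summarizers and prints the percentages they imply.
"""

import raex
from raex.worked_example import (
    five_clone_panel,
    ma_overlap_panel,
    polyclonal_calls_for,
    reprogramming_panel,
)

panel = five_clone_panel()  # 7334 expressed, 126 MA, 48 random AEI
freq = raex.summarize_frequencies(panel, "iPSC_NSC")
print(f"MA in >=1 of 5 clones: {freq.n_ma_any_clone}/{freq.n_expressed} = {freq.pct_ma}%")
print(f"random AEI (clonal estimator): {freq.n_random_aei}/{freq.n_expressed} = {freq.pct_random_aei}%")

poly = raex.polyclonal_estimate(panel, "iPSC_NSC", polyclonal_calls_for(panel))
print(f"random AEI (polyclonal estimator): {poly.extra['n_ba_in_polyclonal']}"
      f"/{poly.n_expressed} = {poly.pct_random_aei}%")
print(f"clonal random-AEI genes biallelic in polyclonal: "
      f"{poly.extra['n_random_aei_ba_in_polyclonal']}/{poly.extra['n_random_aei_clonal']}"
      f" = {poly.extra['pct_random_aei_ba_in_polyclonal']}%")

t23 = raex.transition_analysis(
    reprogramming_panel(n_ma_before=23, n_reset=17, n_retained=2, n_skewed=1, n_lost=3),
    "NSC_parental", "iPSC_early")
print(f"random-AEI genes reset after reprogramming: "
      f"{t23.counts['RESET']}/{t23.n_ma_before_detected_after} = {t23.pct_reset_of_detected}%")

t56 = raex.transition_analysis(reprogramming_panel(), "NSC_parental", "iPSC_early")
print(f"unresolved MA genes reset after reprogramming: "
      f"{t56.counts['RESET']}/{t56.n_ma_before} = {t56.pct_reset_of_ma_before}%")

ov = raex.ma_overlap_between_sets(ma_overlap_panel(), "iPSC_NSC",
                                  ["nsc1a", "nsc1b"], ["nsc2a", "nsc2b"])
print(f"MA genes shared between clone sets: "
      f"{ov.n_ma_both}/{ov.n_expressed_both} = {ov.pct_ma_both}%")

# Every percentage is recomputed from the counts by the same
# summarizers the pipeline uses; two-decimal frequencies are truncated
# and whole-number percentages rounded, matching reporting convention.
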