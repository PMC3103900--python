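"""Estimate an LC50 from a grouped mortality table.

Builds a small dose-response experiment by hand — four concentrations,
20 animals each, dead counts rising with dose — and runs the trimmed
Spearman-Karber estimator on it.
"""

from hydratox import QuantalSeries, DoseGroup, estimate_lc50
from hydratox.records import RunConfig

series = QuantalSeries(
    groups=(
        DoseGroup(dose=50, n_exposed=20, n_dead=0),
        DoseGroup(dose=100, n_exposed=20, n_dead=4),
        DoseGroup(dose=200, n_exposed=20, n_dead=16),
        DoseGroup(dose=400, n_exposed=20, n_dead=20),
    ),
    axis="dose",
    label="TGA-QDs 72 hr",
)

est = estimate_lc50(series, RunConfig(confidence=0.95))
print(f"label      : {est.label}")
print(f"LC50       : {est.point:.2f} nM  (log10 median m = {est.m:.4f})")
print(f"95% CI     : ({est.ci_low:.1f}, {est.ci_high:.1f}) nM")
print(f"SE(log10)  : {est.se_log10:.4f}")

# The LC50 is the concentration at which half the animals die: here the
# response is symmetric around the 100-200 nM interval, so the estimate is
# their geometric mean (~141 nM); the CI comes from the binomial
# delta-method variance of the log10 median.
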