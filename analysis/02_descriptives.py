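"""Weighted descriptive summaries of the simulated survey data.

Reproduces the exploratory layer of the analysis: per-year and overall
weighted mean/median/variance of the vaccine-dose count, the percentage
distribution of doses (the zero spike), and the dispersion diagnosis
that motivates moving beyond Poisson regression.

    python analysis/02_descriptives.py
"""

from pathlib import Path

from vaxcount.descriptives import dispersion_check, weighted_summary, zero_histogram
from vaxcount.pipeline import validate_input

out = Path("results")
data = validate_input(out / "dataset.csv")

summary = weighted_summary(data.y, data.weights, by_year=data.df["year"].to_numpy())
summary.to_csv(out / "summary.csv")
print("weighted outcome summary by survey year:")
print(summary.round(2).to_string())

hist = zero_histogram(data.y, data.weights, max_count=data.meta.get("max_count", 9))
hist.to_csv(out / "outcome_histogram.csv", index=False)

report = dispersion_check(data.y, data.weights)
print()
print(report.describe())
if report.overdispersed and report.excess_zeros:
    print("-> overdispersion and excess zeros: candidates are NB, ZIP and ZINB")
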