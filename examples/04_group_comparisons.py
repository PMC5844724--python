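"""Responder-vs-nonresponder and pre-vs-early comparisons.

Rater-averaged features are compared with the Mann-Whitney U test between
pCR and non-pCR patients, and with the paired Wilcoxon signed-rank test
between the pre- and early-treatment scans.
"""

from larctex import (
    CohortSpec,
    StudyConfig,
    average_raters,
    extract_cohort,
    generate_cohort,
    run_group_tables,
)

images, labels = generate_cohort(CohortSpec(seed=5))
cohort = extract_cohort(images, labels, StudyConfig(seed=5))
averaged = average_raters(cohort)
tables = run_group_tables(averaged, label="pcr")

resp = tables["response"]
print("pre-treatment, pCR vs non-pCR (median (Q1-Q3), Mann-Whitney p):")
print(resp[resp.timepoint == "pre"][["feature", "responder", "nonresponder", "p"]]
      .to_string(index=False))

print("\npre vs early nCRT (paired Wilcoxon p):")
print(tables["paired"][["parameter", "pre", "early", "p"]].to_string(index=False))
# Responders show higher uniformity/energy and lower entropy before
# treatment; early chemoradiotherapy raises SD and lowers
# kurtosis/uniformity as the tumor texture decoheres.
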