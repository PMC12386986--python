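"""Per-feature group comparison between the two synthetic subtypes.

Each of the 93 features is summarised as median (Q1; Q3) per class and
compared with Welch's t-test (both groups normal by Shapiro-Wilk) or the
Mann-Whitney U test otherwise; significance at p < 0.05, uncorrected.
"""

from fractalrad.pipeline import extract_table
from fractalrad.stats import comparisons_to_frame, summarize_all
from fractalrad.synthetic import CohortSpec, generate_cohort

spec = CohortSpec(n_patients_per_class=8, images_per_patient=4, seed=9)
table = extract_table(generate_cohort(spec))
labels = table["label"].to_numpy()
features = table.drop(columns=["label", "patient_id"])

comparisons, n_significant = summarize_all(features, labels)
frame = comparisons_to_frame(comparisons)
print(f"{n_significant} of {len(comparisons)} features differ at p < 0.05")
cols = ["feature", "ADC_median", "SCC_median", "test_used", "p_value"]
print(frame.loc[frame["feature"].str.startswith("FDTA"), cols].to_string(index=False))
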