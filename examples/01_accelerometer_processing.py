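"""Process a simulated accelerometer day: non-wear, cut-points, daily summary.

Builds one planted day (overnight non-wear, then sedentary, light and
moderate-to-vigorous blocks), runs the processing chain and prints the
recovered durations next to the planted schedule — they agree exactly.
"""

from tuscoda import classify_epochs, detect_nonwear, simulate_counts, summarize_days

schedule = [
    ("nonwear", 540),  # device off overnight (9 h)
    ("lpa", 60),
    ("sb", 600),
    ("lpa", 120),
    ("mvpa", 60),
    ("lpa", 60),
]
series, truth = simulate_counts(schedule, epoch_s=10, seed=1)

wear = detect_nonwear(series)
labels = classify_epochs(series, wear)
(day,) = summarize_days(series, labels, wear)

print(f"planted: wear {truth.wear_h:5.2f} h | SB {truth.sb_min:5.0f} "
      f"LPA {truth.lpa_min:5.0f} MVPA {truth.mvpa_min:5.0f} min")
print(f"recovered: wear {day.wear_h:5.2f} h | SB {day.sb_min:5.0f} "
      f"LPA {day.lpa_min:5.0f} MVPA {day.mvpa_min:5.0f} min")
# The non-wear rule (>= 60 min of zeros, <= 2 low-count minutes allowed) finds
# exactly the overnight block; worn epochs fall into their cut-point bins.
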