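"""Score the hearing-handicap questionnaire and a post-task comfort tally.

The 10-item questionnaire scores 0-40 (yes=4 / sometimes=2 / no=0) with
category cutoffs at 8 and 26; the comfort index is Yes + 0.5*Maybe, turned
into a percentage over substantive respondents only.
"""

from hearsim import ComfortTally, comfort_percentage, score_hhies

items = ["yes", "sometimes", "sometimes", "no", "no",
         "sometimes", "no", "yes", "no", "no"]
total, category = score_hhies(items)
print(f"questionnaire total: {total} -> {category}")
print("(scores 0-8: no handicap, 10-24: mild-to-moderate, 26-40: severe)")

# digits-in-noise comfort: seven respondents, all tolerating the task
tally = ComfortTally(yes=7, maybe=0, no=0, no_response=53)
index, pct = comfort_percentage(tally)
print(f"comfort index {index:.1f} over {tally.yes + tally.maybe + tally.no} "
      f"respondents -> {pct:.0f}% comfortable")
print("Non-respondents are excluded from the denominator, so a task that")
print("only 7 of 60 answered can still be rated 100% tolerable.")
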