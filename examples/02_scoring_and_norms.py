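"""From a timestamped event stream to windowed totals and screening levels.

Aggregates a two-participant event log into daily tallies, sums the 7-day
window ending on the last day, and classifies each total against the
built-in published norm table (cuts 19/38/65) and against quartile norms
derived from a synthetic reference cohort.
"""

from datetime import datetime, timezone

from lexiscreen import (
    Category,
    Lexicon,
    LexiconEntry,
    TextEvent,
    aggregate_daily,
    classify_score,
    compute_window_score,
    derive_norms,
)

lexicon = Lexicon(
    [LexiconEntry("sad", Category.MOOD), LexiconEntry("tired", Category.FATIGUE)]
)
UTC = timezone.utc
events = [
    TextEvent("p1", datetime(2023, 5, 1, 9, 0, tzinfo=UTC), "sad sad day"),
    TextEvent("p1", datetime(2023, 5, 3, 22, 0, tzinfo=UTC), "so tired"),
    TextEvent("p2", datetime(2023, 5, 2, 12, 0, tzinfo=UTC), "all fine"),
]

dailies = aggregate_daily(events, lexicon, timezone="UTC")
for d in dailies:
    print(f"{d.participant_id} {d.date}: {d.total} keyword(s)")

end = max(d.date for d in dailies)
for pid in ("p1", "p2"):
    w = compute_window_score(dailies, pid, end, 7)
    level = classify_score(w.total)  # default published norms
    print(f"{pid}: 7-day total={w.total} -> level={level.label} "
          f"(range {level.low}-{level.high})")

# Quartile norms from a reference sample of totals (here a uniform grid):
norms = derive_norms(list(range(165)), source="demo-grid")
print(f"derived cuts: q1={norms.q1} q2={norms.q2} q3={norms.q3} "
      f"max={norms.max_observed}")
# The cuts partition scores into normal / above_normal / high / critical.
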