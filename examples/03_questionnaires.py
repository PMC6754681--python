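"""Score the four paper-and-pencil instruments from item-level answers.

BDI-II and SWLS are plain sums with severity/satisfaction bands; CES-D
reverse-codes its four positive-affect items (positions 4/8/12/16) and
flags totals at or above 16; the Affect Balance Scale reports
positive - negative + 5 on a 0-10 scale.
"""

from lexiscreen import Instrument, InstrumentResponse, abs_balance, score_response

responses = [
    InstrumentResponse("p1", Instrument.BDI2, (1,) * 17 + (0,) * 4),
    InstrumentResponse("p1", Instrument.CESD, (1,) * 20),
    InstrumentResponse("p1", Instrument.ABS, (1, 1, 1, 0, 0, 1, 0, 0, 0, 0)),
    InstrumentResponse("p1", Instrument.SWLS, (4, 5, 4, 3, 5)),
]

for r in responses:
    s = score_response(r)
    extra = f" subscores={s.subscores}" if s.subscores else ""
    print(f"{s.instrument.value:5} total={s.total:5} band={s.band!r}{extra}")

# The balance formula also applies to cohort-level component means:
print("balance from component means 3.15/2.49:", abs_balance(3.15, 2.49))
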