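"""Score a Cornell musculoskeletal discomfort questionnaire.

Each body-region item multiplies a frequency weight (0 / 1.5 / 3.5 / 5 /
10) by severity (1..3) and work interference (1..3); the total is the
sum over regions and is banded at 450 / 900 / 1350.
"""

from moreba import CmdqItem, item_score
from moreba.cmdq import score_responses

responses = [
    CmdqItem("lower_back", frequency="several/day", severity="very", interference="substantial"),
    CmdqItem("neck", frequency="daily", severity="moderate", interference="slight"),
    CmdqItem("wrist", frequency="3-4/week", severity="moderate", interference="slight"),
    CmdqItem("knee", frequency="1-2/week", severity="slight", interference="none"),
    CmdqItem("shoulder", frequency="never"),
]

for item in responses:
    print(f"{item.region:11s} -> {item.score:5.1f}")
result = score_responses(responses)
print(f"total = {result.total}  band = {result.band} (of 4)")
# The worst possible single item scores 10 x 3 x 3 = 90:
assert item_score("several/day", "very", "substantial") == 90
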