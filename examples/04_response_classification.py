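"""Metabolic response labels from per-lesion SUL changes.

A >= 20 % drop in every baseline lesion (no new lesions) is an overall
response; a >= 15 % rise in any lesion or a new lesion is progression; both
kinds coexisting is a mixed response; anything else is stable disease.
"""

import h2opet as h

print("SUL for 7.4 kBq/mL, 370 MBq, 50 kg lean mass:",
      h.suv_lean(7.4, 370.0, 50.0))

cases = [
    ([-39.0], False),
    ([-10.0, 20.0], False),
    ([-25.0, -30.0, 16.0], False),
    ([-50.0, -60.0], True),
    ([-10.0, -5.0], False),
]
for changes, new_lesions in cases:
    label = h.classify_fdg_response(changes, new_lesions)
    print(f"changes {changes!s:<24} new_lesions={new_lesions!s:<5} -> {label.value}")
# The third case is MIXED (responding and progressing lesions coexist) and
# the fourth is PD regardless of the changes because new lesions appeared.
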