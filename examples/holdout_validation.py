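"""Validate intermediate-gene predictions by holding them out.

The prediction tool is tested the way a perturbation study would: a known
intermediate gene's measurement is removed from the input, the network is
rebuilt, and the propagated direction is compared with the withheld truth.
"""

from corenet import Interaction, validate_against_study

# derepression chain: Root -| M -| T, with T measured down.
# Under knockout (root down) the tool should predict M up.
links = [Interaction("Root", -1, "M"), Interaction("M", -1, "T")]
observed = {"T": -1, "M": 1}  # M's known direction will be withheld

verdicts, summary = validate_against_study(links, observed, ["Root"],
                                           held_out={"M": 1})
print("verdicts:", verdicts)
print("summary:", summary)
# "correct" means the propagated direction for the withheld gene matched
# its independently known misregulation.
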