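"""Sugeno fuzzy mapping from fatigue-level scores to assistance velocity.

Feeds the rulebase a score sequence that moves from clear fatigue (high
effort) to clear nonfatigue, and prints the integrated velocity command.
The command ramps by at most 0.1 mm/s per update and stays in [0, 10].
"""

from emgexo import fuzzy

rulebase = fuzzy.build_rulebase()
print(f"rulebase: {rulebase.rule_count} rules over 3 score inputs")

sequence = [[0.0, 0.1, 0.9]] * 30 + [[0.5, 0.5, 0.5]] * 10 + [[0.9, 0.1, 0.0]] * 20
trace = fuzzy.simulate_velocity(rulebase, sequence, v0=0.0)
for k in (0, 29, 39, 59):
    print(f"update {k + 1:2d}: v = {trace[k]:.2f} mm/s")
print("Fatigue raises the assistance velocity, ambiguity holds it, "
      "and clear nonfatigue ramps it back down.")
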