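"""Build the full TCR/CD28 network and export it as model text.

Shows the model's composition (proteins, rules, observables), writes the
BNGL-subset text, and demonstrates that the text round-trips through the
parser to an identical model.
"""

from tcr_phosdyn import build_tcr_model, parse_model, write_model
from tcr_phosdyn.tcr_network import ADDITIONAL_PROTEINS, MEASURED_PROTEINS, load_roster

model = build_tcr_model()
roster = load_roster()

print(f"molecule types: {len(model.molecule_types)} "
      f"({len(MEASURED_PROTEINS)} measured proteins + {len(ADDITIONAL_PROTEINS)} "
      "regulatory proteins + the stimulus crosslinker)")
print(f"rules: {len(model.rules)}, observables: {len(model.observables)}, "
      f"measured pTyr sites: {len(roster.measured())}")

text = write_model(model)
print(f"\nexported model text: {len(text.splitlines())} lines; first rules:\n")
in_rules = False
shown = 0
for line in text.splitlines():
    if line.startswith("begin reaction rules"):
        in_rules = True
        continue
    if in_rules and shown < 5:
        print(" ", line.strip())
        shown += 1

assert parse_model(text) == model.canonical()
print("\nround trip: parse(write(model)) == model  [OK]")
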