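"""Predict the floral phenotypes of one transcribed collection.

Loads the builtin Cg-7 record (the 4-flowered cyme: a trichasial first
order whose primary flower is flanked by bracts on the left, right and
abaxial side), runs the androecial petaloidy rule and the AF model on every
mature flower, and prints prediction vs observation.
"""

from cannasym import floral_formula, get_collection, predict_all

record = get_collection("Cg-7")
print(f"{record.id} ({record.species}) - {record.pf_class}")
print()

for fid, predicted in sorted(predict_all(record.topology).items()):
    observed = record.observed[fid]
    print(f"flower {fid}:")
    print(f"  predicted: {floral_formula(predicted)}")
    print(f"  observed:  {floral_formula(observed)}")

print()
print(
    "The trichasium-flanked primary flower ('0') loses all thecae and its\n"
    "three branch influences resolve to a net abaxial pull: zygomorphic.\n"
    "Each secondary flower is a normal monochasium member: one theca, with\n"
    "the appendage distal to its single tertiary bract."
)
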