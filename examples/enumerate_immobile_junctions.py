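"""Enumerate the immobile four-way junction sequences.

Of the 256 ways to assign Watson-Crick pairs to the four branch-point
positions, only those forbidding one-step branch migration on both
opposing-arm axes are immobile; collapsing cyclic strand relabelings
leaves the 36 classes a crystal designer can choose from.
"""

from hjkit.combinatorics import (
    all_assignments,
    classes_table,
    enumerate_immobile_classes,
    is_immobile,
    realize_sequences,
)

immobile = [a for a in all_assignments() if is_immobile(a)]
classes = enumerate_immobile_classes()

print(f"assignments: {len(all_assignments())}")
print(f"immobile:    {len(immobile)}")
print(f"classes:     {len(classes)}  (orbits of size "
      f"{sorted({c.orbit_size for c in classes})} under rotation)")
print()
print(classes_table(classes).head(6).to_string(index=False))
print("...")

seqs = realize_sequences(classes[0], arm_length=8, stem_seed=0)
print(f"\nstrands realizing {classes[0].label} "
      f"(quartet {classes[0].canonical.refs}, 8-bp arms):")
for i, s in enumerate(seqs.strands, 1):
    print(f"  strand {i}: 5'-{s}-3'")
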