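"""The pipe-delimited architecture notation and the structural rules.

Parses the 17-layer model the particle search produced, checks it against
the three trainability rules, counts its parameters, and shows how rule
violations are reported and repaired.
"""

from swarmnas import (
    TDCN_PSO_NOTATION,
    count_parameters,
    parse_architecture,
    repair_architecture,
    validate_architecture,
)

arch = parse_architecture(TDCN_PSO_NOTATION, input_shape=(128, 128, 3))
print(f"layers: {len(arch)}")
print(f"notation: {arch.notation()}")
print(f"violations: {validate_architecture(arch)}")
print(f"trainable parameters (default layer widths): {count_parameters(arch):,}")
# Zero violations: the search's own output satisfies its constraints
# (at least one dense layer, flatten before the first dense, no conv
# after the flatten).

broken = parse_architecture("C2D | F | DE | C2D")
print(f"\nbroken: {broken.notation()}")
for v in validate_architecture(broken):
    print(f"  rule {v.rule} violated at layer index {v.index}")
fixed = repair_architecture(broken)
print(f"repaired: {fixed.notation()}")
# Repair drops the conv stranded after the flatten, restoring validity
# with the smallest edit.
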