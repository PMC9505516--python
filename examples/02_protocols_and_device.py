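"""Electrode arrays, pulse-delivery protocols, and the device envelope.

Generates the three published protocols, prints their activation sequences,
and validates the pulse trains against the generator's operating envelope.
"""

from skingetsim import (
    build_array,
    classify_contact_impedance,
    default_train,
    generate_protocol,
    validate_against_device,
)

for array_name, protocol_name in [("hex7", "classical"),
                                  ("hex6", "alternative"),
                                  ("mea6", "mea_lv")]:
    array = build_array(array_name)
    protocol = generate_protocol(array, protocol_name)
    print(f"{protocol_name} on {array_name}: {len(protocol)} steps, "
          f"{protocol.total_pulses()} pulses total")
    for i, step in enumerate(protocol.steps[:4]):
        print(f"   step {i + 1}: anodes {sorted(step.anodes)} -> "
              f"cathodes {sorted(step.cathodes)} at {step.amplitude:.0f} V")
    print("   ...")

# Device envelope: 80-600 V, 10-1000 us, 0.1-5000 Hz.  The hex protocols'
# train fits; the MEA low-voltage protocol targets a different generator.
for name in ("alternative", "mea_lv"):
    violations = validate_against_device(default_train(name))
    verdict = "deliverable" if not violations else "NOT deliverable"
    print(f"\n{name} train is {verdict} by this generator")
    for v in violations:
        print(f"   {v}")

# Skin-contact detector: three impedance ranges
print()
for z in [20.0, 2500.0, 50000.0]:
    print(f"impedance {z:8.0f} ohm -> {classify_contact_impedance(z)}")
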