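"""Build a combinatorial design from a source sequence and enumerate it.

Creates a six-bin tagged-GFP library (one backbone; two signal peptides;
two linkers; GFPuv; two affinity tags; one terminator), then adds the
design rule "short WITH sig1" — the short linker may only be built
together with the sig1 signal peptide — and counts what survives.
"""

import random

from partforge import (
    AnnotatedSequence,
    Design,
    add_rule,
    enumeration_report,
    errors_of,
    validate_design,
)

rng = random.Random(0)
backbone_src = AnnotatedSequence(
    "pBB_vector", "".join(rng.choice("ACGT") for _ in range(600)), circular=True
)
insert_src = AnnotatedSequence(
    "insert_pool", "".join(rng.choice("ACGT") for _ in range(500))
)

design = Design(topology="circular", name="tagged_gfp_library")
layout = [
    ("backbone", [("vector_backbone", backbone_src, 550, 120)]),  # wraps origin
    ("signal", [("sig1", insert_src, 1, 60), ("sig2", insert_src, 61, 120)]),
    ("linker", [("long", insert_src, 121, 165), ("short", insert_src, 166, 180)]),
    ("gene", [("gfpuv", insert_src, 181, 420)]),
    ("tag", [("std_tag", insert_src, 421, 450), ("enh_tag", insert_src, 451, 480)]),
    ("term", [("terminator1", insert_src, 481, 500)]),
]
for i, (label, parts) in enumerate(layout):
    design.add_bin(label)
    for name, src, start, stop in parts:
        design.create_part(name, src, start, stop, bin_index=i)

print("validation errors:", errors_of(validate_design(design)))
print("combinations without rules:", enumeration_report(design).total)

add_rule(design, "rule3", "WITH", "short", "sig1")
report = enumeration_report(design)
print(
    f"with 'short WITH sig1': total={report.total} kept={report.kept} "
    f"eliminated={report.eliminated}"
)
# The rule removes exactly the combinations pairing the short linker with
# sig2: 2 of the 8 possible constructs, leaving 6 to build.
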