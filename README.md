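# partforge

Headless combinatorial DNA construct design for synthetic biology.

Researchers building multi-part genetic constructs — promoter/RBS/CDS
swaps, tagged fusion libraries, metabolic pathway variant panels — face
three recurring chores: cutting named *parts* out of annotated (often
circular) source sequences without off-by-one mistakes, enumerating
every allowed combination of interchangeable parts, and handing a
clean, machine-checkable description of the library to DNA assembly
design tools. partforge is a library (plus a thin CLI) that does all
three with a correct-by-construction bias: invalid coordinates,
duplicate part names, and rule references to nonexistent parts are
rejected at creation time, not discovered after the oligos arrive.

## The model

A **design** is an ordered list of **bins**, left to right = 5'→3' of
the target construct; each bin holds one or more interchangeable
**parts** (a named, oriented region `[start, stop]` of an annotated
source sequence, 1-based inclusive, origin-wrapping selections allowed
on circular sources). A design with bin sizes `n_1 … n_k` enumerates

    N = ∏ᵢ nᵢ

candidate **constructs** (one part per bin). Eugene-style design rules
prune that space:

* `A WITH B` — A's presence requires B (directional: a construct
  without A satisfies it vacuously),
* `A NOTWITH B` — A and B never co-occur,
* `A NOTMORETHAN n` — at most n copies of A per construct,

and a construct is kept iff every rule holds on its part multiset.
Kept constructs assemble scar-lessly (pure concatenation, circular
topology closing the last junction) into annotated sequences with every
source feature carried along.

For parts obtained by direct DNA synthesis, consecutive
direct-synthesis bins form one **synthesis span** unless a per-junction
**firewall** splits them; a span over bins with sizes `m_1 … m_r` costs
`∏ mⱼ` distinct fragments, and the design total is the sum over spans —
which is why a misplaced firewall between two 38-variant bins turns an
order of 38 + 38 = 76 fragments into 38 × 38 = 1444.

## Worked example

```python
from partforge import prdr_like_design, add_rule, enumeration_report

design = prdr_like_design(seed=11)           # 6 bins, sizes 1,2,2,1,2,1
add_rule(design, "rule3", "WITH", "short", "sig1")
report = enumeration_report(design)
print(report.total, report.kept, report.eliminated)
```

prints

```
8 6 2
```

— 8 possible combinations; the rule that the short linker must be built
with the sig1 signal peptide eliminates the 2 combinations pairing it
with sig2, leaving 6 constructs to build. The `examples/` directory has
one narrative script per capability (building and enumerating a design,
assembling and frame-checking constructs, firewall cost comparison,
j5-style bundle interchange); each prints the numbers it computes and a
line on what they mean.

## File interchange

* Genbank flat files for sources and assembled constructs (read/write,
  circular topology and origin-wrapping features included).
* A versioned design file (XML, with an equivalent JSON rendering) that
  round-trips every modeled field.
* Eugene rules files (`.eug`), dialect
  `Rule name(op1 OPERATOR op2);` with `//` comments; batch import
  classifies every line (imported / identical / renamed conflict /
  ignored-with-reason).
* A j5-style bundle: parts CSV, bin-order CSV (firewalls, strategies,
  overhangs), rules file, and a zip of Genbank sources resolved by
  record display ID — never by file name.

## CLI

`partforge validate | enumerate | cost | export-j5 | import-j5 |
rules-import | fixture` — exit 0 on success, 1 on validation/domain
failures, 2 on usage or I/O errors. See `partforge --help`.

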