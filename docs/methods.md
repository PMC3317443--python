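# Methods

## Scope and model

partforge implements the design-side core of combinatorial DNA
construct engineering: part definition on annotated sources, ordered
combinatorial bins, a Eugene-rule subset, rule-filtered enumeration,
scar-less in-silico assembly, and direct-synthesis fragment accounting.
It deliberately stops where assembly-protocol design begins: no primer
or oligo design, no melting temperatures, no Golden Gate overhang
selection, no monetary cost models, and no graphical canvas. The
outputs (design files, j5-style CSV bundles, assembled Genbank records)
are the hand-off surface to such downstream tools.

## Coordinates and sequence handling

All public coordinates are 1-based inclusive, matching Genbank. A
selection with `start > stop` is legal only on a circular source and
means the window running through the origin (`start…L` then `1…stop`);
its length is `L − start + stop + 1`. Extraction always yields a linear
sequence. Equivalence with a rotate-then-slice formulation is a tested
invariant.

Features wholly inside an extracted window are remapped; features
partially overlapping are clipped to the window and their label
suffixed ` (truncated)` plus an in-memory boolean flag. This keeps
annotation retention without inventing data; the flag (not the label)
is what assembly uses to drop clipped fragments. A feature can
intersect a wrapped window in two disjoint pieces; each piece becomes
its own truncated fragment rather than a single feature spanning bases
the original never covered.

Residue case is preserved in memory and compared case-insensitively.
Genbank writing goes through Biopython, which canonicalizes case in the
flat file; round-trip guarantees are therefore stated on the
case-folded sequence plus exact feature tuples
(label, type, start, end, strand) and topology. Origin-wrapping
features serialize as `join(a..L,1..b)` locations. `N` is allowed in
sources and flows through assembly untouched — no base-level chemistry
is modeled.

## Parts, linked repeats, and validation

A part is a named, oriented region of a registered source with a glyph
category and an optional forced assembly strategy. Placed instances of
a repeated part share one definition object; edits go through an
atomic `edit_part_definition` that validates the complete update
(range, charset, name uniqueness, the DIGEST-first-bin rule) before
touching anything, and renames propagate into rules referencing the
part. This makes inconsistent repeats unrepresentable rather than
detectable.

Part names match `^[A-Za-z0-9_-]+$`. The charset is chosen for CSV
safety (no commas, no quoting needed) and for unambiguous rule-operand
matching; error messages list the offending characters.

Validation returns a list of diagnostics with stable codes rather than
raising, so callers can render every problem at once:
`E_EMPTY_DESIGN`, `E_EMPTY_BIN`, `E_RANGE`, `E_DUP_NAME`, `E_BAD_NAME`,
`E_RULE_OPERAND_MISSING`, `E_RULE_DUP_NAME`, `E_DIGEST_FIRST_BIN`
(toggleable, on by default — restriction-digest fragments cannot open a
circular assembly), and warnings `W_STRATEGY_MISMATCH` (a part forcing
a strategy different from its bin's consensus), `W_METHOD_ARITY`
(declared single-construct method on a combinatorial design or vice
versa) and `W_FIREWALL_NOOP`. The contract, fuzz-tested over random
designs: zero error-severity diagnostics implies enumeration and
assembly of every combination succeed.

The GUI indicator lights of interactive editors are modeled as derived
predicates (`part_has_rules`, `part_forces_consensus`,
`part_breaks_consensus`) so the same signals are assertable in code.

### Bin consensus strategy

A bin's strategy is derived, never set: the modal non-none forced
strategy of its members, ties broken by the fixed vocabulary order
`PCR < DIGEST < DIRECT_SYNTHESIS < EMBEDDED_IN_PRIMER_FORWARD <
EMBEDDED_IN_PRIMER_REVERSE`, `none` when no member forces one. The
derivation rule is a design choice (the derived-but-not-settable
behaviour is fixed, the aggregation was open); the tie-break table is
tested exhaustively over all strategy pairs.

## Rule semantics

`WITH` is directional: `A WITH B` holds iff `count(A) = 0` or
`count(B) ≥ 1`. The directional reading is pinned by the worked
2-of-8 count for the tagged-GFP library: "short WITH sig1" must
eliminate exactly the two short+sig2 combinations, while a symmetric
reading would also kill the two sig1+long ones (4 total). The test
suite asserts both the 2 and the 4. `NOTMORETHAN` counts every
instance of the named part regardless of orientation. Rule evaluation
is a pure function of the construct's part-name multiset, so filtering
by a rule set equals the intersection of per-rule filters.

The rules-file dialect is one statement per line,
`Rule name(op1 OPERATOR op2);`, `//` comments, case-insensitive
operator keywords. Import classifies each line (imported, identical,
renamed conflict with auto-generated `_k` suffix, ignored with reason);
identical requires equal name *and* equal content — same content under
a new name imports as a new rule. Export/import is the identity on
rule sets.

## Enumeration, naming, assembly

Enumeration is the Cartesian product over bins, leftmost bin varying
slowest, streamed lazily (the 54,872-combination library counts in
well under a second without materializing a sequence). Construct names
are `prefix + ordinal`, the ordinal zero-padded to the decimal width of
the kept-construct count, so names sort in enumeration order (8 kept →
width 1, e.g. `pRDR00001…pRDR00008` from prefix `pRDR0000`).

Assembly is pure concatenation of the extracted part sequences —
scar-less by assumption, junction chemistry being out of scope — with
the design's topology flag deciding circularity. Annotations carried
into the output are exactly: source features fully inside each part
(at their offsets) plus one spanning `misc_feature` per part labelled
with the part name, giving the tested invariant
`features(assembled) = Σ fully-contained + #parts` and making fusion
boundaries inspectable (the frame fixture's translation check relies
on it).

`per_rule_eliminations` in the enumeration report counts combinations
violating each rule irrespective of the others; sums can exceed the
total eliminated when violations overlap.

## Synthesis spans and fragment cost

Maximal runs of consecutive bins whose consensus strategy is
DIRECT_SYNTHESIS form spans; a firewall after a bin inside a run splits
it at that junction. A span costs the product of its bin sizes
(fragment identity is by variant combination, not sequence equality, so
duplicate sequences across variants still count — matching the
38 × 38 = 1444 vs 38 + 38 = 76 arithmetic); the design total is the sum
over spans. Firewalls outside direct-synthesis runs are recorded,
warned about, and contribute nothing.

Splitting a span with side-products P and Q changes its cost from P·Q
to P+Q. This is a non-increase iff both P, Q ≥ 2 and a strict decrease
iff (P−1)(Q−1) > 1; a split against a singleton side (P = 1) *raises*
the count by one. The tests assert this exact characterization.

## File formats

The design file is versioned XML (schema documented in `io.py`,
version 1.0) with a field-equivalent JSON rendering; loading is atomic
(schema violations name the failing path; nothing partial is
returned), a missing topology flag defaults to circular with a
warning, and an unknown schema version is refused. Saving and j5
export are gated on validation returning zero errors.

The j5-style bundle emits a parts CSV
(`Part Name, Part Source, Reverse Complement, Start BP, End BP` — the
historical misspelling "Reverse Compliment" is accepted on read), a
bin-order CSV (`>bin` rows carrying firewall / consensus strategy /
forced overhang, then member part rows), the rules file, and a zip of
Genbank sources. Exact historical j5 header strings live in external
manuals; these headers are self-documented and versioned rather than
claimed bit-compatible. Import resolves sources by record display ID
— never file name — builds a minimal design with every glyph set to
generic (CSV carries no glyph information; the documented lossy set of
the round trip is {glyph, canvas geometry}), and hard-fails on
out-of-range coordinates or unresolved sources with row-numbered
errors.

## Synthetic fixtures

The generator emulates the canonical library shapes at their stated
sizes: the 6-bin `[1,2,2,1,2,1]` tagged-GFP collection (9 parts, named
sig1/sig2, long/short, std/enh tags, with the `short WITH sig1` rule
preset), the two-bin 38 + 38 barcode/gene-3 direct-synthesis fixture,
and the three-bin 38³ library. Random DNA is uniform over ACGT from a
seeded `random.Random`; part lengths default to 30–90 bp (12–48 bp for
the high-variant fixtures, enough to exercise feature remapping while
keeping memory trivial); one fully-contained feature is placed per
part so every assembly exercises annotation propagation. The seed is
recorded in the design's metadata and hence in every saved design
file. Generation is deterministic given (spec, seed); a 200-spec fuzz
asserts generated designs always validate cleanly.

The frame fixture builds codon-aligned signal-peptide / linker / CDS /
tag parts from a stop-free codon alphabet with a leading ATG and a
single terminal TAA, and plants a TTA codon inside the CDS so that
reverse-orienting the CDS provably introduces an in-frame stop — a
built-in negative control for the translation oracle.

What the fixtures do not emulate: real sequence composition (GC skew,
repeats, homopolymers), biologically meaningful features, vendor
synthesis constraints, or the actual deposited plasmid sequences.
Passing tests therefore demonstrate the combinatorial, rule, coordinate
and accounting logic — not that any particular real construct is
buildable.

## Problem sizes and numerical choices

The test suite runs the full published arithmetic at its native sizes
(8, 54,872, 1444/76) — these are trivial at desk scale — and keeps
property batteries at 10–50 random cases per invariant, which is where
the distinct code paths (wrapping, ties, conflicts) are covered; the
whole suite completes in a few seconds. There is no floating-point
anywhere in the core: counts are exact integers, so no tolerances
apply. Tie-breaks (consensus strategy, rename suffixes, feature
ordering by start) are fixed and documented above to keep every output
deterministic.

## Known limitations

* The Eugene subset is the three binary/count operators; no devices,
  properties, assertions or loops.
* Orientation-specific rule operands are not distinguished; all
  instances of a named part count.
* Fragment accounting does not merge identical flanking sequences
  across combinations (a downstream assembly-design concern).
* The j5 CSV headers are this package's documented dialect, not a
  bit-exact clone of any historical j5 release.
* Clipboard-based sequence mapping and SBOL XML import/export are out
  of scope; Genbank files are the annotated-source path.
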