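"""Combinatorial enumeration, rule filtering, and scar-less assembly.

Enumeration is the Cartesian product over bins in lexicographic order
with the leftmost bin varying slowest, which makes construct naming
reproducible. Streams are lazy, so library-scale designs (38^3 and
beyond) can be counted without materializing any sequence. Assembly is
scar-less: pure concatenation of the extracted part sequences in bin
order, with source annotations carried along at their offsets plus one
spanning feature per part.
"""

from __future__ import annotations

import csv
import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator

from .design import Design, Part
from .errors import StructureError
from .rules import evaluate_rule
from .sequence import AnnotatedSequence, Feature


@dataclass
class Construct:
    """One ordered selection of a part from each bin."""

    parts: list[Part]
    index: int  # lexicographic rank in enumeration order

    def part_names(self) -> list[str]:
        return [p.name for p in self.parts]

    def name_counts(self) -> Counter:
        return Counter(self.part_names())


@dataclass
class EnumerationReport:
    total: int
    kept: int
    per_rule_eliminations: dict[str, int] = field(default_factory=dict)

    @property
    def eliminated(self) -> int:
        return self.total - self.kept


def enumerate_constructs(design: Design) -> Iterator[Construct]:
    """Yield every combination (one part per bin), lazily, in order."""
    if not design.bins:
        raise StructureError("design has no bins")
    for i, b in enumerate(design.bins):
        if not b.parts:
            raise StructureError(f"bin {i + 1} ({b.label!r}) is empty")
    for index, combo in enumerate(
        itertools.product(*(b.parts for b in design.bins))
    ):
        yield Construct(list(combo), index)


def total_combinations(design: Design) -> int:
    n = 1
    for b in design.bins:
        n *= len(b.parts)
    return n


def construct_satisfies_rules(design: Design, construct: Construct) -> bool:
    counts = construct.name_counts()
    return all(evaluate_rule(r, counts) for r in design.rules)


def filter_by_rules(design: Design) -> Iterator[Construct]:
    """Lazily yield constructs satisfying every rule of the design."""
    for c in enumerate_constructs(design):
        if construct_satisfies_rules(design, c):
            yield c


def enumeration_report(design: Design) -> EnumerationReport:
    """Count combinations, survivors, and per-rule violations.

    ``per_rule_eliminations`` counts the combinations each rule violates
    irrespective of the other rules, so the per-rule sums may exceed the
    total eliminated when violations overlap.
    """
    total = 0
    kept = 0
    per_rule = {r.name: 0 for r in design.rules}
    for c in enumerate_constructs(design):
        total += 1
        counts = c.name_counts()
        ok = True
        for r in design.rules:
            if not evaluate_rule(r, counts):
                per_rule[r.name] += 1
                ok = False
        if ok:
            kept += 1
    return EnumerationReport(total=total, kept=kept, per_rule_eliminations=per_rule)


def assemble_construct(design: Design, construct: Construct) -> AnnotatedSequence:
    """Concatenate the parts of a construct into one annotated sequence.

    Residues are the extracted (and, for reverse parts, reverse-
    complemented) part sequences joined without scars; topology follows
    the design flag (circular closes the final junction without added
    bases). Source features fully contained in a part are propagated at
    their offset; truncated fragments are dropped. One extra feature per
    part spans the part itself, labelled with the part name, so fusion
    boundaries stay inspectable in the output.
    """
    residues: list[str] = []
    features: list[Feature] = []
    offset = 0
    for part in construct.parts:
        try:
            region = design.part_sequence(part)
        except Exception as exc:
            raise type(exc)(f"part {part.name!r}: {exc}") from exc
        plen = len(region)
        features.append(
            Feature(
                label=part.name,
                feature_type="misc_feature",
                start=offset + 1,
                end=offset + plen,
                strand=1,
            )
        )
        for f in region.features:
            if f.truncated:
                continue
            features.append(
                Feature(
                    label=f.label,
                    feature_type=f.feature_type,
                    start=offset + f.start,
                    end=offset + f.end,
                    strand=f.strand,
                )
            )
        residues.append(region.residues)
        offset += plen
    features.sort(key=lambda f: (f.start, f.end, f.label))
    return AnnotatedSequence(
        name=f"construct_{construct.index + 1}",
        residues="".join(residues),
        circular=design.topology == "circular",
        features=features,
    )


def name_constructs(
    design: Design, prefix: str, constructs: list[Construct] | None = None
) -> dict[int, str]:
    """Sequential names in enumeration order of the kept constructs.

    Returns a map from construct index to name. Ordinals are 1-based and
    zero-padded to the decimal width of the kept count (8 kept ->
    prefix + "1".."8"), so names sort in enumeration order.
    """
    if constructs is None:
        constructs = list(filter_by_rules(design))
    width = max(1, len(str(len(constructs))))
    return {
        c.index: f"{prefix}{ordinal:0{width}d}"
        for ordinal, c in enumerate(constructs, start=1)
    }


def report_rows(design: Design) -> Iterator[dict]:
    """Per-combination rows for the enumeration report CSV."""
    names = name_constructs(design, prefix=f"{design.name}_")
    for c in enumerate_constructs(design):
        counts = c.name_counts()
        violated = [
            r.name for r in design.rules if not evaluate_rule(r, counts)
        ]
        yield {
            "construct": names.get(c.index, ""),
            "kept": not violated,
            "violated_rules": ";".join(violated),
            **{
                f"bin_{i + 1}": p.name
                for i, p in enumerate(c.parts)
            },
        }


def write_report_csv(design: Design, path) -> None:
    rows = list(report_rows(design))
    fieldnames = ["construct", "kept", "violated_rules"] + [
        f"bin_{i + 1}" for i in range(len(design.bins))
    ]
    with open(str(path), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for row in rows:
            row["kept"] = "TRUE" if row["kept"] else "FALSE"
            writer.writerow(row)
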