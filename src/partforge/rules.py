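"""Eugene design-specification rules: NOTMORETHAN, WITH, NOTWITH.

Supported dialect (one statement per line, ``//`` comments):

    Rule <name>(<operand1> <OPERATOR> <operand2-or-count>);

Operator keywords are case-insensitive. WITH is directional: the
presence of operand1 in a construct requires operand2 (a construct
without operand1 satisfies the rule vacuously). NOTWITH forbids
co-occurrence; NOTMORETHAN caps the copy count of operand1.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable

from .errors import OperandError, RuleValueError, UniquenessError


class Operator(str, Enum):
    NOTMORETHAN = "NOTMORETHAN"
    WITH = "WITH"
    NOTWITH = "NOTWITH"


@dataclass
class EugeneRule:
    """A named constraint over the parts of a design."""

    name: str
    operator: Operator
    operand1: str
    operand2: str | int  # part name, or copy count for NOTMORETHAN

    def part_operands(self) -> list[str]:
        if self.operator is Operator.NOTMORETHAN:
            return [self.operand1]
        return [self.operand1, str(self.operand2)]

    def statement(self) -> str:
        return f"Rule {self.name}({self.operand1} {self.operator.value} {self.operand2});"


@dataclass
class RuleImportRecord:
    """Classification of one line of an imported rules file."""

    line_number: int
    raw_text: str
    status: str  # imported | identical | renamed_conflict | ignored
    resolved_name: str = ""
    reason: str = ""


def add_rule(design, name, operator, operand1, operand2) -> EugeneRule:
    """Attach a rule to the design, validating operands against the canvas.

    Both operands of WITH/NOTWITH must name parts presently defined in
    the design — a rule for "ispA" cannot be created when only "ispA-O"
    exists, which is exactly the name-matching trap this check removes.
    """
    operator = Operator(str(operator).upper())
    if any(r.name == name for r in design.rules):
        raise UniquenessError(f"a rule named {name!r} already exists")
    canvas = design.part_names()
    if operand1 not in canvas:
        raise OperandError(
            f"operand {operand1!r} names no part on the canvas"
        )
    if operator is Operator.NOTMORETHAN:
        count = int(operand2)
        if count < 1:
            raise RuleValueError(f"NOTMORETHAN count must be >= 1, got {count}")
        operand2 = count
    else:
        if operand2 not in canvas:
            raise OperandError(
                f"operand {operand2!r} names no part on the canvas"
            )
    rule = EugeneRule(name, operator, operand1, operand2)
    design.rules.append(rule)
    return rule


def evaluate_rule(rule: EugeneRule, construct: Iterable[str]) -> bool:
    """Pure predicate over the multiset of part names of one construct."""
    counts = construct if isinstance(construct, Counter) else Counter(construct)
    n1 = counts[rule.operand1]
    if rule.operator is Operator.NOTMORETHAN:
        return n1 <= int(rule.operand2)
    n2 = counts[str(rule.operand2)]
    if rule.operator is Operator.WITH:
        return n1 == 0 or n2 >= 1
    return not (n1 >= 1 and n2 >= 1)  # NOTWITH


def rules_for_part(design, part_name: str) -> list[EugeneRule]:
    """All rules naming the part as either operand, in creation order."""
    if part_name not in design.part_names():
        raise OperandError(f"no part named {part_name!r} on the canvas")
    return [r for r in design.rules if part_name in r.part_operands()]


_RULE_RE = re.compile(
    r"^\s*Rule\s+(?P<name>[A-Za-z0-9_-]+)\s*\(\s*"
    r"(?P<op1>[A-Za-z0-9_-]+)\s+"
    r"(?P<operator>[A-Za-z]+)\s+"
    r"(?P<op2>[A-Za-z0-9_-]+)\s*\)\s*;\s*$",
    re.IGNORECASE,
)


def _parse_line(line: str) -> EugeneRule | str:
    """Parse one statement; returns a rule or a rejection reason string."""
    m = _RULE_RE.match(line)
    if not m:
        return "unparseable statement"
    try:
        operator = Operator(m.group("operator").upper())
    except ValueError:
        return f"unsupported operator {m.group('operator')!r}"
    op2: str | int = m.group("op2")
    if operator is Operator.NOTMORETHAN:
        try:
            op2 = int(op2)
        except ValueError:
            return f"NOTMORETHAN needs an integer count, got {op2!r}"
        if op2 < 1:
            return f"NOTMORETHAN count must be >= 1, got {op2}"
    return EugeneRule(m.group("name"), operator, m.group("op1"), op2)


def _fresh_name(base: str, taken: set[str]) -> str:
    k = 1
    while f"{base}_{k}" in taken:
        k += 1
    return f"{base}_{k}"


def import_rules_file(design, text: str) -> list[RuleImportRecord]:
    """Classify and import every line of a rules file.

    Classification mirrors the batch-import dialog: imported (new rule),
    identical (same name and same content as an existing rule — no
    change), renamed_conflict (name clash with different content —
    imported under an auto-generated alternative name), ignored
    (blank/comment lines, unparseable statements, unsupported operators,
    operands not on the canvas).
    """
    canvas = design.part_names()
    existing = {r.name: r for r in design.rules}
    records: list[RuleImportRecord] = []
    for line_number, raw in enumerate(text.splitlines(), start=1):
        stripped = raw.strip()
        if not stripped:
            records.append(
                RuleImportRecord(line_number, raw, "ignored", reason="blank line")
            )
            continue
        if stripped.startswith("//"):
            records.append(
                RuleImportRecord(line_number, raw, "ignored", reason="comment")
            )
            continue
        parsed = _parse_line(stripped)
        if isinstance(parsed, str):
            records.append(
                RuleImportRecord(line_number, raw, "ignored", reason=parsed)
            )
            continue
        missing = [op for op in parsed.part_operands() if op not in canvas]
        if missing:
            records.append(
                RuleImportRecord(
                    line_number,
                    raw,
                    "ignored",
                    reason=f"operand(s) not on the canvas: {', '.join(missing)}",
                )
            )
            continue
        clash = existing.get(parsed.name)
        if clash is not None:
            same = (
                clash.operator is parsed.operator
                and clash.operand1 == parsed.operand1
                and str(clash.operand2) == str(parsed.operand2)
            )
            if same:
                records.append(
                    RuleImportRecord(
                        line_number, raw, "identical", resolved_name=parsed.name
                    )
                )
                continue
            new_name = _fresh_name(parsed.name, set(existing))
            parsed.name = new_name
            design.rules.append(parsed)
            existing[new_name] = parsed
            records.append(
                RuleImportRecord(
                    line_number, raw, "renamed_conflict", resolved_name=new_name
                )
            )
            continue
        design.rules.append(parsed)
        existing[parsed.name] = parsed
        records.append(
            RuleImportRecord(
                line_number, raw, "imported", resolved_name=parsed.name
            )
        )
    return records


def export_rules_file(design) -> str:
    """One statement per line; re-importing classifies every line identical."""
    return "".join(r.statement() + "\n" for r in design.rules)
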