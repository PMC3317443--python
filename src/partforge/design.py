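"""Parts, bins, and the combinatorial design (collection).

A design is an ordered list of bins, left-to-right = 5'->3' of the target
construct; each bin holds one or more interchangeable parts. Repeated
placements of the same part share a single definition: editing one
instance edits all of them ("linked repeated parts"). Validation returns
stable diagnostic codes instead of raising, so a caller can render the
full list of problems at once; a design with zero error-severity
diagnostics is guaranteed to enumerate and assemble without raising
(the correct-by-construction contract).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from enum import Enum

from .errors import (
    NamingError,
    RangeError,
    StructureError,
    UniquenessError,
)
from .sequence import AnnotatedSequence, extract_region

NAME_RE = re.compile(r"^[A-Za-z0-9_-]+$")


class Strategy(str, Enum):
    """Forced assembly strategy for a part.

    The enum declaration order is the fixed tie-break order used when a
    bin's members force different strategies equally often.
    """

    PCR = "PCR"
    DIGEST = "DIGEST"
    DIRECT_SYNTHESIS = "DIRECT_SYNTHESIS"
    EMBEDDED_IN_PRIMER_FORWARD = "EMBEDDED_IN_PRIMER_FORWARD"
    EMBEDDED_IN_PRIMER_REVERSE = "EMBEDDED_IN_PRIMER_REVERSE"

    @classmethod
    def parse(cls, text: str | None) -> "Strategy | None":
        if text is None or str(text).strip().lower() in ("", "none"):
            return None
        return cls(str(text).strip().upper())


STRATEGY_ORDER = list(Strategy)

GLYPHS = frozenset(
    {
        "promoter",
        "rbs",
        "cds",
        "terminator",
        "origin_of_replication",
        "signal_peptide",
        "tag",
        "scar",
        "generic",
        "user_defined",
    }
)


@dataclass
class Diagnostic:
    """One validation finding; ``code`` is a stable identifier."""

    code: str
    severity: str  # "error" | "warning"
    subject: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity.upper()} {self.code} {self.subject}: {self.message}"


@dataclass
class PartDefinition:
    """Shared definition behind one or more placed part instances."""

    definition_id: int
    name: str
    source_name: str
    start: int
    stop: int
    reverse: bool = False
    glyph: str = "generic"
    forced_strategy: Strategy | None = None


class Part:
    """A placed instance of a part definition.

    All definition fields are proxied, so instances sharing a definition
    can never disagree.
    """

    __slots__ = ("definition",)

    def __init__(self, definition: PartDefinition):
        self.definition = definition

    @property
    def definition_id(self) -> int:
        return self.definition.definition_id

    @property
    def name(self) -> str:
        return self.definition.name

    @property
    def source_name(self) -> str:
        return self.definition.source_name

    @property
    def start(self) -> int:
        return self.definition.start

    @property
    def stop(self) -> int:
        return self.definition.stop

    @property
    def reverse(self) -> bool:
        return self.definition.reverse

    @property
    def glyph(self) -> str:
        return self.definition.glyph

    @property
    def forced_strategy(self) -> Strategy | None:
        return self.definition.forced_strategy

    def __repr__(self) -> str:
        return f"Part({self.name!r})"


@dataclass
class Bin:
    """A vertical slot holding interchangeable parts.

    ``firewall_after`` prevents direct synthesis from extending through
    the assembly junction to the right of this bin. ``forced_overhang``
    is the optional relative overhang/overlap position for that same
    junction, carried as opaque metadata for downstream assembly design.
    """

    label: str
    parts: list[Part] = field(default_factory=list)
    firewall_after: bool = False
    forced_overhang: int | None = None

    @property
    def consensus_strategy(self) -> Strategy | None:
        return bin_consensus_strategy(self)


class Design:
    """Ordered bins + topology flag + sources + rules.

    Parts may also exist peripheral to the collection (defined but not
    placed in any bin); they are excluded from enumeration and export.
    """

    def __init__(self, topology: str = "circular", name: str = "design"):
        if topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular|linear, got {topology!r}")
        self.name = name
        self.topology = topology
        self.bins: list[Bin] = []
        self.sources: dict[str, AnnotatedSequence] = {}
        self.rules: list = []  # EugeneRule; typed loosely to avoid a cycle
        self.peripheral_parts: list[Part] = []
        self.declared_arity: str | None = None  # "single" | "combinatorial"
        self.meta: dict[str, str] = {}  # provenance (e.g. fixture seed)
        self._next_definition_id = itertools.count(1)

    # -- structure ---------------------------------------------------------

    def add_bin(
        self,
        label: str,
        firewall_after: bool = False,
        forced_overhang: int | None = None,
    ) -> Bin:
        b = Bin(label, [], firewall_after, forced_overhang)
        self.bins.append(b)
        return b

    def add_source(self, source: AnnotatedSequence) -> None:
        self.sources[source.name] = source

    def iter_parts(self):
        """All placed instances in canvas order, then peripheral parts."""
        for b in self.bins:
            yield from b.parts
        yield from self.peripheral_parts

    def part_names(self) -> set[str]:
        return {p.name for p in self.iter_parts()}

    def find_part(self, name: str) -> Part | None:
        for p in self.iter_parts():
            if p.name == name:
                return p
        return None

    def definitions(self) -> dict[int, PartDefinition]:
        return {p.definition_id: p.definition for p in self.iter_parts()}

    @property
    def combinatorial(self) -> bool:
        return any(len(b.parts) > 1 for b in self.bins)

    # -- part lifecycle ----------------------------------------------------

    def create_part(
        self,
        name: str,
        source: AnnotatedSequence,
        start: int,
        stop: int,
        reverse: bool = False,
        glyph: str = "generic",
        forced_strategy: Strategy | None = None,
        bin_index: int | None = None,
    ) -> Part:
        """Create a part mapped to a region of ``source``.

        Range, charset and uniqueness are enforced at creation time:
        referencing base pair 500 of a 100 bp source is impossible, as is
        reusing an existing part name.
        """
        _check_part_name(name)
        if self.find_part(name) is not None:
            raise UniquenessError(f"a part named {name!r} already exists")
        if glyph not in GLYPHS:
            raise NamingError(
                f"unknown glyph {glyph!r}; expected one of {sorted(GLYPHS)}"
            )
        if source.name not in self.sources:
            self.add_source(source)
        # raises RangeError / TopologyError on bad coordinates
        extract_region(source, start, stop, reverse)
        definition = PartDefinition(
            definition_id=next(self._next_definition_id),
            name=name,
            source_name=source.name,
            start=start,
            stop=stop,
            reverse=reverse,
            glyph=glyph,
            forced_strategy=forced_strategy,
        )
        part = Part(definition)
        if bin_index is None:
            self.peripheral_parts.append(part)
        else:
            self._bin_at(bin_index).parts.append(part)
        return part

    def _bin_at(self, bin_index: int) -> Bin:
        if not 0 <= bin_index < len(self.bins):
            raise StructureError(
                f"bin index {bin_index} out of range [0, {len(self.bins) - 1}]"
            )
        return self.bins[bin_index]

    def place_part(self, part: Part, bin_index: int) -> None:
        """Move a peripheral part into a bin."""
        if part in self.peripheral_parts:
            self.peripheral_parts.remove(part)
        self._bin_at(bin_index).parts.append(part)

    def replicate_part(self, part: Part, bin_index: int) -> Part:
        """Place a linked copy of ``part`` into the given bin.

        The copy shares the part's definition: later edits through
        :meth:`edit_part_definition` update every instance in unison.
        """
        if part.definition_id not in self.definitions():
            raise StructureError(f"part {part.name!r} is not in this design")
        clone = Part(part.definition)
        self._bin_at(bin_index).parts.append(clone)
        return clone

    def remove_part(self, part: Part) -> None:
        for b in self.bins:
            if part in b.parts:
                b.parts.remove(part)
                return
        if part in self.peripheral_parts:
            self.peripheral_parts.remove(part)
            return
        raise StructureError(f"part {part.name!r} is not placed in this design")

    def edit_part_definition(
        self, definition_id: int, check_digest_first_bin: bool = True, **updates
    ) -> None:
        """Atomically update the shared definition of a repeated part.

        The update is validated in full before any field changes; on
        rejection the design is untouched. A rename also renames the
        part in every rule that references it.
        """
        defs = self.definitions()
        if definition_id not in defs:
            raise StructureError(f"no part definition with id {definition_id}")
        d = defs[definition_id]
        allowed = {
            "name",
            "source_name",
            "start",
            "stop",
            "reverse",
            "glyph",
            "forced_strategy",
        }
        unknown = set(updates) - allowed
        if unknown:
            raise ValueError(f"unknown definition fields: {sorted(unknown)}")

        new_name = updates.get("name", d.name)
        if new_name != d.name:
            _check_part_name(new_name)
            if new_name in self.part_names():
                raise UniquenessError(f"a part named {new_name!r} already exists")
        source_name = updates.get("source_name", d.source_name)
        if source_name not in self.sources:
            raise StructureError(f"unknown source {source_name!r}")
        source = self.sources[source_name]
        start = updates.get("start", d.start)
        stop = updates.get("stop", d.stop)
        reverse = updates.get("reverse", d.reverse)
        extract_region(source, start, stop, reverse)  # range/topology gate
        glyph = updates.get("glyph", d.glyph)
        if glyph not in GLYPHS:
            raise NamingError(f"unknown glyph {glyph!r}")
        strategy = updates.get("forced_strategy", d.forced_strategy)
        if strategy is not None:
            strategy = Strategy(strategy)
        if (
            check_digest_first_bin
            and strategy is Strategy.DIGEST
            and self.bins
            and any(p.definition_id == definition_id for p in self.bins[0].parts)
        ):
            raise StructureError(
                "E_DIGEST_FIRST_BIN: a DIGEST part may not occupy the first bin"
            )

        old_name = d.name
        d.name, d.source_name = new_name, source_name
        d.start, d.stop, d.reverse = start, stop, reverse
        d.glyph, d.forced_strategy = glyph, strategy
        if new_name != old_name:
            for rule in self.rules:
                if rule.operand1 == old_name:
                    rule.operand1 = new_name
                if rule.operand2 == old_name:
                    rule.operand2 = new_name

    # -- derived indicator surrogates --------------------------------------

    def part_has_rules(self, part: Part) -> bool:
        """Orange-circle indicator: some rule names this part as an operand."""
        return any(
            part.name in (r.operand1, r.operand2) for r in self.rules
        )

    def part_forces_consensus(self, part: Part) -> bool:
        """Blue-rectangle indicator: the part forces its bin's consensus."""
        b = self._bin_of(part)
        return (
            b is not None
            and part.forced_strategy is not None
            and part.forced_strategy is bin_consensus_strategy(b)
        )

    def part_breaks_consensus(self, part: Part) -> bool:
        """Red-rectangle indicator: forced strategy differs from bin consensus."""
        b = self._bin_of(part)
        return (
            b is not None
            and part.forced_strategy is not None
            and part.forced_strategy is not bin_consensus_strategy(b)
        )

    def _bin_of(self, part: Part) -> Bin | None:
        for b in self.bins:
            if part in b.parts:
                return b
        return None

    def part_sequence(self, part: Part) -> AnnotatedSequence:
        """The extracted (and possibly reverse-complemented) part sequence."""
        source = self.sources[part.source_name]
        region = extract_region(source, part.start, part.stop, part.reverse)
        region.name = part.name
        return region


def _check_part_name(name: str) -> None:
    if not name:
        raise NamingError("part name must be non-empty")
    if not NAME_RE.match(name):
        offending = sorted(set(re.sub(r"[A-Za-z0-9_-]", "", name)))
        raise NamingError(
            f"part name {name!r} contains prohibited characters {offending}; "
            "allowed charset is [A-Za-z0-9_-]"
        )


def bin_consensus_strategy(b: Bin) -> Strategy | None:
    """Derived strategy of a bin: the modal non-none forced strategy of
    its members, ties broken by the fixed vocabulary order
    PCR < DIGEST < DIRECT_SYNTHESIS < EMBEDDED_IN_PRIMER_FORWARD <
    EMBEDDED_IN_PRIMER_REVERSE; none when no member forces one."""
    if not b.parts:
        raise StructureError(f"bin {b.label!r} is empty")
    counts: dict[Strategy, int] = {}
    for p in b.parts:
        if p.forced_strategy is not None:
            counts[p.forced_strategy] = counts.get(p.forced_strategy, 0) + 1
    if not counts:
        return None
    best = max(counts.values())
    for s in STRATEGY_ORDER:
        if counts.get(s) == best:
            return s
    raise AssertionError("unreachable")


def validate_design(
    design: Design,
    digest_first_bin: bool = True,
) -> list[Diagnostic]:
    """Run every correct-by-construction check and return all findings.

    Error codes: E_EMPTY_DESIGN, E_EMPTY_BIN, E_RANGE, E_DUP_NAME,
    E_BAD_NAME, E_RULE_OPERAND_MISSING, E_RULE_DUP_NAME,
    E_DIGEST_FIRST_BIN (toggleable, on by default).
    Warning codes: W_STRATEGY_MISMATCH, W_METHOD_ARITY, W_FIREWALL_NOOP.
    A design with zero error-severity findings enumerates and assembles
    without raising.
    """
    out: list[Diagnostic] = []

    if not design.bins:
        out.append(
            Diagnostic(
                "E_EMPTY_DESIGN", "error", design.name, "design has no bins"
            )
        )
    for i, b in enumerate(design.bins):
        if not b.parts:
            out.append(
                Diagnostic(
                    "E_EMPTY_BIN", "error", b.label, f"bin {i + 1} holds no parts"
                )
            )

    seen: dict[str, int] = {}
    for p in design.iter_parts():
        seen[p.name] = seen.get(p.name, 0) + 1
    # repeated linked instances share one definition and are not duplicates
    def_names: dict[str, set[int]] = {}
    for p in design.iter_parts():
        def_names.setdefault(p.name, set()).add(p.definition_id)
    for name, ids in def_names.items():
        if len(ids) > 1:
            out.append(
                Diagnostic(
                    "E_DUP_NAME",
                    "error",
                    name,
                    f"{len(ids)} distinct parts share the name {name!r}",
                )
            )

    for did, d in design.definitions().items():
        if not d.name or not NAME_RE.match(d.name):
            out.append(
                Diagnostic(
                    "E_BAD_NAME",
                    "error",
                    d.name or f"definition {did}",
                    "name is empty or contains prohibited characters",
                )
            )
        source = design.sources.get(d.source_name)
        if source is None:
            out.append(
                Diagnostic(
                    "E_RANGE",
                    "error",
                    d.name,
                    f"source {d.source_name!r} is not registered",
                )
            )
            continue
        L = len(source)
        for pos in (d.start, d.stop):
            if not 1 <= pos <= L:
                out.append(
                    Diagnostic(
                        "E_RANGE",
                        "error",
                        d.name,
                        f"position {pos} outside [1, {L}] on {d.source_name!r}",
                    )
                )
        if d.start > d.stop and not source.circular and 1 <= d.start <= L:
            out.append(
                Diagnostic(
                    "E_RANGE",
                    "error",
                    d.name,
                    f"start {d.start} > stop {d.stop} on linear source",
                )
            )

    rule_names: dict[str, int] = {}
    for r in design.rules:
        rule_names[r.name] = rule_names.get(r.name, 0) + 1
    for name, n in rule_names.items():
        if n > 1:
            out.append(
                Diagnostic(
                    "E_RULE_DUP_NAME", "error", name, f"{n} rules named {name!r}"
                )
            )
    canvas = design.part_names()
    for r in design.rules:
        for operand in r.part_operands():
            if operand not in canvas:
                out.append(
                    Diagnostic(
                        "E_RULE_OPERAND_MISSING",
                        "error",
                        r.name,
                        f"operand {operand!r} names no part on the canvas",
                    )
                )

    if digest_first_bin and design.bins and design.bins[0].parts:
        for p in design.bins[0].parts:
            if p.forced_strategy is Strategy.DIGEST:
                out.append(
                    Diagnostic(
                        "E_DIGEST_FIRST_BIN",
                        "error",
                        p.name,
                        "a DIGEST part may not occupy the first bin",
                    )
                )

    for b in design.bins:
        if not b.parts:
            continue
        consensus = bin_consensus_strategy(b)
        for p in b.parts:
            if p.forced_strategy is not None and p.forced_strategy is not consensus:
                out.append(
                    Diagnostic(
                        "W_STRATEGY_MISMATCH",
                        "warning",
                        p.name,
                        f"forced strategy {p.forced_strategy.value} differs "
                        f"from bin {b.label!r} consensus {consensus.value}",
                    )
                )
        if b.firewall_after and consensus is not Strategy.DIRECT_SYNTHESIS:
            out.append(
                Diagnostic(
                    "W_FIREWALL_NOOP",
                    "warning",
                    b.label,
                    "firewall set on a bin outside a direct-synthesis run",
                )
            )

    if design.declared_arity is not None:
        is_comb = design.combinatorial
        if design.declared_arity == "single" and is_comb:
            out.append(
                Diagnostic(
                    "W_METHOD_ARITY",
                    "warning",
                    design.name,
                    "declared single-construct method but design is combinatorial",
                )
            )
        elif design.declared_arity == "combinatorial" and not is_comb:
            out.append(
                Diagnostic(
                    "W_METHOD_ARITY",
                    "warning",
                    design.name,
                    "declared combinatorial method but design has one combination",
                )
            )

    return out


def errors_of(diagnostics: list[Diagnostic]) -> list[Diagnostic]:
    return [d for d in diagnostics if d.severity == "error"]
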