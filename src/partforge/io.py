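"""Design-file serialization and j5-style CSV + zipped-sequence interchange.

Design files are versioned XML (schema below) with an equivalent JSON
rendering selected by file extension. The j5 bundle is the classic
four-piece upload: a parts CSV, an order CSV in bin order, a Eugene
rules file, and a zip of Genbank sources. Sources inside the zip are
resolved by the record's display ID, never by file name.

Design XML schema, version 1.0::

    <design schema_version="1.0" name="..." topology="circular|linear">
      <meta key="value" .../>
      <sources>
        <source name=".." circular="TRUE|FALSE">
          <residues>ACGT...</residues>
          <feature label=".." type=".." start=".." end=".." strand="1|-1"/>
        </source>...
      </sources>
      <parts>
        <part id="1" name=".." source=".." start=".." stop=".."
              reverse="TRUE|FALSE" glyph=".." strategy=".."/>...
      </parts>
      <bins>
        <bin label=".." firewall_after="TRUE|FALSE" forced_overhang="..">
          <placement ref="1"/>...
        </bin>...
      </bins>
      <peripheral><placement ref="3"/>...</peripheral>
      <rules><rule name=".." operator=".." operand1=".." operand2=".."/>...</rules>
    </design>

The JSON rendering carries the same payload as nested objects.
"""

from __future__ import annotations

import csv
import io as _io
import json
import warnings
import zipfile
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path

from .design import (
    Design,
    Diagnostic,
    Part,
    PartDefinition,
    Strategy,
    bin_consensus_strategy,
    errors_of,
    validate_design,
)
from .errors import (
    FormatError,
    ReferenceError_,
    SchemaError,
    ValidationRefusedError,
    VersionError,
)
from .rules import EugeneRule, Operator, export_rules_file
from .sequence import (
    AnnotatedSequence,
    Feature,
    read_genbank_string,
    write_genbank_string,
)

SCHEMA_VERSION = "1.0"

PARTS_CSV_HEADER = ["Part Name", "Part Source", "Reverse Complement",
                    "Start BP", "End BP"]
# historical j5 files misspell the third column; accepted on read
_REVERSE_ALIASES = {"Reverse Complement", "Reverse Compliment"}
ORDER_CSV_HEADER = ["Bin or Part Name", "Direct Synthesis Firewall",
                    "Forced Assembly Strategy", "Forced Relative Overhang"]


def _bool(value: bool) -> str:
    return "TRUE" if value else "FALSE"


def _parse_bool(text: str, where: str) -> bool:
    t = str(text).strip().upper()
    if t in ("TRUE", "1", "YES"):
        return True
    if t in ("FALSE", "0", "NO", ""):
        return False
    raise SchemaError(f"{where}: expected TRUE/FALSE, got {text!r}")


# ---------------------------------------------------------------------------
# canonical dict payload (shared by XML and JSON renderings)

def design_to_dict(design: Design) -> dict:
    defs = design.definitions()
    return {
        "schema_version": SCHEMA_VERSION,
        "name": design.name,
        "topology": design.topology,
        "meta": dict(design.meta),
        "sources": [
            {
                "name": s.name,
                "circular": s.circular,
                "residues": s.residues,
                "features": [
                    {
                        "label": f.label,
                        "type": f.feature_type,
                        "start": f.start,
                        "end": f.end,
                        "strand": f.strand,
                    }
                    for f in s.features
                ],
            }
            for s in design.sources.values()
        ],
        "parts": [
            {
                "id": did,
                "name": d.name,
                "source": d.source_name,
                "start": d.start,
                "stop": d.stop,
                "reverse": d.reverse,
                "glyph": d.glyph,
                "strategy": d.forced_strategy.value if d.forced_strategy else "",
            }
            for did, d in sorted(defs.items())
        ],
        "bins": [
            {
                "label": b.label,
                "firewall_after": b.firewall_after,
                "forced_overhang": b.forced_overhang,
                "placements": [p.definition_id for p in b.parts],
            }
            for b in design.bins
        ],
        "peripheral": [p.definition_id for p in design.peripheral_parts],
        "rules": [
            {
                "name": r.name,
                "operator": r.operator.value,
                "operand1": r.operand1,
                "operand2": r.operand2,
            }
            for r in design.rules
        ],
    }


def _require(payload: dict, key: str, where: str):
    if key not in payload:
        raise SchemaError(f"{where}: missing required field {key!r}")
    return payload[key]


def design_from_dict(payload: dict) -> Design:
    version = payload.get("schema_version")
    if version is None:
        raise SchemaError("design: missing required field 'schema_version'")
    if version != SCHEMA_VERSION:
        raise VersionError(
            f"unsupported schema_version {version!r} (supported: {SCHEMA_VERSION})"
        )
    topology = payload.get("topology")
    if topology is None:
        warnings.warn("design file missing topology flag; defaulting to circular")
        topology = "circular"
    if topology not in ("circular", "linear"):
        raise SchemaError(f"design.topology: invalid value {topology!r}")
    design = Design(topology=topology, name=payload.get("name", "design"))
    design.meta = dict(payload.get("meta", {}))

    for i, s in enumerate(_require(payload, "sources", "design")):
        where = f"design.sources[{i}]"
        seq = AnnotatedSequence(
            name=_require(s, "name", where),
            residues=_require(s, "residues", where),
            circular=bool(s.get("circular", False)),
            features=[
                Feature(
                    label=_require(f, "label", f"{where}.features[{j}]"),
                    feature_type=f.get("type", "misc_feature"),
                    start=int(_require(f, "start", f"{where}.features[{j}]")),
                    end=int(_require(f, "end", f"{where}.features[{j}]")),
                    strand=int(f.get("strand", 1)),
                )
                for j, f in enumerate(s.get("features", []))
            ],
        )
        design.add_source(seq)

    definitions: dict[int, PartDefinition] = {}
    for i, p in enumerate(_require(payload, "parts", "design")):
        where = f"design.parts[{i}]"
        did = int(_require(p, "id", where))
        strategy_text = p.get("strategy", "")
        definitions[did] = PartDefinition(
            definition_id=did,
            name=_require(p, "name", where),
            source_name=_require(p, "source", where),
            start=int(_require(p, "start", where)),
            stop=int(_require(p, "stop", where)),
            reverse=bool(p.get("reverse", False)),
            glyph=p.get("glyph", "generic"),
            forced_strategy=Strategy.parse(strategy_text),
        )
    if definitions:
        import itertools

        design._next_definition_id = itertools.count(max(definitions) + 1)

    for i, b in enumerate(_require(payload, "bins", "design")):
        where = f"design.bins[{i}]"
        overhang = b.get("forced_overhang")
        made = design.add_bin(
            _require(b, "label", where),
            firewall_after=bool(b.get("firewall_after", False)),
            forced_overhang=None if overhang in (None, "") else int(overhang),
        )
        for ref in b.get("placements", []):
            if int(ref) not in definitions:
                raise SchemaError(f"{where}: placement ref {ref} has no part")
            made.parts.append(Part(definitions[int(ref)]))
    for ref in payload.get("peripheral", []):
        if int(ref) not in definitions:
            raise SchemaError(f"design.peripheral: ref {ref} has no part")
        design.peripheral_parts.append(Part(definitions[int(ref)]))

    for i, r in enumerate(payload.get("rules", [])):
        where = f"design.rules[{i}]"
        operator = Operator(_require(r, "operator", where))
        operand2 = _require(r, "operand2", where)
        if operator is Operator.NOTMORETHAN:
            operand2 = int(operand2)
        design.rules.append(
            EugeneRule(
                _require(r, "name", where),
                operator,
                _require(r, "operand1", where),
                operand2,
            )
        )
    return design


# ---------------------------------------------------------------------------
# XML rendering

def _dict_to_xml(payload: dict) -> ET.Element:
    root = ET.Element(
        "design",
        schema_version=payload["schema_version"],
        name=payload["name"],
        topology=payload["topology"],
    )
    meta = ET.SubElement(root, "meta")
    for k, v in payload["meta"].items():
        meta.set(k, str(v))
    sources = ET.SubElement(root, "sources")
    for s in payload["sources"]:
        el = ET.SubElement(
            sources, "source", name=s["name"], circular=_bool(s["circular"])
        )
        ET.SubElement(el, "residues").text = s["residues"]
        for f in s["features"]:
            ET.SubElement(
                el,
                "feature",
                label=f["label"],
                type=f["type"],
                start=str(f["start"]),
                end=str(f["end"]),
                strand=str(f["strand"]),
            )
    parts = ET.SubElement(root, "parts")
    for p in payload["parts"]:
        ET.SubElement(
            parts,
            "part",
            id=str(p["id"]),
            name=p["name"],
            source=p["source"],
            start=str(p["start"]),
            stop=str(p["stop"]),
            reverse=_bool(p["reverse"]),
            glyph=p["glyph"],
            strategy=p["strategy"],
        )
    bins = ET.SubElement(root, "bins")
    for b in payload["bins"]:
        el = ET.SubElement(
            bins,
            "bin",
            label=b["label"],
            firewall_after=_bool(b["firewall_after"]),
            forced_overhang=""
            if b["forced_overhang"] is None
            else str(b["forced_overhang"]),
        )
        for ref in b["placements"]:
            ET.SubElement(el, "placement", ref=str(ref))
    peripheral = ET.SubElement(root, "peripheral")
    for ref in payload["peripheral"]:
        ET.SubElement(peripheral, "placement", ref=str(ref))
    rules = ET.SubElement(root, "rules")
    for r in payload["rules"]:
        ET.SubElement(
            rules,
            "rule",
            name=r["name"],
            operator=r["operator"],
            operand1=r["operand1"],
            operand2=str(r["operand2"]),
        )
    return root


def _xml_to_dict(root: ET.Element) -> dict:
    if root.tag != "design":
        raise SchemaError(f"root element must be <design>, got <{root.tag}>")
    payload: dict = {k: v for k, v in root.attrib.items()}
    meta = root.find("meta")
    payload["meta"] = dict(meta.attrib) if meta is not None else {}
    payload["sources"] = []
    sources = root.find("sources")
    if sources is None:
        raise SchemaError("design: missing required field 'sources'")
    for el in sources.findall("source"):
        residues_el = el.find("residues")
        payload["sources"].append(
            {
                "name": el.get("name"),
                "circular": _parse_bool(
                    el.get("circular", "FALSE"), "source.circular"
                ),
                "residues": (
                    residues_el.text or "" if residues_el is not None else None
                ),
                "features": [
                    {
                        "label": f.get("label"),
                        "type": f.get("type", "misc_feature"),
                        "start": f.get("start"),
                        "end": f.get("end"),
                        "strand": f.get("strand", "1"),
                    }
                    for f in el.findall("feature")
                ],
            }
        )
    parts = root.find("parts")
    if parts is None:
        raise SchemaError("design: missing required field 'parts'")
    payload["parts"] = [
        {
            "id": p.get("id"),
            "name": p.get("name"),
            "source": p.get("source"),
            "start": p.get("start"),
            "stop": p.get("stop"),
            "reverse": _parse_bool(p.get("reverse", "FALSE"), "part.reverse"),
            "glyph": p.get("glyph", "generic"),
            "strategy": p.get("strategy", ""),
        }
        for p in parts.findall("part")
    ]
    bins = root.find("bins")
    if bins is None:
        raise SchemaError("design: missing required field 'bins'")
    payload["bins"] = [
        {
            "label": b.get("label"),
            "firewall_after": _parse_bool(
                b.get("firewall_after", "FALSE"), "bin.firewall_after"
            ),
            "forced_overhang": b.get("forced_overhang") or None,
            "placements": [pl.get("ref") for pl in b.findall("placement")],
        }
        for b in bins.findall("bin")
    ]
    peripheral = root.find("peripheral")
    payload["peripheral"] = (
        [pl.get("ref") for pl in peripheral.findall("placement")]
        if peripheral is not None
        else []
    )
    rules = root.find("rules")
    payload["rules"] = (
        [
            {
                "name": r.get("name"),
                "operator": r.get("operator"),
                "operand1": r.get("operand1"),
                "operand2": r.get("operand2"),
            }
            for r in rules.findall("rule")
        ]
        if rules is not None
        else []
    )
    return payload


def save_design(design: Design, path) -> Path:
    """Save a validated design as XML (default) or JSON (``.json`` path).

    Saving is refused while the design carries error diagnostics: a file
    on disk is always loadable and assemblable.
    """
    problems = errors_of(validate_design(design))
    if problems:
        raise ValidationRefusedError(problems)
    path = Path(path)
    payload = design_to_dict(design)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=1))
    else:
        root = _dict_to_xml(payload)
        ET.indent(root)
        path.write_text(ET.tostring(root, encoding="unicode"))
    return path


def load_design(path) -> Design:
    """Load a design file (XML or JSON by extension); atomic on failure."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        try:
            payload = json.loads(text)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON: {exc}") from exc
    else:
        try:
            payload = _xml_to_dict(ET.fromstring(text))
        except ET.ParseError as exc:
            raise SchemaError(f"{path}: not valid XML: {exc}") from exc
    return design_from_dict(payload)


# ---------------------------------------------------------------------------
# j5 bundle

@dataclass
class J5Bundle:
    """The four-piece j5-style upload: two CSVs, a rules file, and a
    zip of Genbank sources (in-memory bytes)."""

    parts_csv: str
    order_csv: str
    rules_text: str
    sequences_zip: bytes

    def write_to(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "parts_csv": directory / "parts.csv",
            "order_csv": directory / "order.csv",
            "rules_text": directory / "rules.eug",
            "sequences_zip": directory / "sequences.zip",
        }
        paths["parts_csv"].write_text(self.parts_csv)
        paths["order_csv"].write_text(self.order_csv)
        paths["rules_text"].write_text(self.rules_text)
        paths["sequences_zip"].write_bytes(self.sequences_zip)
        return paths

    @classmethod
    def read_from(cls, directory) -> "J5Bundle":
        directory = Path(directory)
        return cls(
            parts_csv=(directory / "parts.csv").read_text(),
            order_csv=(directory / "order.csv").read_text(),
            rules_text=(directory / "rules.eug").read_text(),
            sequences_zip=(directory / "sequences.zip").read_bytes(),
        )


def export_j5_bundle(design: Design) -> J5Bundle:
    """Export the binned design as a j5-style bundle.

    Refused while the design has error diagnostics (the correct-by-
    construction gate). Peripheral parts are excluded; source display
    IDs come from the records, never from file names.
    """
    problems = errors_of(validate_design(design))
    if problems:
        raise ValidationRefusedError(problems)

    binned = [p for b in design.bins for p in b.parts]
    seen: set[int] = set()
    parts_buf = _io.StringIO()
    writer = csv.writer(parts_buf)
    writer.writerow(PARTS_CSV_HEADER)
    for p in binned:
        if p.definition_id in seen:
            continue
        seen.add(p.definition_id)
        writer.writerow(
            [p.name, p.source_name, _bool(p.reverse), p.start, p.stop]
        )

    order_buf = _io.StringIO()
    writer = csv.writer(order_buf)
    writer.writerow(ORDER_CSV_HEADER)
    for b in design.bins:
        consensus = bin_consensus_strategy(b)
        writer.writerow(
            [
                f">{b.label}",
                _bool(b.firewall_after),
                consensus.value if consensus else "",
                "" if b.forced_overhang is None else b.forced_overhang,
            ]
        )
        for p in b.parts:
            writer.writerow([p.name, "", "", ""])

    used_sources = {p.source_name for p in binned}
    zip_buf = _io.BytesIO()
    with zipfile.ZipFile(zip_buf, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(used_sources):
            zf.writestr(
                f"{name}.gb", write_genbank_string(design.sources[name])
            )

    return J5Bundle(
        parts_csv=parts_buf.getvalue(),
        order_csv=order_buf.getvalue(),
        rules_text=export_rules_file(design),
        sequences_zip=zip_buf.getvalue(),
    )


def _read_zip_sources(blob: bytes) -> dict[str, AnnotatedSequence]:
    """Parse every Genbank entry of the zip, keyed by record display ID."""
    out: dict[str, AnnotatedSequence] = {}
    with zipfile.ZipFile(_io.BytesIO(blob)) as zf:
        for entry in zf.namelist():
            if entry.endswith("/"):
                continue
            seq = read_genbank_string(zf.read(entry).decode())
            out[seq.name] = seq
    return out


def import_j5_bundle(
    bundle: J5Bundle, topology: str = "circular", name: str = "imported_design"
) -> Design:
    """Auto-generate a minimal design from a j5-style bundle.

    Every part gets the generic glyph (CSV files carry no glyph
    information). The resulting design must validate without errors or
    the import fails with the diagnostic list.
    """
    sources = _read_zip_sources(bundle.sequences_zip)
    design = Design(topology=topology, name=name)
    for s in sources.values():
        design.add_source(s)

    rows = list(csv.reader(_io.StringIO(bundle.parts_csv)))
    if not rows:
        raise ValidationRefusedError(
            [Diagnostic("E_EMPTY_DESIGN", "error", name, "empty parts CSV")]
        )
    header = [h.strip() for h in rows[0]]
    expected = list(PARTS_CSV_HEADER)
    ok_header = len(header) == 5 and (
        header[:2] == expected[:2]
        and header[2] in _REVERSE_ALIASES
        and header[3:] == expected[3:]
    )
    if not ok_header:
        raise FormatError(
            f"parts CSV row 1: unexpected header {header!r}; "
            f"expected {expected!r}"
        )
    parts_by_name: dict[str, Part] = {}
    for row_number, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        if len(row) != 5:
            raise FormatError(
                f"parts CSV row {row_number}: expected 5 cells, got {len(row)}"
            )
        part_name, source_name, reverse, start, stop = (c.strip() for c in row)
        if source_name not in sources:
            raise ReferenceError_(
                f"parts CSV row {row_number}: part {part_name!r} references "
                f"source {source_name!r}, which matches no record display ID "
                f"in the sequences zip (IDs: {sorted(sources)})"
            )
        try:
            start_i, stop_i = int(start), int(stop)
        except ValueError as exc:
            raise FormatError(
                f"parts CSV row {row_number}: non-integer coordinate"
            ) from exc
        part = design.create_part(
            name=part_name,
            source=sources[source_name],
            start=start_i,
            stop=stop_i,
            reverse=_parse_bool(reverse, f"parts CSV row {row_number}"),
            glyph="generic",
        )
        parts_by_name[part_name] = part

    order_rows = list(csv.reader(_io.StringIO(bundle.order_csv)))
    current_bin = None
    bin_strategy: Strategy | None = None
    for row_number, row in enumerate(order_rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        cells = [c.strip() for c in row] + [""] * (4 - len(row))
        label = cells[0]
        if label.startswith(">"):
            overhang = cells[3]
            current_bin = design.add_bin(
                label[1:],
                firewall_after=_parse_bool(
                    cells[1], f"order CSV row {row_number}"
                ),
                forced_overhang=None if overhang == "" else int(overhang),
            )
            bin_strategy = Strategy.parse(cells[2])
        else:
            if current_bin is None:
                raise FormatError(
                    f"order CSV row {row_number}: part row before any >bin row"
                )
            part = parts_by_name.get(label)
            if part is None:
                raise ReferenceError_(
                    f"order CSV row {row_number}: part {label!r} not in parts CSV"
                )
            if design._bin_of(part) is None and part in design.peripheral_parts:
                design.place_part(part, len(design.bins) - 1)
            else:
                design.replicate_part(part, len(design.bins) - 1)
            if bin_strategy is not None and part.forced_strategy is None:
                part.definition.forced_strategy = bin_strategy

    from .rules import import_rules_file

    import_rules_file(design, bundle.rules_text)

    problems = errors_of(validate_design(design))
    if problems:
        raise ValidationRefusedError(problems)
    return design
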