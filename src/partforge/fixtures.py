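"""Seeded synthetic designs for testing and demonstration.

The generator builds random annotated sources, cuts one part per
(bin, slot), and wires bins, glyphs, forced strategies and rule presets
into a design that always validates with zero errors. Generation is
deterministic given (spec, seed); the seed is recorded in the design's
metadata so emitted design files carry their own provenance.

Named shapes:

* ``prdr_like`` — the 6-bin, 9-part tagged-GFP library with bin sizes
  [1, 2, 2, 1, 2, 1] (vector backbone; sig1/sig2 signal peptides;
  long/short linkers; GFPuv; std/enh tags; terminator). Enumerates 8
  constructs; the ``short_with_sig1`` rule preset trims that to 6.
* ``barcode_gene3`` — two consecutive 38-variant direct-synthesis bins
  (DNA barcodes, gene-3 orthologs) for firewall cost accounting.
* three 38-part bins — the 38^3 = 54,872-combination over-expression
  library scale.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .design import Design, Strategy
from .rules import add_rule
from .sequence import AnnotatedSequence, Feature

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
]

_PRDR_NAMES = [
    ["vector_backbone"],
    ["sig1", "sig2"],
    ["long", "short"],
    ["gfpuv"],
    ["std_tag", "enh_tag"],
    ["terminator1"],
]
_PRDR_GLYPHS = [
    ["origin_of_replication"],
    ["signal_peptide", "signal_peptide"],
    ["cds", "cds"],
    ["cds"],
    ["tag", "tag"],
    ["terminator", "terminator"],
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic design."""

    bin_sizes: tuple[int, ...]
    part_length_range: tuple[int, int] = (30, 90)
    seed: int = 0
    rules_preset: str | None = None  # "short_with_sig1"
    topology: str = "circular"
    names_preset: str | None = None  # "prdr_like"
    forced_strategy: Strategy | None = None

    def __post_init__(self):
        if not self.bin_sizes or any(n < 1 for n in self.bin_sizes):
            raise ValueError(f"bin_sizes must be >= 1, got {self.bin_sizes}")
        lo, hi = self.part_length_range
        if not 1 <= lo <= hi:
            raise ValueError(
                f"invalid part_length_range {self.part_length_range}"
            )


def _random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(n))


def _part_names(spec: FixtureSpec) -> list[list[str]]:
    if spec.names_preset == "prdr_like":
        if list(spec.bin_sizes) != [len(b) for b in _PRDR_NAMES]:
            raise ValueError(
                "names_preset 'prdr_like' requires bin_sizes [1,2,2,1,2,1]"
            )
        return _PRDR_NAMES
    return [
        [f"part_b{i + 1}_{j + 1}" for j in range(n)]
        for i, n in enumerate(spec.bin_sizes)
    ]


def _glyphs(spec: FixtureSpec) -> list[list[str]]:
    if spec.names_preset == "prdr_like":
        return _PRDR_GLYPHS
    return [["generic"] * n for n in spec.bin_sizes]


def generate_design(spec: FixtureSpec) -> Design:
    """Build a deterministic random design for the given spec.

    One linear source per bin holds that bin's parts end to end; each
    part carries one fully-contained feature so annotation propagation
    is exercised by every assembly.
    """
    rng = random.Random(spec.seed)
    names = _part_names(spec)
    glyphs = _glyphs(spec)
    design = Design(topology=spec.topology, name=f"fixture_seed{spec.seed}")
    design.meta = {
        "seed": str(spec.seed),
        "bin_sizes": ",".join(str(n) for n in spec.bin_sizes),
    }
    lo, hi = spec.part_length_range
    for i, n in enumerate(spec.bin_sizes):
        lengths = [rng.randint(lo, hi) for _ in range(n)]
        residues = _random_dna(rng, sum(lengths))
        features = []
        offset = 0
        for j, plen in enumerate(lengths):
            f_start = offset + 1 + rng.randrange(max(1, plen // 3))
            f_end = min(offset + plen, f_start + max(1, plen // 2))
            features.append(
                Feature(
                    label=f"feat_{names[i][j]}",
                    feature_type="misc_feature",
                    start=f_start,
                    end=f_end,
                    strand=1,
                )
            )
            offset += plen
        source = AnnotatedSequence(
            f"src_bin{i + 1}_seed{spec.seed}", residues, False, features
        )
        design.add_source(source)
        design.add_bin(f"bin{i + 1}")
        offset = 0
        for j, plen in enumerate(lengths):
            design.create_part(
                name=names[i][j],
                source=source,
                start=offset + 1,
                stop=offset + plen,
                glyph=glyphs[i][j],
                forced_strategy=spec.forced_strategy,
                bin_index=i,
            )
            offset += plen
    if spec.rules_preset is not None:
        apply_rules_preset(design, spec.rules_preset)
    return design


def apply_rules_preset(design: Design, preset: str) -> None:
    if preset == "short_with_sig1":
        add_rule(design, "rule3", "WITH", "short", "sig1")
    else:
        raise ValueError(f"unknown rules preset {preset!r}")


def prdr_like_design(seed: int = 0, with_rule: bool = False) -> Design:
    """The [1,2,2,1,2,1] tagged-GFP library; 8 combinations, 6 under rule3."""
    return generate_design(
        FixtureSpec(
            bin_sizes=(1, 2, 2, 1, 2, 1),
            seed=seed,
            names_preset="prdr_like",
            rules_preset="short_with_sig1" if with_rule else None,
        )
    )


def barcode_gene3_design(
    seed: int = 0, n_variants: int = 38, firewall_between: bool = False
) -> Design:
    """Consecutive direct-synthesis barcode and gene-3 bins.

    Without a firewall between them the two bins form one synthesis
    span of ``n_variants ** 2`` fragments; with the firewall they cost
    ``2 * n_variants``.
    """
    design = generate_design(
        FixtureSpec(
            bin_sizes=(n_variants, n_variants),
            part_length_range=(18, 48),
            seed=seed,
            forced_strategy=Strategy.DIRECT_SYNTHESIS,
        )
    )
    design.name = f"barcode_gene3_seed{seed}"
    design.bins[0].label = "barcode"
    design.bins[1].label = "gene3"
    for j, p in enumerate(design.bins[0].parts):
        design.edit_part_definition(p.definition_id, name=f"barcode_{j + 1:02d}")
    for j, p in enumerate(design.bins[1].parts):
        design.edit_part_definition(p.definition_id, name=f"gene3_{j + 1:02d}")
    design.bins[0].firewall_after = firewall_between
    return design


def library_38x3_design(seed: int = 0) -> Design:
    """Three 38-part bins: 38^3 = 54,872 combinations."""
    return generate_design(
        FixtureSpec(bin_sizes=(38, 38, 38), seed=seed, part_length_range=(20, 40))
    )


def _codons(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(_SAFE_CODONS) for _ in range(n))


def generate_frame_fixture(seed: int = 0) -> Design:
    """A signal-peptide/linker/CDS/tag fusion whose open reading frame is
    intact by construction.

    Every part length is divisible by 3; the signal peptide starts with
    ATG; no part contains an in-frame stop codon except the final codon
    of the tag (TAA). The CDS deliberately carries a TTA leucine codon,
    so reverse-orienting the CDS part introduces an in-frame TAA — the
    negative control a translation check must catch.
    """
    rng = random.Random(seed)
    sig = "ATG" + _codons(rng, 7)
    linker_long = _codons(rng, 6)
    linker_short = _codons(rng, 2)
    cds = _codons(rng, 3) + "TTA" + _codons(rng, 16)
    tag = _codons(rng, 4) + "TAA"

    segments = [
        ("sig_pep", "signal_peptide", sig),
        ("linker_long", "cds", linker_long),
        ("linker_short", "cds", linker_short),
        ("orf_main", "cds", cds),
        ("c_tag", "tag", tag),
    ]
    residues = "".join(s for _, _, s in segments)
    source = AnnotatedSequence(f"frame_src_seed{seed}", residues, False, [])
    design = Design(topology="linear", name=f"frame_fixture_seed{seed}")
    design.meta = {"seed": str(seed)}
    design.add_source(source)
    layout = [["sig_pep"], ["linker_long", "linker_short"], ["orf_main"], ["c_tag"]]
    offsets: dict[str, tuple[int, int]] = {}
    pos = 1
    for seg_name, _, seg in segments:
        offsets[seg_name] = (pos, pos + len(seg) - 1)
        pos += len(seg)
    glyph_of = {name: glyph for name, glyph, _ in segments}
    for i, bin_names in enumerate(layout):
        design.add_bin(f"bin{i + 1}")
        for pname in bin_names:
            start, stop = offsets[pname]
            design.create_part(
                name=pname,
                source=source,
                start=start,
                stop=stop,
                glyph=glyph_of[pname],
                bin_index=i,
            )
    return design
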