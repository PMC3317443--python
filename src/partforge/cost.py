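"""Direct-synthesis fragment accounting under firewall placements.

Bins whose consensus strategy is DIRECT_SYNTHESIS form maximal
contiguous synthesis spans; a firewall set after a bin splits the span
at that junction. Each span requires one distinct synthesized fragment
per combination of its member-bin variants, so a span's fragment count
is the product of its bin sizes and the design total is the sum over
spans. This is why a misplaced firewall is expensive: two 38-variant
bins left in one span cost 38 x 38 = 1444 fragments, while a firewall
between them costs 38 + 38 = 76.

Fragment identity is by variant combination (which part was chosen in
each bin), not by sequence string equality: duplicated sequences across
variants still count separately.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .design import Design, Strategy, bin_consensus_strategy
from .errors import StructureError


@dataclass
class SynthesisSpan:
    """A maximal run of direct-synthesis bins synthesized as one fragment class."""

    bin_indices: tuple[int, ...]  # 0-based, contiguous
    fragment_count: int


@dataclass
class FragmentAccount:
    spans: list[SynthesisSpan]
    total: int
    warnings: list[str] = field(default_factory=list)


def synthesis_spans(design: Design) -> list[SynthesisSpan]:
    """Partition the direct-synthesis bins into firewall-respecting spans."""
    ds = [
        bin_consensus_strategy(b) is Strategy.DIRECT_SYNTHESIS
        for b in design.bins
    ]
    spans: list[SynthesisSpan] = []
    run: list[int] = []

    def close_run() -> None:
        if run:
            count = 1
            for i in run:
                count *= len(design.bins[i].parts)
            spans.append(SynthesisSpan(tuple(run), count))
            run.clear()

    for i, is_ds in enumerate(ds):
        if is_ds:
            run.append(i)
            if design.bins[i].firewall_after:
                close_run()
        else:
            close_run()
    close_run()
    return spans


def count_fragments(design: Design) -> FragmentAccount:
    """Total distinct fragments plus the per-span breakdown."""
    warnings = [
        f"firewall after bin {i + 1} ({b.label!r}) lies outside a "
        "direct-synthesis run and has no effect"
        for i, b in enumerate(design.bins)
        if b.firewall_after
        and bin_consensus_strategy(b) is not Strategy.DIRECT_SYNTHESIS
    ]
    spans = synthesis_spans(design)
    return FragmentAccount(
        spans=spans,
        total=sum(s.fragment_count for s in spans),
        warnings=warnings,
    )


@dataclass
class PlacementResult:
    placement: tuple[bool, ...]
    spans: list[SynthesisSpan]
    total: int
    is_minimum: bool = False


def compare_firewall_placements(
    design: Design, placements: list[list[bool]]
) -> list[PlacementResult]:
    """Evaluate candidate firewall layouts; the minimum total is flagged.

    Each placement is a boolean vector over bins (firewall after bin i).
    The design's own firewall flags are restored afterwards.
    """
    n = len(design.bins)
    for p in placements:
        if len(p) != n:
            raise StructureError(
                f"placement length {len(p)} does not match bin count {n}"
            )
    saved = [b.firewall_after for b in design.bins]
    results: list[PlacementResult] = []
    try:
        for p in placements:
            for b, flag in zip(design.bins, p):
                b.firewall_after = bool(flag)
            account = count_fragments(design)
            results.append(
                PlacementResult(tuple(bool(x) for x in p), account.spans, account.total)
            )
    finally:
        for b, flag in zip(design.bins, saved):
            b.firewall_after = flag
    if results:
        best = min(r.total for r in results)
        for r in results:
            r.is_minimum = r.total == best
    return results


def write_cost_csv(results: list[PlacementResult], path) -> None:
    with open(str(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["placement_id", "firewalls_after_bins", "span_ranges",
             "per_span_counts", "total", "minimum"]
        )
        for i, r in enumerate(results, start=1):
            writer.writerow(
                [
                    i,
                    ";".join(
                        str(j + 1) for j, f in enumerate(r.placement) if f
                    ),
                    ";".join(
                        f"{s.bin_indices[0] + 1}-{s.bin_indices[-1] + 1}"
                        for s in r.spans
                    ),
                    ";".join(str(s.fragment_count) for s in r.spans),
                    r.total,
                    "TRUE" if r.is_minimum else "FALSE",
                ]
            )
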