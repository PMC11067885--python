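"""Collinearity chaining and four-class partition of the target genome.

Collinearity is taken in its strictest sense: a chain is an uninterrupted
succession of alignments on the same chromosome strand and in the same
order in both genomes.  It is interrupted by inversions (a change of
alignment strand) and by translocations (one extra aligned region present
in one genome only) of any length — but never by the length of the
unaligned gap between two members.

The target genome is then partitioned into four classes:

* ``collinear_alignment`` — an aligned block that belongs to a chain;
* ``bridge``              — unaligned sequence strictly between two
                            consecutive members of one chain;
* ``isolated_alignment``  — an aligned block collinear with nothing;
* ``breakpoint``          — every remaining unaligned region; where two
                            non-collinear blocks abut, a zero-width
                            breakpoint is recorded at the shared boundary.

Zero-width breakpoints are first-class: they are counted and written as
zero-length BED features, because breakpoint-region counts must not depend
on how much unalignable sequence an event left behind.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AlignmentBlock, AlignmentSet, GenomeLayout

__all__ = [
    "CLASS_NAMES",
    "Chain",
    "Segment",
    "SegmentationResult",
    "chain_collinear",
    "classify_segments",
    "segment",
    "segment_both_directions",
    "class_coverage",
]

CLASS_NAMES = ("collinear_alignment", "bridge", "breakpoint", "isolated_alignment")


@dataclass
class Chain:
    """A maximal run of >= 2 mutually adjacent, same-strand blocks."""

    member_ids: list[int]
    orientation: str
    t_span: tuple[str, int, int]
    q_span: tuple[str, int, int]
    bridges: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    cls: str

    @property
    def width(self) -> int:
        return self.end - self.start


class SegmentationResult:
    """Complete partition of the target genome into the four classes."""

    def __init__(
        self,
        segments: dict[str, list[Segment]],
        chains: list[Chain],
        layout: GenomeLayout,
    ):
        self.segments = segments
        self.chains = chains
        self.layout = layout

    def iter_segments(self):
        for chrom in sorted(self.segments):
            for seg in self.segments[chrom]:
                yield seg.chrom, seg.start, seg.end, seg.cls

    def breakpoints(
        self, chrom: str | None = None, include_zero_width: bool = True
    ) -> list[Segment]:
        out = []
        chroms = [chrom] if chrom is not None else sorted(self.segments)
        for c in chroms:
            for seg in self.segments[c]:
                if seg.cls == "breakpoint" and (include_zero_width or seg.width > 0):
                    out.append(seg)
        return out

    def class_lengths(self) -> dict[str, int]:
        out = dict.fromkeys(CLASS_NAMES, 0)
        for segs in self.segments.values():
            for seg in segs:
                out[seg.cls] += seg.width
        return out

    def aligned_length(self) -> int:
        lengths = self.class_lengths()
        return lengths["collinear_alignment"] + lengths["isolated_alignment"]

    def chain_table(self) -> pd.DataFrame:
        rows = []
        for i, ch in enumerate(self.chains):
            rows.append(
                {
                    "chain_id": i,
                    "n_members": len(ch.member_ids),
                    "member_ids": ",".join(map(str, ch.member_ids)),
                    "orientation": ch.orientation,
                    "t_chrom": ch.t_span[0],
                    "t_start": ch.t_span[1],
                    "t_end": ch.t_span[2],
                    "q_chrom": ch.q_span[0],
                    "q_start": ch.q_span[1],
                    "q_end": ch.q_span[2],
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "chain_id", "n_members", "member_ids", "orientation",
                "t_chrom", "t_start", "t_end", "q_chrom", "q_start", "q_end",
            ],
        )


def _order_index(blocks: list[AlignmentBlock], side: str) -> dict[int, tuple[str, int]]:
    """block id -> (chromosome, rank among aligned blocks on that chromosome)."""
    if side == "target":
        key = lambda b: (b.t_chrom, b.t_start)
        chrom_of = lambda b: b.t_chrom
    else:
        key = lambda b: (b.q_chrom, b.q_start)
        chrom_of = lambda b: b.q_chrom
    out: dict[int, tuple[str, int]] = {}
    rank = 0
    prev_chrom = None
    for b in sorted(blocks, key=key):
        chrom = chrom_of(b)
        if chrom != prev_chrom:
            rank = 0
            prev_chrom = chrom
        out[b.id] = (chrom, rank)
        rank += 1
    return out


def _linked(a: AlignmentBlock, b: AlignmentBlock, t_idx, q_idx) -> bool:
    """True iff block b directly follows block a in a collinear chain.

    b must be the next aligned block after a on the target chromosome, the
    neighbouring aligned block on the query chromosome in the direction the
    shared strand dictates, and on the same strand.  Ranks count every
    aligned block on a chromosome, so one extra aligned region on either
    genome — whatever its partner chromosome — breaks adjacency.
    """
    if a.strand != b.strand or a.q_chrom != b.q_chrom or a.t_chrom != b.t_chrom:
        return False
    if t_idx[b.id][1] != t_idx[a.id][1] + 1:
        return False
    step = 1 if a.strand == "+" else -1
    return q_idx[b.id][1] == q_idx[a.id][1] + step


def chain_collinear(aln: AlignmentSet) -> list[Chain]:
    """Maximal collinear chains of an alignment set.

    Returns chains of >= 2 members; blocks in no chain are isolated.
    """
    blocks = aln.by_target()
    if not blocks:
        return []
    t_idx = _order_index(blocks, "target")
    q_idx = _order_index(blocks, "query")

    chains: list[Chain] = []
    run: list[AlignmentBlock] = [blocks[0]]
    for prev, cur in zip(blocks, blocks[1:]):
        if _linked(prev, cur, t_idx, q_idx):
            run.append(cur)
        else:
            if len(run) >= 2:
                chains.append(_make_chain(run))
            run = [cur]
    if len(run) >= 2:
        chains.append(_make_chain(run))
    return chains


def _make_chain(run: list[AlignmentBlock]) -> Chain:
    bridges = [
        (a.t_end, b.t_start) for a, b in zip(run, run[1:]) if b.t_start > a.t_end
    ]
    return Chain(
        member_ids=[b.id for b in run],
        orientation=run[0].strand,
        t_span=(run[0].t_chrom, run[0].t_start, run[-1].t_end),
        q_span=(
            run[0].q_chrom,
            min(b.q_start for b in run),
            max(b.q_end for b in run),
        ),
        bridges=bridges,
    )


def classify_segments(aln: AlignmentSet, chains: list[Chain]) -> SegmentationResult:
    """Partition every target chromosome into the four region classes.

    Unaligned sequence before the first and after the last aligned block is
    breakpoint, never bridge (bridges exist only between chain members).
    Chromosomes with no alignment at all are one whole-length breakpoint.
    """
    known_ids = {b.id for b in aln.blocks}
    in_chain: set[int] = set()
    successor: set[tuple[int, int]] = set()
    for ch in chains:
        for bid in ch.member_ids:
            if bid not in known_ids:
                raise ValueError(f"chain references unknown block id {bid}")
            in_chain.add(bid)
        for a, b in zip(ch.member_ids, ch.member_ids[1:]):
            successor.add((a, b))

    by_chrom: dict[str, list[AlignmentBlock]] = {}
    for b in aln.by_target():
        by_chrom.setdefault(b.t_chrom, []).append(b)

    segments: dict[str, list[Segment]] = {}
    for chrom_layout in aln.target_layout:
        chrom, length = chrom_layout.name, chrom_layout.length
        segs: list[Segment] = []
        blocks = by_chrom.get(chrom, [])
        if not blocks:
            segs.append(Segment(chrom, 0, length, "breakpoint"))
            segments[chrom] = segs
            continue
        if blocks[0].t_start > 0:
            segs.append(Segment(chrom, 0, blocks[0].t_start, "breakpoint"))
        for i, b in enumerate(blocks):
            cls = "collinear_alignment" if b.id in in_chain else "isolated_alignment"
            segs.append(Segment(chrom, b.t_start, b.t_end, cls))
            if i + 1 < len(blocks):
                nxt = blocks[i + 1]
                gap_cls = "bridge" if (b.id, nxt.id) in successor else "breakpoint"
                if nxt.t_start > b.t_end:
                    segs.append(Segment(chrom, b.t_end, nxt.t_start, gap_cls))
                elif gap_cls == "breakpoint":
                    # abutting non-collinear blocks: zero-width breakpoint
                    segs.append(Segment(chrom, b.t_end, b.t_end, "breakpoint"))
        if blocks[-1].t_end < length:
            segs.append(Segment(chrom, blocks[-1].t_end, length, "breakpoint"))
        segments[chrom] = segs
    return SegmentationResult(segments, chains, aln.target_layout)


def segment(aln: AlignmentSet) -> SegmentationResult:
    """Chain and classify in one call."""
    return classify_segments(aln, chain_collinear(aln))


def segment_both_directions(
    aln: AlignmentSet,
) -> tuple[SegmentationResult, SegmentationResult]:
    """Target-centric and query-centric segmentations of one alignment."""
    return segment(aln), segment(aln.swapped())


def class_coverage(seg: SegmentationResult) -> pd.DataFrame:
    """Per-class genome coverage plus breakpoint count/width statistics.

    Returns a one-row-per-class table; fractions sum to 1.  Attributes
    ``n_breakpoints`` (all, including zero-width), ``n_breakpoints_positive``
    and breakpoint width mean/SD ride along in ``DataFrame.attrs``.
    """
    lengths = seg.class_lengths()
    total = seg.layout.total_length
    rows = [
        {"cls": cls, "total_bases": lengths[cls], "fraction_of_genome": lengths[cls] / total}
        for cls in CLASS_NAMES
    ]
    df = pd.DataFrame(rows)
    widths = np.array([s.width for s in seg.breakpoints()], dtype=float)
    df.attrs["n_breakpoints"] = int(widths.size)
    df.attrs["n_breakpoints_positive"] = int((widths > 0).sum())
    df.attrs["breakpoint_width_mean"] = float(widths.mean()) if widths.size else float("nan")
    df.attrs["breakpoint_width_sd"] = float(widths.std(ddof=1)) if widths.size > 1 else float("nan")
    return df
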