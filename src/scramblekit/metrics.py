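"""Scrambling index, breakpoint-accumulation rate and macrosynteny blocks.

The scrambling index (strand-randomisation index) of a grouping unit — a
chromosome or a chromosome arm — is

    | L_same - L_opposite | / (L_same + L_opposite)

where L_same / L_opposite are the total lengths, measured on the target
genome within the unit, of same-strand and opposite-strand alignments.
A value of 1 means all alignments agree in orientation (note a whole-unit
inversion also scores 1: the absolute value makes the index insensitive
to which orientation dominates); a value of 0 means the two orientations
are balanced, i.e. orientations look random.  The genome-wide summary is
the mean of unit indices weighted by full unit sequence length (not
aligned length); units with no aligned base are undefined and excluded
from both the numerator and the weight sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .io_formats import AlignmentSet, GenomeLayout, ValidationError

__all__ = [
    "ScramblingIndexReport",
    "BreakpointRate",
    "SyntenyBlock",
    "strand_randomisation_index",
    "scrambling_index",
    "breakpoint_rate",
    "breakpoint_rate_from_counts",
    "synteny_blocks",
    "synteny_block_histogram",
    "dotplot_table",
]


@dataclass
class ScramblingIndexReport:
    """Per-unit strand-randomisation indices and their weighted mean."""

    per_unit: pd.DataFrame  # unit, L_same, L_opposite, index, weight
    weighted_mean: float
    grouping: str

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ScramblingIndexReport grouping={self.grouping!r} "
            f"weighted_mean={self.weighted_mean:.4f} units={len(self.per_unit)}>"
        )


@dataclass(frozen=True)
class BreakpointRate:
    """Breakpoint regions per megabase aligned per million years diverged."""

    n_breakpoints: int
    aligned_length: int
    divergence_time: float

    @property
    def rate(self) -> float:
        return self.n_breakpoints / (self.aligned_length / 1e6) / self.divergence_time


@dataclass
class SyntenyBlock:
    """A maximal run of single-copy ortholog pairs with consecutive ranks
    along both genomes (query rank ascending or descending; strand ignored)."""

    pairs: list[tuple[str, str]]
    t_chrom: str
    q_chrom: str

    @property
    def size(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Scrambling index
# ---------------------------------------------------------------------------


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def strand_randomisation_index(
    aln: AlignmentSet, unit_chrom: str, unit_interval: tuple[int, int] | None = None
) -> float:
    """Index for one target chromosome, or one interval of it (an arm).

    Returns NaN when the unit contains no aligned base (undefined value;
    callers exclude such units from averaging).
    """
    lo, hi = unit_interval if unit_interval else (0, aln.target_layout.length(unit_chrom))
    same = opposite = 0
    for b in aln.blocks:
        if b.t_chrom != unit_chrom:
            continue
        w = _overlap(b.t_start, b.t_end, lo, hi)
        if w == 0:
            continue
        if b.strand == "+":
            same += w
        else:
            opposite += w
    total = same + opposite
    if total == 0:
        return math.nan
    return abs(same - opposite) / total


def scrambling_index(
    aln: AlignmentSet, grouping: str = "chromosome", layout: GenomeLayout | None = None
) -> ScramblingIndexReport:
    """Per-unit indices plus the length-weighted genome-wide mean.

    grouping "chromosome" weights by chromosome length; grouping "arm"
    requires arm annotations in the layout (default: the alignment's own
    target layout) and weights by arm length.  Weights use full unit
    sequence length including unaligned bases.
    """
    layout = layout or aln.target_layout
    units: list[tuple[str, str, int, int, int]] = []  # unit label, chrom, lo, hi, weight
    if grouping == "chromosome":
        for c in layout:
            units.append((c.name, c.name, 0, c.length, c.length))
    elif grouping == "arm":
        any_arms = False
        for c in layout:
            for arm in c.arms:
                any_arms = True
                units.append(
                    (f"{c.name}:{arm.name}", c.name, arm.start, arm.end, arm.end - arm.start)
                )
        if not any_arms:
            raise ValidationError("arm grouping requires arm annotations in the layout")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    num = wsum = 0.0
    for label, chrom, lo, hi, weight in units:
        same = opposite = 0
        for b in aln.blocks:
            if b.t_chrom != chrom:
                continue
            w = _overlap(b.t_start, b.t_end, lo, hi)
            if b.strand == "+":
                same += w
            else:
                opposite += w
        total = same + opposite
        idx = abs(same - opposite) / total if total else math.nan
        rows.append(
            {"unit": label, "L_same": same, "L_opposite": opposite,
             "index": idx, "weight": weight}
        )
        if total:
            num += weight * idx
            wsum += weight
    per_unit = pd.DataFrame(rows, columns=["unit", "L_same", "L_opposite", "index", "weight"])
    weighted_mean = num / wsum if wsum else math.nan
    return ScramblingIndexReport(per_unit, weighted_mean, grouping)


# ---------------------------------------------------------------------------
# Breakpoint accumulation rate
# ---------------------------------------------------------------------------


def breakpoint_rate_from_counts(
    n_breakpoints: int, aligned_length: int, divergence_time: float
) -> BreakpointRate:
    """Rate from raw counts: breakpoints / (aligned Mbp) / My.

    Divergence time enters once (time since the split, not twice the
    branch length).
    """
    if divergence_time <= 0:
        raise ValueError("divergence_time must be positive")
    if aligned_length <= 0:
        raise ValueError("aligned_length must be positive")
    if n_breakpoints < 0:
        raise ValueError("n_breakpoints must be >= 0")
    return BreakpointRate(n_breakpoints, aligned_length, divergence_time)


def breakpoint_rate(
    seg, divergence_time: float, count_zero_width: bool = True
) -> BreakpointRate:
    """Breakpoint accumulation rate of a segmentation.

    Aligned length is the total of collinear and isolated alignment bases
    on the target genome.
    """
    n = len(seg.breakpoints(include_zero_width=count_zero_width))
    return breakpoint_rate_from_counts(n, seg.aligned_length(), divergence_time)


# ---------------------------------------------------------------------------
# Ortholog-based macrosynteny blocks
# ---------------------------------------------------------------------------


def _rank_genes(pairs: pd.DataFrame, prefix: str) -> pd.Series:
    """Rank genes along one genome by (chromosome, start) among the pairs."""
    order = pairs.sort_values([f"{prefix}_chrom", f"{prefix}_start"]).index
    ranks = pd.Series(range(len(order)), index=order)
    return ranks.reindex(pairs.index)


def synteny_blocks(pairs: pd.DataFrame) -> list[SyntenyBlock]:
    """Partition single-copy ortholog pairs into strand-independent blocks.

    ``pairs`` needs columns t_gene, t_chrom, t_start, q_gene, q_chrom,
    q_start.  Genes are ranked along each genome by (chromosome, start)
    among single-copy orthologs only, so intervening non-ortholog genes
    never break a run.  Blocks are maximal runs whose ranks are consecutive
    in both genomes, with the query rank ascending or descending; every
    pair belongs to exactly one block (size >= 1).
    """
    if pairs.empty:
        return []
    for col in ("t_gene", "q_gene"):
        if pairs[col].duplicated().any():
            dup = pairs[col][pairs[col].duplicated()].iloc[0]
            raise ValidationError(f"gene {dup!r} appears in more than one pair")
    df = pairs.copy()
    df["t_rank"] = _rank_genes(df, "t")
    df["q_rank"] = _rank_genes(df, "q")
    df = df.sort_values("t_rank").reset_index(drop=True)

    blocks: list[SyntenyBlock] = []
    run: list[pd.Series] = [df.iloc[0]]
    direction = 0  # 0 = undecided (run of size 1)
    for i in range(1, len(df)):
        row = df.iloc[i]
        prev = run[-1]
        same_chroms = (row.t_chrom == prev.t_chrom) and (row.q_chrom == prev.q_chrom)
        dq = row.q_rank - prev.q_rank
        ok = same_chroms and row.t_rank == prev.t_rank + 1 and abs(dq) == 1 and (
            direction == 0 or dq == direction
        )
        if ok:
            run.append(row)
            direction = dq
        else:
            blocks.append(_finish_block(run))
            run, direction = [row], 0
    blocks.append(_finish_block(run))
    return blocks


def _finish_block(run: list[pd.Series]) -> SyntenyBlock:
    return SyntenyBlock(
        pairs=[(r.t_gene, r.q_gene) for r in run],
        t_chrom=run[0].t_chrom,
        q_chrom=run[0].q_chrom,
    )


def synteny_block_histogram(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """Block-size histogram: one row per observed size, with counts."""
    sizes = pd.Series([b.size for b in blocks], dtype=int)
    hist = sizes.value_counts().sort_index()
    return pd.DataFrame({"block_size": hist.index, "count": hist.values})


def dotplot_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Macrosynteny dot-plot export: one row per ortholog pair.

    Positions are gene midpoints; needs the synteny_blocks columns plus
    t_end / q_end.  Deterministic (target chromosome, position) order.
    """
    out = pd.DataFrame(
        {
            "t_chrom": pairs["t_chrom"],
            "t_pos": (pairs["t_start"] + pairs["t_end"]) // 2,
            "q_chrom": pairs["q_chrom"],
            "q_pos": (pairs["q_start"] + pairs["q_end"]) // 2,
        }
    )
    return out.sort_values(["t_chrom", "t_pos"], kind="stable").reset_index(drop=True)
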