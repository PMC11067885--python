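"""Operon calling, cross-genome operon equivalence, and breakpoint overlap.

An operon here is a maximal run of >= 2 genes on the same strand of the
same chromosome separated by intergenic gaps of at most ``max_gap`` bases
(default 500).  Tunicate operons are transcribed polycistronically and
resolved by trans-splicing; at the annotation level the 500-bp intergenic
rule is what identifies them.  Overlapping same-strand genes count as gap
zero and are merged.

Two operons from different genomes are equivalent when their genes map to
the same orthogroups: "exact" requires the orthogroup multisets to be
identical; "inexact" additionally accepts one substituted gene, but only
for operons of three or more genes (so ABC matches ABC, XBC, AXC and ABX,
while AB matches only AB).  Genes lacking an orthogroup assignment never
match any gene.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FeatureTrack, GeneModel, OrthologMap, ValidationError
from .segmentation import SegmentationResult

__all__ = [
    "Operon",
    "EquivalenceCriteria",
    "call_operons",
    "operon_equivalent",
    "shared_operons",
    "breakpoint_overlap",
    "overlaps_breakpoint",
    "operonic_status_test",
    "operon_size_by_breakpoint",
    "OperonicStatusResult",
]


@dataclass
class Operon:
    operon_id: str
    chrom: str
    strand: str
    gene_ids: list[str]
    start: int
    end: int

    @property
    def size(self) -> int:
        return len(self.gene_ids)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class EquivalenceCriteria:
    gene_equivalence: str = "HOG"  # HOG | OG
    operon_equivalence: str = "exact"  # exact | inexact

    def __post_init__(self) -> None:
        if self.gene_equivalence not in ("HOG", "OG"):
            raise ValueError("gene_equivalence must be HOG or OG")
        if self.operon_equivalence not in ("exact", "inexact"):
            raise ValueError("operon_equivalence must be exact or inexact")


# ---------------------------------------------------------------------------
# Operon calling
# ---------------------------------------------------------------------------


def call_operons(genes: list[GeneModel], max_gap: int = 500) -> list[Operon]:
    """Maximal same-strand gene runs with intergenic gaps <= max_gap.

    Singleton genes are not operons.  Gap is (next gene start) - (previous
    gene end) on gene spans; negative gaps (overlapping genes) count as 0.
    """
    operons: list[Operon] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.end))
        run: list[GeneModel] = []
        for g in chrom_genes:
            if run and g.strand == run[-1].strand and max(0, g.start - run[-1].end) <= max_gap:
                run.append(g)
            else:
                if len(run) >= 2:
                    operons.append(_make_operon(run))
                run = [g]
        if len(run) >= 2:
            operons.append(_make_operon(run))
    return operons


def _make_operon(run: list[GeneModel]) -> Operon:
    start = run[0].start
    end = max(g.end for g in run)
    return Operon(
        operon_id=f"{run[0].chrom}:{start}-{end}",
        chrom=run[0].chrom,
        strand=run[0].strand,
        gene_ids=[g.gene_id for g in run],
        start=start,
        end=end,
    )


def operon_track(operons: list[Operon]) -> FeatureTrack:
    return FeatureTrack("operon", sorted((o.chrom, o.start, o.end) for o in operons))


# ---------------------------------------------------------------------------
# Equivalence
# ---------------------------------------------------------------------------

_MISSING = object()


def _orthogroup_multiset(op: Operon, assignments: dict[str, str]) -> list:
    """Orthogroup ids of the operon's genes; unassigned genes become unique
    sentinels that compare equal to nothing."""
    out: list = []
    for i, gid in enumerate(op.gene_ids):
        og = assignments.get(gid)
        out.append(og if og is not None else (_MISSING, op.operon_id, i))
    return out


def operon_equivalent(
    op1: Operon,
    op2: Operon,
    omap_or_assignments,
    crit: EquivalenceCriteria = EquivalenceCriteria(),
    genome1: str | None = None,
    genome2: str | None = None,
) -> bool:
    """Whether two operons are equivalent under the given criteria.

    Order and strand are ignored: comparison is on orthogroup multisets.
    Pass either an OrthologMap plus the two genome ids, or a pre-built
    ``(assignments1, assignments2)`` tuple of gene -> orthogroup dicts.
    """
    if isinstance(omap_or_assignments, OrthologMap):
        a1 = omap_or_assignments.assignments(genome1, crit.gene_equivalence)
        a2 = omap_or_assignments.assignments(genome2, crit.gene_equivalence)
    else:
        a1, a2 = omap_or_assignments
    m1 = Counter(_orthogroup_multiset(op1, a1))
    m2 = Counter(_orthogroup_multiset(op2, a2))
    if m1 == m2:
        return True
    if crit.operon_equivalence == "inexact":
        if op1.size != op2.size or op1.size < 3:
            return False
        diff = sum((m1 - m2).values())
        return diff == 1 and sum((m2 - m1).values()) == 1
    return False


def shared_operons(
    operon_sets: dict[str, list[Operon]],
    omap: OrthologMap,
    crit: EquivalenceCriteria = EquivalenceCriteria(),
    reference: str | None = None,
) -> dict[frozenset, int]:
    """Count reference-genome operons by the exact set of genomes sharing them.

    For each operon of the reference genome, the key is the frozenset of
    other genomes that contain at least one equivalent operon; the empty
    frozenset collects operons unique to the reference.  Counts over all
    subsets sum to the reference operon count.
    """
    genomes = sorted(operon_sets)
    if len(genomes) < 2:
        raise ValidationError("shared_operons needs >= 2 genomes")
    reference = reference or genomes[0]
    assignments = {
        g: omap.assignments(g, crit.gene_equivalence) for g in genomes
    }
    counts: dict[frozenset, int] = {}
    others = [g for g in genomes if g != reference]
    for op in operon_sets[reference]:
        sharing = frozenset(
            g
            for g in others
            if any(
                operon_equivalent(op, other_op, (assignments[reference], assignments[g]), crit)
                for other_op in operon_sets[g]
            )
        )
        counts[sharing] = counts.get(sharing, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Breakpoint overlap
# ---------------------------------------------------------------------------


def _breakpoint_arrays(seg: SegmentationResult) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out = {}
    for chrom in seg.segments:
        bps = seg.breakpoints(chrom)
        starts = np.array([b.start for b in bps], dtype=np.int64)
        ends = np.array([b.end for b in bps], dtype=np.int64)
        out[chrom] = (starts, ends)
    return out


def overlaps_breakpoint(
    chrom: str, start: int, end: int, bp_arrays: dict[str, tuple[np.ndarray, np.ndarray]]
) -> bool:
    """Half-open intersection with any breakpoint region.

    A zero-width breakpoint at p overlaps the element iff start < p < end
    (a point sitting exactly on an element edge does not cut it).
    """
    if chrom not in bp_arrays:
        raise ValidationError(f"chromosome {chrom!r} absent from segmentation")
    starts, ends = bp_arrays[chrom]
    if starts.size == 0:
        return False
    pos = (starts < ends) & (starts < end) & (ends > start)
    zero = (starts == ends) & (starts > start) & (starts < end)
    return bool((pos | zero).any())


def breakpoint_overlap(
    elements: dict[str, list[tuple[str, int, int]]] | dict[str, FeatureTrack],
    seg: SegmentationResult,
) -> pd.DataFrame:
    """Per element class: how many elements intersect >= 1 breakpoint region.

    ``elements`` maps a class name (operon/gene/exon/...) to its intervals.
    Returns columns element_class, n_total, n_overlapping, proportion.
    """
    bp_arrays = _breakpoint_arrays(seg)
    rows = []
    for cls in sorted(elements):
        track = elements[cls]
        intervals = track.intervals if isinstance(track, FeatureTrack) else track
        n_total = len(intervals)
        n_over = sum(
            overlaps_breakpoint(c, s, e, bp_arrays) for c, s, e in intervals
        )
        rows.append(
            {
                "element_class": cls,
                "n_total": n_total,
                "n_overlapping": n_over,
                "proportion": n_over / n_total if n_total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Operonic-status contingency test
# ---------------------------------------------------------------------------


@dataclass
class OperonicStatusResult:
    """Association between operonic status of orthologous genes in two genomes.

    ``counts`` orders the four joint categories as (both, A only, B only,
    neither).  The headline statistic is a 4-category goodness-of-fit of
    the observed joint counts against expectations from independent
    marginal operonic rates (df = 3); the plain 2x2 independence test
    (df = 1) is reported alongside as a cross-check.
    """

    counts: dict[str, int]
    expected: dict[str, float]
    chi2: float
    df: int
    p: float
    chi2_2x2: float
    p_2x2: float

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.counts),
                "observed": list(self.counts.values()),
                "expected": [self.expected[k] for k in self.counts],
            }
        )


def operonic_status_test(
    pairs: list[tuple[str, str]],
    operonic_a: set[str],
    operonic_b: set[str],
) -> OperonicStatusResult:
    """Are operonic genes in genome A more likely to be operonic in genome B?

    Classifies each single-copy ortholog pair as operonic in both genomes,
    in A only, in B only, or neither, and tests the observed 4-cell counts
    against the products of the marginal operonic rates.
    """
    n = len(pairs)
    if n == 0:
        raise ValidationError("no ortholog pairs given")
    obs = {"both": 0, "a_only": 0, "b_only": 0, "neither": 0}
    for ga, gb in pairs:
        ina, inb = ga in operonic_a, gb in operonic_b
        key = ("both" if inb else "a_only") if ina else ("b_only" if inb else "neither")
        obs[key] += 1
    pa = (obs["both"] + obs["a_only"]) / n
    pb = (obs["both"] + obs["b_only"]) / n
    exp = {
        "both": n * pa * pb,
        "a_only": n * pa * (1 - pb),
        "b_only": n * (1 - pa) * pb,
        "neither": n * (1 - pa) * (1 - pb),
    }
    if any(e == 0 for e in exp.values()):
        raise ValidationError(
            "degenerate test: an expected count is zero (a marginal rate is 0 or 1)"
        )
    chi2 = sum((obs[k] - exp[k]) ** 2 / exp[k] for k in obs)
    df = 3
    p = float(stats.chi2.sf(chi2, df))
    table = np.array(
        [[obs["both"], obs["a_only"]], [obs["b_only"], obs["neither"]]], dtype=float
    )
    res = stats.chi2_contingency(table, correction=False)
    return OperonicStatusResult(
        counts=obs, expected=exp, chi2=float(chi2), df=df, p=p,
        chi2_2x2=float(res.statistic), p_2x2=float(res.pvalue),
    )


# ---------------------------------------------------------------------------
# Operon size vs breakpoint overlap
# ---------------------------------------------------------------------------


def operon_size_by_breakpoint(
    operons: list[Operon], seg: SegmentationResult
) -> dict:
    """Operon size distributions split by breakpoint-overlap status.

    Returns sizes of overlapping and non-overlapping operons and a
    two-sided Wilcoxon rank-sum (Mann-Whitney) comparison; if either group
    is empty the test is reported as missing.
    """
    bp_arrays = _breakpoint_arrays(seg)
    over, non = [], []
    for op in operons:
        (over if overlaps_breakpoint(op.chrom, op.start, op.end, bp_arrays) else non).append(
            op.size
        )
    out = {
        "sizes_overlapping": over,
        "sizes_non_overlapping": non,
        "statistic": None,
        "p_value": None,
        "note": None,
    }
    if not over or not non:
        out["note"] = "one group empty; no test performed"
        return out
    res = stats.mannwhitneyu(over, non, alternative="two-sided")
    out["statistic"] = float(res.statistic)
    out["p_value"] = float(res.pvalue)
    return out
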