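"""Readers/writers for the interchange formats the pipeline touches.

Internal coordinate convention: 0-based, half-open, on the forward strand of
both genomes.  Strand is a property of an alignment block (the relative
orientation of the two genomes over that block), never of an interval.
GFF3 (1-based inclusive) and MAF (minus-strand coordinates counted from the
sequence end) are converted at the boundary; PAF and BED already use the
internal convention.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

ARM_CLASSES = {"short", "long", "PAR", "XSR", "YSR", "unassigned"}

__all__ = [
    "ARM_CLASSES",
    "Arm",
    "ChromosomeLayout",
    "GenomeLayout",
    "AlignmentBlock",
    "AlignmentSet",
    "GeneModel",
    "FeatureTrack",
    "OrthologMap",
    "ValidationError",
    "ParseError",
    "read_paf",
    "write_paf",
    "read_maf",
    "read_gff3",
    "write_gff3",
    "write_bed",
    "read_bed",
    "read_ortholog_table",
    "read_layout",
    "write_layout",
]


class ValidationError(ValueError):
    """An input violated a structural invariant (not a syntax problem)."""


class ParseError(ValueError):
    """An input file could not be parsed; message names the offending line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Arm:
    name: str
    start: int
    end: int
    arm_class: str = "unassigned"

    def __post_init__(self) -> None:
        if self.arm_class not in ARM_CLASSES:
            raise ValidationError(
                f"unknown arm class {self.arm_class!r}; expected one of {sorted(ARM_CLASSES)}"
            )
        if not (0 <= self.start < self.end):
            raise ValidationError(f"bad arm interval [{self.start}, {self.end})")


@dataclass
class ChromosomeLayout:
    name: str
    length: int
    centromere: int | None = None
    arms: list[Arm] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError(f"chromosome {self.name}: nonpositive length")
        prev_end = None
        for arm in sorted(self.arms, key=lambda a: a.start):
            if arm.end > self.length:
                raise ValidationError(
                    f"chromosome {self.name}: arm {arm.name} exceeds length {self.length}"
                )
            if prev_end is not None and arm.start < prev_end:
                raise ValidationError(
                    f"chromosome {self.name}: overlapping arm intervals"
                )
            prev_end = arm.end
        self.arms = sorted(self.arms, key=lambda a: a.start)


class GenomeLayout:
    """Chromosome lengths, centromere positions and arm classification."""

    def __init__(self, chromosomes: list[ChromosomeLayout]):
        names = [c.name for c in chromosomes]
        dup = [n for n, k in Counter(names).items() if k > 1]
        if dup:
            raise ValidationError(f"duplicated chromosome names: {dup}")
        self._chroms: dict[str, ChromosomeLayout] = {c.name: c for c in chromosomes}

    def __getitem__(self, name: str) -> ChromosomeLayout:
        return self._chroms[name]

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __iter__(self):
        return iter(self._chroms.values())

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    def length(self, name: str) -> int:
        return self._chroms[name].length

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self)

    def arm_of(self, chrom: str, pos: int) -> Arm | None:
        """Arm containing position ``pos`` (half-open intervals), or None."""
        for arm in self._chroms[chrom].arms:
            if arm.start <= pos < arm.end:
                return arm
        return None

    def check_compatible(self, lengths: dict[str, int]) -> None:
        """Raise if observed chromosome lengths disagree with this layout.

        Silent length mismatches corrupt downstream length-weighted
        statistics, so a mismatch is an error, not a warning.
        """
        for name, length in lengths.items():
            if name not in self._chroms:
                raise ValidationError(f"chromosome {name!r} absent from layout")
            if self._chroms[name].length != length:
                raise ValidationError(
                    f"chromosome {name!r}: layout length {self._chroms[name].length}"
                    f" != observed length {length}"
                )


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned segment linking a target interval to a query interval.

    Widths on the two genomes may differ (indels inside the block); both
    must be >= 1 because a zero-width block has no defined strand
    contribution.
    """

    t_chrom: str
    t_start: int
    t_end: int
    q_chrom: str
    q_start: int
    q_end: int
    strand: str
    id: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"block {self.id}: strand must be + or -")
        if not (0 <= self.t_start < self.t_end):
            raise ValidationError(f"block {self.id}: empty/invalid target interval")
        if not (0 <= self.q_start < self.q_end):
            raise ValidationError(f"block {self.id}: empty/invalid query interval")

    @property
    def t_width(self) -> int:
        return self.t_end - self.t_start

    @property
    def q_width(self) -> int:
        return self.q_end - self.q_start

    def swapped(self) -> "AlignmentBlock":
        """Target/query swap, preserving relative strand."""
        return AlignmentBlock(
            self.q_chrom, self.q_start, self.q_end,
            self.t_chrom, self.t_start, self.t_end,
            self.strand, self.id,
        )


def _check_one_to_one(blocks: list[AlignmentBlock], side: str) -> None:
    key = (lambda b: (b.t_chrom, b.t_start, b.t_end)) if side == "target" else (
        lambda b: (b.q_chrom, b.q_start, b.q_end))
    prev = None
    for b in sorted(blocks, key=key):
        chrom, start, end = key(b)
        if prev is not None and prev[0] == chrom and start < prev[1]:
            raise ValidationError(
                f"one-to-one violation on {side}: blocks {prev[2]} and {b.id} "
                f"overlap on {chrom}"
            )
        prev = (chrom, end, b.id)


class AlignmentSet:
    """A one-to-one set of pairwise alignment blocks plus the two layouts.

    One-to-one: blocks are pairwise non-overlapping on the target AND on
    the query.  Verified at construction.
    """

    def __init__(
        self,
        blocks: list[AlignmentBlock],
        target_layout: GenomeLayout,
        query_layout: GenomeLayout,
    ):
        _check_one_to_one(blocks, "target")
        _check_one_to_one(blocks, "query")
        for b in blocks:
            if b.t_chrom not in target_layout:
                raise ValidationError(f"block {b.id}: unknown target chromosome {b.t_chrom}")
            if b.q_chrom not in query_layout:
                raise ValidationError(f"block {b.id}: unknown query chromosome {b.q_chrom}")
            if b.t_end > target_layout.length(b.t_chrom):
                raise ValidationError(f"block {b.id}: exceeds target chromosome length")
            if b.q_end > query_layout.length(b.q_chrom):
                raise ValidationError(f"block {b.id}: exceeds query chromosome length")
        self.blocks = list(blocks)
        self.target_layout = target_layout
        self.query_layout = query_layout

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def by_target(self) -> list[AlignmentBlock]:
        return sorted(self.blocks, key=lambda b: (b.t_chrom, b.t_start))

    def by_query(self) -> list[AlignmentBlock]:
        return sorted(self.blocks, key=lambda b: (b.q_chrom, b.q_start))

    def swapped(self) -> "AlignmentSet":
        """Query-centric view: every block target/query-swapped."""
        return AlignmentSet(
            [b.swapped() for b in self.blocks], self.query_layout, self.target_layout
        )

    def aligned_target_length(self) -> int:
        return sum(b.t_width for b in self.blocks)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(f"gene {self.gene_id}: invalid span")
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValidationError(f"gene {self.gene_id}: exon outside gene span")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class FeatureTrack:
    """A named set of genomic intervals (repeats, CNEs, exons, operons, ...)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def sorted(self) -> "FeatureTrack":
        return FeatureTrack(self.name, sorted(self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)


class OrthologMap:
    """Gene-to-orthogroup assignment at two granularities (HOG and OG).

    HOGs (hierarchical orthogroups) are fine-grained, near one-to-one;
    OGs (orthogroups) are gene-family level and more permissive.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"genome_id", "gene_id", "hog_id", "og_id"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"ortholog table missing columns: {sorted(missing)}")
        dup = table.duplicated(subset=["genome_id", "gene_id"])
        if dup.any():
            row = table[dup].iloc[0]
            raise ValidationError(
                f"duplicate (genome, gene) row: ({row.genome_id}, {row.gene_id})"
            )
        self.table = table.reset_index(drop=True)

    @property
    def genomes(self) -> list[str]:
        return sorted(self.table["genome_id"].unique())

    def assignments(self, genome_id: str, granularity: str = "HOG") -> dict[str, str]:
        """gene_id -> orthogroup id for one genome; unassigned genes omitted."""
        col = {"HOG": "hog_id", "OG": "og_id"}[granularity]
        sub = self.table[self.table["genome_id"] == genome_id]
        sub = sub[sub[col].notna() & (sub[col] != "")]
        return dict(zip(sub["gene_id"], sub[col]))

    def single_copy_pairs(
        self, genome_a: str, genome_b: str, granularity: str = "HOG"
    ) -> list[tuple[str, str]]:
        """Ortholog pairs from groups with exactly one gene in each genome.

        Group membership in genomes other than the two under comparison is
        ignored.
        """
        col = {"HOG": "hog_id", "OG": "og_id"}[granularity]
        sub = self.table[self.table["genome_id"].isin([genome_a, genome_b])]
        sub = sub[sub[col].notna() & (sub[col] != "")]
        pairs = []
        for _, grp in sub.groupby(col, sort=True):
            a = grp[grp["genome_id"] == genome_a]["gene_id"].tolist()
            b = grp[grp["genome_id"] == genome_b]["gene_id"].tolist()
            if len(a) == 1 and len(b) == 1:
                pairs.append((a[0], b[0]))
        seen_a = Counter(p[0] for p in pairs)
        seen_b = Counter(p[1] for p in pairs)
        if seen_a and seen_a.most_common(1)[0][1] > 1:
            raise ValidationError("gene appears in more than one single-copy pair")
        if seen_b and seen_b.most_common(1)[0][1] > 1:
            raise ValidationError("gene appears in more than one single-copy pair")
        return pairs


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------


def _infer_layout(lengths: dict[str, int]) -> GenomeLayout:
    return GenomeLayout([ChromosomeLayout(n, ln) for n, ln in sorted(lengths.items())])


def read_paf(
    path: str | Path,
    target_layout: GenomeLayout | None = None,
    query_layout: GenomeLayout | None = None,
) -> AlignmentSet:
    """Read a PAF file into an AlignmentSet.

    PAF columns 1-4 describe the query, 6-9 the target; all coordinates are
    0-based half-open on the forward strand already.  Layouts are inferred
    from the length columns unless provided, in which case observed lengths
    are cross-checked against them.
    """
    t_lengths: dict[str, int] = {}
    q_lengths: dict[str, int] = {}
    blocks: list[AlignmentBlock] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ParseError(f"{path}: line {lineno}: expected >=12 PAF columns")
            try:
                qname, qlen, qstart, qend = cols[0], int(cols[1]), int(cols[2]), int(cols[3])
                strand = cols[4]
                tname, tlen, tstart, tend = cols[5], int(cols[6]), int(cols[7]), int(cols[8])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            for lengths, name, ln in ((t_lengths, tname, tlen), (q_lengths, qname, qlen)):
                if lengths.setdefault(name, ln) != ln:
                    raise ParseError(
                        f"{path}: line {lineno}: inconsistent length for {name}"
                    )
            blocks.append(
                AlignmentBlock(tname, tstart, tend, qname, qstart, qend, strand,
                               id=len(blocks))
            )
    tl = target_layout or _infer_layout(t_lengths)
    ql = query_layout or _infer_layout(q_lengths)
    if target_layout is not None:
        target_layout.check_compatible(t_lengths)
    if query_layout is not None:
        query_layout.check_compatible(q_lengths)
    return AlignmentSet(blocks, tl, ql)


def write_paf(aln: AlignmentSet, path: str | Path) -> None:
    """Write an AlignmentSet as minimal 12-column PAF, target-sorted."""
    with open(path, "w") as fh:
        for b in aln.by_target():
            matches = min(b.t_width, b.q_width)
            span = max(b.t_width, b.q_width)
            fh.write(
                "\t".join(
                    map(str, [
                        b.q_chrom, aln.query_layout.length(b.q_chrom),
                        b.q_start, b.q_end, b.strand,
                        b.t_chrom, aln.target_layout.length(b.t_chrom),
                        b.t_start, b.t_end, matches, span, 255,
                    ])
                ) + "\n"
            )


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def read_maf(path: str | Path) -> AlignmentSet:
    """Read a two-species MAF into an AlignmentSet.

    The first "s" line of each block is the target, the second the query.
    MAF minus-strand starts count from the sequence end and are converted
    to forward-strand offsets here.  If the target row is itself on the
    minus strand the whole block is flipped so the target is forward.
    """
    t_lengths: dict[str, int] = {}
    q_lengths: dict[str, int] = {}
    blocks: list[AlignmentBlock] = []
    rows: list[tuple[str, int, int, str, int]] = []

    def flush(lineno: int) -> None:
        nonlocal rows
        if not rows:
            return
        if len(rows) != 2:
            raise ValidationError(
                f"{path}: alignment block ending near line {lineno} has "
                f"{len(rows)} sequence rows; only two-species MAF is supported"
            )
        (tn, ts, tsz, tstr, tlen), (qn, qs, qsz, qstr, qlen) = rows
        # forward-strand conversion: minus-strand MAF starts count from the end
        t0 = ts if tstr == "+" else tlen - ts - tsz
        q0 = qs if qstr == "+" else qlen - qs - qsz
        strand = "+" if tstr == qstr else "-"
        t_lengths.setdefault(tn, tlen)
        q_lengths.setdefault(qn, qlen)
        blocks.append(
            AlignmentBlock(tn, t0, t0 + tsz, qn, q0, q0 + qsz, strand, id=len(blocks))
        )
        rows = []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("a") or not line.strip():
                flush(lineno)
            elif line.startswith("s"):
                cols = line.split()
                if len(cols) < 7:
                    raise ParseError(f"{path}: line {lineno}: malformed s line")
                try:
                    rows.append(
                        (cols[1], int(cols[2]), int(cols[3]), cols[4], int(cols[5]))
                    )
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
        flush(lineno)
    return AlignmentSet(blocks, _infer_layout(t_lengths), _infer_layout(q_lengths))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _gff3_attrs(col9: str) -> dict[str, str]:
    out = {}
    for item in col9.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> tuple[list[GeneModel], dict[str, FeatureTrack]]:
    """Parse gene/mRNA/exon records from a GFF3 file.

    1-based inclusive GFF3 coordinates become 0-based half-open.  Exons are
    attached to their gene through the Parent chain (directly or via mRNA);
    introns are derived as the gaps between consecutive exons and returned
    as a feature track alongside the exon track.
    """
    genes: dict[str, GeneModel] = {}
    mrna_parent: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    pending_exons: list[tuple[str, int, int, int]] = []  # parent, start, end, lineno

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 GFF3 columns")
            chrom, _, ftype, start1, end1, _, strand, _, attrs_s = cols
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from None
            attrs = _gff3_attrs(attrs_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}: line {lineno}: gene without ID")
                genes[gid] = GeneModel(gid, chrom, start, end, strand)
                exons.setdefault(gid, [])
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid and parent:
                    mrna_parent[mid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise ParseError(f"{path}: line {lineno}: exon without Parent")
                pending_exons.append((parent, start, end, lineno))

    for parent, start, end, lineno in pending_exons:
        gid = mrna_parent.get(parent, parent)
        if gid not in genes:
            raise ValidationError(
                f"{path}: line {lineno}: exon parent {parent!r} resolves to no gene"
            )
        g = genes[gid]
        if start < g.start or end > g.end:
            raise ValidationError(
                f"{path}: line {lineno}: exon outside span of gene {gid}"
            )
        exons[gid].append((start, end))

    out = []
    for gid, g in genes.items():
        ex = sorted(set(exons[gid])) or [(g.start, g.end)]
        out.append(GeneModel(gid, g.chrom, g.start, g.end, g.strand, ex))
    out.sort(key=lambda g: (g.chrom, g.start))

    exon_track = FeatureTrack("exon", [(g.chrom, s, e) for g in out for s, e in g.exons])
    intron_track = FeatureTrack(
        "intron", [(g.chrom, s, e) for g in out for s, e in g.introns]
    )
    gene_track = FeatureTrack("gene", [(g.chrom, g.start, g.end) for g in out])
    return out, {
        "gene": gene_track.sorted(),
        "exon": exon_track.sorted(),
        "intron": intron_track.sorted(),
    }


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tscramblekit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tscramblekit\tmRNA\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tscramblekit\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_bed(track, path: str | Path) -> None:
    """Write a FeatureTrack or SegmentationResult as BED (0-based half-open).

    Segmentation classes go in the name column; ordering is deterministic
    (chromosome, start).  Zero-width segments are written as zero-length
    BED features.
    """
    with open(path, "w") as fh:
        if isinstance(track, FeatureTrack):
            fh.write(f"# track {track.name}\n")
            for chrom, start, end in sorted(track.intervals):
                fh.write(f"{chrom}\t{start}\t{end}\t{track.name}\n")
        else:  # SegmentationResult (duck-typed to avoid an import cycle)
            fh.write("# segmentation classes\n")
            for chrom, start, end, cls in track.iter_segments():
                fh.write(f"{chrom}\t{start}\t{end}\t{cls}\n")


def read_bed(path: str | Path, name: str | None = None) -> FeatureTrack:
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >=3 BED columns")
            intervals.append((cols[0], int(cols[1]), int(cols[2])))
    return FeatureTrack(name or Path(path).stem, sorted(intervals))


# ---------------------------------------------------------------------------
# Ortholog table & layout
# ---------------------------------------------------------------------------


def read_ortholog_table(path: str | Path) -> OrthologMap:
    """Read a TSV with columns genome_id, gene_id, hog_id, og_id."""
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    table = table.replace({"": None})
    return OrthologMap(table)


def write_ortholog_table(omap: OrthologMap, path: str | Path) -> None:
    omap.table.fillna("").to_csv(path, sep="\t", index=False)


def read_layout(path: str | Path) -> GenomeLayout:
    """Read a layout TSV: chrom length centromere arm_name arm_start arm_end arm_class.

    One row per arm; chromosome-level fields repeat.  Empty centromere and
    arm fields are allowed (a chromosome row without arms has them blank).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    chroms = []
    for name, grp in df.groupby("chrom", sort=False):
        length = int(grp["length"].iloc[0])
        cent_s = grp["centromere"].iloc[0]
        cent = int(cent_s) if cent_s not in ("", ".") else None
        arms = [
            Arm(r["arm_name"], int(r["arm_start"]), int(r["arm_end"]), r["arm_class"])
            for _, r in grp.iterrows()
            if r["arm_name"] not in ("", ".")
        ]
        chroms.append(ChromosomeLayout(name, length, cent, arms))
    return GenomeLayout(chroms)


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write("chrom\tlength\tcentromere\tarm_name\tarm_start\tarm_end\tarm_class\n")
    for c in layout:
        cent = "" if c.centromere is None else str(c.centromere)
        if not c.arms:
            buf.write(f"{c.name}\t{c.length}\t{cent}\t\t\t\t\n")
        for arm in c.arms:
            buf.write(
                f"{c.name}\t{c.length}\t{cent}\t{arm.name}\t{arm.start}\t"
                f"{arm.end}\t{arm.arm_class}\n"
            )
    Path(path).write_text(buf.getvalue())
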