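"""Boundary feature-enrichment and percent-of-chromosome-length profiles.

``boundary_enrichment`` asks, for each segmentation class, what fraction of
that class's region boundaries have a given genomic feature (exon, intron,
operon, repeat, CNE...) at each offset in a window around the boundary —
the kind of profile that shows alignment/breakpoint edges coinciding with
exon starts.  ``binned_profile`` averages a per-element quantity (gene
length, operon size, breakpoint count, dN/dS...) in bins of percent of
chromosome length, the natural axis for comparing chromosomes of unequal
size and for contrasting short against long arms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import FeatureTrack, GenomeLayout, ValidationError
from .segmentation import CLASS_NAMES, SegmentationResult

__all__ = [
    "EnrichmentProfile",
    "BinnedProfile",
    "boundary_enrichment",
    "binned_profile",
    "average_profiles",
    "arm_class_compare",
    "gene_breakpoint_rate_by_arm",
]


@dataclass
class EnrichmentProfile:
    """Fraction of class boundaries covered by each feature, per offset.

    ``table`` rows are (region_class, side, offset) and one column per
    feature track; offset 0 is the boundary base, orientation is
    genome-forward.  ``n_boundaries`` gives the denominator per
    (region_class, side).
    """

    table: pd.DataFrame
    n_boundaries: dict[tuple[str, str], int]
    window: int
    step: int


@dataclass
class BinnedProfile:
    """Mean of a quantity in bins of percent of chromosome length."""

    table: pd.DataFrame  # bin, mean, n
    n_bins: int
    quantity: str


# ---------------------------------------------------------------------------
# Boundary enrichment
# ---------------------------------------------------------------------------


def _merged_intervals(track: FeatureTrack) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome merged (start, end) arrays for point-in-set queries."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in sorted(track.intervals):
        ivs = by_chrom.setdefault(chrom, [])
        if ivs and s <= ivs[-1][1]:
            ivs[-1] = (ivs[-1][0], max(ivs[-1][1], e))
        else:
            ivs.append((s, e))
    return {
        c: (np.array([s for s, _ in ivs], dtype=np.int64),
            np.array([e for _, e in ivs], dtype=np.int64))
        for c, ivs in by_chrom.items()
    }


def _covered(positions: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    if starts.size == 0:
        return np.zeros(positions.shape, dtype=bool)
    idx = np.searchsorted(starts, positions, side="right") - 1
    ok = idx >= 0
    out = np.zeros(positions.shape, dtype=bool)
    out[ok] = ends[idx[ok]] > positions[ok]
    return out


def boundary_enrichment(
    seg: SegmentationResult,
    tracks: list[FeatureTrack],
    window: int = 1000,
    step: int = 10,
    classes: tuple[str, ...] = CLASS_NAMES,
) -> EnrichmentProfile:
    """Feature coverage around class-boundary positions.

    For each region class and boundary side (start/stop), and each offset
    in [-window, +window] with the given step, the fraction of boundaries
    whose position+offset lies inside the feature.  A zero-width breakpoint
    contributes one start and one stop boundary at its position.  Offsets
    falling off the chromosome count as uncovered.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    offsets = np.arange(-window, window + 1, step, dtype=np.int64)
    merged = {t.name: _merged_intervals(t) for t in tracks}

    boundaries: dict[tuple[str, str], list[tuple[str, int]]] = {
        (cls, side): [] for cls in classes for side in ("start", "stop")
    }
    for chrom, start, end, cls in seg.iter_segments():
        if cls not in classes:
            continue
        boundaries[(cls, "start")].append((chrom, start))
        boundaries[(cls, "stop")].append((chrom, end))

    rows = []
    n_boundaries = {}
    for (cls, side), pts in boundaries.items():
        n_boundaries[(cls, side)] = len(pts)
        frac = {t.name: np.full(offsets.shape, np.nan) for t in tracks}
        if pts:
            for t in tracks:
                hits = np.zeros(offsets.shape, dtype=np.int64)
                for chrom, pos in pts:
                    ivs = merged[t.name].get(chrom)
                    query = pos + offsets
                    if ivs is None:
                        continue
                    hits += _covered(query, *ivs)
                frac[t.name] = hits / len(pts)
        for k, off in enumerate(offsets):
            row = {"region_class": cls, "side": side, "offset": int(off)}
            for t in tracks:
                row[t.name] = float(frac[t.name][k])
            rows.append(row)
    table = pd.DataFrame(rows)
    return EnrichmentProfile(table, n_boundaries, window, step)


# ---------------------------------------------------------------------------
# Percent-length binned profiles
# ---------------------------------------------------------------------------


def binned_profile(
    elements: pd.DataFrame,
    layout: GenomeLayout,
    n_bins: int = 50,
    quantity: str = "value",
) -> BinnedProfile:
    """Bin per-element values by percent of chromosome length.

    ``elements`` needs columns chrom, pos (element midpoint in bases) and
    value.  Element i goes to bin floor(B * pos / chrom_length), clipped
    into the last bin for pos == length.  Bins with no elements report a
    NaN mean and n = 0.
    """
    for col in ("chrom", "pos", "value"):
        if col not in elements.columns:
            raise ValidationError(f"elements table missing column {col!r}")
    bins = np.full(len(elements), -1, dtype=int)
    for i, (chrom, pos) in enumerate(zip(elements["chrom"], elements["pos"])):
        if chrom not in layout:
            raise ValidationError(f"chromosome {chrom!r} absent from layout")
        length = layout.length(chrom)
        if not (0 <= pos <= length):
            raise ValidationError(f"position {pos} beyond chromosome {chrom} end")
        bins[i] = min(int(n_bins * pos / length), n_bins - 1)
    df = elements.assign(_bin=bins)
    grouped = df.groupby("_bin")["value"]
    mean = grouped.mean()
    count = grouped.size()
    table = pd.DataFrame(
        {
            "bin": range(n_bins),
            "mean": [mean.get(b, np.nan) for b in range(n_bins)],
            "n": [int(count.get(b, 0)) for b in range(n_bins)],
        }
    )
    return BinnedProfile(table, n_bins, quantity)


def average_profiles(profiles: list[BinnedProfile]) -> BinnedProfile:
    """Average per-genome bin means (not pooled elements) across genomes.

    Bins empty in some genome are averaged over the genomes where they are
    occupied.
    """
    if not profiles:
        raise ValidationError("no profiles to average")
    n_bins = profiles[0].n_bins
    if any(p.n_bins != n_bins for p in profiles):
        raise ValidationError("profiles have differing bin counts")
    means = np.vstack([p.table["mean"].to_numpy() for p in profiles])
    ns = np.vstack([p.table["n"].to_numpy() for p in profiles])
    import warnings

    with warnings.catch_warnings():
        # bins empty in every genome legitimately average to NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        avg = np.nanmean(means, axis=0)
    table = pd.DataFrame({"bin": range(n_bins), "mean": avg, "n": ns.sum(axis=0)})
    return BinnedProfile(table, n_bins, profiles[0].quantity)


# ---------------------------------------------------------------------------
# Arm-class comparisons
# ---------------------------------------------------------------------------


def arm_class_compare(
    values: pd.DataFrame, classes: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Pairwise two-sided Wilcoxon rank-sum tests between arm classes.

    ``values`` needs columns arm_class and value.  Every unordered pair of
    occupied classes is compared (e.g. short vs long, short vs XSR, long vs
    XSR); a class with fewer than two elements is skipped with a notice in
    the ``note`` column.
    """
    present = sorted(values["arm_class"].unique())
    if classes is not None:
        present = [c for c in classes if c in present]
    if len(present) < 2:
        raise ValidationError("need >= 2 occupied arm classes")
    groups = {c: values.loc[values["arm_class"] == c, "value"].to_numpy() for c in present}
    rows = []
    for i, a in enumerate(present):
        for b in present[i + 1:]:
            row = {
                "class_a": a, "class_b": b,
                "n_a": len(groups[a]), "n_b": len(groups[b]),
                "median_a": float(np.median(groups[a])) if len(groups[a]) else np.nan,
                "median_b": float(np.median(groups[b])) if len(groups[b]) else np.nan,
                "statistic": np.nan, "p_value": np.nan, "note": "",
            }
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                row["note"] = "skipped: a class has < 2 elements"
            else:
                pooled = np.concatenate([groups[a], groups[b]])
                method = (
                    "exact"
                    if max(len(groups[a]), len(groups[b])) <= 25
                    and len(np.unique(pooled)) == len(pooled)
                    else "asymptotic"
                )
                res = stats.mannwhitneyu(
                    groups[a], groups[b], alternative="two-sided", method=method
                )
                row["statistic"] = float(res.statistic)
                row["p_value"] = float(res.pvalue)
            rows.append(row)
    return pd.DataFrame(rows)


def gene_breakpoint_rate_by_arm(
    genes: pd.DataFrame,
    classes: tuple[str, ...] = ("short", "long", "XSR"),
) -> dict:
    """Do genes on some arm classes overlap breakpoint regions more often?

    ``genes`` needs columns arm_class and overlaps (bool).  Builds the
    (arm class) x (overlapping, not overlapping) contingency table over
    the requested classes, dropping empty ones (the degrees of freedom
    shrink accordingly), and runs a chi-squared independence test.
    """
    rows = []
    for cls in classes:
        sub = genes[genes["arm_class"] == cls]
        if len(sub):
            rows.append((cls, int(sub["overlaps"].sum()), int((~sub["overlaps"]).sum())))
    out = {
        "table": pd.DataFrame(rows, columns=["arm_class", "n_overlapping", "n_not_overlapping"]),
        "chi2": None, "df": None, "p_value": None, "note": None,
    }
    if len(rows) < 2:
        out["note"] = "degenerate: fewer than two occupied arm classes"
        return out
    counts = np.array([[r[1], r[2]] for r in rows], dtype=float)
    if counts.sum(axis=0).min() == 0:
        out["note"] = "degenerate: a column of the contingency table is empty"
        return out
    res = stats.chi2_contingency(counts, correction=False)
    out["chi2"] = float(res.statistic)
    out["df"] = int(res.dof)
    out["p_value"] = float(res.pvalue)
    return out
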