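"""ROH incidence tracks, island calling, classification and gene annotation.

An *incidence track* records, per SNP, the fraction of a group's
individuals covered by at least one ROH segment.  A *ROH island* is a
maximal run of consecutive SNPs whose incidence strictly exceeds a sharing
threshold (0.5 in the standard setting: "shared by more than 50%").
Islands are candidate selection signatures; they can be classified as
private to a group or shared between groups by reciprocal interval
overlap, and annotated with overlapping genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .roh import ROHSegment


@dataclass
class IncidenceTrack:
    """Per-SNP ROH coverage fraction for one chromosome and one group."""

    chromosome: str
    positions: np.ndarray
    fraction: np.ndarray
    group_label: str
    n_individuals: int

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.positions.shape != self.fraction.shape:
            raise ValueError("positions and fraction must have matching shapes")
        if self.fraction.size and (self.fraction.min() < 0 or self.fraction.max() > 1):
            raise ValueError("incidence fractions must lie in [0, 1]")


@dataclass
class ROHIsland:
    """A shared homozygous interval: begin/end are the first/last SNP of the
    qualifying run; ``freq`` is the maximum per-SNP incidence inside it
    (``mean_freq`` is also kept)."""

    chromosome: str
    begin_bp: int
    end_bp: int
    freq: float
    mean_freq: float
    group_label: str
    n_snps: int
    genes: tuple[str, ...] = ()
    shared_with: tuple[str, ...] = ()

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.begin_bp

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


@dataclass(frozen=True)
class GeneInterval:
    """A named gene interval in 1-based closed coordinates."""

    name: str
    chromosome: str
    start_bp: int
    end_bp: int
    source_line: int = 0

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(f"gene {self.name!r}: start > end")


class AnnotationParseError(ValueError):
    """Malformed gene-annotation line (message names the line number)."""


# ---------------------------------------------------------------------------
# incidence
# ---------------------------------------------------------------------------

def incidence(
    segments: Sequence[ROHSegment],
    variants: pd.DataFrame,
    sample_ids: Sequence[str],
    group_label: str = "",
) -> dict[str, IncidenceTrack]:
    """Per-SNP coverage fraction for a group, one track per chromosome.

    ``sample_ids`` defines the group (its size is the denominator, so
    individuals without any segment still count); each individual
    contributes at most once per SNP no matter how many of its segments
    cover it.
    """
    if len(sample_ids) == 0:
        raise ValueError("group has no individuals")
    sample_set = set(sample_ids)
    chrom_arr = variants["chromosome"].to_numpy()
    pos_all = variants["position"].to_numpy()

    tracks: dict[str, IncidenceTrack] = {}
    for c in pd.unique(chrom_arr):
        pos = pos_all[chrom_arr == c]
        counts = np.zeros(pos.size, dtype=np.int64)
        segs_c = [s for s in segments if s.chromosome == str(c) and s.sample_id in sample_set]
        by_sample: dict[str, list[ROHSegment]] = {}
        for s in segs_c:
            by_sample.setdefault(s.sample_id, []).append(s)
        for segs in by_sample.values():
            covered = np.zeros(pos.size, dtype=bool)
            for s in segs:
                lo = np.searchsorted(pos, s.start_bp, side="left")
                hi = np.searchsorted(pos, s.end_bp, side="right")
                covered[lo:hi] = True
            counts += covered
        tracks[str(c)] = IncidenceTrack(
            chromosome=str(c),
            positions=pos,
            fraction=counts / len(sample_ids),
            group_label=group_label,
            n_individuals=len(sample_ids),
        )
    return tracks


# ---------------------------------------------------------------------------
# island calling and classification
# ---------------------------------------------------------------------------

def call_islands(
    track: IncidenceTrack, threshold: float = 0.5, min_snps: int = 2
) -> list[ROHIsland]:
    """Maximal runs of SNPs with incidence strictly above ``threshold``.

    Runs with fewer than ``min_snps`` SNPs are suppressed (default 2 keeps
    very short islands callable while discarding single-SNP spikes).
    Sub-threshold gaps are never bridged.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    above = track.fraction > threshold
    if not above.any():
        return []
    # run boundaries
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size - 1)
    out = []
    for lo, hi in zip(starts, ends):
        if hi - lo + 1 < min_snps:
            continue
        frac = track.fraction[lo : hi + 1]
        out.append(
            ROHIsland(
                chromosome=track.chromosome,
                begin_bp=int(track.positions[lo]),
                end_bp=int(track.positions[hi]),
                freq=float(frac.max()),
                mean_freq=float(frac.mean()),
                group_label=track.group_label,
                n_snps=int(hi - lo + 1),
            )
        )
    return out


def _reciprocal_overlap(a: ROHIsland, b: ROHIsland) -> float:
    if a.chromosome != b.chromosome:
        return 0.0
    ov = min(a.end_bp, b.end_bp) - max(a.begin_bp, b.begin_bp)
    if ov <= 0:
        return 0.0
    la = max(a.length_bp, 1)
    lb = max(b.length_bp, 1)
    return min(ov / la, ov / lb)


def classify_islands(
    islands_by_group: Mapping[str, Sequence[ROHIsland]],
    reciprocal_overlap: float = 0.5,
) -> list[ROHIsland]:
    """Label each island private or shared across groups.

    Two islands from different groups are the same signal when their
    reciprocal overlap is at least ``reciprocal_overlap``; matching is
    closed transitively, so a chain of pairwise matches forms one shared
    signal.  Returns all islands with ``shared_with`` set to the sorted
    tuple of groups carrying the signal (length 1 == private).
    """
    if len(islands_by_group) < 2:
        raise ValueError("need at least two groups to classify islands")
    items: list[tuple[str, ROHIsland]] = [
        (grp, isl) for grp, lst in islands_by_group.items() for isl in lst
    ]
    n = len(items)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    for i in range(n):
        for j in range(i + 1, n):
            gi, a = items[i]
            gj, b = items[j]
            if gi == gj:
                continue
            if _reciprocal_overlap(a, b) >= reciprocal_overlap:
                union(i, j)

    members: dict[int, set[str]] = {}
    for i, (grp, _) in enumerate(items):
        members.setdefault(find(i), set()).add(grp)
    out = []
    for i, (grp, isl) in enumerate(items):
        isl.shared_with = tuple(sorted(members[find(i)]))
        out.append(isl)
    return out


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def annotate_islands(
    islands: Sequence[ROHIsland], genes: Sequence[GeneInterval]
) -> list[ROHIsland]:
    """Attach the names of genes overlapping each island by >= 1 bp.

    Both islands and genes are 1-based closed intervals; genes are listed
    in position order.
    """
    genes_sorted = sorted(genes, key=lambda x: (x.chromosome, x.start_bp, x.end_bp))
    for isl in islands:
        hits = [
            gx.name
            for gx in genes_sorted
            if gx.chromosome == isl.chromosome
            and gx.start_bp <= isl.end_bp
            and gx.end_bp >= isl.begin_bp
        ]
        isl.genes = tuple(hits)
    return list(islands)


def read_bed(source) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open -> 1-based closed)."""
    out = []
    lines = source.read().splitlines() if hasattr(source, "read") else Path(source).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        tok = line.split("\t") if "\t" in line else line.split()
        if len(tok) < 3:
            raise AnnotationParseError(f"BED line {lineno}: expected at least 3 columns")
        try:
            start0, end0 = int(tok[1]), int(tok[2])
        except ValueError as exc:
            raise AnnotationParseError(f"BED line {lineno}: non-integer coordinates") from exc
        if end0 <= start0:
            raise AnnotationParseError(f"BED line {lineno}: end <= start")
        name = tok[3] if len(tok) > 3 else f"feature_{lineno}"
        out.append(GeneInterval(name=name, chromosome=tok[0], start_bp=start0 + 1,
                                end_bp=end0, source_line=lineno))
    return out


def read_gff3(source, feature_types: tuple[str, ...] = ("gene",)) -> list[GeneInterval]:
    """Read gene intervals from GFF3 (1-based closed coordinates).

    The name is taken from the ``Name=`` attribute, falling back to ``ID=``.
    """
    out = []
    lines = source.read().splitlines() if hasattr(source, "read") else Path(source).read_text().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        tok = line.split("\t")
        if len(tok) != 9:
            raise AnnotationParseError(f"GFF3 line {lineno}: expected 9 tab-separated columns")
        if tok[2] not in feature_types:
            continue
        try:
            start, end = int(tok[3]), int(tok[4])
        except ValueError as exc:
            raise AnnotationParseError(f"GFF3 line {lineno}: non-integer coordinates") from exc
        attrs = dict(
            kv.split("=", 1) for kv in tok[8].split(";") if "=" in kv
        )
        name = attrs.get("Name") or attrs.get("ID") or f"feature_{lineno}"
        out.append(GeneInterval(name=name, chromosome=tok[0], start_bp=start,
                                end_bp=end, source_line=lineno))
    return out


def islands_to_dataframe(islands: Sequence[ROHIsland]) -> pd.DataFrame:
    """Tabular island report (Chr, Begin, End, Length kb, ROH freq., genes)."""
    rows = [
        {
            "group": isl.group_label,
            "chromosome": isl.chromosome,
            "begin_bp": isl.begin_bp,
            "end_bp": isl.end_bp,
            "length_kb": round(isl.length_kb, 1),
            "roh_freq": round(isl.freq, 3),
            "mean_freq": round(isl.mean_freq, 3),
            "n_snps": isl.n_snps,
            "shared_with": ",".join(isl.shared_with),
            "genes": ",".join(isl.genes),
        }
        for isl in islands
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "group", "chromosome", "begin_bp", "end_bp", "length_kb",
            "roh_freq", "mean_freq", "n_snps", "shared_with", "genes",
        ],
    )


def plot_incidence(track: IncidenceTrack, islands: Sequence[ROHIsland] = (),
                   threshold: float = 0.5, ax=None):
    """Line plot of an incidence track with island begin/end reference lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    ax.plot(track.positions / 1e6, track.fraction, lw=0.8,
            label=track.group_label or None)
    ax.axhline(threshold, color="grey", ls="--", lw=0.8)
    for isl in islands:
        if isl.chromosome == track.chromosome:
            ax.axvline(isl.begin_bp / 1e6, color="red", lw=0.8)
            ax.axvline(isl.end_bp / 1e6, color="red", lw=0.8)
    ax.set_xlabel(f"position on chromosome {track.chromosome} (Mb)")
    ax.set_ylabel("ROH incidence")
    ax.set_ylim(0, 1)
    return ax
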