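"""Run-of-homozygosity detection.

A ROH segment is a maximal stretch of SNPs for one individual on one
chromosome that satisfies, as a whole, the final-segment constraints:

* span (last SNP position - first SNP position) above a minimum length,
* more than a minimum number of homozygous SNPs,
* at most ``max_het`` heterozygous and ``max_missing`` missing calls,
* no gap between consecutive SNPs larger than ``max_gap_bp``,
* average SNP density of at least one SNP per ``max_bp_per_snp``,
* first and last SNP homozygous (segment ends are trimmed to homozygous
  calls, as PLINK does).

The caller applies these constraints directly to candidate segments — a
greedy left-to-right scan that, repeatedly, takes the qualifying segment
with the smallest start (ties broken by the largest end) that does not
overlap anything already emitted.  This is deterministic and is checked in
the test suite against exhaustive enumeration of all qualifying
subintervals on small instances.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import HET, HOM_A, HOM_B, MISSING, GenotypeMatrix


@dataclass(frozen=True)
class ROHParams:
    """Standard segment constraints (array-density defaults).

    ``strict_length``/``strict_hom`` control whether the minimum length and
    minimum homozygous-SNP count are strict ('>', the default) or inclusive
    ('>=') comparisons.  ``min_hom_snps`` counts homozygous SNPs only;
    heterozygous and missing calls count toward the segment's SNP total and
    the gap/density checks but never toward ``min_hom_snps``.
    """

    min_length_bp: int = 500_000
    min_hom_snps: int = 80
    max_het: int = 1
    max_missing: int = 2
    max_gap_bp: int = 100_000
    max_bp_per_snp: int = 50_000
    strict_length: bool = True
    strict_hom: bool = True

    def __post_init__(self) -> None:
        if self.min_length_bp <= 0:
            raise ValueError("min_length_bp must be positive")
        for name in ("min_hom_snps", "max_het", "max_missing", "max_gap_bp", "max_bp_per_snp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def _length_ok(self, length: int) -> bool:
        return length > self.min_length_bp if self.strict_length else length >= self.min_length_bp

    def _hom_ok(self, n_hom: int) -> bool:
        return n_hom > self.min_hom_snps if self.strict_hom else n_hom >= self.min_hom_snps


@dataclass(frozen=True)
class FineScanParams(ROHParams):
    """Relaxed preset for rescanning short homozygous stretches
    (80 kb minimum span, at least 20 homozygous SNPs, inclusive minima)."""

    min_length_bp: int = 80_000
    min_hom_snps: int = 20
    strict_length: bool = False
    strict_hom: bool = False


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run for one individual.

    ``start_bp``/``end_bp`` are the positions of the first and last SNP in
    the segment; ``length_bp`` is their difference (not +1), matching how
    interval lengths are reported downstream.
    """

    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_hom: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _scan_chromosome(
    pos: np.ndarray, codes: np.ndarray, params: ROHParams
) -> list[tuple[int, int]]:
    """Greedy scan of one chromosome; returns (start_idx, end_idx) pairs."""
    n = pos.size
    if n == 0:
        return []
    hom = (codes == HOM_A) | (codes == HOM_B)
    het = codes == HET
    mis = codes == MISSING

    cum_hom = np.concatenate([[0], np.cumsum(hom)])
    cum_het = np.concatenate([[0], np.cumsum(het)])
    cum_mis = np.concatenate([[0], np.cumsum(mis)])
    het_idx = np.flatnonzero(het)
    mis_idx = np.flatnonzero(mis)

    # chunks delimited by gaps larger than max_gap_bp (a candidate segment
    # can never span such a gap)
    big_gap = np.diff(pos) > params.max_gap_bp
    chunk_id = np.concatenate([[0], np.cumsum(big_gap)])
    # last index of each chunk
    chunk_last = np.full(chunk_id[-1] + 1, n - 1, dtype=np.intp)
    chunk_last[chunk_id[:-1][big_gap]] = np.flatnonzero(big_gap)
    chunk_end = chunk_last[chunk_id]

    idx = np.arange(n)
    # largest j such that [i, j] keeps the het budget: index before the
    # (max_het+1)-th heterozygote at or after i
    def _budget_limit(cum: np.ndarray, marker_idx: np.ndarray, budget: int) -> np.ndarray:
        if marker_idx.size == 0:
            return np.full(n, n - 1, dtype=np.intp)
        k = cum[:-1] + budget
        return np.where(
            k < marker_idx.size, marker_idx[np.minimum(k, marker_idx.size - 1)] - 1, n - 1
        )

    j_het = _budget_limit(cum_het, het_idx, params.max_het)
    j_mis = _budget_limit(cum_mis, mis_idx, params.max_missing)
    j_lim = np.minimum(np.minimum(j_het, j_mis), chunk_end)

    # candidate starts: homozygous SNPs whose budget-limited span can reach
    # the minimum length at all
    span = pos[np.maximum(j_lim, idx)] - pos
    can_start = hom & (j_lim >= idx)
    can_start &= (span > params.min_length_bp) if params.strict_length else (
        span >= params.min_length_bp
    )
    cand = np.flatnonzero(can_start)

    # previous homozygous index at or before j (-1 if none)
    prev_hom = np.maximum.accumulate(np.where(hom, idx, -1))

    segments: list[tuple[int, int]] = []
    ci = 0
    while ci < cand.size:
        i = int(cand[ci])
        j = int(j_lim[i])
        found = -1
        while j > i:
            if not hom[j]:
                j = int(prev_hom[j])
                if j <= i:
                    break
            length = int(pos[j] - pos[i])
            if not params._length_ok(length):
                break  # shrinking j only shortens the span
            n_hom_ij = int(cum_hom[j + 1] - cum_hom[i])
            if not params._hom_ok(n_hom_ij):
                break  # shrinking j only removes homozygous SNPs
            if length <= params.max_bp_per_snp * (j - i + 1):
                found = j
                break
            j -= 1  # density failed; a shorter end may still qualify
        if found >= 0:
            segments.append((i, found))
            ci = int(np.searchsorted(cand, found + 1))
        else:
            ci += 1
    return segments


def _segments_for_sample(
    g: GenotypeMatrix, sample_id: str, params: ROHParams
) -> list[ROHSegment]:
    row = g.calls[g.sample_index(sample_id)]
    chrom = g.variants["chromosome"].to_numpy()
    pos = g.variants["position"].to_numpy()
    out: list[ROHSegment] = []
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        p = pos[sel]
        codes = row[sel]
        for i, j in _scan_chromosome(p, codes, params):
            seg_codes = codes[i : j + 1]
            out.append(
                ROHSegment(
                    sample_id=sample_id,
                    chromosome=str(c),
                    start_bp=int(p[i]),
                    end_bp=int(p[j]),
                    n_snps=int(j - i + 1),
                    n_hom=int(np.count_nonzero((seg_codes == HOM_A) | (seg_codes == HOM_B))),
                    n_het=int(np.count_nonzero(seg_codes == HET)),
                    n_missing=int(np.count_nonzero(seg_codes == MISSING)),
                )
            )
    return out


def detect_roh(
    g: GenotypeMatrix,
    sample_id: str | None = None,
    params: ROHParams | None = None,
) -> list[ROHSegment]:
    """Detect ROH segments for one sample (or all samples if None).

    Variants must be sorted by (chromosome, position); raises otherwise.
    """
    params = params or ROHParams()
    g.check_sorted()
    if sample_id is not None:
        return _segments_for_sample(g, sample_id, params)
    out: list[ROHSegment] = []
    for sid in g.sample_ids:
        out.extend(_segments_for_sample(g, sid, params))
    return out


def fine_scan(
    g: GenotypeMatrix,
    region: tuple[str, int, int],
    params: ROHParams | None = None,
    sample_id: str | None = None,
) -> list[ROHSegment]:
    """Rescan a region with relaxed thresholds (:class:`FineScanParams`).

    Only SNPs inside ``region`` (chromosome, start bp, end bp; inclusive)
    are considered, so reported segments are clipped to the region.  An
    empty region yields an empty list.
    """
    params = params or FineScanParams()
    chrom, start, end = region
    mask = (
        (g.variants["chromosome"] == chrom)
        & (g.variants["position"] >= start)
        & (g.variants["position"] <= end)
    ).to_numpy()
    if not mask.any():
        return []
    sub = g.take_variants(np.flatnonzero(mask))
    return detect_roh(sub, sample_id=sample_id, params=params)


# ---------------------------------------------------------------------------
# tabular output (PLINK .hom dialect plus het/missing bookkeeping)
# ---------------------------------------------------------------------------

_HOM_COLUMNS = ["FID", "IID", "CHR", "POS1", "POS2", "KB", "NSNP", "NHOM", "NHET", "NMISS"]


def segments_to_dataframe(
    segments: Sequence[ROHSegment], subpopulations: dict[str, str] | None = None
) -> pd.DataFrame:
    subpopulations = subpopulations or {}
    rows = [
        {
            "FID": subpopulations.get(s.sample_id, "0"),
            "IID": s.sample_id,
            "CHR": s.chromosome,
            "POS1": s.start_bp,
            "POS2": s.end_bp,
            "KB": round(s.length_bp / 1000.0, 3),
            "NSNP": s.n_snps,
            "NHOM": s.n_hom,
            "NHET": s.n_het,
            "NMISS": s.n_missing,
        }
        for s in segments
    ]
    return pd.DataFrame(rows, columns=_HOM_COLUMNS)


def write_hom(
    segments: Sequence[ROHSegment],
    path,
    subpopulations: dict[str, str] | None = None,
) -> None:
    segments_to_dataframe(segments, subpopulations).to_csv(path, sep="\t", index=False)


def read_hom(path) -> tuple[list[ROHSegment], dict[str, str]]:
    """Read a segment table written by :func:`write_hom`.

    Returns the segments and the IID -> FID (subpopulation) mapping.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"CHR": str, "FID": str, "IID": str})
    segments = [
        ROHSegment(
            sample_id=row.IID,
            chromosome=row.CHR,
            start_bp=int(row.POS1),
            end_bp=int(row.POS2),
            n_snps=int(row.NSNP),
            n_hom=int(row.NHOM),
            n_het=int(row.NHET),
            n_missing=int(row.NMISS),
        )
        for row in frame.itertuples()
    ]
    groups = dict(zip(frame["IID"], frame["FID"]))
    return segments, groups
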