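"""Per-individual and per-group ROH summaries.

Variables follow the standard ROH vocabulary: N_ROH is the number of
segments, S_ROH the summed segment length in Mb, L_ROH the mean segment
length in Mb (0 when there are no segments), and the genomic inbreeding
coefficient F_ROH = S_ROH / L_AUTO, where L_AUTO is the autosomal genome
length (2243 Mb for the horse by default).

The length-class decomposition splits F_ROH by segment-length bins
(0.5-1, 1-2, 2-4, 4-6, 6-8, 8-10, >10 Mb, half-open [lo, hi)); old
inbreeding shows up in the short classes and recent inbreeding in the long
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .roh import ROHSegment

#: equine autosome length in Mb
DEFAULT_L_AUTO_MB = 2243.0

#: length-class bin edges in Mb; the final bin is open-ended
DEFAULT_BIN_EDGES_MB = (0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class GenomeConstant:
    """Autosomal genome length used as the F_ROH denominator (Mb)."""

    l_auto_mb: float = DEFAULT_L_AUTO_MB

    def __post_init__(self) -> None:
        if self.l_auto_mb <= 0:
            raise ValueError("l_auto_mb must be positive")


@dataclass(frozen=True)
class ROHSummary:
    sample_id: str
    n_roh: int
    s_roh_mb: float
    l_roh_mb: float
    f_roh: float


def summarize_individual(
    segments: Sequence[ROHSegment],
    genome: GenomeConstant = GenomeConstant(),
    sample_id: str | None = None,
) -> ROHSummary:
    """Summarize one individual's segments (empty list -> all zeros)."""
    ids = {s.sample_id for s in segments}
    if len(ids) > 1:
        raise ValueError(f"segments belong to more than one individual: {sorted(ids)}")
    if sample_id is None:
        sample_id = next(iter(ids)) if ids else ""
    n = len(segments)
    s_mb = sum(s.length_bp for s in segments) / 1e6
    return ROHSummary(
        sample_id=sample_id,
        n_roh=n,
        s_roh_mb=s_mb,
        l_roh_mb=s_mb / n if n else 0.0,
        f_roh=s_mb / genome.l_auto_mb,
    )


def froh_from_sroh(s_roh_mb: float, genome: GenomeConstant = GenomeConstant()) -> float:
    """F_ROH = S_ROH / L_AUTO (both in Mb)."""
    return s_roh_mb / genome.l_auto_mb


def summarize_cohort(
    segments: Sequence[ROHSegment],
    sample_ids: Sequence[str],
    genome: GenomeConstant = GenomeConstant(),
) -> pd.DataFrame:
    """Per-individual summary table; individuals without segments get zeros."""
    by_sample: dict[str, list[ROHSegment]] = {sid: [] for sid in sample_ids}
    for seg in segments:
        if seg.sample_id not in by_sample:
            raise KeyError(f"segment for unknown sample {seg.sample_id!r}")
        by_sample[seg.sample_id].append(seg)
    rows = []
    for sid in sample_ids:
        s = summarize_individual(by_sample[sid], genome, sample_id=sid)
        rows.append((sid, s.n_roh, s.s_roh_mb, s.l_roh_mb, s.f_roh))
    return pd.DataFrame(
        rows, columns=["sample_id", "N_ROH", "S_ROH", "L_ROH", "F_ROH"]
    ).set_index("sample_id")


@dataclass
class LengthClassTable:
    """Length-class decomposition for a group of individuals.

    ``table`` has one row per bin with the share of segments (% of N_ROH)
    and the F_ROH contribution (%); ``cumulative`` gives F_ROH below each
    successive bin upper edge; ``total_froh_pct`` is the group-mean F_ROH
    in percent (equal to the sum of the per-bin contributions).
    """

    table: pd.DataFrame
    cumulative: pd.Series
    total_froh_pct: float
    n_individuals: int


def _bin_labels(edges: Sequence[float]) -> list[str]:
    labels = [f"{edges[k]:g}-{edges[k + 1]:g} Mb" for k in range(len(edges) - 1)]
    labels.append(f">{edges[-1]:g} Mb")
    return labels


def length_class_table(
    segments: Sequence[ROHSegment],
    n_individuals: int,
    genome: GenomeConstant = GenomeConstant(),
    bin_edges_mb: Sequence[float] = DEFAULT_BIN_EDGES_MB,
) -> LengthClassTable:
    """Distribute a group's segments over length classes.

    Bins are half-open ``[lo, hi)`` in Mb; a segment shorter than the
    smallest edge is an error (the caller's minimum length was violated).
    The F_ROH contribution of a bin is the group-mean per-individual summed
    length in that bin divided by L_AUTO, in percent.
    """
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    edges = list(bin_edges_mb)
    lengths_mb = np.asarray([s.length_bp / 1e6 for s in segments], dtype=float)
    if lengths_mb.size and lengths_mb.min() < edges[0]:
        raise ValueError(
            f"segment of {lengths_mb.min():.3f} Mb is shorter than the smallest "
            f"length class ({edges[0]:g} Mb)"
        )
    # np.digitize with right=False: index k means edges[k-1] <= x < edges[k]
    bin_of = np.digitize(lengths_mb, edges, right=False) - 1
    n_bins = len(edges)
    counts = np.bincount(bin_of, minlength=n_bins).astype(float)
    sums_mb = np.bincount(bin_of, weights=lengths_mb, minlength=n_bins)

    total_segments = lengths_mb.size
    share_pct = 100.0 * counts / total_segments if total_segments else np.zeros(n_bins)
    froh_pct = 100.0 * (sums_mb / n_individuals) / genome.l_auto_mb

    labels = _bin_labels(edges)
    table = pd.DataFrame(
        {"segment_share_pct": share_pct, "froh_pct": froh_pct}, index=pd.Index(labels, name="length_class")
    )
    cum_values = np.cumsum(froh_pct[:-1])
    cum_labels = [f"<{edges[k + 1]:g} Mb" for k in range(len(edges) - 1)]
    cumulative = pd.Series(cum_values, index=cum_labels, name="froh_cumulative_pct")
    return LengthClassTable(
        table=table,
        cumulative=cumulative,
        total_froh_pct=float(froh_pct.sum()),
        n_individuals=n_individuals,
    )


def group_summary(
    cohort: pd.DataFrame, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Mean/SD/min/max of each ROH variable per group and overall.

    ``cohort`` is the output of :func:`summarize_cohort`; ``groups`` maps
    sample_id to a group label.  SD is the sample standard deviation
    (ddof=1; NaN for singleton groups).
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    missing = [s for s in cohort.index if s not in groups.index]
    if missing:
        raise KeyError(f"samples without group label: {missing[:5]}")
    labels = groups.loc[cohort.index]
    for name in pd.unique(labels):
        if (labels == name).sum() == 0:  # pragma: no cover - defensive
            raise ValueError(f"empty group: {name!r}")

    def _stats(frame: pd.DataFrame, label: str) -> pd.DataFrame:
        agg = frame.agg(["mean", "std", "min", "max"]).T
        agg.columns = ["mean", "sd", "min", "max"]
        agg.insert(0, "n", len(frame))
        agg.index = pd.MultiIndex.from_product([[label], agg.index], names=["group", "variable"])
        return agg

    parts = [_stats(cohort, "All")]
    for name in sorted(pd.unique(labels)):
        sub = cohort.loc[labels[labels == name].index]
        if sub.empty:
            raise ValueError(f"empty group: {name!r}")
        parts.append(_stats(sub, name))
    return pd.concat(parts)
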