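"""Synthetic SNP-array genotypes with planted autozygosity and structure.

The generator emulates a multi-stud-farm horse panel: several
subpopulations diverged from a common ancestral gene pool at a target
F_ST (Balding–Nichols beta model), genotyped at array density on the
autosomes.  Autozygosity is planted as per-individual tracts within which
both haplotypes copy a single allele draw — tract-level identity by
descent, so tract allele content follows local frequencies and looks to a
detector exactly like real autozygosity.  One optional high-frequency
"island" locus forces a shared homozygous tract in a chosen fraction of
carriers.  Heterozygote-error and missingness noise are applied last.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``; the same configuration always yields bit-identical
output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, HET, HOM_A, HOM_B, MISSING

#: approximate EquCab2 autosome lengths in Mb (31 autosomes, ~2243 Mb total)
EQUINE_AUTOSOME_MB: tuple[float, ...] = (
    186, 121, 119, 109, 100, 85, 99, 94, 84, 84, 61, 33, 43, 94, 92, 87,
    81, 82, 60, 64, 58, 50, 56, 47, 40, 42, 40, 46, 34, 30, 25,
)

DEFAULT_CHROMOSOMES: tuple[tuple[str, int], ...] = tuple(
    (str(i + 1), int(mb * 1_000_000)) for i, mb in enumerate(EQUINE_AUTOSOME_MB)
)

#: tract length mixture (Mb, weight) following the observed segment-length
#: spectrum: short background tracts dominate, long recent-inbreeding
#: tracts are rare
DEFAULT_TRACT_MIX: tuple[tuple[float, float], ...] = (
    (0.75, 0.281), (1.5, 0.248), (3.0, 0.231), (5.0, 0.104),
    (7.0, 0.056), (9.0, 0.030), (12.0, 0.050),
)

_STUD_FARM_LABELS = ("Austria", "Slovakia", "Croatia", "Hungary", "Lipica")


@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: 377 individuals in four subpopulations, 31
    autosomes at ~1 SNP / 4 kb, divergence F_ST 0.05, mean autozygosity
    F_ROH 0.13, and a forced-homozygosity island on chromosome 25."""

    samples_per_subpop: tuple[int, ...] = (254, 55, 45, 23)
    subpop_labels: tuple[str, ...] | None = None
    chromosomes: tuple[tuple[str, int], ...] = DEFAULT_CHROMOSOMES
    snp_spacing: int = 4000
    target_fst: float = 0.05
    planted_tract_length_mix: tuple[tuple[float, float], ...] = DEFAULT_TRACT_MIX
    per_individual_froh_target: float = 0.13
    island_spec: tuple[str, int, int, float] | None = ("25", 6_394_110, 6_794_044, 0.66)
    het_error_rate: float = 0.005
    missing_rate: float = 0.002
    seed: int = 0

    @property
    def n_subpops(self) -> int:
        return len(self.samples_per_subpop)

    @property
    def genome_length_bp(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def labels(self) -> tuple[str, ...]:
        if self.subpop_labels is not None:
            return self.subpop_labels
        if self.n_subpops <= len(_STUD_FARM_LABELS):
            return _STUD_FARM_LABELS[: self.n_subpops]
        return tuple(f"pop{i + 1}" for i in range(self.n_subpops))

    def validate(self) -> None:
        if not self.samples_per_subpop or min(self.samples_per_subpop) < 1:
            raise ValueError("each subpopulation needs at least one individual")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1)")
        if not 0.0 <= self.per_individual_froh_target <= 0.5:
            raise ValueError("per_individual_froh_target must be in [0, 0.5]")
        weights = [w for _, w in self.planted_tract_length_mix]
        if self.planted_tract_length_mix and abs(sum(weights) - 1.0) > 1e-6:
            raise ValueError("tract mixture weights must sum to 1")
        if not 0.0 <= self.het_error_rate < 1.0 or not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("noise rates must be in [0, 1)")
        chrom_len = dict(self.chromosomes)
        if self.island_spec is not None:
            chrom, start, end, cf = self.island_spec
            if chrom not in chrom_len:
                raise ValueError(f"island chromosome {chrom!r} not in chromosome list")
            if not 0 < start < end <= chrom_len[chrom]:
                raise ValueError("island interval must lie inside its chromosome")
            if not 0.0 <= cf <= 1.0:
                raise ValueError("island carrier fraction must be in [0, 1]")
        if self.per_individual_froh_target > 0:
            longest = max(length for _, length in self.chromosomes)
            for mb, _w in self.planted_tract_length_mix:
                if mb * 1e6 > longest:
                    raise ValueError(
                        f"tract length {mb} Mb exceeds the longest chromosome"
                    )


@dataclass
class SimTruth:
    """Ground truth for a simulated panel.

    ``tracts`` maps each sample to its merged planted-autozygosity
    intervals; ``ancestral_freqs``/``subpop_freqs`` are the B-allele
    frequencies per chromosome; ``island_carriers`` are the samples that
    received the forced island tract.
    """

    tracts: dict[str, list[tuple[str, int, int]]]
    subpop: dict[str, str]
    ancestral_freqs: dict[str, np.ndarray]
    subpop_freqs: dict[str, np.ndarray]
    island_carriers: frozenset
    config: SimConfig


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _draw_tracts(
    cfg: SimConfig, rng: np.random.Generator
) -> dict[int, list[tuple[str, int, int]]]:
    """Plant tracts per individual until the F_ROH budget is met.

    The final tract is trimmed to the remaining budget so the planted
    total tracks the target closely, but never below the smallest length
    class of the mixture: trimming must not create tracts outside the
    configured length spectrum.
    """
    n_total = sum(cfg.samples_per_subpop)
    target = cfg.per_individual_froh_target * cfg.genome_length_bp
    if target <= 0:
        return {i: [] for i in range(n_total)}
    lengths_bp = np.asarray([mb * 1e6 for mb, _ in cfg.planted_tract_length_mix])
    weights = np.asarray([w for _, w in cfg.planted_tract_length_mix])
    weights = weights / weights.sum()
    chrom_labels = [c for c, _ in cfg.chromosomes]
    chrom_len = np.asarray([length for _, length in cfg.chromosomes], dtype=float)

    out: dict[int, list[tuple[str, int, int]]] = {}
    for ind in range(n_total):
        tracts: list[tuple[str, int, int]] = []
        total = 0.0
        while total < target:
            cls = int(rng.choice(lengths_bp.size, p=weights))
            length = float(lengths_bp[cls]) * rng.uniform(0.85, 1.15)
            remaining = target - total
            if total + length > target:
                length = max(remaining, min(float(lengths_bp.min()), length))
            eligible = np.flatnonzero(chrom_len >= length)
            if eligible.size == 0:
                raise ValueError(
                    f"tract of {length / 1e6:.2f} Mb is longer than every chromosome"
                )
            probs = chrom_len[eligible] / chrom_len[eligible].sum()
            ci = int(eligible[rng.choice(eligible.size, p=probs)])
            center = rng.uniform(length / 2.0, chrom_len[ci] - length / 2.0)
            start = int(center - length / 2.0)
            end = int(center + length / 2.0)
            tracts.append((chrom_labels[ci], max(start, 1), end))
            total += length
        out[ind] = tracts
    return out


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Simulate a structured, partially autozygous SNP panel.

    Returns the genotype matrix (variants sorted by chromosome/position,
    alleles 'A'/'B') and the ground truth.  Deterministic for a fixed
    configuration.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.labels()
    n_per = cfg.samples_per_subpop
    n_total = sum(n_per)
    subpop_of_row = np.repeat(np.arange(cfg.n_subpops), n_per)
    sample_ids = []
    for k, lab in enumerate(labels):
        sample_ids.extend(f"{lab}_{i + 1:03d}" for i in range(n_per[k]))

    tracts_by_ind = _draw_tracts(cfg, rng)

    island = cfg.island_spec
    carriers_idx: np.ndarray = np.empty(0, dtype=np.intp)
    if island is not None:
        n_carriers = int(round(island[3] * n_total))
        carriers_idx = rng.choice(n_total, size=n_carriers, replace=False)

    var_frames = []
    call_blocks = []
    ancestral: dict[str, np.ndarray] = {}
    subfreq: dict[str, np.ndarray] = {}
    F = cfg.target_fst
    for chrom, length in cfg.chromosomes:
        # jittered positions around the mean spacing
        max_snps = int(length / (0.6 * cfg.snp_spacing)) + 2
        gaps = rng.uniform(0.6, 1.4, size=max_snps) * cfg.snp_spacing
        pos = np.cumsum(gaps).astype(np.int64)
        pos = pos[pos <= length]
        m = pos.size

        p_anc = rng.uniform(0.05, 0.95, size=m)
        if F > 0:
            alpha = p_anc * (1 - F) / F
            beta = (1 - p_anc) * (1 - F) / F
            p_sub = rng.beta(alpha[None, :], beta[None, :], size=(cfg.n_subpops, m))
        else:
            p_sub = np.tile(p_anc, (cfg.n_subpops, 1))
        ancestral[chrom] = p_anc
        subfreq[chrom] = p_sub

        p_rows = p_sub[subpop_of_row]  # (n_total, m)
        h1 = rng.random((n_total, m)) < p_rows
        h2 = rng.random((n_total, m)) < p_rows

        # planted autozygosity: both haplotypes copy h1 inside tracts
        for ind in range(n_total):
            for tc, lo, hi in tracts_by_ind[ind]:
                if tc != chrom:
                    continue
                a = np.searchsorted(pos, lo, side="left")
                b = np.searchsorted(pos, hi, side="right")
                h2[ind, a:b] = h1[ind, a:b]
        if island is not None and island[0] == chrom:
            a = np.searchsorted(pos, island[1], side="left")
            b = np.searchsorted(pos, island[2], side="right")
            for ind in carriers_idx:
                h2[ind, a:b] = h1[ind, a:b]

        dosage = h1.astype(np.int8) + h2.astype(np.int8)
        codes = dosage.copy()  # 0 -> HOM_A, 1 -> HET, 2 -> HOM_B
        if cfg.het_error_rate > 0:
            codes[rng.random((n_total, m)) < cfg.het_error_rate] = HET
        if cfg.missing_rate > 0:
            codes[rng.random((n_total, m)) < cfg.missing_rate] = MISSING

        var_frames.append(
            pd.DataFrame(
                {
                    "variant_id": [f"snp_{chrom}_{i + 1}" for i in range(m)],
                    "chromosome": chrom,
                    "position": pos,
                    "allele_a": "A",
                    "allele_b": "B",
                }
            )
        )
        call_blocks.append(codes)

    variants = pd.concat(var_frames, ignore_index=True)
    calls = np.concatenate(call_blocks, axis=1)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subpopulation": [labels[k] for k in subpop_of_row],
        }
    )
    g = GenotypeMatrix(samples=samples, variants=variants, calls=calls)

    truth = SimTruth(
        tracts={
            sample_ids[ind]: [
                (c, lo, hi)
                for c in [cc for cc, _ in cfg.chromosomes]
                for lo, hi in _merge_intervals(
                    [(l, h) for tc, l, h in tracts_by_ind[ind] if tc == c]
                )
            ]
            for ind in range(n_total)
        },
        subpop=dict(zip(sample_ids, samples["subpopulation"])),
        ancestral_freqs=ancestral,
        subpop_freqs=subfreq,
        island_carriers=frozenset(sample_ids[i] for i in carriers_idx),
        config=cfg,
    )
    return g, truth


# ---------------------------------------------------------------------------
# ground-truth and config I/O
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, path) -> None:
    """Tab-separated planted-tract list (sample, chromosome, start, end)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tchromosome\tstart_bp\tend_bp\tis_island_carrier\n")
        for sid, tracts in truth.tracts.items():
            carrier = int(sid in truth.island_carriers)
            if not tracts:
                fh.write(f"{sid}\t.\t0\t0\t{carrier}\n")
            for chrom, lo, hi in tracts:
                fh.write(f"{sid}\t{chrom}\t{lo}\t{hi}\t{carrier}\n")


def config_to_json(cfg: SimConfig) -> str:
    return json.dumps(dataclasses.asdict(cfg), indent=2)


def config_from_json(text: str) -> SimConfig:
    raw = json.loads(text)
    raw["samples_per_subpop"] = tuple(raw["samples_per_subpop"])
    if raw.get("subpop_labels") is not None:
        raw["subpop_labels"] = tuple(raw["subpop_labels"])
    raw["chromosomes"] = tuple((str(c), int(l)) for c, l in raw["chromosomes"])
    raw["planted_tract_length_mix"] = tuple(
        (float(a), float(b)) for a, b in raw["planted_tract_length_mix"]
    )
    if raw.get("island_spec") is not None:
        c, s, e, f = raw["island_spec"]
        raw["island_spec"] = (str(c), int(s), int(e), float(f))
    return SimConfig(**raw)
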