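"""Genotype containers and PLINK-text I/O.

Genotypes live in a dense ``n_samples x n_variants`` matrix of four call
codes (:data:`HOM_A`, :data:`HET`, :data:`HOM_B`, :data:`MISSING`).  The A/B
allele roles are assigned per variant by first occurrence in the input file;
they are cosmetic for every downstream analysis (ROH calling and IBS only
distinguish hom/het/missing and allele sharing), but the assignment is
deterministic so files round-trip.

Coordinates are 1-based base pairs throughout; kb/Mb appear only in
reporting code.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# call codes (int8)
HOM_A = 0
HET = 1
HOM_B = 2
MISSING = 3

CODE_NAMES = {HOM_A: "HOM_A", HET: "HET", HOM_B: "HOM_B", MISSING: "MISSING"}

#: dosage of the B allele per call code; missing -> -1 sentinel
_DOSAGE = np.array([0, 1, 2, -1], dtype=np.int8)


class PlinkParseError(ValueError):
    """Malformed PLINK-dialect text input (message names the line)."""


class QcError(ValueError):
    """Quality-control left no usable data."""


def chromosome_sort_key(label: str) -> tuple[int, int, str]:
    """Order autosomes numerically, then X, Y, unplaced ('0')."""
    if label.isdigit() and label != "0":
        return (0, int(label), "")
    return (1, {"X": 0, "Y": 1, "0": 2}.get(label, 3), label)


def _sort_key_frame(variants: pd.DataFrame) -> np.ndarray:
    keys = [chromosome_sort_key(c) for c in variants["chromosome"]]
    order = sorted(range(len(keys)), key=lambda i: (keys[i], int(variants["position"].iloc[i])))
    return np.asarray(order, dtype=np.intp)


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls with sample and variant metadata.

    Parameters
    ----------
    samples : DataFrame with columns ``sample_id``, ``subpopulation``.
    variants : DataFrame with columns ``variant_id``, ``chromosome``,
        ``position``, ``allele_a``, ``allele_b``; sorted by (chromosome,
        position) with strictly increasing positions per chromosome.
    calls : int8 array, shape (n_samples, n_variants).
    """

    samples: pd.DataFrame
    variants: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.calls.size and (self.calls.min() < 0 or self.calls.max() > 3):
            raise ValueError("calls contain codes outside {HOM_A, HET, HOM_B, MISSING}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def subpopulations(self) -> pd.Series:
        return self.samples.set_index("sample_id")["subpopulation"]

    def sample_index(self, sample_id: str) -> int:
        idx = np.flatnonzero((self.samples["sample_id"] == sample_id).to_numpy())
        if idx.size == 0:
            raise KeyError(f"unknown sample: {sample_id!r}")
        return int(idx[0])

    def b_dosage(self) -> np.ndarray:
        """Dosage of the B allele (0/1/2), -1 where missing."""
        return _DOSAGE[self.calls]

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def check_sorted(self) -> None:
        """Raise if variants are not sorted with strictly increasing positions."""
        pos = self.variants["position"].to_numpy()
        chrom = self.variants["chromosome"].to_numpy()
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"variant positions not strictly increasing on chromosome {c}")

    # -- subsetting --------------------------------------------------------
    def take_variants(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples.reset_index(drop=True),
            variants=self.variants.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples.iloc[index].reset_index(drop=True),
            variants=self.variants.reset_index(drop=True),
            calls=self.calls[index, :],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = np.asarray([self.sample_index(s) for s in sample_ids], dtype=np.intp)
        return self.take_samples(idx)

    # -- per-variant statistics -------------------------------------------
    def variant_missing_rate(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def minor_allele_frequency(self) -> np.ndarray:
        """MAF per variant over non-missing calls; NaN if all calls missing."""
        dos = self.b_dosage().astype(np.float64)
        dos[dos < 0] = np.nan
        with np.errstate(invalid="ignore"):
            freq_b = np.nanmean(dos, axis=0) / 2.0
        return np.minimum(freq_b, 1.0 - freq_b)


@dataclass(frozen=True)
class QcParams:
    """Variant-level quality-control thresholds.

    ``maf_min`` removes variants with minor allele frequency strictly below
    the threshold (computed on non-missing calls); ``max_missing_rate``
    removes variants with missingness strictly above the threshold;
    ``excluded_chromosomes`` are dropped first (sex chromosomes and unplaced
    markers in the standard setting).
    """

    maf_min: float = 0.01
    max_missing_rate: float = 0.10
    excluded_chromosomes: frozenset = frozenset({"X", "Y", "0"})

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ValueError("max_missing_rate must be in [0, 1]")


@dataclass
class QcReport:
    """Counts of variants removed by each rule, in application order."""

    n_input: int
    removed_chromosome: int
    removed_missing: int
    removed_maf: int
    n_retained: int

    def to_tsv(self) -> str:
        rows = [
            ("input_variants", self.n_input),
            ("removed_excluded_chromosome", self.removed_chromosome),
            ("removed_missingness", self.removed_missing),
            ("removed_maf", self.removed_maf),
            ("retained_variants", self.n_retained),
        ]
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _read_lines(source) -> list[str]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    return text.splitlines()


def _parse_map(map_source) -> pd.DataFrame:
    rows = []
    for lineno, line in enumerate(_read_lines(map_source), start=1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) != 4:
            raise PlinkParseError(f"MAP line {lineno}: expected 4 columns, got {len(tok)}")
        chrom, vid, _cm, bp = tok
        try:
            pos = int(bp)
        except ValueError as exc:
            raise PlinkParseError(f"MAP line {lineno}: non-integer position {bp!r}") from exc
        if pos <= 0:
            raise PlinkParseError(f"MAP line {lineno}: position must be positive, got {pos}")
        rows.append((vid, chrom, pos))
    frame = pd.DataFrame(rows, columns=["variant_id", "chromosome", "position"])
    dup = frame["variant_id"].duplicated()
    if dup.any():
        raise PlinkParseError(f"duplicate variant id: {frame['variant_id'][dup].iloc[0]!r}")
    return frame


def _code_variant(a1: np.ndarray, a2: np.ndarray, variant_id: str) -> tuple[np.ndarray, str, str]:
    """Code one variant's allele pairs; roles by first observed allele."""
    miss = (a1 == "0") | (a2 == "0")
    # allele roles come from fully-called genotypes only: a half-missing
    # pair is treated as missing and must not influence the A/B assignment
    interleaved = np.empty(a1.size * 2, dtype=a1.dtype)
    interleaved[0::2] = np.where(miss, "0", a1)
    interleaved[1::2] = np.where(miss, "0", a2)
    observed = pd.unique(interleaved[interleaved != "0"])
    if observed.size > 2:
        raise PlinkParseError(
            f"variant {variant_id!r}: more than two alleles observed ({list(observed)})"
        )
    allele_a = str(observed[0]) if observed.size >= 1 else "0"
    allele_b = str(observed[1]) if observed.size == 2 else "0"
    codes = np.full(a1.size, MISSING, dtype=np.int8)
    hom = (a1 == a2) & ~miss
    codes[hom & (a1 == allele_a)] = HOM_A
    if allele_b != "0":
        codes[hom & (a1 == allele_b)] = HOM_B
        codes[~hom & ~miss] = HET
    return codes, allele_a, allele_b


def read_plink_text(ped_source, map_source) -> GenotypeMatrix:
    """Read a PED/MAP pair (whitespace separated, allele '0' = missing).

    The PED family id is kept as the subpopulation label.  Variants are
    returned sorted by (chromosome, position); HOM_A is the homozygote for
    the first allele observed at each variant.
    """
    variants = _parse_map(map_source)
    m = len(variants)

    sample_rows = []
    allele_rows = []
    for lineno, line in enumerate(_read_lines(ped_source), start=1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) != 6 + 2 * m:
            raise PlinkParseError(
                f"PED line {lineno}: expected {6 + 2 * m} fields "
                f"(6 metadata + 2 alleles x {m} variants), got {len(tok)}"
            )
        sample_rows.append((tok[1], tok[0]))
        allele_rows.append(tok[6:])
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "subpopulation"])
    if samples["sample_id"].duplicated().any():
        dup = samples["sample_id"][samples["sample_id"].duplicated()].iloc[0]
        raise PlinkParseError(f"duplicate sample id: {dup!r}")

    n = len(samples)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    allele_a = [""] * m
    allele_b = [""] * m
    if n:
        alleles = np.asarray(allele_rows)
        for j in range(m):
            codes, a, b = _code_variant(
                alleles[:, 2 * j], alleles[:, 2 * j + 1], variants["variant_id"].iloc[j]
            )
            calls[:, j] = codes
            allele_a[j] = a
            allele_b[j] = b
    variants = variants.assign(allele_a=allele_a, allele_b=allele_b)

    order = _sort_key_frame(variants)
    variants = variants.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    g = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    g.check_sorted()
    return g


def read_plink_transposed(tped_source, tfam_source) -> GenotypeMatrix:
    """Read the transposed TPED/TFAM dialect (one variant per TPED row)."""
    sample_rows = []
    for lineno, line in enumerate(_read_lines(tfam_source), start=1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) != 6:
            raise PlinkParseError(f"TFAM line {lineno}: expected 6 columns, got {len(tok)}")
        sample_rows.append((tok[1], tok[0]))
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "subpopulation"])
    if samples["sample_id"].duplicated().any():
        dup = samples["sample_id"][samples["sample_id"].duplicated()].iloc[0]
        raise PlinkParseError(f"duplicate sample id: {dup!r}")
    n = len(samples)

    var_rows = []
    code_cols = []
    aa, bb = [], []
    for lineno, line in enumerate(_read_lines(tped_source), start=1):
        if not line.strip():
            continue
        tok = line.split()
        if len(tok) != 4 + 2 * n:
            raise PlinkParseError(
                f"TPED line {lineno}: expected {4 + 2 * n} fields, got {len(tok)}"
            )
        chrom, vid, _cm, bp = tok[:4]
        pos = int(bp)
        if pos <= 0:
            raise PlinkParseError(f"TPED line {lineno}: position must be positive, got {pos}")
        var_rows.append((vid, chrom, pos))
        pairs = np.asarray(tok[4:])
        codes, a, b = _code_variant(pairs[0::2], pairs[1::2], vid)
        code_cols.append(codes)
        aa.append(a)
        bb.append(b)
    variants = pd.DataFrame(var_rows, columns=["variant_id", "chromosome", "position"])
    dup = variants["variant_id"].duplicated()
    if dup.any():
        raise PlinkParseError(f"duplicate variant id: {variants['variant_id'][dup].iloc[0]!r}")
    variants = variants.assign(allele_a=aa, allele_b=bb)
    calls = np.stack(code_cols, axis=1) if code_cols else np.empty((n, 0), dtype=np.int8)

    order = _sort_key_frame(variants)
    variants = variants.iloc[order].reset_index(drop=True)
    calls = calls[:, order]
    g = GenotypeMatrix(samples=samples, variants=variants, calls=calls)
    g.check_sorted()
    return g


def write_plink_text(g: GenotypeMatrix, ped_path, map_path) -> None:
    """Write PED/MAP; inverse of :func:`read_plink_text` on its own output."""
    map_lines = [
        f"{row.chromosome}\t{row.variant_id}\t0\t{row.position}"
        for row in g.variants.itertuples()
    ]
    Path(map_path).write_text("\n".join(map_lines) + ("\n" if map_lines else ""))

    a = g.variants["allele_a"].to_numpy()
    b = g.variants["allele_b"].to_numpy()
    if np.any((b == "0") & np.isin(g.calls, [HET, HOM_B]).any(axis=0)):
        raise ValueError("HET/HOM_B call at a variant with no second allele recorded")
    # per-variant lookup tables: code -> "x y"
    zeros = np.full(a.shape, "0", dtype=a.dtype)
    pair = np.char.add(np.char.add(np.stack([a, a, b, zeros]), " "),
                       np.stack([a, b, b, zeros]))  # rows: HOM_A, HET, HOM_B, MISSING
    with open(ped_path, "w") as fh:
        for i, srow in enumerate(g.samples.itertuples()):
            geno = pair[g.calls[i], np.arange(g.n_variants)]
            fh.write(
                f"{srow.subpopulation} {srow.sample_id} 0 0 0 -9 " + " ".join(geno) + "\n"
            )


# ---------------------------------------------------------------------------
# QC and per-SNP statistics
# ---------------------------------------------------------------------------

def apply_qc(g: GenotypeMatrix, qc: QcParams) -> tuple[GenotypeMatrix, QcReport]:
    """Apply variant QC in fixed order: chromosome -> missingness -> MAF.

    Returns the filtered matrix and a report of how many variants each rule
    removed.  Raises :class:`QcError` if nothing survives.
    """
    if g.n_variants == 0:
        raise QcError("empty genotype matrix")
    n0 = g.n_variants

    keep = ~g.variants["chromosome"].isin(qc.excluded_chromosomes).to_numpy()
    removed_chrom = int(n0 - keep.sum())
    g1 = g.take_variants(np.flatnonzero(keep))

    miss = g1.variant_missing_rate()
    keep = miss <= qc.max_missing_rate
    removed_missing = int(keep.size - keep.sum())
    g2 = g1.take_variants(np.flatnonzero(keep))

    maf = g2.minor_allele_frequency()
    # variants with zero non-missing calls have undefined MAF; the missingness
    # rule is responsible for them, so they are kept here
    keep = ~(maf < qc.maf_min)
    removed_maf = int(keep.size - keep.sum())
    g3 = g2.take_variants(np.flatnonzero(keep))

    if g3.n_variants == 0:
        raise QcError("no variants remain after QC")
    report = QcReport(
        n_input=n0,
        removed_chromosome=removed_chrom,
        removed_missing=removed_missing,
        removed_maf=removed_maf,
        n_retained=g3.n_variants,
    )
    return g3, report


def snp_homozygosity(
    g: GenotypeMatrix,
    variant_ids: Sequence[str],
    sample_ids: Sequence[str] | None = None,
) -> pd.Series:
    """Fraction of homozygous calls per SNP among the selected samples.

    The denominator counts non-missing calls only.  A SNP with no
    non-missing call in the selection yields NaN.
    """
    vindex = g.variants.set_index("variant_id").index
    missing = [v for v in variant_ids if v not in vindex]
    if missing:
        raise KeyError(f"unknown variant ids: {missing}")
    cols = np.asarray([vindex.get_loc(v) for v in variant_ids], dtype=np.intp)

    sub = g if sample_ids is None else g.subset_samples(sample_ids)
    calls = sub.calls[:, cols]
    hom = ((calls == HOM_A) | (calls == HOM_B)).sum(axis=0).astype(float)
    nonmiss = (calls != MISSING).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(nonmiss > 0, hom / nonmiss, np.nan)
    return pd.Series(frac, index=list(variant_ids), name="fraction_homozygous")
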