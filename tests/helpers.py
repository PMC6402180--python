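"""Shared test utilities: matrix builders and independent oracles.

The oracles here deliberately avoid the production code paths: the ROH
oracle enumerates every subinterval with prefix-sum broadcasting and then
applies the same greedy selection rule (smallest start, largest end,
non-overlapping) that the scanning caller promises.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from rohscape.genotypes import GenotypeMatrix, HOM_A, HET, HOM_B, MISSING


def make_matrix(codes, positions=None, chromosomes=None, sample_ids=None,
                subpops=None, spacing=5000):
    """Build a GenotypeMatrix from a 2-D code array (samples x variants)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    if positions is None:
        positions = (np.arange(m) + 1) * spacing
    positions = np.asarray(positions)
    if chromosomes is None:
        chromosomes = ["1"] * m
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if subpops is None:
        subpops = ["pop"] * n
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chromosome": list(chromosomes),
            "position": positions,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    samples = pd.DataFrame({"sample_id": sample_ids, "subpopulation": subpops})
    return GenotypeMatrix(samples=samples, variants=variants, calls=codes)


def qualifying_intervals(pos, codes, params):
    """Boolean matrix Q[i, j]: does the subinterval [i, j] qualify as a ROH.

    Checks every constraint independently of the scanning caller: het and
    missing budgets, maximum gap, minimum span, minimum homozygous count,
    density, homozygous endpoints.
    """
    pos = np.asarray(pos, dtype=np.int64)
    codes = np.asarray(codes)
    n = pos.size
    hom = (codes == HOM_A) | (codes == HOM_B)
    het = codes == HET
    mis = codes == MISSING
    c_hom = np.concatenate([[0], np.cumsum(hom)])
    c_het = np.concatenate([[0], np.cumsum(het)])
    c_mis = np.concatenate([[0], np.cumsum(mis)])
    bad_gap = np.concatenate([[0], np.cumsum(np.diff(pos) > params.max_gap_bp)])

    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    length = pos[None, :] - pos[:, None]
    n_snps = j - i + 1
    n_hom = c_hom[j + 1] - c_hom[i]
    n_het = c_het[j + 1] - c_het[i]
    n_mis = c_mis[j + 1] - c_mis[i]
    gaps_ok = (bad_gap[j] - bad_gap[i]) == 0

    len_ok = length > params.min_length_bp if params.strict_length else length >= params.min_length_bp
    hom_ok = n_hom > params.min_hom_snps if params.strict_hom else n_hom >= params.min_hom_snps
    q = (
        (j >= i)
        & hom[:, None]
        & hom[None, :]
        & (n_het <= params.max_het)
        & (n_mis <= params.max_missing)
        & gaps_ok
        & len_ok
        & hom_ok
        & (length <= params.max_bp_per_snp * n_snps)
    )
    return q


def exhaustive_roh_oracle(pos, codes, params):
    """Greedy selection over the full qualifying-interval enumeration."""
    q = qualifying_intervals(pos, codes, params)
    n = q.shape[0]
    selected = []
    p = 0
    while p < n:
        rows = np.flatnonzero(q[p:, :].any(axis=1))
        if rows.size == 0:
            break
        i = p + int(rows[0])
        j = int(np.flatnonzero(q[i])[-1])
        selected.append((i, j))
        p = j + 1
    return selected


def reciprocal_overlap(a_start, a_end, b_start, b_end):
    ov = min(a_end, b_end) - max(a_start, b_start)
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))
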