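"""LD, kinship, and map statistics for inbred biparental panels.

Implements pairwise r² (squared genotype correlation — identical to the
haplotype r² for fully homozygous biallelic data), LD decay binned in 100-kb
physical-distance increments, the average LD between adjacent markers of a
marker set (ALAM), a realized-kinship matrix as proportion identity-by-state,
and an expanded genetic map estimated from adjacent-marker discordance via
the inverse Haldane map function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._haldane import inverse_haldane_cm
from .io import MISSING, GeneticMap, GenotypeMatrix


def average_adjacent_distance(total_map_length_cm: float, n_markers: int) -> float:
    """Average adjacent genetic distance of an evenly spread marker set.

    Defined as total map length divided by the number of markers, e.g. a
    6,240-cM map sampled at 800 markers averages 7.80 cM between adjacent
    markers.
    """
    if n_markers <= 0:
        raise ValueError("n_markers must be positive")
    return total_map_length_cm / n_markers


def pairwise_r2(col_a: np.ndarray, col_b: np.ndarray) -> float:
    """Squared Pearson correlation between two marker code columns.

    Rows where either column is missing are dropped; a column that is
    monomorphic after dropping yields ``nan`` (undefined LD, excluded from
    averages).
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    keep = (a != MISSING) & (b != MISSING)
    a, b = a[keep], b[keep]
    if len(a) < 2 or len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(codes: np.ndarray) -> np.ndarray:
    """All-pairs r² between columns of a complete {0,2} code matrix."""
    x = codes.astype(float)
    x -= x.mean(axis=0)
    sd = x.std(axis=0)
    poly = sd > 0
    x[:, poly] /= sd[poly]
    r = (x.T @ x) / x.shape[0]
    r2 = r * r
    r2[~poly, :] = np.nan
    r2[:, ~poly] = np.nan
    return r2


@dataclass(frozen=True)
class KinshipMatrix:
    """Realized relationship matrix: proportion of markers identical by state."""

    line_ids: np.ndarray
    values: np.ndarray
    _write_index = True

    @property
    def mean_off_diagonal(self) -> float:
        n = len(self.line_ids)
        mask = ~np.eye(n, dtype=bool)
        return float(self.values[mask].mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.line_ids, columns=self.line_ids)


def kinship_matrix(genotypes: GenotypeMatrix) -> KinshipMatrix:
    """Allele-sharing similarity: K_ij = fraction of markers with equal codes.

    Requires complete (imputed) homozygous genotypes; the diagonal is exactly
    1 and off-diagonals lie in [0, 1].
    """
    if genotypes.n_markers == 0:
        raise ValueError("genotype matrix has zero markers")
    if genotypes.n_missing:
        raise ValueError("kinship requires complete genotypes; impute first")
    a = (genotypes.codes == 0).astype(np.float64)
    b = (genotypes.codes == 2).astype(np.float64)
    match = a @ a.T + b @ b.T
    values = match / genotypes.n_markers
    return KinshipMatrix(genotypes.line_ids, values)


def ld_decay_curve(
    genotypes: GenotypeMatrix, max_dist: int, bin_width: int = 100_000
) -> pd.DataFrame:
    """Mean r² of intra-chromosomal marker pairs binned by physical distance.

    Pairs with bp distance below ``max_dist`` fall into half-open bins
    ``[k·bin, (k+1)·bin)``; each bin reports the unweighted mean of defined
    r² values and the pair count.  Bins without pairs carry ``nan``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    complete = genotypes.n_missing == 0
    for chrom in genotypes.map.chromosomes:
        sl = genotypes.map.chrom_slice(chrom)
        pos = genotypes.map.physical_pos[sl]
        codes = genotypes.codes[:, sl]
        m = len(pos)
        if m < 2:
            continue
        if complete:
            r2 = _r2_matrix(codes)
            iu, ju = np.triu_indices(m, k=1)
            dist = np.abs(pos[ju] - pos[iu])
            vals = r2[iu, ju]
        else:
            pairs = [
                (abs(int(pos[j]) - int(pos[i])), pairwise_r2(codes[:, i], codes[:, j]))
                for i in range(m) for j in range(i + 1, m)
                if abs(int(pos[j]) - int(pos[i])) < max_dist
            ]
            if not pairs:
                continue
            dist = np.array([d for d, _ in pairs])
            vals = np.array([v for _, v in pairs])
        keep = (dist < max_dist) & ~np.isnan(vals)
        b = (dist[keep] // bin_width).astype(int)
        np.add.at(sums, b, vals[keep])
        np.add.at(counts, b, 1)

    mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_lower": np.arange(n_bins, dtype=np.int64) * bin_width,
            "bin_upper": (np.arange(n_bins, dtype=np.int64) + 1) * bin_width,
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def alam(genotypes: GenotypeMatrix, marker_subset=None) -> float:
    """Average LD between adjacent markers (ALAM) of a marker set.

    Mean of pairwise r² over all intra-chromosomal adjacent pairs of the
    subset (full panel when ``marker_subset`` is None), in map order;
    undefined pairs are excluded.
    """
    geno = genotypes if marker_subset is None else genotypes.subset_markers(marker_subset)
    vals = []
    for chrom in geno.map.chromosomes:
        sl = geno.map.chrom_slice(chrom)
        codes = geno.codes[:, sl]
        for j in range(codes.shape[1] - 1):
            vals.append(pairwise_r2(codes[:, j], codes[:, j + 1]))
    vals = np.asarray(vals, dtype=float)
    if vals.size == 0:
        raise ValueError("marker subset has fewer than 2 markers on every chromosome")
    return float(np.nanmean(vals))


def estimate_expanded_map(
    genotypes: GenotypeMatrix,
    ril_correction: bool = False,
    cap_cm: float = 200.0,
) -> GeneticMap:
    """Estimate the realized (expanded) genetic map from a homozygous panel.

    Adjacent-marker discordance rates serve as recombination-fraction
    estimates ĉ (directly, as appropriate for doubled haploids and for maps
    meant to absorb design effects; with ``ril_correction`` the selfed-RIL
    back-transform c = R/(2 − 2R) is applied first).  Each interval is
    converted to cM via the inverse Haldane function and cumulated within
    chromosomes; intervals with ĉ ≥ 0.5 are set to ``cap_cm`` and flagged
    with a warning.  Physical positions are carried over unchanged.
    """
    if genotypes.n_lines < 30:
        raise ValueError("need at least 30 lines to estimate an expanded map")
    gmap = genotypes.map
    new_cm = np.empty(len(gmap), dtype=float)
    n_capped = 0
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        codes = genotypes.codes[:, sl]
        m = codes.shape[1]
        d = np.zeros(m - 1)
        for j in range(m - 1):
            a, b = codes[:, j], codes[:, j + 1]
            keep = (a != MISSING) & (b != MISSING)
            if keep.sum() == 0:
                d[j] = 0.0
                continue
            c_hat = float((a[keep] != b[keep]).mean())
            if ril_correction and c_hat < 0.5:
                c_hat = c_hat / (2.0 - 2.0 * c_hat)
            if c_hat >= 0.5:
                d[j] = cap_cm
                n_capped += 1
            else:
                d[j] = float(inverse_haldane_cm(c_hat))
        new_cm[sl] = np.concatenate([[0.0], np.cumsum(d)])
    if n_capped:
        warnings.warn(
            f"{n_capped} intervals had discordance >= 0.5 and were capped at "
            f"{cap_cm} cM",
            stacklevel=2,
        )
    return GeneticMap(gmap.marker_ids, gmap.chromosome, new_cm, gmap.physical_pos)
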