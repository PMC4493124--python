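"""Genotype imputation for fully inbred biparental panels.

Two complementary operations:

* :func:`impute_missing_hmm` — fill missing cells within a panel using a
  two-state (AA/BB) hidden Markov model along each chromosome.  Transition
  probabilities between adjacent markers follow the Haldane map function on
  the panel's genetic distances; emissions allow a symmetric genotyping error
  rate ε.  Each missing cell is replaced by the forward–backward posterior
  mode; observed cells are never altered.

* :func:`impute_cross_panel` — project a dense marker panel onto lines
  genotyped at a sparse panel sharing the same physical coordinates, using
  the nearest flanking sparse markers: agreeing flanks decide the genotype,
  disagreeing flanks fall back to the physically nearer one, and exact ties
  are left missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._haldane import haldane_c_cm
from .io import MISSING, GeneticMap, GenotypeMatrix


@dataclass(frozen=True)
class HmmParams:
    """Parameters of the two-state imputation HMM.

    ``error_rate`` is the probability that an observed call disagrees with
    the underlying genotype; it must be below 0.5 for the states to remain
    identifiable.
    """

    error_rate: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


def _observation_index(codes: np.ndarray) -> np.ndarray:
    """Map codes {0, 2, MISSING} -> observation symbols {0, 1, 2=missing}."""
    obs = np.full(codes.shape, 2, dtype=np.int8)
    obs[codes == 0] = 0
    obs[codes == 2] = 1
    return obs


def impute_missing_hmm(
    genotypes: GenotypeMatrix,
    params: HmmParams = HmmParams(),
    gmap: GeneticMap | None = None,
    return_posterior: bool = False,
):
    """Fill missing genotype codes by forward–backward posterior mode.

    Runs the HMM independently per line and chromosome.  ``gmap`` overrides
    the distances used for transitions (pass the panel's *expanded* map when
    the stored map is on the base scale); it must list the same markers in
    the same order.  Posterior ties at exactly 0.5 stay missing (and are
    reported via a warning).

    Returns the imputed :class:`~ibmgs.io.GenotypeMatrix`, plus the posterior
    probability array ``(n_lines, n_markers, 2)`` if ``return_posterior``.
    """
    dist_map = genotypes.map if gmap is None else gmap
    if list(dist_map.marker_ids) != list(genotypes.map.marker_ids):
        raise ValueError("distance map must list the same markers in the same order")

    eps = params.error_rate
    # emission[state, obs]: obs 2 = missing is uninformative
    emission = np.array([[1.0 - eps, eps, 1.0], [eps, 1.0 - eps, 1.0]])
    obs = _observation_index(genotypes.codes)
    n_lines, n_markers = obs.shape
    posterior = np.empty((n_lines, n_markers, 2), dtype=float)

    for chrom in dist_map.chromosomes:
        sl = dist_map.chrom_slice(chrom)
        g = dist_map.genetic_pos[sl]
        c = haldane_c_cm(np.diff(g))  # per-interval recombination fractions
        o = obs[:, sl]
        m = o.shape[1]

        alpha = np.empty((n_lines, m, 2))
        scale = np.empty((n_lines, m))
        alpha[:, 0] = 0.5 * emission[:, o[:, 0]].T
        scale[:, 0] = alpha[:, 0].sum(axis=1)
        alpha[:, 0] /= scale[:, 0, None]
        for j in range(1, m):
            stay, move = 1.0 - c[j - 1], c[j - 1]
            pred = np.empty((n_lines, 2))
            pred[:, 0] = alpha[:, j - 1, 0] * stay + alpha[:, j - 1, 1] * move
            pred[:, 1] = alpha[:, j - 1, 0] * move + alpha[:, j - 1, 1] * stay
            a = pred * emission[:, o[:, j]].T
            scale[:, j] = a.sum(axis=1)
            if (scale[:, j] <= 0).any():
                raise ValueError(
                    f"zero forward probability on chromosome {chrom}; "
                    "data inconsistent with error_rate=0"
                )
            alpha[:, j] = a / scale[:, j, None]

        beta = np.ones((n_lines, 2))
        post = posterior[:, sl]  # view into the full posterior array
        post[:, m - 1] = alpha[:, m - 1]
        for j in range(m - 2, -1, -1):
            stay, move = 1.0 - c[j], c[j]
            be = beta * emission[:, o[:, j + 1]].T
            nb = np.empty_like(beta)
            nb[:, 0] = be[:, 0] * stay + be[:, 1] * move
            nb[:, 1] = be[:, 0] * move + be[:, 1] * stay
            beta = nb / nb.sum(axis=1, keepdims=True)
            p = alpha[:, j] * beta
            post[:, j] = p / p.sum(axis=1, keepdims=True)

    codes = genotypes.codes.copy()
    missing = codes == MISSING
    mode = np.where(posterior[:, :, 1] > 0.5, 2, 0).astype(np.int8)
    tie = np.isclose(posterior[:, :, 1], 0.5, rtol=0.0, atol=1e-12)
    mode[tie] = MISSING
    codes[missing] = mode[missing]
    if (missing & tie).any():
        warnings.warn(
            f"{int((missing & tie).sum())} cells had posterior exactly 0.5 "
            "and were left missing",
            stacklevel=2,
        )
    imputed = GenotypeMatrix(genotypes.line_ids, genotypes.map, codes)
    return (imputed, posterior) if return_posterior else imputed


def impute_cross_panel(
    sparse: GenotypeMatrix, dense_map: GeneticMap
) -> GenotypeMatrix:
    """Impute a dense marker panel from sparsely genotyped lines.

    Both maps must share the physical (bp) coordinate system.  For each dense
    marker: copy an exactly coinciding sparse marker; otherwise take the
    shared genotype of agreeing flanking sparse markers, the physically
    nearer flank when they disagree, the single flank at chromosome ends, and
    missing on an exact distance tie between disagreeing flanks.
    """
    if sparse.n_missing:
        raise ValueError("sparse panel has missing codes; run impute_missing_hmm first")
    smap = sparse.map
    sparse_chroms = set(int(c) for c in smap.chromosomes)
    n_lines = sparse.n_lines
    out = np.empty((n_lines, len(dense_map)), dtype=np.int8)

    for chrom in dense_map.chromosomes:
        if int(chrom) not in sparse_chroms:
            raise ValueError(f"chromosome {chrom} absent from the sparse map")
        dsl = dense_map.chrom_slice(chrom)
        ssl = smap.chrom_slice(chrom)
        dpos = dense_map.physical_pos[dsl]
        spos = smap.physical_pos[ssl]
        scodes = sparse.codes[:, ssl]

        right = np.searchsorted(spos, dpos, side="left")
        left = right - 1
        left_ok = left >= 0
        right_ok = right < len(spos)
        # clip for safe gathering; validity masks applied below
        lidx = np.clip(left, 0, len(spos) - 1)
        ridx = np.clip(right, 0, len(spos) - 1)
        ldist = np.where(left_ok, dpos - spos[lidx], np.iinfo(np.int64).max)
        rdist = np.where(right_ok, spos[ridx] - dpos, np.iinfo(np.int64).max)

        lcode = scodes[:, lidx]
        rcode = scodes[:, ridx]
        exact = right_ok & (rdist == 0)

        chosen = np.where(ldist[None, :] <= rdist[None, :], lcode, rcode)
        agree = lcode == rcode
        tie = (ldist == rdist) & left_ok & right_ok
        cell = np.where(agree, lcode, chosen)
        cell = np.where(~agree & tie[None, :], MISSING, cell)
        cell = np.where(~left_ok[None, :], rcode, cell)
        cell = np.where(~right_ok[None, :], lcode, cell)
        cell = np.where(exact[None, :], rcode, cell)
        out[:, dsl] = cell

    return GenotypeMatrix(sparse.line_ids, dense_map, out)
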