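"""Synthetic-data generator for intermated biparental maize-like populations.

Simulates the statistical structure the analysis assumes: two fully inbred
founders (B73/Mo17-like), an F1, an F2 pool, several generations of random
intermating, and a terminal inbreeding step — either doubled haploids (DH,
Syn10-like) or recombinant inbred lines by selfing (RIL, Syn4-like).  Meiosis
follows the Haldane model: per chromosome, crossover counts are Poisson in
the map length (Morgans) and crossover positions are uniform on the genetic
scale (no interference).

Two named designs emulate the study populations:

* ``SYN10_DESIGN`` — 194 DH lines after 10 generations of intermating.
* ``SYN4_DESIGN`` — 244 selfed RILs after 4 generations of intermating.

Additive traits are simulated from a small number of QTL (default 17) whose
positions are interleaved into the map but excluded from the marker panel, so
markers tag QTL only through linkage disequilibrium.  Plot-level phenotypes
get i.i.d. normal residuals scaled so that the line-mean heritability at the
requested replicate number matches the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from ._haldane import haldane_c_cm
from .io import MISSING, GeneticMap, GenotypeMatrix, PlotPhenotypes

# Base (F2-scale) genome: 10 chromosomes, B73-like physical lengths (Mb) and
# ~0.83 cM/Mb, i.e. ~2.05 Gb and ~1700 cM before any map expansion.
_CHROM_MB = (301, 237, 232, 242, 217, 169, 176, 175, 157, 149)
_CM_PER_MB = 0.83


@dataclass(frozen=True)
class PopulationDesign:
    """Pedigree of an intermated biparental inbred-line population."""

    n_lines: int
    intermating_generations: int
    terminal: Literal["DH", "RIL"] = "DH"
    selfing_generations: int = 6  # used for RIL terminal only
    intermating_pool_size: int = 200

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.intermating_generations < 0:
            raise ValueError("intermating_generations must be >= 0")
        if self.intermating_pool_size < 2:
            raise ValueError("intermating pool size must be >= 2")
        if self.terminal not in ("DH", "RIL"):
            raise ValueError("terminal must be 'DH' or 'RIL'")


# Pool sizes differ between the two presets: drift (the only free knob of the
# neutral pedigree) is calibrated so that the Syn4-like panel shows the higher
# mean realized kinship of the two, as observed in the real populations.
SYN10_DESIGN = PopulationDesign(
    n_lines=194, intermating_generations=10, terminal="DH", intermating_pool_size=400
)
SYN4_DESIGN = PopulationDesign(
    n_lines=244, intermating_generations=4, terminal="RIL",
    selfing_generations=6, intermating_pool_size=60,
)


@dataclass
class TraitModel:
    """Additive genetic architecture of a simulated quantitative trait."""

    n_qtl: int = 17
    qtl_marker_ids: tuple | None = None  # loci of the genotype map acting as QTL
    additive_effects: np.ndarray | None = None  # per-allele substitution effects
    target_Vg: float | None = None  # rescale breeding values to this variance
    target_h2: float = 0.8  # line-mean heritability at n_reps plots
    target_Ve: float | None = None  # plot residual variance; overrides target_h2
    n_reps: int = 4


@dataclass
class TraitRealization:
    """True breeding values plus plot-level phenotypes for one population."""

    true_breeding_values: pd.Series  # indexed by line id
    plot_phenotypes: PlotPhenotypes
    qtl_marker_ids: tuple
    additive_effects: np.ndarray
    realized_Vg: float
    realized_Ve: float


class _MeiosisEngine:
    """Precomputed per-chromosome structure for fast repeated meiosis."""

    def __init__(self, gmap: GeneticMap) -> None:
        self.chroms = []
        for chrom in gmap.chromosomes:
            sl = gmap.chrom_slice(chrom)
            g = gmap.genetic_pos[sl]
            self.chroms.append((sl, g, float(g[-1] - g[0]) / 100.0))
        self.n_loci = len(gmap)

    def gamete(self, hap_pair: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = np.empty(self.n_loci, dtype=hap_pair.dtype)
        for sl, g, morgans in self.chroms:
            start = int(rng.integers(2))
            n_x = int(rng.poisson(morgans)) if morgans > 0 else 0
            if n_x == 0:
                out[sl] = hap_pair[start, sl]
                continue
            xo = np.sort(rng.uniform(g[0], g[-1], size=n_x))
            crossings = np.searchsorted(xo, g, side="right")
            which = (start + crossings) % 2
            seg = hap_pair[:, sl]
            out[sl] = np.where(which == 0, seg[0], seg[1])
        return out


def simulate_gamete(
    parent_haplopair: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete from a (2, n_markers) haplotype pair.

    Crossover counts per chromosome are Poisson in the chromosome's length in
    Morgans; positions are uniform on the genetic scale (Haldane model).
    """
    hap_pair = np.asarray(parent_haplopair)
    if hap_pair.shape != (2, len(gmap)):
        raise ValueError(f"haplotype pair must have shape (2, {len(gmap)})")
    return _MeiosisEngine(gmap).gamete(hap_pair, rng)


def simulate_population(
    design: PopulationDesign,
    base_map: GeneticMap,
    rng: np.random.Generator,
    line_prefix: str = "L",
) -> GenotypeMatrix:
    """Simulate a terminal inbred population under the given pedigree.

    Founders are two fully homozygous inbreds coded 0 and 2 at every locus of
    *base_map* (given on the F2/base cM scale).  The pedigree is
    F1 → F2 pool → random non-self intermating for the stated generations →
    terminal DH (one doubled gamete per line) or RIL selfing.  Output codes
    are fully homozygous {0, 2}.
    """
    eng = _MeiosisEngine(base_map)
    n_loci = len(base_map)
    pool_n = design.intermating_pool_size

    f1 = np.zeros((2, n_loci), dtype=np.int8)
    f1[1] = 1  # haplotype alleles: 0 = founder A, 1 = founder B

    # F2 pool: each individual from two independent F1 gametes
    pool = np.empty((pool_n, 2, n_loci), dtype=np.int8)
    for i in range(pool_n):
        pool[i, 0] = eng.gamete(f1, rng)
        pool[i, 1] = eng.gamete(f1, rng)

    # random non-self mating, one offspring per pairing, parents drawn with
    # replacement across pairings
    for _ in range(design.intermating_generations):
        new_pool = np.empty_like(pool)
        for i in range(pool_n):
            a = int(rng.integers(pool_n))
            b = int(rng.integers(pool_n - 1))
            if b >= a:
                b += 1
            new_pool[i, 0] = eng.gamete(pool[a], rng)
            new_pool[i, 1] = eng.gamete(pool[b], rng)
        pool = new_pool

    codes = np.empty((design.n_lines, n_loci), dtype=np.int8)
    for i in range(design.n_lines):
        parent = pool[int(rng.integers(pool_n))]
        if design.terminal == "DH":
            codes[i] = 2 * eng.gamete(parent, rng)
        else:
            ind = parent
            for _ in range(design.selfing_generations):
                ind = np.stack([eng.gamete(ind, rng), eng.gamete(ind, rng)])
            # single-seed-descent continuation: keep selfing until fixation so
            # residual heterozygous blocks resolve without breaking linkage
            extra = 0
            while (ind[0] != ind[1]).any() and extra < 40:
                ind = np.stack([eng.gamete(ind, rng), eng.gamete(ind, rng)])
                extra += 1
            het = ind[0] != ind[1]
            if het.any():  # pragma: no cover - vanishing probability
                pick = rng.integers(2, size=int(het.sum())).astype(np.int8)
                fixed = ind[0].copy()
                fixed[het] = ind[pick, np.flatnonzero(het)]
                codes[i] = 2 * fixed
            else:
                codes[i] = 2 * ind[0]

    line_ids = np.array([f"{line_prefix}{i + 1:04d}" for i in range(design.n_lines)],
                        dtype=object)
    return GenotypeMatrix(line_ids, base_map, codes)


def simulate_trait(
    genotypes: GenotypeMatrix, model: TraitModel, rng: np.random.Generator
) -> TraitRealization:
    """Simulate an additive trait with replicated plot phenotypes.

    Breeding values are the QTL-code cross product, centered, and (if
    ``target_Vg`` is set) rescaled so their sample variance across lines is
    exactly ``target_Vg``.  Plot residuals are i.i.d. normal with variance
    chosen so that the expected line-mean heritability at ``n_reps`` plots per
    line equals ``target_h2`` (or with variance ``target_Ve`` if given).
    """
    if not 0 < model.target_h2 <= 1:
        raise ValueError("target_h2 must lie in (0, 1]")
    if model.qtl_marker_ids is None:
        if model.n_qtl > genotypes.n_markers:
            raise ValueError("n_qtl exceeds the number of mapped loci")
        qtl_ids = tuple(draw_qtl_ids(genotypes.map, model.n_qtl, rng))
    else:
        qtl_ids = tuple(model.qtl_marker_ids)
    cols = genotypes.map.index_of(qtl_ids)
    X = genotypes.codes[:, cols].astype(float)
    if (X == MISSING).any():
        raise ValueError("QTL genotypes contain missing codes; impute first")

    if model.additive_effects is None:
        effects = rng.standard_normal(len(qtl_ids))
    else:
        effects = np.asarray(model.additive_effects, dtype=float).copy()
        if len(effects) != len(qtl_ids):
            raise ValueError("additive_effects length does not match QTL count")

    bv = X @ effects
    bv -= bv.mean()
    vg = float(np.var(bv, ddof=1)) if len(bv) > 1 else 0.0
    if model.target_Vg is not None and vg > 0:
        scale = float(np.sqrt(model.target_Vg / vg))
        bv *= scale
        effects *= scale
        vg = float(np.var(bv, ddof=1))

    if model.target_Ve is not None:
        ve = float(model.target_Ve)
    elif model.target_h2 == 1.0:
        ve = 0.0
    else:
        # line-mean h2 = Vg / (Vg + Ve/r)  =>  Ve = r * Vg * (1 - h2) / h2
        ve = model.n_reps * vg * (1.0 - model.target_h2) / model.target_h2

    n, r = genotypes.n_lines, model.n_reps
    resid = rng.normal(0.0, np.sqrt(ve), size=(n, r)) if ve > 0 else np.zeros((n, r))
    values = bv[:, None] + resid
    table = pd.DataFrame(
        {
            "line": np.repeat(genotypes.line_ids, r),
            "replicate": np.tile([f"r{k + 1}" for k in range(r)], n),
            "value": values.ravel(),
        }
    )
    return TraitRealization(
        true_breeding_values=pd.Series(bv, index=genotypes.line_ids),
        plot_phenotypes=PlotPhenotypes(table),
        qtl_marker_ids=qtl_ids,
        additive_effects=effects,
        realized_Vg=vg,
        realized_Ve=ve,
    )


# ---------------------------------------------------------------------------
# map construction helpers


def make_marker_map(n_markers: int, n_chromosomes: int = 10) -> GeneticMap:
    """Evenly spaced marker map on the base (F2-scale) maize-like genome.

    Markers are allocated to chromosomes proportionally to physical length and
    placed on a uniform bp grid; cM positions follow a constant cM/Mb rate.
    """
    if not 1 <= n_chromosomes <= len(_CHROM_MB):
        raise ValueError(f"n_chromosomes must be in 1..{len(_CHROM_MB)}")
    mb = np.array(_CHROM_MB[:n_chromosomes], dtype=float)
    frac = mb / mb.sum()
    counts = np.floor(frac * n_markers).astype(int)
    # largest-remainder top-up so counts sum to n_markers
    rem = frac * n_markers - counts
    for i in np.argsort(rem)[::-1][: n_markers - counts.sum()]:
        counts[i] += 1
    counts = np.maximum(counts, 1)

    ids, chroms, cms, bps = [], [], [], []
    for c, (n_c, chrom_mb) in enumerate(zip(counts, mb), start=1):
        chrom_bp = chrom_mb * 1e6
        pos = (np.arange(n_c) + 0.5) / n_c * chrom_bp
        bp = np.maximum(1, np.round(pos).astype(np.int64))
        cm = bp / 1e6 * _CM_PER_MB
        ids.extend(f"m{c:02d}_{k + 1:05d}" for k in range(n_c))
        chroms.extend([c] * n_c)
        cms.extend(cm)
        bps.extend(bp)
    return GeneticMap(np.array(ids, dtype=object), chroms, cms, bps)


def insert_qtl_loci(
    gmap: GeneticMap, n_qtl: int, rng: np.random.Generator
) -> tuple[GeneticMap, tuple]:
    """Interleave QTL loci, uniform on the genetic map, into a marker map.

    Returns the augmented map plus the QTL locus ids.  QTL are kept out of
    the marker panel itself, so panel markers tag them only via LD.
    """
    spans = []
    for chrom in gmap.chromosomes:
        g = gmap.genetic_pos[gmap.chrom_slice(chrom)]
        spans.append((int(chrom), float(g[0]), float(g[-1])))
    weights = np.array([hi - lo for _, lo, hi in spans], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("map has zero total genetic length")
    probs = weights / weights.sum()

    ids, chroms, cms, bps = (list(gmap.marker_ids), list(gmap.chromosome),
                             list(gmap.genetic_pos), list(gmap.physical_pos))
    qtl_ids = []
    for q in range(n_qtl):
        k = int(rng.choice(len(spans), p=probs))
        chrom, lo, hi = spans[k]
        cm = float(rng.uniform(lo, hi))
        sl = gmap.chrom_slice(chrom)
        g, p = gmap.genetic_pos[sl], gmap.physical_pos[sl]
        bp = int(np.round(np.interp(cm, g, p)))
        qtl_ids.append(f"q{q + 1:03d}")
        ids.append(qtl_ids[-1])
        chroms.append(chrom)
        cms.append(cm)
        bps.append(max(1, bp))
    order = np.lexsort((cms, chroms))
    arr = lambda x: np.asarray(x, dtype=object)[order]
    return (
        GeneticMap(arr(ids), np.asarray(chroms)[order], np.asarray(cms)[order],
                   np.asarray(bps)[order]),
        tuple(qtl_ids),
    )


def draw_qtl_ids(gmap: GeneticMap, n_qtl: int, rng: np.random.Generator) -> list:
    """Draw QTL loci uniformly on the genetic map, without replacement.

    Positions are drawn uniformly on the cumulative cM axis and snapped to the
    nearest mapped locus; used when QTL must coincide with existing loci.
    """
    if n_qtl > len(gmap):
        raise ValueError("n_qtl exceeds the number of mapped loci")
    chosen: set[int] = set()
    cum, offsets = _cumulative_cm(gmap)
    total = offsets[-1]
    while len(chosen) < n_qtl:
        u = rng.uniform(0.0, total, size=n_qtl - len(chosen))
        for pos in u:
            j = int(np.argmin(np.abs(cum - pos)))
            chosen.add(j)
    return [gmap.marker_ids[j] for j in sorted(chosen)]


def _cumulative_cm(gmap: GeneticMap) -> tuple[np.ndarray, np.ndarray]:
    """Genome-wide cumulative cM coordinate; chromosomes laid end to end."""
    cum = np.empty(len(gmap), dtype=float)
    offset = 0.0
    bounds = [0.0]
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        g = gmap.genetic_pos[sl]
        cum[sl] = g - g[0] + offset
        offset += float(g[-1] - g[0])
        bounds.append(offset)
    return cum, np.asarray(bounds)


def thin_markers_even(gmap: GeneticMap, n_markers: int) -> list:
    """Deterministic evenly spaced subset of marker ids (map order)."""
    if n_markers > len(gmap):
        raise ValueError("cannot thin to more markers than the map holds")
    idx = np.unique(np.round(np.linspace(0, len(gmap) - 1, n_markers)).astype(int))
    return [gmap.marker_ids[i] for i in idx]


# ---------------------------------------------------------------------------
# study-level orchestration


@dataclass
class StudyData:
    """Two simulated populations on a common dense marker panel plus a trait.

    ``genotypes`` maps population name → marker-panel genotypes (QTL columns
    excluded).  ``syn4_sparse_ids`` is the subset of dense markers treated as
    the Syn4-like population's actually genotyped (low-density) panel.
    """

    marker_map: GeneticMap
    qtl_ids: tuple
    genotypes: dict
    traits: dict
    syn4_sparse_ids: list
    target_Vg: float
    target_h2: float
    n_reps: int

    def line_means(self, pop: str) -> pd.Series:
        trait = self.traits[pop]
        return trait.plot_phenotypes.line_means(self.genotypes[pop].line_ids)


def simulate_study(
    rng: np.random.Generator,
    n_markers_dense: int = 6611,
    n_markers_sparse: int = 1339,
    syn10_design: PopulationDesign = SYN10_DESIGN,
    syn4_design: PopulationDesign = SYN4_DESIGN,
    n_qtl: int = 17,
    target_Vg: float = 1022.71,
    target_h2: float = 0.80,
    n_reps: int = 4,
) -> StudyData:
    """Simulate the full two-population study design.

    Both populations segregate at the same dense marker panel and share one
    QTL architecture (same founders, same biology).  Effects are rescaled so
    the *combined* 438-line population hits ``target_Vg``; plot residual
    variance is set from the combined-population heritability, mirroring the
    use of mixed-population variance components throughout the analysis.
    """
    marker_map = make_marker_map(n_markers_dense)
    aug_map, qtl_ids = insert_qtl_loci(marker_map, n_qtl, rng)

    pops = {
        "syn10": simulate_population(syn10_design, aug_map, rng, line_prefix="S10_"),
        "syn4": simulate_population(syn4_design, aug_map, rng, line_prefix="S4_"),
    }

    qtl_cols = aug_map.index_of(qtl_ids)
    effects = rng.standard_normal(len(qtl_ids))
    combined = np.vstack([pops[p].codes[:, qtl_cols].astype(float) for p in pops])
    bv_all = combined @ effects
    vg0 = float(np.var(bv_all, ddof=1))
    if vg0 > 0:
        effects *= np.sqrt(target_Vg / vg0)
    ve = n_reps * target_Vg * (1.0 - target_h2) / target_h2 if target_h2 < 1 else 0.0

    model = TraitModel(
        n_qtl=n_qtl, qtl_marker_ids=qtl_ids, additive_effects=effects,
        target_Vg=None, target_h2=target_h2, target_Ve=ve, n_reps=n_reps,
    )
    traits = {p: simulate_trait(pops[p], model, rng) for p in pops}

    marker_ids = list(marker_map.marker_ids)
    genotypes = {p: pops[p].subset_markers(marker_ids) for p in pops}
    sparse_ids = thin_markers_even(marker_map, n_markers_sparse)
    return StudyData(
        marker_map=marker_map, qtl_ids=qtl_ids, genotypes=genotypes, traits=traits,
        syn4_sparse_ids=sparse_ids, target_Vg=target_Vg, target_h2=target_h2,
        n_reps=n_reps,
    )
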