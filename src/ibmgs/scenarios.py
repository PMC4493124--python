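"""Training/validation scenario engine for genomic-selection experiments.

Runs the seven prediction scenarios over a grid of marker densities (N_M)
and training-population sizes (N_P), with repeated random sampling of marker
sets and training/validation splits:

=========  =================  ===================  ==================
Scenario   Training           Validation           Prediction type
=========  =================  ===================  ==================
1          syn10              syn10                within population
2          syn4               syn4                 within population
3          syn10              syn4                 between populations
4          syn4               syn10                between populations
5          mixed              mixed                across populations
6          mixed              syn10                across populations
7          mixed              syn4                 across populations
=========  =================  ===================  ==================

Within-population scenarios validate on the lines left out of training;
between-population scenarios validate on the entire other population; mixed
training draws equal numbers from both populations and validates on the
remaining lines of the named population(s).  Every repeat redraws its marker
set and split independently; repeat-level randomness derives from the master
seed through a counter-based scheme, so any single cell is reproducible in
isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneticMap, GenotypeMatrix
from .popsim import _cumulative_cm
from .rrblup import VarianceEstimates, accuracy, fit_rrblup, predict_gebv


@dataclass(frozen=True)
class ScenarioSpec:
    """One training/validation configuration."""

    id: int
    training_source: str  # 'syn10' | 'syn4' | 'mixed'
    validation_source: str
    prediction_type: str  # 'within' | 'between' | 'across'


#: The seven standard scenarios, keyed by id.
SCENARIOS: dict[int, ScenarioSpec] = {
    1: ScenarioSpec(1, "syn10", "syn10", "within"),
    2: ScenarioSpec(2, "syn4", "syn4", "within"),
    3: ScenarioSpec(3, "syn10", "syn4", "between"),
    4: ScenarioSpec(4, "syn4", "syn10", "between"),
    5: ScenarioSpec(5, "mixed", "mixed", "across"),
    6: ScenarioSpec(6, "mixed", "syn10", "across"),
    7: ScenarioSpec(7, "mixed", "syn4", "across"),
}


@dataclass(frozen=True)
class GridSpec:
    """Marker-count × training-size × repeat grid."""

    marker_counts: tuple = (100, 200, 400, 800, 1600, 3200, None)  # None = full panel
    training_sizes: tuple = (30, 60, 90, 120, 150, 180)
    n_repeats: int = 100
    seed: int = 0


@dataclass
class AccuracyTable:
    """Repeat-level and summarized prediction accuracies."""

    repeats: pd.DataFrame  # scenario, N_P, N_M, repeat, r_MP, r_MG
    summary: pd.DataFrame  # scenario, N_P, N_M, mean_r_MG, sd, n
    failures: pd.DataFrame  # scenario, N_P, N_M, repeat, reason

    def to_frame(self) -> pd.DataFrame:
        return self.repeats

    def cell_mean(self, scenario: int, n_p: int, n_m: int) -> float:
        s = self.summary
        row = s[(s.scenario == scenario) & (s.N_P == n_p) & (s.N_M == n_m)]
        if row.empty:
            raise KeyError(f"no summary cell for scenario {scenario}, "
                           f"N_P={n_p}, N_M={n_m}")
        return float(row["mean_r_MG"].iloc[0])


def sample_marker_set(
    gmap: GeneticMap, n_m: int, rng: np.random.Generator
) -> list:
    """Draw n_m markers evenly spread over the cumulative genetic map.

    The genome-wide cM axis is split into n_m equal strata; one marker is
    drawn uniformly within each non-empty stratum, and empty strata borrow a
    still-unused marker from the nearest stratum that has one.  Returns
    distinct marker ids in map order.
    """
    if n_m > len(gmap):
        raise ValueError("marker set larger than the panel")
    if n_m < gmap.n_chromosomes:
        warnings.warn("marker set smaller than the chromosome count: some "
                      "chromosomes will be uncovered", stacklevel=2)
    if n_m == len(gmap):
        return list(gmap.marker_ids)

    cum, bounds = _cumulative_cm(gmap)
    total = bounds[-1]
    edges = np.linspace(0.0, total, n_m + 1)
    stratum = np.clip(np.searchsorted(edges, cum, side="right") - 1, 0, n_m - 1)

    members: list[list[int]] = [[] for _ in range(n_m)]
    for idx, s in enumerate(stratum):
        members[s].append(idx)
    for mem in members:
        rng.shuffle(mem)  # pop() then draws uniformly without replacement

    chosen: list[int] = []
    empty: list[int] = []
    for s in range(n_m):
        if members[s]:
            chosen.append(members[s].pop())
        else:
            empty.append(s)
    for s in empty:
        for offset in range(1, n_m):
            for t in (s - offset, s + offset):
                if 0 <= t < n_m and members[t]:
                    chosen.append(members[t].pop())
                    break
            else:
                continue
            break
        else:  # pragma: no cover - unreachable while n_m <= len(map)
            raise RuntimeError("could not fill all marker strata")
    chosen.sort()
    return [gmap.marker_ids[i] for i in chosen]


def build_split(
    scenario: ScenarioSpec,
    pop_lines: Mapping[str, Sequence[str]],
    n_p: int,
    rng: np.random.Generator,
) -> tuple[list, list]:
    """Random training/validation line split for one scenario.

    ``pop_lines`` maps population name ('syn10'/'syn4') to its line ids.
    Training and validation sets are always disjoint.
    """
    pops = {k: list(v) for k, v in pop_lines.items()}
    if scenario.training_source == "mixed":
        if n_p % 2:
            raise ValueError("mixed-training scenarios need an even N_P")
        half = n_p // 2
        train: list = []
        leftover: dict[str, list] = {}
        for name, ids in pops.items():
            if half >= len(ids):
                raise ValueError(f"N_P/2 = {half} exhausts population {name!r}")
            pick = list(rng.choice(len(ids), size=half, replace=False))
            train += [ids[i] for i in pick]
            leftover[name] = [ids[i] for i in range(len(ids)) if i not in set(pick)]
        if scenario.validation_source == "mixed":
            val = leftover["syn10"] + leftover["syn4"]
        else:
            val = leftover[scenario.validation_source]
    else:
        source = pops[scenario.training_source]
        if scenario.prediction_type == "within" and n_p >= len(source):
            raise ValueError(
                f"N_P = {n_p} leaves no validation lines in "
                f"{scenario.training_source!r} ({len(source)} lines)"
            )
        if n_p > len(source):
            raise ValueError(f"N_P = {n_p} exceeds population size {len(source)}")
        pick = set(rng.choice(len(source), size=n_p, replace=False).tolist())
        train = [source[i] for i in sorted(pick)]
        if scenario.prediction_type == "within":
            val = [source[i] for i in range(len(source)) if i not in pick]
        else:  # between populations: the entire other population
            val = pops[scenario.validation_source]
    return train, val


def run_grid(
    scenario_ids: Sequence[int],
    grid: GridSpec,
    genotypes: Mapping[str, GenotypeMatrix],
    line_means: Mapping[str, pd.Series],
    var: VarianceEstimates,
) -> AccuracyTable:
    """Run the full scenario × N_P × N_M × repeat experiment.

    All populations must share one marker panel (same map, same column
    order).  For every repeat a fresh marker set is sampled, a fresh split is
    drawn, RR-BLUP is fitted on the training line means with
    λ = (Ve/n_reps)/(Vg/N_M), and validation accuracy is recorded.  Repeats
    with fewer than 3 validation lines are skipped and logged.
    """
    names = list(genotypes)
    panel = genotypes[names[0]].map
    for name in names[1:]:
        if list(genotypes[name].map.marker_ids) != list(panel.marker_ids):
            raise ValueError("all populations must share one marker panel")

    codes_all = np.vstack([genotypes[n].codes for n in names])
    ids_all = np.concatenate([genotypes[n].line_ids for n in names])
    means_all = pd.concat([pd.Series(line_means[n]).reindex(genotypes[n].line_ids)
                           for n in names])
    if means_all.isna().any():
        raise ValueError("line means missing for some genotyped lines")
    row_of = {lid: i for i, lid in enumerate(ids_all)}
    pop_lines = {n: list(genotypes[n].line_ids) for n in names}
    marker_col = {m: j for j, m in enumerate(panel.marker_ids)}

    rows, fails = [], []
    for sid in scenario_ids:
        scenario = SCENARIOS[int(sid)]
        for n_p in grid.training_sizes:
            for n_m_spec in grid.marker_counts:
                n_m = len(panel) if n_m_spec is None else int(n_m_spec)
                for rep in range(grid.n_repeats):
                    rng = np.random.default_rng(
                        [int(grid.seed), int(scenario.id), int(n_p), n_m, rep]
                    )
                    marker_ids = sample_marker_set(panel, n_m, rng)
                    cols = np.array([marker_col[m] for m in marker_ids])
                    train, val = build_split(scenario, pop_lines, int(n_p), rng)
                    if len(val) < 3:
                        fails.append((scenario.id, n_p, n_m, rep,
                                      f"only {len(val)} validation lines"))
                        continue
                    tr = np.array([row_of[l] for l in train])
                    va = np.array([row_of[l] for l in val])
                    fit = fit_rrblup(
                        codes_all[np.ix_(tr, cols)].astype(float),
                        means_all.iloc[tr].to_numpy(),
                        var=var, marker_ids=marker_ids, training_ids=train,
                    )
                    pred = predict_gebv(fit, codes_all[np.ix_(va, cols)].astype(float))
                    acc = accuracy(pred, means_all.iloc[va].to_numpy(), var.h2)
                    rows.append((scenario.id, n_p, n_m, rep, acc.r_MP, acc.r_MG))

    repeats = pd.DataFrame(rows,
                           columns=["scenario", "N_P", "N_M", "repeat", "r_MP", "r_MG"])
    failures = pd.DataFrame(fails,
                            columns=["scenario", "N_P", "N_M", "repeat", "reason"])
    if repeats.empty:
        summary = pd.DataFrame(
            columns=["scenario", "N_P", "N_M", "mean_r_MG", "sd", "n"])
    else:
        summary = (
            repeats.groupby(["scenario", "N_P", "N_M"])["r_MG"]
            .agg(mean_r_MG="mean", sd="std", n="count")
            .reset_index()
        )
    return AccuracyTable(repeats=repeats, summary=summary, failures=failures)


@dataclass
class LsdResult:
    """Bonferroni-adjusted least significant difference for one scenario."""

    scenario: int
    lsd: float
    mse: float
    df_error: int
    alpha_adjusted: float
    flags: pd.DataFrame  # cell_a, cell_b, mean_diff, significant


def lsd_bonferroni(table: AccuracyTable, alpha: float = 0.05) -> dict[int, LsdResult]:
    """Bonferroni-adjusted LSD over (N_P, N_M) cells, per scenario.

    A one-way ANOVA of repeat-level r_MG with the (N_P, N_M) combination as
    the factor supplies the error mean square; the comparison threshold is
    LSD = t(1 − α′/2, df_error) · sqrt(2·MSE/n) with α′ = α / C(k, 2) for k
    cells and n the (harmonic-mean) repeat count.  All cell pairs whose mean
    difference exceeds the LSD are flagged.
    """
    results: dict[int, LsdResult] = {}
    for sid, df in table.repeats.groupby("scenario"):
        cells = df.groupby(["N_P", "N_M"])["r_MG"]
        k = cells.ngroups
        if k < 2:
            raise ValueError(f"scenario {sid}: need >= 2 (N_P, N_M) cells for an LSD")
        counts = cells.size()
        if (counts < 2).any():
            raise ValueError(f"scenario {sid}: every cell needs >= 2 repeats")
        if counts.nunique() > 1:
            warnings.warn(f"scenario {sid}: unequal repeat counts; harmonic mean used",
                          stacklevel=2)
        n_h = k / float((1.0 / counts).sum())
        means = cells.mean()
        ss_within = float(((df["r_MG"] - cells.transform("mean")) ** 2).sum())
        df_error = int(counts.sum() - k)
        mse = ss_within / df_error
        alpha_adj = alpha / (k * (k - 1) / 2)
        t_crit = float(stats.t.ppf(1.0 - alpha_adj / 2.0, df_error))
        lsd = t_crit * np.sqrt(2.0 * mse / n_h)

        flag_rows = []
        for a, b in combinations(means.index, 2):
            diff = float(means[a] - means[b])
            flag_rows.append((a, b, diff, bool(abs(diff) > lsd)))
        flags = pd.DataFrame(flag_rows,
                             columns=["cell_a", "cell_b", "mean_diff", "significant"])
        results[int(sid)] = LsdResult(
            scenario=int(sid), lsd=float(lsd), mse=mse, df_error=df_error,
            alpha_adjusted=alpha_adj, flags=flags,
        )
    return results


def summary_matrix(table: AccuracyTable, scenario: int) -> pd.DataFrame:
    """Mean r_MG as an N_P (rows) × N_M (columns) matrix for one scenario."""
    s = table.summary[table.summary.scenario == scenario]
    return s.pivot(index="N_P", columns="N_M", values="mean_r_MG")
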