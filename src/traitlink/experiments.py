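"""Replicate runs, parameter sweeps, and the inferential statistics layer.

The canonical experiment crosses selection strength s with preference
strength pf (the study grid is s in {0.5, 0.6, 0.7, 0.8} x pf in
{0.3, 0.6, 1.2, 2.4}, 20 replicates per combination), averages the
per-generation distance series across the replicates of a combination,
and takes the minimum of that mean series over the whole run as the
combination's measure of realized physical linkage.  The combination-level
minima are then analysed with ordinary least squares (partial F-tests for
s and pf, plus a separate interaction model), and a replicate-level
snapshot at one generation feeds a Pearson correlation between linkage
and assortative mating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ModelParams
from .lifecycle import SimulationResult, run_simulation

#: study grid defaults
DEFAULT_S_VALUES = (0.5, 0.6, 0.7, 0.8)
DEFAULT_PF_VALUES = (0.3, 0.6, 1.2, 2.4)

#: sweep-summary distance columns (phenotype class, locus type)
_DIST_COLS = [
    "dist_AA_pref_A",
    "dist_AA_pref_Ap",
    "dist_AA_neutral",
    "dist_ApAp_pref_A",
    "dist_ApAp_pref_Ap",
    "dist_ApAp_neutral",
]


@dataclass
class ReplicateRuns:
    """A set of independent replicate simulations of one parameter point.

    ``runs`` holds each replicate's metrics table; ``mean`` and ``sem``
    aggregate the surviving replicates per generation.
    """

    params: ModelParams
    seeds: list[int]
    runs: list[pd.DataFrame]
    extinct: list[int | None]
    mean: pd.DataFrame
    sem: pd.DataFrame


def run_replicates(
    params: ModelParams,
    n_reps: int,
    base_seed: int | None = None,
    snapshot_generations: tuple[int, ...] = (),
) -> ReplicateRuns:
    """Run ``n_reps`` independent replicates; replicate r uses seed
    ``base_seed + r``.

    Replicates that go extinct are recorded but excluded from the
    mean/SEM aggregation (with a warning).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if base_seed is None:
        base_seed = params.seed
    seeds, runs, extinct = [], [], []
    results: list[SimulationResult] = []
    for r in range(n_reps):
        seed = int(base_seed) + r
        res = run_simulation(
            params.with_(seed=seed), snapshot_generations=snapshot_generations
        )
        seeds.append(seed)
        runs.append(res.metrics)
        extinct.append(res.extinct_at)
        results.append(res)
    surviving = [m for m, e in zip(runs, extinct) if e is None]
    if len(surviving) < len(runs):
        warnings.warn(
            f"{len(runs) - len(surviving)} of {len(runs)} replicates went extinct; "
            "excluded from replicate means",
            stacklevel=2,
        )
    if not surviving:
        raise RuntimeError("all replicates went extinct")
    stacked = pd.concat(surviving, keys=range(len(surviving)), names=["rep"])
    grouped = stacked.groupby(level="generation")
    out = ReplicateRuns(
        params=params,
        seeds=seeds,
        runs=runs,
        extinct=extinct,
        mean=grouped.mean(),
        sem=grouped.sem(),
    )
    out._results = results  # full results (snapshots) for callers that need them
    return out


def min_avg_distance(series) -> tuple[float, int]:
    """Minimum of a per-generation distance series and the generation of
    the minimum (earliest on ties); NaN entries are skipped."""
    s = pd.Series(series).dropna()
    if s.empty:
        raise ValueError("series contains no non-missing values")
    gen = s.idxmin()
    return float(s.loc[gen]), int(gen)


def generation_to_assortment(series, threshold: float = 0.9) -> int | None:
    """First generation at which the matching-pair proportion reaches the
    threshold (no hysteresis); ``None`` if it never does."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    s = pd.Series(series)
    hit = s[s >= threshold]
    return None if hit.empty else int(hit.index[0])


def distance_assortment_correlation(
    distances: Sequence[float], assortment: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson correlation across simulations between a distance statistic
    and the matching-pair proportion.

    Returns ``(r, df, p)`` with ``df = n - 2`` and a two-sided p-value from
    the t transform.  Pairs with a missing value are dropped; requires at
    least 3 complete pairs and non-degenerate variance.
    """
    x = np.asarray(distances, dtype=float)
    y = np.asarray(assortment, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance")
    r, p = stats.pearsonr(x, y)
    return float(r), len(x) - 2, float(p)


def correlation_table(rows: pd.DataFrame, match_col: str = "matching") -> pd.DataFrame:
    """Correlations for every distance column of a per-simulation table.

    ``rows`` has one row per simulation with the six ``dist_*`` columns and
    a matching-proportion column.  Returns one row per (phenotype class,
    locus type) with r, df, p.
    """
    out = []
    for col in _DIST_COLS:
        if col not in rows.columns:
            continue
        _, cls, lt = col.split("_", 2)
        try:
            r, df_, p = distance_assortment_correlation(rows[col], rows[match_col])
        except ValueError:
            r, df_, p = float("nan"), len(rows) - 2, float("nan")
        out.append(
            {"phenotype_class": cls, "locus_type": lt, "r": r, "df": df_, "p": p}
        )
    return pd.DataFrame(out)


# --- OLS over the sweep grid -------------------------------------------------

def _ols(X: np.ndarray, y: np.ndarray):
    """Least squares via statsmodels; returns the fitted results object."""
    import statsmodels.api as sm

    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def sweep_regression(
    table: pd.DataFrame, response: str, interaction: bool = False
) -> pd.DataFrame:
    """OLS of a combination-level statistic on s and pf with partial F-tests.

    ``table`` has one row per (s, pf) combination — the study design gives
    16 rows, hence residual df 13 for the main-effects model and 12 with
    the s x pf interaction.  Each predictor's F is the partial
    (type-III) F comparing the full model against the model without that
    term; for a single-df term this equals the squared t statistic.

    Returns one row per predictor: coef, F, df_num, df_den, p.
    """
    import statsmodels.api as sm

    need = {"s", "pf", response}
    if not need.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(need)}")
    y = table[response].to_numpy(dtype=float)
    s = table["s"].to_numpy(dtype=float)
    pf = table["pf"].to_numpy(dtype=float)
    cols = {"s": s, "pf": pf}
    if interaction:
        cols["s:pf"] = s * pf
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(sm.add_constant(X, has_constant="add")) < X.shape[1] + 1:
        raise ValueError("rank-deficient design (too few distinct s, pf values)")
    fit = _ols(X, y)
    rows = []
    for i, name in enumerate(cols, start=1):
        t = fit.tvalues[i]
        rows.append(
            {
                "predictor": name,
                "coef": float(fit.params[i]),
                "F": float(t**2),
                "df_num": 1,
                "df_den": int(fit.df_resid),
                "p": float(fit.pvalues[i]),
            }
        )
    return pd.DataFrame(rows)


# --- the full sweep -----------------------------------------------------------

@dataclass
class SweepResult:
    """Everything the sweep produces.

    ``runs``: one row per (s, pf, replicate) with per-replicate summary
    statistics and the generation-700/1000 snapshot metrics.
    ``combos``: one row per (s, pf) with the minimum of the replicate-mean
    distance series for each distance column and the generation at which
    the mean matching proportion first reaches 0.9.
    ``mean_series``: replicate-mean metric tables keyed by (s, pf).
    """

    runs: pd.DataFrame
    combos: pd.DataFrame
    mean_series: dict = field(default_factory=dict)


def run_sweep(
    base_params: ModelParams,
    s_values: Sequence[float] = DEFAULT_S_VALUES,
    pf_values: Sequence[float] = DEFAULT_PF_VALUES,
    n_reps: int = 20,
    base_seed: int = 0,
    snapshot_metric_generations: tuple[int, ...] = (700, 1000),
    assortment_threshold: float = 0.9,
) -> SweepResult:
    """Run the full s x pf sweep.

    Replicates of successive combinations use disjoint seed blocks
    (``base_seed + combo_index * n_reps + r``) so every row is
    reproducible from (s, pf, seed) alone.
    """
    run_rows, combo_rows, mean_series = [], [], {}
    combo_index = 0
    for s in s_values:
        for pf in pf_values:
            params = base_params.with_(s=s, pf=pf)
            reps = run_replicates(
                params, n_reps, base_seed=base_seed + combo_index * n_reps
            )
            combo_index += 1
            for r, (seed, m, ext) in enumerate(zip(reps.seeds, reps.runs, reps.extinct)):
                row = {"s": s, "pf": pf, "rep": r, "seed": seed, "extinct_at": ext}
                for col in _DIST_COLS:
                    try:
                        v, g = min_avg_distance(m[col])
                    except ValueError:
                        v, g = float("nan"), -1
                    row[f"min_{col}"] = v
                    row[f"argmin_{col}"] = g
                row["gen_to_90"] = generation_to_assortment(
                    m["matching"], assortment_threshold
                )
                for g in snapshot_metric_generations:
                    if g in m.index:
                        for col in _DIST_COLS + ["matching", "pref_per_chrom"]:
                            row[f"{col}_g{g}"] = m.loc[g, col]
                run_rows.append(row)
            combo = {"s": s, "pf": pf, "n_reps": n_reps}
            for col in _DIST_COLS:
                try:
                    v, g = min_avg_distance(reps.mean[col])
                except ValueError:
                    v, g = float("nan"), -1
                combo[f"min_{col}"] = v
                combo[f"argmin_{col}"] = g
            combo["gen_to_90"] = generation_to_assortment(
                reps.mean["matching"], assortment_threshold
            )
            combo_rows.append(combo)
            mean_series[(s, pf)] = reps.mean
    return SweepResult(
        runs=pd.DataFrame(run_rows),
        combos=pd.DataFrame(combo_rows),
        mean_series=mean_series,
    )
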