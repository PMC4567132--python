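"""Clinical cross-tabulations, exact tests and survival analysis.

Categorical covariates are compared across XCI groups with a generalized
(r x c) Fisher exact test: conditional on both margins, the p-value is the
total multivariate-hypergeometric probability of all tables no more probable
than the observed one. Feasible tables are enumerated exactly (vectorized
over the two largest rows); above a size bound the test falls back to seeded
Monte-Carlo sampling of fixed-margin tables (Patefield's algorithm via
:func:`scipy.stats.random_table`), and the result records which method ran.

Continuous covariates use one-way ANOVA. Survival uses Kaplan-Meier curves
with the k-group log-rank test, and Cox proportional hazards (Efron tie
handling) adjusting for clinical stage, with stage I-II and preserved Xi as
reference levels. Missing covariates are handled by complete-case analysis
per test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .types import ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# contingency tables


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative counts with derived column percentages."""

    counts: pd.DataFrame
    degenerate: bool = False

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("contingency counts must be non-negative")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValidationError("contingency counts must be integers")

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def column_percentages(self) -> pd.DataFrame:
        """Each column as percentages of its column total (one decimal,
        matching how cross-tabulations are conventionally printed)."""
        col_totals = self.counts.sum(axis=0)
        return (100.0 * self.counts / col_totals).round(1)

    @property
    def row_percentages(self) -> pd.DataFrame:
        row_totals = self.counts.sum(axis=1)
        return (100.0 * self.counts.T / row_totals).T.round(1)


def crosstab(
    field: pd.Series,
    calls: pd.DataFrame,
    drop_missing: bool = True,
) -> ContingencyTable:
    """Cross-tabulate a categorical clinical field against XCI groups.

    ``field`` is indexed by sample id; ``calls`` carries ``sample_id`` and
    ``xci_group``. Missing field values are dropped (complete-case), and the
    effective N is the table total. Continuous fields are rejected.
    """
    if pd.api.types.is_float_dtype(field.dtype):
        raise ValidationError(
            "field is continuous; use anova_by_group for continuous covariates"
        )
    groups = calls.set_index("sample_id")["xci_group"]
    shared = field.index.intersection(groups.index)
    df = pd.DataFrame({"field": field.loc[shared], "xci_group": groups.loc[shared]})
    if drop_missing:
        df = df.dropna(subset=["field"])
    counts = pd.crosstab(df["field"], df["xci_group"])
    # keep canonical XCI group order where present
    order = [g for g in ("preserved_Xi", "Xa_plus", "two_Xa") if g in counts.columns]
    counts = counts[order + [c for c in counts.columns if c not in order]]
    degenerate = counts.shape[0] < 2 or counts.shape[1] < 2
    if degenerate:
        logger.warning("crosstab is degenerate (%dx%d)", *counts.shape)
    return ContingencyTable(counts, degenerate=degenerate)


# ---------------------------------------------------------------------------
# generalized Fisher exact test


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str  # "exact" | "monte_carlo" | "degenerate"
    n_tables: int | None = None  # enumerated tables or Monte-Carlo draws

    def __float__(self) -> float:
        return self.p_value


def _ways(n: int, bounds: Sequence[int]) -> int:
    """Number of compositions of ``n`` into len(bounds) bounded parts."""
    dp = np.zeros(n + 1, dtype=float)
    dp[0] = 1.0
    for b in bounds:
        new = np.cumsum(dp)
        if b + 1 <= n:
            new[b + 1:] -= np.cumsum(dp)[: n - b]
        dp = new
    return int(dp[n])


def _compositions(n: int, bounds: tuple[int, ...]):
    """Yield all compositions of ``n`` into bounded non-negative parts."""
    if len(bounds) == 1:
        if 0 <= n <= bounds[0]:
            yield (n,)
        return
    lo = max(0, n - sum(bounds[1:]))
    hi = min(bounds[0], n)
    for v in range(lo, hi + 1):
        for rest in _compositions(n - v, bounds[1:]):
            yield (v,) + rest


def _tail_mass(
    n: int,
    col_rem: np.ndarray,
    acc: float,
    const: float,
    thresh: float,
    lgf: np.ndarray,
) -> tuple[float, int]:
    """Probability mass at or below the threshold, summed over all completions
    where the penultimate row (margin ``n``) runs over a vectorized grid and
    the final row is determined by the column remainders. Also returns the
    number of valid completions."""
    c = len(col_rem)
    shapes = [int(min(b, n)) + 1 for b in col_rem[:-1]]
    grids = np.indices(shapes).reshape(c - 1, -1)
    s = grids.sum(axis=0)
    last_cell = n - s
    valid = (last_cell >= 0) & (last_cell <= col_rem[-1])
    if not valid.any():
        return 0.0, 0
    rows = grids[:, valid]
    last_cell = last_cell[valid]
    final_rows = col_rem[:-1, None] - rows
    final_last = col_rem[-1] - last_cell
    logp = (
        const
        + acc
        - lgf[rows].sum(axis=0)
        - lgf[last_cell]
        - lgf[final_rows].sum(axis=0)
        - lgf[final_last]
    )
    below = logp <= thresh
    return float(np.exp(logp[below]).sum()), int(valid.sum())


def _exact_pvalue(table: np.ndarray, thresh_logp: float) -> tuple[float, int]:
    """Exact p by enumeration. Rows are reordered (the conditional law is
    row-exchangeable) so the python loop walks the smallest rows, the second
    largest row is vectorized, and the largest is margin-determined."""
    row_m = np.sort(table.sum(axis=1))
    col_m = table.sum(axis=0).astype(int)
    n_total = int(table.sum())
    lgf = gammaln(np.arange(n_total + 2) + 1.0)
    const = float(lgf[row_m].sum() + lgf[col_m].sum() - lgf[n_total])

    loop_rows = [int(v) for v in row_m[:-2]]
    penult = int(row_m[-2])

    total = 0.0
    count = 0

    def rec(i: int, col_rem: np.ndarray, acc: float) -> None:
        nonlocal total, count
        if i == len(loop_rows):
            mass, n_valid = _tail_mass(penult, col_rem, acc, const, thresh_logp, lgf)
            total += mass
            count += n_valid
            return
        for comp in _compositions(loop_rows[i], tuple(int(b) for b in col_rem)):
            arr = np.asarray(comp)
            rec(i + 1, col_rem - arr, acc - float(lgf[arr].sum()))

    rec(0, col_m.copy(), 0.0)
    return min(total, 1.0), count


def _monte_carlo_pvalue(
    table: np.ndarray, thresh_logp: float, draws: int, seed: int
) -> float:
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    n_total = int(table.sum())
    lgf = gammaln(np.arange(n_total + 2) + 1.0)
    const = float(lgf[row_m].sum() + lgf[col_m].sum() - lgf[n_total])
    rng = np.random.default_rng(seed)
    dist = stats.random_table(row_m, col_m)
    hits = 0
    chunk = 100_000
    remaining = draws
    while remaining > 0:
        m = min(chunk, remaining)
        samples = dist.rvs(m, random_state=rng)
        if samples.ndim == 2:
            samples = samples[None, :, :]
        logp = const - lgf[samples.astype(int)].sum(axis=(1, 2))
        hits += int((logp <= thresh_logp).sum())
        remaining -= m
    return (hits + 1) / (draws + 1)


def fisher_exact_rxc(
    table: ContingencyTable | np.ndarray | Sequence[Sequence[int]],
    *,
    max_tables: int = 10_000_000,
    mc_draws: int = 1_000_000,
    seed: int = 0,
) -> FisherResult:
    """Generalized Fisher exact test for an r x c contingency table.

    The p-value is the sum, over all tables sharing the observed margins, of
    the conditional (multivariate hypergeometric) probabilities that do not
    exceed the observed table's probability (with the usual 1e-7 relative
    tolerance). Exact enumeration is used when the table space is small
    enough, otherwise seeded Monte Carlo over fixed-margin tables.
    """
    if isinstance(table, ContingencyTable):
        arr = table.counts.to_numpy()
    else:
        arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValidationError("fisher_exact_rxc needs an at-least-2x2 table")
    if (arr < 0).any():
        raise ValidationError("negative counts in contingency table")
    arr = arr.astype(int)
    row_m = arr.sum(axis=1)
    col_m = arr.sum(axis=0)
    if arr.sum() == 0 or (row_m == 0).any() or (col_m == 0).any():
        return FisherResult(p_value=1.0, method="degenerate")

    n_total = int(arr.sum())
    lgf = gammaln(np.arange(n_total + 2) + 1.0)
    const = float(lgf[row_m].sum() + lgf[col_m].sum() - lgf[n_total])
    logp_obs = const - float(lgf[arr].sum())
    thresh = logp_obs + 1e-7  # relative tolerance on the probability scale

    # orient with fewer rows than columns: fewer enumeration levels
    work = arr if arr.shape[0] <= arr.shape[1] else arr.T
    wrow = work.sum(axis=1)
    wcol = work.sum(axis=0).astype(int)

    rows_sorted = np.sort(wrow)
    free = rows_sorted[:-1]  # all but the margin-determined final row
    bound = 1
    for n_i in free:
        bound *= _ways(int(n_i), wcol.tolist())
        if bound > max_tables:
            break
    grid_cells = 1
    if len(free):
        grid_cells = int(
            np.prod([min(int(free[-1]), int(b)) + 1 for b in wcol[:-1]])
        )

    if bound <= max_tables and grid_cells <= 4_000_000:
        p, n_tab = _exact_pvalue(work, thresh)
        if p >= 1.0 - 1e-9:  # all tables included: roundoff-free 1
            p = 1.0
        return FisherResult(p_value=max(p, np.finfo(float).tiny), method="exact", n_tables=n_tab)
    p = _monte_carlo_pvalue(work, thresh, mc_draws, seed)
    logger.info("fisher_exact_rxc: Monte-Carlo fallback with %d draws", mc_draws)
    return FisherResult(p_value=p, method="monte_carlo", n_tables=mc_draws)


# ---------------------------------------------------------------------------
# continuous covariates


def anova_by_group(
    values: pd.Series,
    calls: pd.DataFrame,
) -> tuple[float, float]:
    """One-way ANOVA of a continuous covariate across XCI groups.

    Complete-case per test; a constant covariate is degenerate and reported
    as (0, 1).
    """
    groups = calls.set_index("sample_id")["xci_group"]
    shared = values.index.intersection(groups.index)
    df = pd.DataFrame({"v": pd.to_numeric(values.loc[shared]), "g": groups.loc[shared]}).dropna()
    arrays = [grp["v"].to_numpy() for _, grp in df.groupby("g") if len(grp) >= 2]
    if len(arrays) < 2:
        raise ValidationError("anova_by_group needs at least two groups with two values")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvivalResult:
    """Kaplan-Meier curves plus log-rank and/or Cox components."""

    km_curves: dict[str, pd.DataFrame] | None = None
    logrank_statistic: float = float("nan")
    logrank_p: float = float("nan")
    cox: pd.DataFrame | None = None  # index term; columns hr, ci_low, ci_high, p
    flags: tuple[str, ...] = ()


def km_logrank(
    times: pd.Series | np.ndarray,
    events: pd.Series | np.ndarray,
    groups: pd.Series | np.ndarray,
) -> SurvivalResult:
    """Kaplan-Meier estimates per group and the k-group log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    df = pd.DataFrame(
        {"time": np.asarray(times, float), "event": np.asarray(events), "group": np.asarray(groups)}
    ).dropna()
    df["event"] = df["event"].astype(bool)
    if (df["time"] < 0).any():
        raise ValidationError("negative survival times")
    if not df["event"].any():
        raise ValidationError("all observations censored; nothing to analyze")
    if df["group"].nunique() < 2:
        raise ValidationError("log-rank needs at least two groups")

    curves: dict[str, pd.DataFrame] = {}
    for g, grp in df.groupby("group"):
        if not grp["event"].any():
            logger.warning("group %r has zero events; included in log-rank anyway", g)
        kmf = KaplanMeierFitter()
        kmf.fit(grp["time"], grp["event"])
        table = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": kmf.event_table["at_risk"].reindex(
                    kmf.survival_function_.index, method="ffill"
                ).to_numpy(),
            }
        )
        curves[str(g)] = table
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return SurvivalResult(
        km_curves=curves,
        logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value),
    )


def cox_stage_adjusted(
    times: pd.Series | np.ndarray,
    events: pd.Series | np.ndarray,
    xci_group: pd.Series | np.ndarray,
    stage: pd.Series | np.ndarray,
) -> SurvivalResult:
    """Cox proportional hazards with categorical stage and XCI group.

    Reference levels are stage I-II and preserved Xi; ties use Efron's
    method. Returns hazard ratios with 95% CIs and Wald p per term.
    """
    from lifelines import CoxPHFitter

    df = pd.DataFrame(
        {
            "time": np.asarray(times, float),
            "event": np.asarray(events),
            "xci": np.asarray(xci_group),
            "stage": np.asarray(stage),
        }
    ).dropna()
    df["event"] = df["event"].astype(bool)
    if len(df) == 0 or not df["event"].any():
        raise ValidationError("no events available for Cox regression")
    design = pd.DataFrame(
        {
            "time": df["time"],
            "event": df["event"].astype(int),
            "stage_III": (df["stage"] == "III").astype(float),
            "stage_IV": (df["stage"] == "IV").astype(float),
            "xci_Xa_plus": (df["xci"] == "Xa_plus").astype(float),
            "xci_two_Xa": (df["xci"] == "two_Xa").astype(float),
        }
    )
    # drop all-zero covariates (level absent in this cohort)
    keep = [c for c in design.columns[2:] if design[c].var() > 0]
    flags: tuple[str, ...] = ()
    cph = CoxPHFitter()
    try:
        cph.fit(design[["time", "event"] + keep], duration_col="time", event_col="event")
    except Exception:
        # complete separation (e.g. a covariate level with no events) makes
        # the unpenalized partial likelihood unbounded; refit with a small
        # ridge and flag the result
        cph = CoxPHFitter(penalizer=0.1)
        try:
            cph.fit(design[["time", "event"] + keep], duration_col="time", event_col="event")
        except Exception as exc:  # convergence failure surfaces with diagnostics
            raise ValidationError(f"Cox regression failed to converge: {exc}") from exc
        flags = ("separation_penalized",)
        logger.warning("Cox fit required ridge penalization (possible separation)")
    summ = cph.summary
    cox = pd.DataFrame(
        {
            "hr": np.exp(summ["coef"]),
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    return SurvivalResult(cox=cox, flags=flags)
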