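"""Per-user fitting over a cohort and population-level comparisons.

For every user, both hidden-state models are estimated from the same
stream: the self-driven machine from the output sequence alone and the
social-induced transducer from the aligned (parent, output) pair, each
with its own train/test-selected maximum history length.  The report
aggregates state-count and history-length histograms, correlations among
the information measures (after dropping zero-complexity users and
outliers), and the population tests contrasting the two model families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .cssr import estimate_machine, select_lmax
from .measures import InfoSummary, summarize
from .models import CSSRConfig, IOSequencePair
from .transducer import estimate_transducer, select_transducer_lmax

__all__ = [
    "UserResult",
    "CohortReport",
    "CohortRunConfig",
    "fit_user",
    "filter_for_correlation",
    "pearson_r",
    "welch_t",
    "anova_oneway",
    "run_cohort",
]


@dataclass(frozen=True)
class CohortRunConfig:
    """Cohort-run settings: CSSR level, history-length grid, scoring
    floor, and the outlier rule (standard deviations from the cohort
    mean) used before correlations."""

    alpha: float = 0.001
    lmax_grid: tuple = (1, 2, 3)
    min_count: int = 5
    smoothing_floor: float = 1e-6
    outlier_sd: float = 3.0

    def cssr(self, lmax: int) -> CSSRConfig:
        return CSSRConfig(
            alpha=self.alpha,
            lmax=lmax,
            min_count=self.min_count,
            smoothing_floor=self.smoothing_floor,
        )


@dataclass(frozen=True)
class UserResult:
    user_id: str
    machine: InfoSummary | None
    transducer: InfoSummary | None
    troll_count: int
    n_comments: int
    error: str | None = None

    def __post_init__(self) -> None:
        if self.troll_count < 0 or self.troll_count > self.n_comments:
            raise ValueError("troll_count must lie in [0, n_comments]")


@dataclass
class CohortReport:
    n_users: int
    n_failures: int
    machine_state_hist: dict
    transducer_state_hist: dict
    machine_lmax_hist: dict
    transducer_lmax_hist: dict
    correlations: dict
    tests: dict
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def fit_user(pair: IOSequencePair, cfg: CohortRunConfig, user_id: str = "") -> UserResult:
    """Fit and summarize both models for one user.  Failures are recorded
    on the result rather than raised, so a cohort run can continue."""
    outputs = pair.outputs
    troll_count = int(outputs.symbols.sum())
    try:
        m_lmax, _ = select_lmax(outputs, cfg.lmax_grid, cfg.cssr(cfg.lmax_grid[0]))
        machine = estimate_machine(outputs, cfg.cssr(m_lmax))
        machine_summary = summarize(machine, outputs, m_lmax)

        t_lmax, _ = select_transducer_lmax(pair, cfg.lmax_grid, cfg.cssr(cfg.lmax_grid[0]))
        transducer = estimate_transducer(pair, cfg.cssr(t_lmax))
        transducer_summary = summarize(transducer, pair, t_lmax)
    except (ValueError, RuntimeError) as exc:
        return UserResult(
            user_id=user_id,
            machine=None,
            transducer=None,
            troll_count=troll_count,
            n_comments=len(outputs),
            error=str(exc),
        )
    return UserResult(
        user_id=user_id,
        machine=machine_summary,
        transducer=transducer_summary,
        troll_count=troll_count,
        n_comments=len(outputs),
    )


def filter_for_correlation(summaries: list, outlier_sd: float = 3.0) -> list:
    """Retain the summaries entering the measure correlations: drop
    C = 0 users, then drop users with any measure beyond ``outlier_sd``
    standard deviations of the cohort mean."""
    kept = [s for s in summaries if s.C > 0]
    if len(kept) >= 3:
        arr = np.array([[s.C, s.E, s.h] for s in kept])
        mean, sd = arr.mean(axis=0), arr.std(axis=0, ddof=1)
        sd[sd == 0] = np.inf
        inlier = (np.abs(arr - mean) <= outlier_sd * sd).all(axis=1)
        kept = [s for s, ok in zip(kept, inlier) if ok]
    return kept


def pearson_r(x, y) -> tuple:
    """Sample Pearson correlation with its two-sided t-test p-value,
    returned as (r, n, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), int(x.size), float(res.pvalue)


def welch_t(a, b) -> tuple:
    """Welch's unequal-variance t-test: (t, Welch-Satterthwaite df,
    two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf, float(a.size + b.size - 2), 0.0
    sa, sb = va / a.size, vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def anova_oneway(groups: list) -> tuple:
    """One-way fixed-effects ANOVA: (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    total_n = sum(g.size for g in groups)
    df1, df2 = len(groups) - 1, total_n - len(groups)
    if df2 < 1:
        raise ValueError("total n must exceed the number of groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, df1, df2, 1.0
    F, p = stats.f_oneway(*groups)
    if math.isnan(F):  # within-group variance zero, between nonzero
        return math.inf, df1, df2, 0.0
    return float(F), df1, df2, float(p)


def _hist(values: list) -> dict:
    out: dict = {}
    for v in values:
        out[int(v)] = out.get(int(v), 0) + 1
    return dict(sorted(out.items()))


def run_cohort(cohort: list, cfg: CohortRunConfig | None = None) -> CohortReport:
    """Fit every user and build the population report.

    ``cohort`` is a list of objects with ``user_id`` and ``pair``
    attributes (e.g. ``synth.CohortUser``) or of (user_id, pair) tuples.
    """
    cfg = cfg or CohortRunConfig()
    if not cohort:
        raise ValueError("cohort must be nonempty")

    results: list[UserResult] = []
    for entry in cohort:
        if hasattr(entry, "pair"):
            user_id, pair = entry.user_id, entry.pair
        else:
            user_id, pair = entry
        results.append(fit_user(pair, cfg, user_id=user_id))

    ok = [r for r in results if r.error is None]
    warnings_list = [f"user {r.user_id}: {r.error}" for r in results if r.error]

    report = CohortReport(
        n_users=len(results),
        n_failures=len(results) - len(ok),
        machine_state_hist=_hist([r.machine.n_states for r in ok]),
        transducer_state_hist=_hist([r.transducer.n_states for r in ok]),
        machine_lmax_hist=_hist([r.machine.lmax for r in ok]),
        transducer_lmax_hist=_hist([r.transducer.lmax for r in ok]),
        correlations={},
        tests={},
        warnings=warnings_list,
    )

    for label, get in (("machine", lambda r: r.machine), ("transducer", lambda r: r.transducer)):
        kept = filter_for_correlation([get(r) for r in ok], cfg.outlier_sd)
        if len(kept) < 3:
            report.warnings.append(f"{label}: fewer than 3 users after filtering; correlations skipped")
            continue
        C = [s.C for s in kept]
        for other in ("h", "E"):
            vals = [getattr(s, other) for s in kept]
            try:
                r, n, p = pearson_r(C, vals)
                report.correlations[f"{label}_C_vs_{other}"] = {"r": r, "n": n, "p": p}
            except ValueError as exc:
                report.warnings.append(f"{label} C-{other} correlation skipped: {exc}")

    m_states = [r.machine.n_states for r in ok]
    t_states = [r.transducer.n_states for r in ok]
    m_E = [r.machine.E for r in ok]
    t_E = [r.transducer.E for r in ok]
    for name, a, b in (
        ("welch_states_transducer_vs_machine", t_states, m_states),
        ("welch_E_transducer_vs_machine", t_E, m_E),
    ):
        try:
            t, df, p = welch_t(a, b)
            report.tests[name] = {"t": t, "df": df, "p": p, "mean_a": float(np.mean(a)), "mean_b": float(np.mean(b))}
        except ValueError as exc:
            report.warnings.append(f"{name} skipped: {exc}")

    multi = [r for r in ok if r.transducer.n_states > 1]
    single = [r for r in ok if r.transducer.n_states == 1]
    for name, key in (
        ("welch_troll_count_multi_vs_single", lambda r: r.troll_count),
        ("welch_n_comments_single_vs_multi", lambda r: r.n_comments),
    ):
        groups = (multi, single) if "troll" in name else (single, multi)
        try:
            t, df, p = welch_t([key(r) for r in groups[0]], [key(r) for r in groups[1]])
            report.tests[name] = {"t": t, "df": df, "p": p}
        except ValueError as exc:
            report.warnings.append(f"{name} skipped: {exc}")

    # ANOVA of each measure across transducer state counts (multi-state users)
    by_states: dict = {}
    for r in ok:
        if r.transducer.n_states > 1:
            by_states.setdefault(r.transducer.n_states, []).append(r.transducer)
    groups = [v for _k, v in sorted(by_states.items()) if len(v) >= 2]
    if len(groups) >= 2:
        for measure in ("C", "E", "h"):
            try:
                F, df1, df2, p = anova_oneway([[getattr(s, measure) for s in g] for g in groups])
                report.tests[f"anova_{measure}_by_transducer_states"] = {
                    "F": F, "df1": df1, "df2": df2, "p": p,
                }
            except ValueError as exc:
                report.warnings.append(f"anova {measure} skipped: {exc}")
    return report
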