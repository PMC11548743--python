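"""Rank-transform repeated-measures ANOVA for the 2x2 within-subject design.

Each behavioral or call category is analysed per session type in a 2x2
within-subject design: factor "lighting" (before/after the light change) x
factor "phase" (early days 1-3 / late days 4-6), with housing boxes as
subjects.  Because durations are typically non-normal, the values entering
one analysis are pooled, rank-transformed (average ranks at ties) and the
classical repeated-measures ANOVA is run on the ranks — the rank-transform
ANOVA of Conover & Iman.  With two levels per factor every effect has 1
numerator df and n_subjects - 1 denominator df, so sphericity is moot.

Effect sizes are partial eta squared, SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

logger = logging.getLogger(__name__)

EFFECTS = ("lighting", "phase", "interaction")
ALPHA = 0.05

NORMALITY_TESTS = ("anderson_darling", "dagostino_pearson", "shapiro_wilk", "kolmogorov_smirnov")


def normality_screen(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> pd.DataFrame:
    """Run the four normality tests on every cell of values.

    Returns a long table (cell, test, statistic, p_or_crit, passed).  Cells
    with fewer than 3 values are skipped with a log entry; tests with their
    own minimum sample size (D'Agostino-Pearson needs 8, Lilliefors 4) are
    skipped for smaller cells.  Downstream rank transformation is applied
    unconditionally as soon as any test fails for any cell.
    """
    rows = []
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        if x.size < 3:
            logger.info("normality screen: cell %r skipped (n=%d < 3)", name, x.size)
            continue
        if np.ptp(x) == 0:
            # constant cell: trivially non-normal
            for test in NORMALITY_TESTS:
                rows.append((name, test, np.nan, np.nan, False))
            continue
        with warnings.catch_warnings():
            # scipy >= 1.17 deprecates the critical-value return; the
            # classical 5% critical value is what this screen uses
            warnings.simplefilter("ignore", FutureWarning)
            ad = sps.anderson(x, dist="norm")
        crit = ad.critical_values[list(ad.significance_level).index(5.0)]
        rows.append((name, "anderson_darling", ad.statistic, crit, ad.statistic < crit))
        if x.size >= 8:
            stat, p = sps.normaltest(x)
            rows.append((name, "dagostino_pearson", stat, p, p > alpha))
        else:
            logger.info(
                "normality screen: D'Agostino-Pearson skipped for cell %r (n=%d < 8)",
                name,
                x.size,
            )
        stat, p = sps.shapiro(x)
        rows.append((name, "shapiro_wilk", stat, p, p > alpha))
        if x.size >= 4:
            stat, p = lilliefors(x, dist="norm")
            rows.append((name, "kolmogorov_smirnov", stat, p, p > alpha))
        else:
            logger.info(
                "normality screen: Kolmogorov-Smirnov skipped for cell %r (n=%d < 4)",
                name,
                x.size,
            )
    return pd.DataFrame(
        rows, columns=["cell", "test", "statistic", "p_or_crit", "passed"]
    )


def rank_transform(values) -> np.ndarray:
    """Ranks 1..n of the pooled values entering one analysis; ties get
    average ranks."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("rank_transform needs at least one value")
    return sps.rankdata(x, method="average")


@dataclass
class RMAnovaEffect:
    effect: str
    ss_effect: float
    ss_error: float
    df_num: int
    df_den: int
    F: float
    p: float
    partial_eta_sq: float


@dataclass
class RMAnovaResults:
    """Results of one 2x2 within-subject repeated-measures ANOVA."""

    category: str
    session_type: str
    n_subjects: int
    ranked: bool
    effects: list[RMAnovaEffect]
    dropped_subjects: list = field(default_factory=list)

    @property
    def anova_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": e.effect,
                    "F": e.F,
                    "df_num": e.df_num,
                    "df_den": e.df_den,
                    "p": e.p,
                    "partial_eta_sq": e.partial_eta_sq,
                    "significant": e.p < ALPHA,
                }
                for e in self.effects
            ]
        )

    def summary(self) -> str:
        head = (
            f"Rank RM-ANOVA (2x2 within): {self.category} / {self.session_type}\n"
            f"subjects (boxes): n = {self.n_subjects}; "
            f"ranked = {self.ranked}\n"
        )
        lines = [head]
        for e in self.effects:
            star = " *" if e.p < ALPHA else ""
            lines.append(
                f"  {e.effect:<12} F({e.df_num},{e.df_den}) = {e.F:8.3f}  "
                f"p = {e.p:.4f}  partial eta^2 = {e.partial_eta_sq:.3f}{star}"
            )
        return "\n".join(lines)


class RankRMAnova2x2:
    """Two-way (2x2) within-subject repeated-measures ANOVA, optionally on
    ranks.

    Parameters
    ----------
    data : long DataFrame with one value per subject x A x B cell
    dv : value column name
    subject : subject column name
    factor_a, factor_b : the two within factors (each must have 2 levels)
    rank : "auto" applies the rank transform when any normality test fails
        in any cell; True/False force it on/off.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        dv: str = "value",
        subject: str = "box",
        factor_a: str = "lighting",
        factor_b: str = "phase",
        rank: bool | str = "auto",
        category: str = "",
        session_type: str = "",
    ) -> None:
        self.dv = dv
        self.subject = subject
        self.factor_a = factor_a
        self.factor_b = factor_b
        self.rank = rank
        self.category = category
        self.session_type = session_type
        self.data = data.copy()
        for f in (factor_a, factor_b):
            if data[f].nunique() != 2:
                raise ValueError(f"factor {f!r} must have exactly 2 levels")

    def _complete_table(self) -> tuple[np.ndarray, list, list]:
        """(n, 2, 2) value array over complete subjects + dropped list."""
        a_levels = sorted(self.data[self.factor_a].unique())
        b_levels = sorted(self.data[self.factor_b].unique())
        wide = self.data.pivot_table(
            index=self.subject,
            columns=[self.factor_a, self.factor_b],
            values=self.dv,
            aggfunc="mean",
        )
        full_cols = pd.MultiIndex.from_product([a_levels, b_levels])
        wide = wide.reindex(columns=full_cols)
        complete = wide.dropna()
        dropped = sorted(set(wide.index) - set(complete.index))
        if dropped:
            logger.warning(
                "%s/%s: dropping incomplete subjects %s",
                self.category,
                self.session_type,
                dropped,
            )
        if len(complete) < 2:
            raise ValueError("fewer than 2 complete subjects")
        y = complete.to_numpy(float).reshape(len(complete), 2, 2)
        return y, list(complete.index), dropped

    def fit(self) -> RMAnovaResults:
        y, subjects, dropped = self._complete_table()
        ranked = self.rank is True
        if self.rank == "auto":
            groups = {
                f"a{a}b{b}": y[:, a, b] for a in range(2) for b in range(2)
            }
            screen = normality_screen(groups)
            ranked = bool(len(screen) == 0 or (~screen["passed"]).any())
        if ranked:
            y = rank_transform(y.ravel()).reshape(y.shape)
        effects = _rm_anova_2x2_from_array(y)
        return RMAnovaResults(
            category=self.category,
            session_type=self.session_type,
            n_subjects=len(subjects),
            ranked=ranked,
            effects=effects,
            dropped_subjects=dropped,
        )


def _f_p(ss_eff: float, ss_err: float, df_den: int) -> tuple[float, float]:
    if ss_err <= 0:
        if ss_eff <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_eff / 1.0) / (ss_err / df_den)
    return F, float(sps.f.sf(F, 1, df_den))


def _rm_anova_2x2_from_array(y: np.ndarray) -> list[RMAnovaEffect]:
    """Sums-of-squares decomposition for an (n_subjects, 2, 2) table.

    Each within effect is tested against its own subject-by-effect
    interaction error term.  SS_error = 0 with a non-zero effect is
    reported as F = +inf, p = 0.
    """
    n = y.shape[0]
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = 2 * n * np.sum((m_a - grand) ** 2)
    ss_err_a = 2 * np.sum(
        (m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2
    )
    ss_b = 2 * n * np.sum((m_b - grand) ** 2)
    ss_err_b = 2 * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_ab = n * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2
    )
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_err_ab = np.sum(resid**2)

    out = []
    df_den = n - 1
    for name, ss_eff, ss_err in (
        ("lighting", ss_a, ss_err_a),
        ("phase", ss_b, ss_err_b),
        ("interaction", ss_ab, ss_err_ab),
    ):
        F, p = _f_p(ss_eff, ss_err, df_den)
        denom = ss_eff + ss_err
        eta = ss_eff / denom if denom > 0 else 0.0
        out.append(
            RMAnovaEffect(
                effect=name,
                ss_effect=float(ss_eff),
                ss_error=float(ss_err),
                df_num=1,
                df_den=df_den,
                F=float(F),
                p=float(p),
                partial_eta_sq=float(eta),
            )
        )
    return out


def run_battery(
    cells: pd.DataFrame,
    categories: list[str] | None = None,
    session_types: list[str] | None = None,
    rank: bool | str = "auto",
    holm: bool = False,
) -> pd.DataFrame:
    """One rank RM-ANOVA per category x session type over the cell means.

    ``cells`` is the :func:`ethousv.aggregate.collapse_design` output (box,
    session_type, category, lighting, phase, value).  The full study yields
    15 categories x 2 session types = 30 analyses, each reporting the
    lighting effect, the phase effect and their interaction at alpha 0.05.
    Missing categories are skipped and counted in the log.  ``holm`` applies
    a Holm correction across analyses per effect (off by default, matching
    the uncorrected per-test alpha of the study design).
    """
    if categories is None:
        categories = sorted(cells["category"].unique())
    if session_types is None:
        session_types = sorted(cells["session_type"].unique())
    rows = []
    n_skipped = 0
    for st in session_types:
        for cat in categories:
            sub = cells[(cells["category"] == cat) & (cells["session_type"] == st)]
            if len(sub) == 0:
                logger.warning("battery: no data for %s / %s; skipped", cat, st)
                n_skipped += 1
                continue
            try:
                res = RankRMAnova2x2(
                    sub, rank=rank, category=cat, session_type=st
                ).fit()
            except ValueError as exc:
                logger.warning("battery: %s / %s failed: %s; skipped", cat, st, exc)
                n_skipped += 1
                continue
            for e in res.effects:
                rows.append(
                    {
                        "category": cat,
                        "session_type": st,
                        "effect": e.effect,
                        "F": e.F,
                        "df_num": e.df_num,
                        "df_den": e.df_den,
                        "p": e.p,
                        "partial_eta_sq": e.partial_eta_sq,
                        "n_subjects": res.n_subjects,
                        "ranked": res.ranked,
                    }
                )
    table = pd.DataFrame(rows)
    if n_skipped:
        logger.info("battery skipped %d category/session analyses", n_skipped)
    if len(table):
        if holm:
            from statsmodels.stats.multitest import multipletests

            flags = np.zeros(len(table), dtype=bool)
            for eff in EFFECTS:
                m = table["effect"] == eff
                if m.any():
                    flags[m.to_numpy()] = multipletests(
                        table.loc[m, "p"], alpha=ALPHA, method="holm"
                    )[0]
            table["significant"] = flags
        else:
            table["significant"] = table["p"] < ALPHA
    return table


def one_way_binned_anova(counts_by_group: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA across groups of binned event counts (demo path for
    water-spout head entries aggregated in 10-minute bins).

    The published lickometer analysis pools bins across boxes and days as
    independent observations; this helper mirrors that layout as a plain
    one-way ANOVA on the binned counts.
    """
    groups = [np.asarray(v, dtype=float) for v in counts_by_group.values()]
    F, p = sps.f_oneway(*groups)
    return float(F), float(p)
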