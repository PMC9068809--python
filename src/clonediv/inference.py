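"""Inference layer: slope fits, pooled-resampling randomization tests, and
the two-lineage contrast model.

The central question — is the dN-versus-dS slope (relative dN/dS accrued
since each founder) different between two genetically isolated lineages? —
is answered by a randomization test: pool the pairwise rows of both
lineages, resample group-sized sets with replacement, refit both ordinary
least-squares slopes, and compare the observed slope difference with the
resampled differences (1999 replicates by default).  Significance follows
the "larger than 95% of the null differences" rule, applied two-sided on
absolute differences by default, and the Monte-Carlo p-value uses the
add-one estimator so it can never be exactly zero.

:class:`LineageContrastModel` packages the full panel of contrasts
(dS ~ dn-C, dN ~ dn-C, dN ~ dS, dS_hom ~ dS_het, dN_hom ~ dN_het, plus the
dN_hom location test) behind a statsmodels-style ``fit()`` returning a
results object with a ``summary()`` table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05

#: (y, x) field pairs fitted per lineage and contrasted between lineages
SLOPE_CONTRASTS: list[tuple[str, str]] = [
    ("dS", "dnC"),
    ("dN", "dnC"),
    ("dN", "dS"),
    ("dS_hom", "dS_het"),
    ("dN_hom", "dN_het"),
]


@dataclass
class SlopeFit:
    """Ordinary least-squares slope with its 95% CI half-width."""

    slope: float
    intercept: float
    ci95_halfwidth: float
    p_slope: float
    n: int
    stderr: float = float("nan")

    @property
    def significant(self) -> bool:
        return self.p_slope < ALPHA


def ols_slope(xs: Sequence[float], ys: Sequence[float]) -> SlopeFit:
    """Least-squares fit with intercept; CI from the t(n-2) reference."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValueError("xs and ys must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points for a slope with a CI")
    if np.var(x) == 0:
        raise ValueError("degenerate x: zero variance")
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    return SlopeFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        ci95_halfwidth=float(tcrit * res.stderr),
        p_slope=float(res.pvalue),
        n=n,
        stderr=float(res.stderr),
    )


def _extract(rows, fields: tuple[str, ...]) -> np.ndarray:
    """Columns from a DataFrame or attribute arrays from dataclass rows."""
    if isinstance(rows, pd.DataFrame):
        return np.column_stack([rows[f].to_numpy(dtype=float) for f in fields])
    return np.array([[float(getattr(r, f)) for f in fields] for r in rows])


def _vectorized_slopes(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise OLS slopes and x-variances for resample batches."""
    mx = X.mean(axis=1)
    my = Y.mean(axis=1)
    sxx = (X * X).mean(axis=1) - mx * mx
    sxy = (X * Y).mean(axis=1) - mx * my
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = sxy / sxx
    return slopes, sxx


def _is_significant(null_abs: np.ndarray, obs_abs: float, n_rand: int) -> bool:
    """Observed statistic larger than 95% of the null values."""
    return int(np.sum(null_abs >= obs_abs)) < math.ceil(ALPHA * n_rand)


def _mc_p(null: np.ndarray, obs: float) -> float:
    """Add-one Monte-Carlo p (never zero)."""
    return (1 + int(np.sum(null >= obs))) / (null.size + 1)


@dataclass
class SlopeComparison:
    """Randomization comparison of two lineages' slopes."""

    fit_a: SlopeFit
    fit_b: SlopeFit
    observed_diff: float
    null_diffs: np.ndarray
    p_mc: float
    significant: bool
    n_degenerate_redraws: int = 0


@dataclass
class LocationComparison:
    """Randomization comparison of two lineages' means."""

    mean_a: float
    mean_b: float
    observed_diff: float
    null_diffs: np.ndarray
    p_mc: float
    significant: bool


def _draw_group_slopes(
    rng: np.random.Generator,
    pool_x: np.ndarray,
    pool_y: np.ndarray,
    n_group: int,
    n_rand: int,
) -> tuple[np.ndarray, int]:
    """Bootstrap slopes of group-sized resamples from the pooled rows.

    Resamples with zero x-variance cannot yield a slope and are redrawn;
    the redraw count is returned for logging.
    """
    n_pool = pool_x.size
    slopes = np.empty(n_rand)
    pending = np.arange(n_rand)
    redraws = 0
    while pending.size:
        idx = rng.integers(0, n_pool, size=(pending.size, n_group))
        s, sxx = _vectorized_slopes(pool_x[idx], pool_y[idx])
        ok = sxx > 0
        slopes[pending[ok]] = s[ok]
        redraws += int(np.sum(~ok))
        pending = pending[~ok]
    return slopes, redraws


def randomization_slope_test(
    pairs_a,
    pairs_b,
    x_field: str,
    y_field: str,
    n_rand: int = 1999,
    seed: int | np.random.Generator | None = None,
    two_sided: bool = True,
) -> SlopeComparison:
    """Pooled-resampling randomization test for a slope difference.

    ``pairs_a``/``pairs_b`` are the two lineages' pairwise rows (DataFrame
    or :class:`~clonediv.counting.PairwiseCounts` sequences).  The null is
    built by drawing, with replacement, group-sized row sets from the pooled
    rows, refitting both slopes and recording the difference, ``n_rand``
    times.  Two-sided by default (absolute differences); one-sided tests
    whether slope_a - slope_b is extreme in the positive direction.
    """
    xa, ya = _extract(pairs_a, (x_field, y_field)).T
    xb, yb = _extract(pairs_b, (x_field, y_field)).T
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each group needs at least 3 pairwise rows")
    fit_a = ols_slope(xa, ya)
    fit_b = ols_slope(xb, yb)
    observed = fit_a.slope - fit_b.slope

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool_x = np.concatenate([xa, xb])
    pool_y = np.concatenate([ya, yb])
    slopes_a, r1 = _draw_group_slopes(rng, pool_x, pool_y, xa.size, n_rand)
    slopes_b, r2 = _draw_group_slopes(rng, pool_x, pool_y, xb.size, n_rand)
    null = slopes_a - slopes_b

    if two_sided:
        p = _mc_p(np.abs(null), abs(observed))
        sig = _is_significant(np.abs(null), abs(observed), n_rand)
    else:
        p = _mc_p(null, observed)
        sig = _is_significant(null, observed, n_rand)
    return SlopeComparison(
        fit_a=fit_a,
        fit_b=fit_b,
        observed_diff=observed,
        null_diffs=null,
        p_mc=p,
        significant=sig,
        n_degenerate_redraws=r1 + r2,
    )


def randomization_location_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_rand: int = 1999,
    seed: int | np.random.Generator | None = None,
    two_sided: bool = True,
) -> LocationComparison:
    """Pooled-resampling randomization test for a mean difference.

    Used for the dN_hom contrast when neither lineage's hom-versus-het
    regression is itself significant: the lineages' mean dN_hom values are
    compared without conditioning on dN_het.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    observed = float(a.mean() - b.mean())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.concatenate([a, b])
    idx_a = rng.integers(0, pool.size, size=(n_rand, a.size))
    idx_b = rng.integers(0, pool.size, size=(n_rand, b.size))
    null = pool[idx_a].mean(axis=1) - pool[idx_b].mean(axis=1)

    if two_sided:
        p = _mc_p(np.abs(null), abs(observed))
        sig = _is_significant(np.abs(null), abs(observed), n_rand)
    else:
        p = _mc_p(null, observed)
        sig = _is_significant(null, observed, n_rand)
    return LocationComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        observed_diff=observed,
        null_diffs=null,
        p_mc=p,
        significant=sig,
    )


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], n_comparisons: int = 3
) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with a Bonferroni-corrected p.

    Exact enumeration p when the smaller group has <= 8 observations and
    there are no ties; otherwise the tie-corrected normal approximation.
    The default Bonferroni factor 3 covers the S / N / N-over-S family.
    Returns (U, p_raw, p_bonferroni).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p_raw = float(res.pvalue)
    return float(res.statistic), p_raw, min(1.0, p_raw * n_comparisons)


def two_sample_t(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test: Student (pooled variance) by default, Welch on flag.

    Returns (t, df, p).  When both groups have zero variance the statistic
    is degenerate: equal means give (0, df, 1); unequal means give
    (inf-signed, df, 0) with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        df = a.size + b.size - 2
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        warnings.warn("zero variance in both groups; p set to 0", stacklevel=2)
        return math.copysign(math.inf, a.mean() - b.mean()), float(df), 0.0
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def genotype_permutation_slope_test(
    genome,
    callsets_a,
    callsets_b,
    x_field: str,
    y_field: str,
    n_rand: int = 1999,
    seed: int | np.random.Generator | None = None,
    two_sided: bool = True,
) -> SlopeComparison:
    """Genotype-label permutation variant of the slope contrast.

    The pooled-row bootstrap treats the n(n-1)/2 pairwise rows as
    independent, but rows sharing a genotype are correlated, which makes
    that procedure anticonservative.  This variant resamples at the level
    of the exchangeable unit instead: genotype labels are permuted across
    the two lineages, the within-group pairwise row sets are rebuilt from
    the full cross-genotype pair matrix, and both slopes are refit.  It is
    calibrated under the exchangeable null, at the cost of power when the
    alternative itself drives pooled heterogeneity.

    ``callsets_a``/``callsets_b`` are mappings genotype-id ->
    :class:`~clonediv.genome.GenotypeCallSet`.
    """
    from .counting import pairwise_counts

    ids_a = sorted(callsets_a)
    ids_b = sorted(callsets_b)
    na, nb = len(ids_a), len(ids_b)
    if na < 3 or nb < 3:
        raise ValueError("each group needs at least 3 genotypes")
    ids = ids_a + ids_b
    n = len(ids)
    pooled = {**callsets_a, **callsets_b}

    xmat = np.zeros((n, n))
    ymat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = pairwise_counts(genome, pooled[ids[i]], pooled[ids[j]])
            x, y = float(getattr(p, x_field)), float(getattr(p, y_field))
            xmat[i, j] = xmat[j, i] = x
            ymat[i, j] = ymat[j, i] = y

    comb_a = np.array(list(combinations(range(na), 2)))
    comb_b = np.array(list(combinations(range(nb), 2)))

    def group_rows(members: np.ndarray, comb: np.ndarray):
        i = members[..., comb[:, 0]]
        j = members[..., comb[:, 1]]
        return xmat[i, j], ymat[i, j]

    xa, ya = group_rows(np.arange(na), comb_a)
    xb, yb = group_rows(np.arange(na, n), comb_b)
    fit_a = ols_slope(xa, ya)
    fit_b = ols_slope(xb, yb)
    observed = fit_a.slope - fit_b.slope

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    null = np.empty(n_rand)
    filled = 0
    redraws = 0
    while filled < n_rand:
        batch = min(256, n_rand - filled + 64)
        perms = np.argsort(rng.random((batch, n)), axis=1)
        Xa, Ya = group_rows(perms[:, :na], comb_a)
        Xb, Yb = group_rows(perms[:, na:], comb_b)
        sa, va = _vectorized_slopes(Xa, Ya)
        sb, vb = _vectorized_slopes(Xb, Yb)
        ok = (va > 0) & (vb > 0)
        redraws += int(np.sum(~ok))
        take = (sa - sb)[ok][: n_rand - filled]
        null[filled : filled + take.size] = take
        filled += take.size

    if two_sided:
        p = _mc_p(np.abs(null), abs(observed))
        sig = _is_significant(np.abs(null), abs(observed), n_rand)
    else:
        p = _mc_p(null, observed)
        sig = _is_significant(null, observed, n_rand)
    return SlopeComparison(
        fit_a=fit_a,
        fit_b=fit_b,
        observed_diff=observed,
        null_diffs=null,
        p_mc=p,
        significant=sig,
        n_degenerate_redraws=redraws,
    )


# ---------------------------------------------------------------- model object

class LineageContrastModel:
    """Two-lineage contrast of within-lineage substitution accumulation.

    Built from the pairwise-counts table (one row per within-lineage
    genotype pair, with a lineage column); ``fit`` runs the full contrast
    panel and returns a :class:`LineageContrastResults`.

    Parameters
    ----------
    pairwise : DataFrame or sequence of PairwiseCounts
        Pairwise rows for exactly two lineages.
    lineage_col : str
        Column/attribute naming the lineage of each row.
    """

    def __init__(self, pairwise, lineage_col: str = "lineage_id") -> None:
        if not isinstance(pairwise, pd.DataFrame):
            from .counting import pairwise_frame

            pairwise = pairwise_frame(list(pairwise))
        self.data = pairwise.reset_index(drop=True)
        self.lineage_col = lineage_col
        lineages = sorted(self.data[lineage_col].unique())
        if len(lineages) != 2:
            raise ValueError(
                f"expected exactly 2 lineages, found {lineages}"
            )
        self.lineage_a, self.lineage_b = lineages

    @classmethod
    def from_pairs(cls, pairs) -> "LineageContrastModel":
        return cls(pairs)

    def _group(self, lineage: str) -> pd.DataFrame:
        return self.data[self.data[self.lineage_col] == lineage]

    def fit(
        self, n_rand: int = 1999, seed: int | None = None, two_sided: bool = True
    ) -> "LineageContrastResults":
        """Run every slope contrast plus the dN_hom location test."""
        rng = np.random.default_rng(seed)
        group_a = self._group(self.lineage_a)
        group_b = self._group(self.lineage_b)
        slope_tests: dict[tuple[str, str], SlopeComparison] = {}
        for y_field, x_field in SLOPE_CONTRASTS:
            slope_tests[(y_field, x_field)] = randomization_slope_test(
                group_a,
                group_b,
                x_field=x_field,
                y_field=y_field,
                n_rand=n_rand,
                seed=rng,
                two_sided=two_sided,
            )
        location = randomization_location_test(
            group_a["dN_hom"],
            group_b["dN_hom"],
            n_rand=n_rand,
            seed=rng,
            two_sided=two_sided,
        )
        return LineageContrastResults(self, slope_tests, location, n_rand)


class LineageContrastResults:
    """Fitted contrast panel: per-lineage slopes, slope differences and
    randomization p-values for every contrast, plus the dN_hom location
    test."""

    def __init__(
        self,
        model: LineageContrastModel,
        slope_tests: dict[tuple[str, str], SlopeComparison],
        location_test: LocationComparison,
        n_rand: int,
    ) -> None:
        self.model = model
        self.slope_tests = slope_tests
        self.location_test = location_test
        self.n_rand = n_rand

    def to_frame(self) -> pd.DataFrame:
        """One tidy row per contrast (machine-readable results table)."""
        a, b = self.model.lineage_a, self.model.lineage_b
        rows = []
        for (y, x), cmp_ in self.slope_tests.items():
            rows.append(
                {
                    "contrast": f"{y}~{x}",
                    "statistic": "slope",
                    f"estimate_{a}": cmp_.fit_a.slope,
                    f"ci95_{a}": cmp_.fit_a.ci95_halfwidth,
                    f"estimate_{b}": cmp_.fit_b.slope,
                    f"ci95_{b}": cmp_.fit_b.ci95_halfwidth,
                    "observed_diff": cmp_.observed_diff,
                    "p_mc": cmp_.p_mc,
                    "significant": cmp_.significant,
                }
            )
        loc = self.location_test
        rows.append(
            {
                "contrast": "dN_hom",
                "statistic": "mean",
                f"estimate_{a}": loc.mean_a,
                f"ci95_{a}": float("nan"),
                f"estimate_{b}": loc.mean_b,
                f"ci95_{b}": float("nan"),
                "observed_diff": loc.observed_diff,
                "p_mc": loc.p_mc,
                "significant": loc.significant,
            }
        )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable panel summary."""
        a, b = self.model.lineage_a, self.model.lineage_b
        lines = [
            "Lineage contrast of within-lineage substitution accumulation",
            f"lineages: {a} vs {b}  "
            f"(n pairs {len(self.model._group(a))} vs {len(self.model._group(b))}; "
            f"{self.n_rand} randomization replicates)",
            "-" * 78,
            f"{'contrast':<16}{a + ' slope':>14}{b + ' slope':>14}"
            f"{'diff':>10}{'p_mc':>9}  significant",
        ]
        for (y, x), cmp_ in self.slope_tests.items():
            lines.append(
                f"{y + '~' + x:<16}"
                f"{cmp_.fit_a.slope:>9.3f}±{cmp_.fit_a.ci95_halfwidth:<5.3f}"
                f"{cmp_.fit_b.slope:>8.3f}±{cmp_.fit_b.ci95_halfwidth:<5.3f}"
                f"{cmp_.observed_diff:>10.3f}{cmp_.p_mc:>9.4f}  "
                f"{'yes' if cmp_.significant else 'no'}"
            )
        loc = self.location_test
        lines.append(
            f"{'dN_hom (mean)':<16}{loc.mean_a:>14.3f}{loc.mean_b:>14.3f}"
            f"{loc.observed_diff:>10.3f}{loc.p_mc:>9.4f}  "
            f"{'yes' if loc.significant else 'no'}"
        )
        return "\n".join(lines)

    def plot(self, axes=None):
        """Quick-look scatter panels for every contrast (requires matplotlib)."""
        import matplotlib.pyplot as plt

        a, b = self.model.lineage_a, self.model.lineage_b
        if axes is None:
            _, axes = plt.subplots(1, len(SLOPE_CONTRASTS), figsize=(4 * 5, 4))
        for ax, (y, x) in zip(np.atleast_1d(axes).ravel(), SLOPE_CONTRASTS):
            for lineage, color in ((a, "tab:red"), (b, "tab:blue")):
                grp = self.model._group(lineage)
                ax.scatter(grp[x], grp[y], s=18, color=color, label=lineage)
            cmp_ = self.slope_tests[(y, x)]
            ax.set_xlabel(x)
            ax.set_ylabel(y)
            ax.set_title(f"p_mc={cmp_.p_mc:.3f}")
            ax.legend(frameon=False)
        return axes
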