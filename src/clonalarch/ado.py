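"""Allele-dropout (ADO) modelling, rate estimation, and exact count tests.

Whole-genome amplification of a single cell can fail to amplify one
allele.  With a per-allele dropout probability ``d`` acting
independently on the two alleles, the observed genotype given the true
one is

    HET -> WT   with d(1-d)    (variant allele dropped)
           HET  with (1-d)^2
           HOM  with d(1-d)    (reference allele dropped)
           MISSING with d^2    (both dropped)
    HOM -> HOM  with 1-d^2,  MISSING with d^2
    WT  -> WT   with 1-d^2,  MISSING with d^2

Amplification-free colony genotypes provide an ADO-free reference
distribution, but colonies grown in semisolid culture may over-represent
fit clones; the estimators below make that assumption explicit:

* ``method="moment"`` (default when the cell MISSING count is known):
  d = sqrt(missing fraction).  This is the maximum-likelihood estimate
  when the colony distribution is allowed to be fitness-biased (the
  colony counts then carry no information about the cells' genotype
  mix), because P(MISSING) = d^2 regardless of the mix.
* ``method="joint"``: joint MLE of (genotype mix, d) from cell and
  colony counts, assuming colonies are an unbiased sample.
* ``method="contrast"``: plug-in estimator that treats the colony
  distribution as the true mix, pushes it through the dropout model
  conditioned on non-MISSING, and minimizes the three-category
  multinomial negative log-likelihood by golden-section search.  This is
  the only option when the MISSING count is unavailable; its sampling
  error is considerably larger.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .genotype_io import GenotypeState

logger = logging.getLogger(__name__)

__all__ = [
    "ADOEstimate",
    "TestResult",
    "ado_genotype_probs",
    "estimate_ado_rate",
    "fisher_exact_2x2",
    "genotype_distribution_test",
]

_STATES = ("WT", "HET", "HOM", "MISSING")


def ado_genotype_probs(true_state: GenotypeState | str, d: float) -> dict[str, float]:
    """Distribution over observed states given the true genotype.

    Per-allele independent dropout at rate ``d`` in [0, 0.5].
    """
    if not 0.0 <= d <= 0.5:
        raise ValueError("ADO rate d must be in [0, 0.5]")
    if isinstance(true_state, str):
        true_state = GenotypeState[true_state]
    if true_state == GenotypeState.HET:
        return {
            "WT": d * (1 - d),
            "HET": (1 - d) ** 2,
            "HOM": d * (1 - d),
            "MISSING": d * d,
        }
    if true_state == GenotypeState.HOM:
        return {"WT": 0.0, "HET": 0.0, "HOM": 1 - d * d, "MISSING": d * d}
    if true_state == GenotypeState.WT:
        return {"WT": 1 - d * d, "HET": 0.0, "HOM": 0.0, "MISSING": d * d}
    raise ValueError("true state must be WT, HET or HOM")


def _forward(mix: np.ndarray, d: float) -> np.ndarray:
    """Observed-state probabilities (WT, HET, HOM, MISSING) for a genotype mix."""
    wt, het, hom = mix
    return np.array(
        [
            wt * (1 - d * d) + het * d * (1 - d),
            het * (1 - d) ** 2,
            hom * (1 - d * d) + het * d * (1 - d),
            d * d,
        ]
    )


def _golden_min(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Golden-section minimization on [lo, hi]."""
    gr = (math.sqrt(5.0) - 1.0) / 2.0
    c = hi - gr * (hi - lo)
    d_ = lo + gr * (hi - lo)
    fc, fd = f(c), f(d_)
    while hi - lo > tol:
        if fc < fd:
            hi, d_, fd = d_, c, fc
            c = hi - gr * (hi - lo)
            fc = f(c)
        else:
            lo, c, fc = c, d_, fd
            d_ = lo + gr * (hi - lo)
            fd = f(d_)
    return (lo + hi) / 2.0


@dataclass
class ADOEstimate:
    """Point estimate of the per-allele dropout rate with a bootstrap CI."""

    d_hat: float
    ci: tuple[float, float]
    nll: float
    method: str
    identifiable: bool = True
    warnings: list[str] = field(default_factory=list)


@dataclass
class TestResult:
    """Outcome of an exact count test."""

    statistic: float
    p_value: float
    method: str
    table: list[list[int]]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = min(self.p_value, 1.0)


def _contrast_nll(d: float, cell_counts: np.ndarray, colony_dist: np.ndarray) -> float:
    p = _forward(colony_dist, d)[:3]
    p = np.clip(p / p.sum(), 1e-300, 1.0)
    return float(-(cell_counts * np.log(p)).sum())


def _fit_contrast(cell_counts: np.ndarray, colony_counts: np.ndarray) -> tuple[float, float]:
    colony_dist = colony_counts / colony_counts.sum()
    d_hat = _golden_min(lambda d: _contrast_nll(d, cell_counts, colony_dist), 0.0, 0.5)
    if d_hat < 1e-5:  # boundary optimum
        if _contrast_nll(0.0, cell_counts, colony_dist) <= _contrast_nll(
            d_hat, cell_counts, colony_dist
        ):
            d_hat = 0.0
    return d_hat, _contrast_nll(d_hat, cell_counts, colony_dist)


def _joint_nll(params: np.ndarray, cell4: np.ndarray, colony: np.ndarray) -> float:
    a, b, t = params
    e = np.exp([min(a, 500), min(b, 500), 0.0])
    mix = e / e.sum()
    d = 0.5 / (1.0 + math.exp(-min(max(t, -500), 500)))
    p = np.clip(_forward(mix, d), 1e-300, 1.0)
    mixc = np.clip(mix, 1e-300, 1.0)
    return float(-(cell4 * np.log(p)).sum() - (colony * np.log(mixc)).sum())


def _fit_joint(cell4: np.ndarray, colony: np.ndarray) -> tuple[float, float]:
    best = None
    for t0 in (-6.0, -2.0, 0.0):
        res = optimize.minimize(
            _joint_nll,
            x0=np.array([0.0, 0.3, t0]),
            args=(cell4, colony),
            method="Nelder-Mead",
            options=dict(xatol=1e-8, fatol=1e-12, maxiter=3000),
        )
        if best is None or res.fun < best.fun:
            best = res
    d_hat = 0.5 / (1.0 + math.exp(-min(max(best.x[2], -500), 500)))
    if d_hat < 1e-5:
        d_hat = 0.0
    return float(d_hat), float(best.fun)


def estimate_ado_rate(
    cell_counts,
    colony_counts,
    *,
    cell_missing: int | None = None,
    method: str | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> ADOEstimate:
    """Estimate the per-allele dropout rate from cell and colony counts.

    ``cell_counts`` and ``colony_counts`` are (WT, HET, HOM) counts for
    one mutation; ``cell_missing`` is the number of cells with no call.
    Method defaults to "moment" when ``cell_missing`` is given and
    "contrast" otherwise (see module docstring).  The CI is a seeded
    percentile bootstrap over ``n_boot`` resamples of both tables.
    """
    cell_counts = np.asarray(cell_counts, dtype=float)
    colony_counts = np.asarray(colony_counts, dtype=float)
    if cell_counts.shape != (3,) or colony_counts.shape != (3,):
        raise ValueError("cell_counts and colony_counts must be (WT, HET, HOM) triples")
    if cell_counts.sum() <= 0 or colony_counts.sum() <= 0:
        raise ValueError("count vectors must have positive totals")
    if method is None:
        method = "moment" if cell_missing is not None else "contrast"
    if method in ("moment", "joint") and cell_missing is None:
        raise ValueError(f"method {method!r} requires cell_missing")

    warnings: list[str] = []
    identifiable = True
    if method in ("contrast", "joint") and colony_counts[1] == 0:
        # no heterozygous colonies: the dropout-distorted mix is then
        # indistinguishable from the mix itself among defined calls
        identifiable = False
        warnings.append(
            "colony distribution has no heterozygotes; d is unidentifiable "
            "from defined genotype counts"
        )

    def _estimate(cells3: np.ndarray, missing: float | None, colonies: np.ndarray) -> tuple[float, float]:
        if method == "moment":
            total = cells3.sum() + missing
            return float(math.sqrt(missing / total)), float("nan")
        if method == "joint":
            return _fit_joint(np.append(cells3, missing), colonies)
        return _fit_contrast(cells3, colonies)

    if method == "moment":
        d_hat, nll = _estimate(cell_counts, float(cell_missing), colony_counts)
        d_hat = min(d_hat, 0.5)
    elif identifiable:
        miss = float(cell_missing) if cell_missing is not None else None
        d_hat, nll = _estimate(cell_counts, miss, colony_counts)
    else:
        d_hat, nll = float("nan"), float("nan")
        logger.warning(warnings[-1])

    # percentile bootstrap over both tables
    ci = (float("nan"), float("nan"))
    if identifiable and n_boot > 0:
        rng = np.random.default_rng(seed)
        n_cells = int(cell_counts.sum() + (cell_missing or 0))
        n_col = int(colony_counts.sum())
        p_cells = np.append(cell_counts, cell_missing or 0) / n_cells
        p_col = colony_counts / n_col
        reps = np.empty(n_boot)
        for b in range(n_boot):
            c4 = rng.multinomial(n_cells, p_cells).astype(float)
            col = rng.multinomial(n_col, p_col).astype(float)
            col = np.maximum(col, 0)
            if col.sum() == 0 or c4[:3].sum() == 0:
                reps[b] = np.nan
                continue
            if method in ("contrast", "joint") and col[1] == 0:
                reps[b] = np.nan
                continue
            reps[b], _ = _estimate(c4[:3], float(c4[3]) if cell_missing is not None else None, col)
        reps = reps[~np.isnan(reps)]
        if reps.size:
            lo, hi = np.percentile(reps, [2.5, 97.5])
            # the percentile interval is widened, if needed, to honor the
            # contract that it contains the point estimate
            ci = (float(min(lo, d_hat)), float(max(hi, d_hat)))

    return ADOEstimate(
        d_hat=float(d_hat), ci=ci, nll=float(nll), method=method,
        identifiable=identifiable, warnings=warnings,
    )


# -- exact tests -------------------------------------------------------------

def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test with the point-probability rule.

    p = sum of hypergeometric probabilities of all tables (same margins)
    whose probability does not exceed the observed table's.  A zero
    margin makes every table equally (un)informative: p = 1 with a
    warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 nonnegative integers")
    a, b = t[0]
    c, d = t[1]
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = t.sum()
    odds = math.inf if b * c == 0 and a * d > 0 else (
        math.nan if b * c == 0 else (a * d) / (b * c)
    )
    if 0 in (r1, r2, c1, c2):
        logger.warning("fisher_exact_2x2: zero margin, p = 1")
        return TestResult(statistic=odds, p_value=1.0, method="fisher-exact-2x2", table=t.tolist())
    lo, hi = max(0, r1 - c2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, c1, r1)
    p_obs = float(stats.hypergeom.pmf(a, n, c1, r1))
    # normalizing by the full sum makes an all-inclusive p exactly 1
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum() / pmf.sum())
    return TestResult(statistic=odds, p_value=min(p, 1.0), method="fisher-exact-2x2", table=t.tolist())


def _log_table_weight(row: np.ndarray, col_margins: np.ndarray) -> float:
    """log of the product of per-column binomials (table weight given margins)."""
    return float(sum(math.lgamma(c + 1) - math.lgamma(k + 1) - math.lgamma(c - k + 1)
                     for k, c in zip(row, col_margins)))


def genotype_distribution_test(cell_counts, colony_counts, *, seed: int = 0,
                               enumeration_limit: int = 200, n_mc: int = 100_000) -> TestResult:
    """Exact conditional test on the 2 x 3 (cells vs colonies) table.

    Freeman–Halton extension of Fisher's exact test: the p-value sums
    conditional probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's.  Full
    enumeration (exact integer weights) when the grand total is at most
    ``enumeration_limit``; otherwise seeded Monte Carlo over ``n_mc``
    draws from the margin-conditional distribution.
    """
    row1 = np.asarray(cell_counts, dtype=int)
    row2 = np.asarray(colony_counts, dtype=int)
    if row1.shape != (3,) or row2.shape != (3,) or (row1 < 0).any() or (row2 < 0).any():
        raise ValueError("cell_counts and colony_counts must be nonnegative (WT, HET, HOM)")
    if row1.sum() <= 0 or row2.sum() <= 0:
        raise ValueError("count vectors must have positive totals")
    n1 = int(row1.sum())
    cols = row1 + row2
    total = int(cols.sum())
    # chi-squared statistic reported as a descriptive effect summary
    expected = np.outer([n1, total - n1], cols) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(expected > 0, (np.vstack([row1, row2]) - expected) ** 2 / expected, 0.0))

    if total <= enumeration_limit:
        w_obs = math.comb(int(cols[0]), int(row1[0])) * math.comb(int(cols[1]), int(row1[1])) * math.comb(
            int(cols[2]), int(row1[2])
        )
        num = 0
        den = 0
        for x0 in range(max(0, n1 - cols[1] - cols[2]), min(cols[0], n1) + 1):
            for x1 in range(max(0, n1 - x0 - cols[2]), min(cols[1], n1 - x0) + 1):
                x2 = n1 - x0 - x1
                w = math.comb(int(cols[0]), x0) * math.comb(int(cols[1]), x1) * math.comb(int(cols[2]), x2)
                den += w
                if w <= w_obs:
                    num += w
        return TestResult(statistic=float(chi2), p_value=num / den,
                          method="freeman-halton-enumeration", table=[row1.tolist(), row2.tolist()])

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(cols, n1, size=n_mc)
    logw = _log_weights(draws, cols)
    logw_obs = _log_table_weight(row1, cols)
    # add-one Monte Carlo p: never exactly 0, valid by construction
    p = float((1 + (logw <= logw_obs + 1e-9).sum()) / (n_mc + 1))
    return TestResult(statistic=float(chi2), p_value=p,
                      method=f"freeman-halton-montecarlo-{n_mc}", table=[row1.tolist(), row2.tolist()])


def _log_weights(draws: np.ndarray, cols: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    lg_cols = gammaln(cols + 1.0)
    return (lg_cols - gammaln(draws + 1.0) - gammaln(cols - draws + 1.0)).sum(axis=1)
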