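"""Bootstrap propagation of phenotype measurement uncertainty into
epistatic-coefficient uncertainty, with z-score significance and Bonferroni
correction.

Each pseudoreplicate draws one phenotype per genotype from
Normal(phenotype_mean, phenotype_sd), optionally re-estimates and applies
the power-transform linearization, and decomposes the resulting vector into
epistatic coefficients. Running means and variances are checked every batch
(default 50 pseudoreplicates): the ensemble has converged when every
coefficient's mean and variance changed by less than ``tol`` (default 0.1%)
relative to the previous batch. A z-score per coefficient (bootstrap mean
over bootstrap standard deviation) is converted to a two-sided normal
P-value and Bonferroni-corrected over all non-constant coefficients; the
constant term has no null hypothesis of interest and is not tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

from .gpmap import EncodedGenotypes, GenotypePhenotypeMap, walsh_encode, wyk_encode
from .linear import decompose, fit_additive
from .scale import (
    PowerTransform,
    ScaleDomainError,
    fit_power_transform,
    linearize,
)

__all__ = ["BootstrapSummary", "bootstrap_coefficients", "significance"]

_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class BootstrapSummary:
    """Per-coefficient bootstrap ensemble statistics and significance calls.

    ``mean``/``sd`` are over pseudoreplicates. P-value fields are NaN for
    the constant term, which is excluded from testing; ``m_tested`` is the
    Bonferroni denominator (number of non-constant coefficients).
    """

    names: tuple[str, ...]
    orders: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_pseudoreplicates: int
    converged: bool
    seed: int | None = None
    n_clipped: int = 0
    alpha: float = 0.05
    z: np.ndarray | None = None
    p_raw: np.ndarray | None = None
    p_bonferroni: np.ndarray | None = None
    significant: np.ndarray | None = None
    stars: list[str] | None = None
    m_tested: int = 0

    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "n_pseudoreplicates": self.n_pseudoreplicates,
            "converged": self.converged,
            "alpha": self.alpha,
            "m_tested": self.m_tested,
            "n_clipped_linearizations": self.n_clipped,
        }


def _relative_change(new: np.ndarray, old: np.ndarray) -> np.ndarray:
    denom = np.maximum(np.maximum(np.abs(new), np.abs(old)), 1e-300)
    return np.abs(new - old) / denom


def bootstrap_coefficients(
    gpm: GenotypePhenotypeMap,
    scale: str = "power",
    refit_transform: bool = True,
    point_transform: PowerTransform | None = None,
    max_order: int | str = "full",
    batch: int = 50,
    tol: float = 1e-3,
    max_reps: int = 100_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> BootstrapSummary:
    """Bootstrap the epistatic coefficients of a map with phenotype noise.

    Parameters
    ----------
    scale
        ``"power"`` linearizes every pseudoreplicate with a power transform
        (refit per pseudoreplicate when ``refit_transform``, else the
        supplied or precomputed ``point_transform`` is reused);
        ``"none"`` decomposes the raw pseudo-phenotypes.
    batch, tol
        Convergence is declared when, after a batch, every coefficient's
        running mean and running variance changed by less than ``tol``
        (relative). With zero phenotype noise every pseudoreplicate is
        identical and the loop stops after the second batch.
    max_reps
        Hard cap; reaching it without convergence emits a warning and
        returns the summary with ``converged=False``.

    Occasional pseudoreplicates can fall outside the representable range of
    their fitted scale; their back-transform bracket is clipped to a tiny
    positive value and the event counted in ``n_clipped``.

    Fully reproducible for a given seed.
    """
    design = (
        walsh_encode(gpm, max_order) if gpm.is_binary else wyk_encode(gpm, max_order)
    )
    means = gpm.phenotypes
    sds = gpm.stdevs
    G = len(means)
    rng = np.random.default_rng(seed)

    if scale == "power" and point_transform is None:
        # Anchor transform from the observed means: reused directly when not
        # refitting, otherwise warm-starts every per-pseudoreplicate refit.
        additive = fit_additive(gpm)
        point_transform = fit_power_transform(additive.p_add, means)
    warm = (
        None
        if point_transform is None
        else (point_transform.lam, point_transform.A, point_transform.B)
    )

    C = design.n_columns
    count = 0
    run_mean = np.zeros(C)
    run_m2 = np.zeros(C)  # sum of squared deviations (Welford)
    prev_mean = None
    prev_var = None
    converged = False
    n_clipped = 0

    # Masks for the fast per-site background averages used to re-estimate
    # the additive prediction inside each pseudoreplicate.
    mut_masks, wt_masks = _additive_masks(gpm)
    wt_index = gpm.genotypes.index(gpm.wildtype)

    X = design.matrix
    hadamard = design.is_square and np.array_equal(X.T @ X, G * np.eye(C, dtype=X.dtype))

    while count < max_reps:
        n_draw = min(batch, max_reps - count)
        pseudo = rng.normal(means[None, :], sds[None, :], size=(n_draw, G))
        if scale == "none":
            if hadamard:
                betas = pseudo @ X / G
            else:
                betas = np.vstack(
                    [decompose(row, design).values for row in pseudo]
                )
        else:
            rows = []
            for row in pseudo:
                p_add = _fast_p_add(row, mut_masks, wt_masks, wt_index)
                pt = (
                    fit_power_transform(p_add, row, init=warm)
                    if refit_transform
                    else point_transform
                )
                lin, clipped = _safe_linearize(row, pt)
                n_clipped += clipped
                rows.append(lin)
            lin_arr = np.vstack(rows)
            if hadamard:
                betas = lin_arr @ X / G
            else:
                betas = np.vstack(
                    [decompose(row, design).values for row in lin_arr]
                )
        # merge the batch into the running moments (parallel Welford: exact
        # zeros for identical pseudoreplicates, no catastrophic cancellation)
        b_mean = betas.mean(axis=0)
        b_m2 = ((betas - b_mean) ** 2).sum(axis=0)
        delta = b_mean - run_mean
        new_count = count + n_draw
        run_m2 += b_m2 + delta**2 * (count * n_draw / new_count)
        run_mean += delta * (n_draw / new_count)
        count = new_count

        cur_mean = run_mean.copy()
        cur_var = run_m2 / count
        if prev_mean is not None:
            if (
                np.all(_relative_change(cur_mean, prev_mean) < tol)
                and np.all(_relative_change(cur_var, prev_var) < tol)
            ):
                converged = True
        prev_mean, prev_var = cur_mean, cur_var
        if converged:
            break

    if not converged:
        warnings.warn(
            f"bootstrap did not converge within {max_reps} pseudoreplicates",
            ConvergenceWarning,
            stacklevel=2,
        )

    mean = run_mean
    sd = np.sqrt(run_m2 / max(count - 1, 1))  # unbiased (ddof=1)
    summary = BootstrapSummary(
        names=tuple(design.column_names()),
        orders=design.orders.copy(),
        mean=mean,
        sd=sd,
        n_pseudoreplicates=count,
        converged=converged,
        seed=seed,
        n_clipped=n_clipped,
        alpha=alpha,
    )
    return significance(summary, alpha)


def _additive_masks(gpm: GenotypePhenotypeMap):
    genotypes = gpm.genotypes
    mut_masks, wt_masks = [], []
    for site in gpm.sites:
        at_site = np.array([g[site.index] for g in genotypes])
        wt = at_site == site.wildtype_state
        for state in site.mutant_states:
            mut_masks.append(at_site == state)
            wt_masks.append(wt)
    return mut_masks, wt_masks


def _fast_p_add(
    phen: np.ndarray, mut_masks, wt_masks, wt_index: int
) -> np.ndarray:
    p_add = np.full(len(phen), phen[wt_index])
    for mut, wt in zip(mut_masks, wt_masks):
        p_add[mut] += phen[mut].mean() - phen[wt].mean()
    return p_add


def _safe_linearize(p: np.ndarray, pt: PowerTransform):
    """Linearize, clipping out-of-range values to the domain edge."""
    try:
        return linearize(p, pt), 0
    except ScaleDomainError:
        if abs(pt.lam) < 1e-5:
            raise
        bracket = pt.lam * pt.GM ** (pt.lam - 1.0) * (p - pt.B) + 1.0
        clipped = int(np.sum(bracket <= 0))
        bracket = np.maximum(bracket, 1e-10)
        return np.power(bracket, 1.0 / pt.lam) - pt.A, clipped


def significance(summary: BootstrapSummary, alpha: float = 0.05) -> BootstrapSummary:
    """z-scores, two-sided normal P-values and Bonferroni correction.

    z = bootstrap mean / bootstrap sd. A coefficient with zero bootstrap sd
    gets p_raw = 0 when its mean is nonzero (the ensemble is certain) and
    p_raw = 1 when the mean is zero too. The constant term is not tested.
    """
    tested = summary.orders > 0
    m = int(tested.sum())
    C = len(summary.mean)
    z = np.zeros(C)
    p_raw = np.full(C, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        nonzero_sd = summary.sd > 0
        z[nonzero_sd] = summary.mean[nonzero_sd] / summary.sd[nonzero_sd]
    zero_sd = ~nonzero_sd
    z[zero_sd & (summary.mean != 0)] = np.inf * np.sign(
        summary.mean[zero_sd & (summary.mean != 0)]
    )
    p_raw[tested] = 2.0 * norm.sf(np.abs(z[tested]))
    p_raw[tested & zero_sd & (summary.mean != 0)] = 0.0
    p_raw[tested & zero_sd & (summary.mean == 0)] = 1.0

    p_bonf = np.full(C, np.nan)
    p_bonf[tested] = np.minimum(1.0, m * p_raw[tested])
    significant = np.zeros(C, dtype=bool)
    significant[tested] = p_bonf[tested] < alpha
    stars = []
    for c in range(C):
        if not tested[c] or np.isnan(p_bonf[c]):
            stars.append("ns")
            continue
        label = "ns"
        for threshold, s in _STAR_THRESHOLDS:
            if p_bonf[c] < threshold:
                label = s
                break
        stars.append(label)
    return replace(
        summary,
        alpha=alpha,
        z=z,
        p_raw=p_raw,
        p_bonferroni=p_bonf,
        significant=significant,
        stars=stars,
        m_tested=m,
    )
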