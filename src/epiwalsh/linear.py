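"""Linear epistasis analysis: additive model, Walsh decomposition,
truncated-order models and order-wise variance partitioning.

The additive model estimates the average effect of each mutation across all
genetic backgrounds and predicts a phenotype for every genotype by summing
the effects of its mutations. The Walsh decomposition inverts the ±1 design
matrix to express the phenotype vector as epistatic coefficients — the
constant (map center), first-order (average mutational effects), and
interaction terms of every order. Truncated least-squares models quantify
how much phenotypic variation each interaction order explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .gpmap import EncodedGenotypes, GenotypePhenotypeMap, walsh_encode, wyk_encode

__all__ = [
    "AdditiveModel",
    "EpistasisCoefficients",
    "VariancePartition",
    "fit_additive",
    "decompose",
    "reconstruct",
    "partition_variance",
]


@dataclass
class AdditiveModel:
    """Per-mutation average effects and additive phenotype predictions.

    ``avg_effects[j]`` is the mean, over all backgrounds, of the phenotype
    change caused by introducing mutation ``j`` (a non-wild-type state at
    one site). ``p_add[i] = intercept + sum_j avg_effects[j] * x_{i,j}``
    with x in {0, 1}; the intercept is the observed wild-type phenotype, so
    the prediction for the wild type is its measured phenotype.
    """

    mutations: tuple[tuple[int, str], ...]  # (site index, mutant state label)
    avg_effects: np.ndarray
    intercept: float
    p_add: np.ndarray

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)


@dataclass
class EpistasisCoefficients:
    """Order-tagged epistatic coefficients for one design.

    One value per design column; ``orders`` and ``labels`` mirror the
    encoding's column metadata, and ``names`` are the rendered term names
    (1-based site numbers). ``origin_scale`` records whether the phenotypes
    that were decomposed had been linearized first.
    """

    values: np.ndarray
    orders: np.ndarray
    labels: tuple[tuple[tuple[int, int], ...], ...]
    names: tuple[str, ...]
    origin_scale: str = "raw"

    def __post_init__(self) -> None:
        if not (len(self.values) == len(self.orders) == len(self.labels)):
            raise ValueError("values, orders and labels must align")

    def of_order(self, k: int) -> np.ndarray:
        return self.values[self.orders == k]

    @property
    def max_order(self) -> int:
        return int(self.orders.max())

    @property
    def nonconstant(self) -> np.ndarray:
        """Boolean mask selecting every non-constant coefficient."""
        return self.orders > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sites": list(self.names), "order": self.orders, "beta": self.values}
        )


@dataclass
class VariancePartition:
    """Fraction of phenotypic variation explained, by interaction order.

    ``contributions[k-1]`` is the gain in squared Pearson correlation
    (between model fit and observation) when order-k terms join the model;
    ``cumulative[k-1]`` is the fit of the model truncated at order k.
    """

    orders: np.ndarray
    contributions: np.ndarray
    cumulative: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "order": self.orders,
                "contribution": self.contributions,
                "cumulative_fit": self.cumulative,
            }
        )


def _encode_any(gpm: GenotypePhenotypeMap, max_order: int | str) -> EncodedGenotypes:
    return walsh_encode(gpm, max_order) if gpm.is_binary else wyk_encode(gpm, max_order)


def fit_additive(gpm: GenotypePhenotypeMap) -> AdditiveModel:
    """Average effect of each mutation across all backgrounds (Walsh-free).

    For each site and each non-wild-type state, the effect is the mean
    phenotype of genotypes carrying that state minus the mean phenotype of
    genotypes carrying the wild-type state at that site — on a complete map
    this equals the paired average over all backgrounds.
    """
    phen = gpm.phenotypes
    genotypes = gpm.genotypes
    mutations: list[tuple[int, str]] = []
    effects: list[float] = []
    membership: list[np.ndarray] = []
    for site in gpm.sites:
        at_site = np.array([g[site.index] for g in genotypes])
        wt_mask = at_site == site.wildtype_state
        for state in site.mutant_states:
            mask = at_site == state
            mutations.append((site.index, state))
            effects.append(float(phen[mask].mean() - phen[wt_mask].mean()))
            membership.append(mask.astype(float))
    intercept = gpm.wildtype_phenotype()
    X01 = np.column_stack(membership) if membership else np.zeros((len(phen), 0))
    p_add = intercept + X01 @ np.asarray(effects)
    return AdditiveModel(
        mutations=tuple(mutations),
        avg_effects=np.asarray(effects),
        intercept=intercept,
        p_add=p_add,
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[i] for i in sorted(piv[rank:])]


def decompose(
    phenotypes: np.ndarray,
    design: EncodedGenotypes,
    origin_scale: str = "raw",
) -> EpistasisCoefficients:
    """Solve X β = P for the epistatic coefficients.

    For a square orthogonal design (full encoding of a complete map) the
    solution is the exact Hadamard inverse β = Xᵀ P / N; other square
    designs are solved directly and non-square (truncated) designs by
    ordinary least squares. Rank-deficient truncated designs raise with the
    names of the collinear columns.
    """
    phen = np.asarray(phenotypes, dtype=float)
    X = design.matrix
    if phen.shape[0] != X.shape[0]:
        raise ValueError(
            f"{phen.shape[0]} phenotypes for a {X.shape[0]}-row design"
        )
    G, C = X.shape
    if C == G:
        XtX = X.T @ X
        if np.array_equal(XtX, G * np.eye(G, dtype=XtX.dtype)):
            values = (X.T @ phen) / G
        else:
            values = np.linalg.solve(X.astype(float), phen)
    else:
        if np.linalg.matrix_rank(X) < C:
            bad = _collinear_columns(X.astype(float), design.column_names())
            raise np.linalg.LinAlgError(
                f"rank-deficient design; collinear columns: {bad}"
            )
        values, *_ = np.linalg.lstsq(X.astype(float), phen, rcond=None)
    return EpistasisCoefficients(
        values=values,
        orders=design.orders.copy(),
        labels=design.labels,
        names=tuple(design.column_names()),
        origin_scale=origin_scale,
    )


def reconstruct(coefs: EpistasisCoefficients, design: EncodedGenotypes) -> np.ndarray:
    """Phenotypes implied by coefficients under a design: X β."""
    if len(coefs.values) != design.n_columns:
        raise ValueError(
            f"{len(coefs.values)} coefficients for a "
            f"{design.n_columns}-column design"
        )
    return design.matrix @ coefs.values


def _r2(fitted: np.ndarray, observed: np.ndarray) -> float:
    # 1 - SSR/SST: equals the squared Pearson correlation between fit and
    # data for an intercept-bearing least-squares model, and degenerates to
    # 0 (not NaN/noise) when the fit is constant.
    sst = float(np.sum((observed - observed.mean()) ** 2))
    if sst == 0:
        return 0.0
    ssr = float(np.sum((observed - fitted) ** 2))
    return max(0.0, 1.0 - ssr / sst)


def partition_variance(
    phenotypes: np.ndarray,
    gpm: GenotypePhenotypeMap,
    max_order: int | None = None,
) -> VariancePartition:
    """Order-wise variance partition via truncated least-squares models.

    For each truncation order k = 1..L, fit an ordinary-least-squares model
    using all design columns of order <= k; the model fit is the squared
    Pearson correlation between fitted and observed phenotypes. Order k's
    contribution is fit(k) − fit(k−1), with fit(0) = 0 for the
    constant-only model. On a complete binary map the full model
    interpolates, so the contributions sum to 1.
    """
    phen = np.asarray(phenotypes, dtype=float)
    L = max_order if max_order is not None else gpm.n_sites
    full = _encode_any(gpm, L)
    X = full.matrix.astype(float)
    fits = [0.0]
    for k in range(1, L + 1):
        Xk = X[:, full.orders <= k]
        beta, *_ = np.linalg.lstsq(Xk, phen, rcond=None)
        fits.append(_r2(Xk @ beta, phen))
    fits_arr = np.asarray(fits)
    return VariancePartition(
        orders=np.arange(1, L + 1),
        contributions=np.diff(fits_arr),
        cumulative=fits_arr[1:],
    )


def coefficient_table(
    coefs: EpistasisCoefficients,
    beta_sd: np.ndarray | None = None,
    z: np.ndarray | None = None,
    p_raw: np.ndarray | None = None,
    p_bonferroni: np.ndarray | None = None,
    significant: np.ndarray | None = None,
    stars: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the coefficient output table, optionally with bootstrap
    uncertainty columns. Row order follows the design's column ordering."""
    df = coefs.to_frame()
    for name, col in [
        ("beta_sd", beta_sd),
        ("z", z),
        ("p_raw", p_raw),
        ("p_bonferroni", p_bonferroni),
        ("significant", significant),
        ("stars", stars),
    ]:
        if col is not None:
            df[name] = col
    return df
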