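"""Simulation of genotype-phenotype maps with known epistasis, scale and noise.

The generator draws random epistatic coefficients up to a chosen order,
builds the linear phenotypes P = X β on the full binary Walsh design, pushes
them through an optional monotone nonlinear scale, adds replicate
measurement noise, and packages the result as a regular
:class:`~epiwalsh.gpmap.GenotypePhenotypeMap` together with the generating
ground truth. This is the engine for the validation experiments: recovering
known coefficients through a saturating scale, and demonstrating the
spurious high-order epistasis a linear analysis extracts from a purely
additive but nonlinear map.

Coefficient magnitudes default to Normal(0, 1) for first-order terms and
Normal(0, 0.35) for every higher order; both are free parameters of the
generator. Before a saturating scale is applied, the linear phenotypes are
shifted so their minimum sits at the scale's lower fixed point (0); the
stored ground-truth coefficients are those of the shifted linear phenotypes
(an affine change that leaves coefficient correlations intact).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .gpmap import GenotypePhenotypeMap, walsh_encode
from .linear import EpistasisCoefficients, fit_additive, reconstruct
from .scale import saturating_scale, transform as power_transform_eval, PowerTransform

__all__ = [
    "SimulatedMap",
    "random_coefficients",
    "build_map",
    "padd_vs_pobs_table",
    "DEFAULT_ORDER1_SD",
    "DEFAULT_HIGHER_SD",
]

DEFAULT_ORDER1_SD = 1.0
DEFAULT_HIGHER_SD = 0.35


@dataclass
class SimulatedMap:
    """A synthetic map plus the ground truth that generated it.

    ``true_coefs`` are the coefficients of the *linear-scale* phenotypes
    actually fed to the scale function (i.e. after any affine pre-scaling),
    so that with ``scale_spec=None`` and no noise, decomposing the map
    returns them to solver tolerance. ``linear_phenotypes`` are those same
    noiseless linear-scale values; ``scaled_phenotypes`` are the noiseless
    values after the scale.
    """

    true_coefs: EpistasisCoefficients
    scale_spec: tuple | None
    noise_sd: float
    seed: int | None
    map: GenotypePhenotypeMap
    linear_phenotypes: np.ndarray
    scaled_phenotypes: np.ndarray

    def truth_document(self) -> dict:
        """JSON-serializable sidecar with the generating ground truth."""
        return {
            "true_beta": self.true_coefs.values.tolist(),
            "names": list(self.true_coefs.names),
            "orders": self.true_coefs.orders.tolist(),
            "scale_spec": list(self.scale_spec) if self.scale_spec else None,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
        }


def _binary_skeleton(L: int) -> GenotypePhenotypeMap:
    genotypes = ["".join(bits) for bits in _binary_strings(L)]
    return GenotypePhenotypeMap.from_arrays(genotypes, np.zeros(len(genotypes)))


def _binary_strings(L: int):
    import itertools

    return itertools.product("01", repeat=L)


def random_coefficients(
    L: int,
    order: int,
    magnitudes: dict[int, float] | None = None,
    seed: int | np.random.Generator | None = None,
) -> EpistasisCoefficients:
    """Draw zero-centered random epistatic coefficients for an L-site map.

    Every full-design column up to interaction order ``order`` receives an
    independent Normal(0, s_k) draw, where s_k is ``magnitudes[k]``
    (defaults: s_1 = 1, s_k = 0.35 for k >= 2); columns above ``order`` and
    the constant term are zero. Deterministic for a given seed.
    """
    if not 1 <= order <= L:
        raise ValueError(f"order must be in [1, {L}]; got {order}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    design = walsh_encode(_binary_skeleton(L), "full")
    sd_of = dict(magnitudes) if magnitudes else {}
    values = np.zeros(design.n_columns)
    for c, k in enumerate(design.orders):
        if k == 0 or k > order:
            continue
        s_k = sd_of.get(int(k), DEFAULT_ORDER1_SD if k == 1 else DEFAULT_HIGHER_SD)
        values[c] = rng.normal(0.0, s_k)
    return EpistasisCoefficients(
        values=values,
        orders=design.orders.copy(),
        labels=design.labels,
        names=tuple(design.column_names()),
        origin_scale="linearized",
    )


def _apply_scale(p: np.ndarray, scale_spec: tuple | None):
    """Apply the scale; returns (scaled, affine (a, b) applied beforehand)."""
    if scale_spec is None:
        return p.copy(), (1.0, 0.0)
    kind = scale_spec[0]
    if kind == "saturating":
        K = float(scale_spec[1])
        # Shift so the smallest phenotype sits at the scale's lower fixed
        # point (0); the span is left untouched, so larger maps reach deeper
        # into saturation, as when the scale acts on raw simulated values.
        b = -float(p.min())
        u = p + b
        return saturating_scale(u, K), (1.0, b)
    if kind == "power":
        lam, A, B = (float(v) for v in scale_spec[1:4])
        GM = float(np.exp(np.mean(np.log(p + A))))
        pt = PowerTransform(
            lam=lam, A=A, B=B, GM=GM,
            residuals=np.zeros(0), objective=0.0, n_points=len(p),
        )
        return power_transform_eval(p, pt), (1.0, 0.0)
    if callable(kind):
        return np.asarray(kind(p), dtype=float), (1.0, 0.0)
    raise ValueError(f"unknown scale_spec {scale_spec!r}")


def build_map(
    coefs: EpistasisCoefficients,
    scale_spec: tuple | None = None,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int | np.random.Generator | None = None,
    noise_model: str = "replicates",
) -> SimulatedMap:
    """Realize a genotype-phenotype map from generating coefficients.

    Phenotypes are P = X β on the full Walsh design, transformed pointwise
    by ``scale_spec`` (``None``, ``("saturating", K)``, ``("power", lam, A,
    B)`` or ``(callable,)``), then observed with Gaussian measurement noise:

    * ``noise_model="replicates"`` draws ``n_replicates`` values per
      genotype from Normal(scaled, noise_sd) and records their sample mean,
      sample standard deviation and count — mimicking an experiment that
      reports replicate statistics;
    * ``noise_model="known"`` perturbs the mean once by Normal(0, noise_sd)
      and records ``noise_sd`` itself as the stdev — the idealized case in
      which the measurement error is known exactly.

    The stored ground truth is expressed on the (possibly affinely
    pre-scaled) linear scale; see :class:`SimulatedMap`.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    L = 1 + max((max(s for s, _ in label) for label in coefs.labels if label), default=0)
    skeleton = _binary_skeleton(L)
    design = walsh_encode(skeleton, "full")
    p_linear_raw = reconstruct(coefs, design)
    p_scaled, (a, b) = _apply_scale(p_linear_raw, scale_spec)

    true_values = a * coefs.values.copy()
    true_values[coefs.orders == 0] += b  # affine pre-scale shifts the constant
    true_coefs = EpistasisCoefficients(
        values=true_values,
        orders=coefs.orders.copy(),
        labels=coefs.labels,
        names=coefs.names,
        origin_scale="linearized",
    )
    p_linear = a * p_linear_raw + b

    G = len(p_scaled)
    if noise_sd > 0:
        if noise_model == "replicates":
            if n_replicates < 2:
                raise ValueError("replicate noise needs n_replicates >= 2")
            draws = rng.normal(p_scaled[:, None], noise_sd, size=(G, n_replicates))
            means = draws.mean(axis=1)
            sds = draws.std(axis=1, ddof=1)
            ns = np.full(G, n_replicates)
        elif noise_model == "known":
            means = p_scaled + rng.normal(0.0, noise_sd, size=G)
            sds = np.full(G, float(noise_sd))
            ns = np.full(G, n_replicates)
        else:
            raise ValueError(f"unknown noise_model {noise_model!r}")
    else:
        means, sds, ns = p_scaled.copy(), np.zeros(G), np.full(G, n_replicates)

    gpm = GenotypePhenotypeMap.from_arrays(
        skeleton.genotypes, means, stdevs=sds, n=ns
    )
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return SimulatedMap(
        true_coefs=true_coefs,
        scale_spec=scale_spec,
        noise_sd=float(noise_sd),
        seed=None if seed_val is None else int(seed_val),
        map=gpm,
        linear_phenotypes=p_linear,
        scaled_phenotypes=p_scaled,
    )


def padd_vs_pobs_table(sim: SimulatedMap) -> np.ndarray:
    """(G, 2) array of (estimated additive phenotype, observed phenotype).

    The additive prediction is estimated from the realized map itself (as it
    would be for real data, where the generating truth is unknown), so this
    is exactly the input to the power-transform scale fit.
    """
    additive = fit_additive(sim.map)
    return np.column_stack([additive.p_add, sim.map.phenotypes])
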