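"""Synthetic data with the statistical structure the analyses assume.

The default two-group scenario mirrors the calibration design: a normative
group with latent trait ~ N(0, 1), n = 721, and a clinical group with
elevated mean ~ N(1.01, 1.17^2), n = 743, responding to the published
8-item bank.  DIF can be injected as uniform intercept shifts and/or slope
scalings for chosen items in chosen groups, and external covariates can be
generated with prescribed zero-order correlations to the latent trait,
optionally routed through a shared confounder (a neuroticism analogue).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .bank import ItemParameters, LatentDist, gafs8_bank
from .data import ResponseMatrix
from .grm import category_probabilities, expected_item_score

__all__ = [
    "GroupSpec",
    "DIFShift",
    "SimulationConfig",
    "simulate_responses",
    "simulate_bifactor_ordinal",
    "simulate_covariates",
    "default_two_group_config",
    "load_simulation_config",
]


@dataclasses.dataclass(frozen=True)
class GroupSpec:
    """Latent distribution and sample size for one group."""

    dist: LatentDist
    n: int

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError("group size must be positive")


@dataclasses.dataclass(frozen=True)
class DIFShift:
    """Parameter perturbation applied to one item in one group.

    ``d_shift`` is added to every intercept (uniform shift: positive makes
    the item "easier" in that group); ``a_scale`` multiplies the slope.
    """

    d_shift: float = 0.0
    a_scale: float = 1.0


@dataclasses.dataclass
class SimulationConfig:
    bank: list
    group_specs: Mapping[str, GroupSpec]
    dif_spec: Mapping[tuple, DIFShift] = dataclasses.field(default_factory=dict)
    seed: int = 20210810

    def shifted_item(self, item: ItemParameters, group: str) -> ItemParameters:
        shift = self.dif_spec.get((item.label, group))
        if shift is None:
            return item
        d = tuple(np.asarray(item.d) + shift.d_shift)
        a = item.a * shift.a_scale
        return ItemParameters(item.label, a, d)  # ordering re-validated here


def default_two_group_config(
    n_norm: int = 721, n_clin: int = 743, seed: int = 20210810,
    dif_spec: Mapping | None = None, bank=None,
) -> SimulationConfig:
    """The calibration-design scenario: N(0,1) vs N(1.01, 1.17^2)."""
    return SimulationConfig(
        bank=bank if bank is not None else gafs8_bank(),
        group_specs={
            "normative": GroupSpec(LatentDist(0.0, 1.0), n_norm),
            "clinical": GroupSpec(LatentDist(1.01, 1.17), n_clin),
        },
        dif_spec={} if dif_spec is None else dict(dif_spec),
        seed=seed,
    )


def load_simulation_config(path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML file.

    Layout::

        seed: 20210810
        bank: bank.csv            # optional; defaults to the GAFS-8 bank
        groups:
          normative: {mu: 0.0, sigma: 1.0, n: 721}
          clinical:  {mu: 1.01, sigma: 1.17, n: 743}
        dif:                      # optional
          - {item: 6, group: clinical, d_shift: 0.75, a_scale: 1.0}
    """
    import yaml

    from .bank import read_bank

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    bank = read_bank(raw["bank"]) if "bank" in raw else gafs8_bank()
    groups = {
        name: GroupSpec(
            LatentDist(float(spec["mu"]), float(spec["sigma"])), int(spec["n"])
        )
        for name, spec in raw["groups"].items()
    }
    dif_spec = {
        (entry["item"], entry["group"]): DIFShift(
            d_shift=float(entry.get("d_shift", 0.0)),
            a_scale=float(entry.get("a_scale", 1.0)),
        )
        for entry in raw.get("dif", [])
    }
    return SimulationConfig(
        bank=bank, group_specs=groups, dif_spec=dif_spec,
        seed=int(raw.get("seed", 20210810)),
    )


def simulate_responses(config: SimulationConfig, return_theta: bool = False):
    """Draw graded responses group by group.

    Latent traits are drawn from each group's normal distribution; responses
    are sampled from the category probabilities of the (possibly
    DIF-shifted) bank.  Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    blocks, glabels, thetas = [], [], []
    for gname, spec in config.group_specs.items():
        theta = rng.normal(spec.dist.mu, spec.dist.sigma, size=spec.n)
        cols = []
        for item in config.bank:
            it = config.shifted_item(item, gname)
            probs = category_probabilities(it, theta)  # (n, K)
            u = rng.random(spec.n)
            cdf = np.cumsum(probs, axis=1)
            cols.append((u[:, None] < cdf).argmax(axis=1) + 1)
        blocks.append(np.column_stack(cols).astype(float))
        glabels.append(np.repeat(gname, spec.n))
        thetas.append(theta)
    rm = ResponseMatrix(
        np.vstack(blocks), [it.label for it in config.bank],
        np.concatenate(glabels),
    )
    if return_theta:
        return rm, np.concatenate(thetas)
    return rm


def simulate_bifactor_ordinal(structure, n: int, seed: int = 20210810,
                              return_factors: bool = False):
    """Ordinal responses from a bifactor structure.

    General and specific factors are independent standard normals; each
    item's continuous response is the loading-weighted factor sum plus a
    residual scaled so the total variance is 1, then cut at the (probit)
    thresholds into categories 1..K.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    factors = sorted({f for f, _ in structure.iter_specifics()})
    general = rng.standard_normal(n)
    spec_draws = {f: rng.standard_normal(n) for f in factors}
    cols = []
    for i, item in enumerate(structure.items):
        lam_g = structure.general_loadings[i]
        y = lam_g * general
        h2 = lam_g**2
        for fac, lam in structure.item_specifics(item):
            y = y + lam * spec_draws[fac]
            h2 += lam**2
        if h2 > 1:
            raise ValueError(f"item {item}: communality {h2:.3f} > 1")
        y = y + np.sqrt(1.0 - h2) * rng.standard_normal(n)
        tau = np.asarray(structure.thresholds[i])
        cols.append(np.searchsorted(tau, y) + 1)
    rm = ResponseMatrix(np.column_stack(cols).astype(float),
                        list(structure.items), None)
    if return_factors:
        return rm, general, spec_draws
    return rm


def simulate_covariates(
    theta: np.ndarray,
    targets: Mapping[str, tuple],
    confounder_r: float = 0.475,
    seed: int = 20210810,
    confounder_name: str = "confounder",
) -> pd.DataFrame:
    """External covariates with prescribed correlations to the latent trait.

    Each covariate is ``a * theta_std + b * W + noise`` where the confounder
    W itself correlates ``confounder_r`` with theta.  ``targets`` maps a
    covariate name to ``(target_r, confounder_share)``: the zero-order
    correlation with theta and the fraction of it routed through W (share 1
    means the association is fully confounder-mediated, so the partial
    correlation given W is zero in expectation).
    """
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta, dtype=float)
    z = (theta - theta.mean()) / theta.std()
    n = z.size
    rho_w = float(confounder_r)
    if not abs(rho_w) < 1:
        raise ValueError("|confounder_r| must be < 1")
    W = rho_w * z + np.sqrt(1 - rho_w**2) * rng.standard_normal(n)
    out = {confounder_name: W}
    for name, (r_t, share) in targets.items():
        if not abs(r_t) < 1:
            raise ValueError(f"{name}: |target r| must be < 1")
        share = float(share)
        if rho_w == 0 and share != 0:
            raise ValueError(f"{name}: cannot route through an uncorrelated confounder")
        b = share * r_t / rho_w if share != 0 else 0.0
        a = (1.0 - share) * r_t
        var_sys = a * a + b * b + 2 * a * b * rho_w
        if var_sys > 1:
            raise ValueError(f"{name}: infeasible correlation spec")
        out[name] = a * z + b * W + np.sqrt(1 - var_sys) * rng.standard_normal(n)
    return pd.DataFrame(out)
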