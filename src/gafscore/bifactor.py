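"""Model-based bifactor coefficients and the polychoric utility.

Works from a loading/threshold structure (one general factor, optional
specific and method factors, probit-scale thresholds): categorical omegas
per Green-Yang (expected covariances of the categorized items via
bivariate-normal orthant probabilities), the explained-common-variance
(ECV) family, and the percentage of uncontaminated correlations (PUC).
A pair of items counts as contaminated when it shares ANY non-general
factor — specific subscale or method factor alike.
"""

from __future__ import annotations

import dataclasses
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import multivariate_normal, norm

__all__ = [
    "BifactorStructure",
    "BifactorIndices",
    "puc",
    "ecv",
    "omega_categorical",
    "bifactor_indices",
    "polychoric",
    "tas20_structure",
    "gafs11_structure",
    "TAS20_SUBSCALES",
    "TAS20_METHOD_FACTOR",
    "read_structure",
]

#: TAS-20 subscale membership: difficulty identifying feelings (DIF),
#: difficulty describing feelings (DDF), externally oriented thinking (EOT).
TAS20_SUBSCALES = {
    "DIF": frozenset({1, 3, 6, 7, 9, 13, 14}),
    "DDF": frozenset({2, 4, 11, 12, 17}),
    "EOT": frozenset({5, 8, 10, 15, 16, 18, 19, 20}),
}

#: Reverse-coded items share a common method factor (standard TAS-20 key).
TAS20_METHOD_FACTOR = frozenset({4, 5, 10, 18, 19})


@dataclasses.dataclass
class BifactorStructure:
    """Bifactor loading/threshold structure.

    Every item loads on the general factor; ``specifics`` maps each item
    label to a list of (factor name, loading) memberships (at most one
    subscale plus optionally a method factor).  Thresholds, when present,
    are strictly increasing probit cut points per item.
    """

    items: list
    general_loadings: np.ndarray
    specifics: dict
    thresholds: list | None = None

    def __post_init__(self):
        self.general_loadings = np.asarray(self.general_loadings, dtype=float)
        if len(self.items) != self.general_loadings.size:
            raise ValueError("one general loading per item required")
        for i, item in enumerate(self.items):
            h2 = self.general_loadings[i] ** 2 + sum(
                l**2 for _, l in self.specifics.get(item, [])
            )
            if h2 > 1 + 1e-9:
                raise ValueError(f"item {item}: communality {h2:.3f} exceeds 1")
        if self.thresholds is not None:
            for item, tau in zip(self.items, self.thresholds):
                tau = np.asarray(tau)
                if np.any(np.diff(tau) <= 0):
                    raise ValueError(f"item {item}: thresholds must increase")

    def item_specifics(self, item):
        return self.specifics.get(item, [])

    def iter_specifics(self):
        for item in self.items:
            for fac, lam in self.item_specifics(item):
                yield fac, lam

    def factor_names(self):
        return sorted({f for f, _ in self.iter_specifics()})


def _membership_structure(memberships: dict, items) -> BifactorStructure:
    """Structure with unit bookkeeping loadings (enough for PUC)."""
    specifics = {
        it: [(fac, 0.0) for fac, members in memberships.items() if it in members]
        for it in items
    }
    return BifactorStructure(
        items=list(items),
        general_loadings=np.zeros(len(items)),
        specifics=specifics,
    )


def tas20_structure() -> BifactorStructure:
    """Membership structure of the full 20-item TAS-20 bifactor model:
    three subscale factors plus the reverse-coded method factor."""
    memberships = dict(TAS20_SUBSCALES)
    memberships["REV"] = TAS20_METHOD_FACTOR
    return _membership_structure(memberships, list(range(1, 21)))


def gafs11_structure() -> BifactorStructure:
    """Membership structure of the reduced 11-item model: the 7 DIF items
    and the 4 forward-coded DDF items as the two specific factors."""
    items = [1, 2, 3, 6, 7, 9, 11, 12, 13, 14, 17]
    memberships = {
        "DIF": TAS20_SUBSCALES["DIF"],
        "DDF": frozenset({2, 11, 12, 17}),
    }
    return _membership_structure(memberships, items)


def puc(structure: BifactorStructure) -> float:
    """Percentage (as a proportion) of uncontaminated correlations.

    Direct enumeration over all C(J, 2) item pairs; a pair is contaminated
    iff the two items share at least one specific or method factor.
    """
    J = len(structure.items)
    if J < 2:
        raise ValueError("PUC needs at least 2 items")
    fac_sets = {
        it: {f for f, _ in structure.item_specifics(it)} for it in structure.items
    }
    pairs = list(combinations(structure.items, 2))
    contaminated = sum(bool(fac_sets[i] & fac_sets[j]) for i, j in pairs)
    return 1.0 - contaminated / len(pairs)


@dataclasses.dataclass
class ECVResult:
    ecv: float
    item_ecv: dict
    s_ecv: dict


def ecv(structure: BifactorStructure) -> ECVResult:
    """Explained common variance of the general factor.

    ECV = sum(lambda_G^2) / (sum(lambda_G^2) + sum(lambda_spec^2)); the
    item- and subscale-level versions apply the same ratio over one item or
    one subscale's item set.
    """
    lg2 = structure.general_loadings**2
    ls2 = np.array([
        sum(l**2 for _, l in structure.item_specifics(it))
        for it in structure.items
    ])
    total = lg2.sum() + ls2.sum()
    if total <= 0:
        raise ValueError("all loadings are zero")
    item_ecv = {}
    for i, it in enumerate(structure.items):
        denom = lg2[i] + ls2[i]
        item_ecv[it] = float(lg2[i] / denom) if denom > 0 else np.nan
    s_ecv = {}
    for fac in structure.factor_names():
        idx = [i for i, it in enumerate(structure.items)
               if fac in {f for f, _ in structure.item_specifics(it)}]
        if not idx:
            continue
        denom = lg2[idx].sum() + ls2[idx].sum()
        s_ecv[fac] = float(lg2[idx].sum() / denom) if denom > 0 else np.nan
    return ECVResult(ecv=float(lg2.sum() / total), item_ecv=item_ecv, s_ecv=s_ecv)


# ---------------------------------------------------------------------------
# Green-Yang categorical omegas
# ---------------------------------------------------------------------------

def _implied_corr(structure: BifactorStructure, which: str, subscale=None):
    """Model-implied latent correlations restricted to a factor subset."""
    items = structure.items
    J = len(items)
    lg = structure.general_loadings
    facs = structure.factor_names()
    lam = {f: np.zeros(J) for f in facs}
    for i, it in enumerate(items):
        for f, l in structure.item_specifics(it):
            lam[f][i] = l
    if which == "all":
        R = np.outer(lg, lg) + sum(np.outer(lam[f], lam[f]) for f in facs)
    elif which == "general":
        R = np.outer(lg, lg)
    elif which == "specific":
        if subscale is None:
            raise ValueError("subscale required")
        R = np.outer(lam[subscale], lam[subscale])
    else:
        raise ValueError(which)
    return R


def _bvn_cdf_grid(tau_i, tau_j, rho):
    """Bivariate normal CDF on the threshold grid, batched per pair."""
    rho = float(np.clip(rho, -0.9999, 0.9999))
    pts = np.array([(s, t) for s in tau_i for t in tau_j])
    mvn = multivariate_normal(mean=[0.0, 0.0],
                              cov=[[1.0, rho], [rho, 1.0]],
                              allow_singular=True)
    return mvn.cdf(pts).reshape(len(tau_i), len(tau_j))


def _cat_cov(tau_i, tau_j, rho) -> float:
    """Covariance of threshold-categorized variables given latent rho.

    With X = #thresholds exceeded, Cov(X_i, X_j) =
    sum_k sum_l [Phi2(tau_ik, tau_jl; rho) - Phi(tau_ik) Phi(tau_jl)].
    """
    if abs(rho) >= 1 - 1e-9:
        rho = np.sign(rho) * (1 - 1e-9)
    cdf2 = _bvn_cdf_grid(tau_i, tau_j, rho)
    return float(np.sum(cdf2 - np.outer(norm.cdf(tau_i), norm.cdf(tau_j))))


def omega_categorical(structure: BifactorStructure, which: str = "total",
                      subscale=None) -> float:
    """Green-Yang model-based reliability of the (sub)scale sum score.

    ``total``: all common factors in the numerator; ``hierarchical``:
    general factor only; ``subscale`` / ``hier_subscale``: the same two
    numerators restricted to one subscale's items (``hier_subscale`` uses
    the specific factor alone).  Denominators use the full implied
    correlation matrix with unit diagonal (total variance of the
    categorized items).
    """
    if structure.thresholds is None:
        raise ValueError("omega needs thresholds")
    J = len(structure.items)
    R_full = _implied_corr(structure, "all")
    R_total = R_full.copy()
    np.fill_diagonal(R_total, 1.0)
    if np.linalg.eigvalsh(R_total).min() < -1e-8:
        raise ValueError("implied correlation matrix is not positive semi-definite")
    if which in ("total", "hierarchical"):
        idx = list(range(J))
        R_num = _implied_corr(structure, "all" if which == "total" else "general")
    elif which in ("subscale", "hier_subscale"):
        if subscale is None:
            raise ValueError("subscale name required")
        idx = [i for i, it in enumerate(structure.items)
               if subscale in {f for f, _ in structure.item_specifics(it)}]
        if not idx:
            raise ValueError(f"no items on subscale {subscale!r}")
        R_num = (
            _implied_corr(structure, "all") if which == "subscale"
            else _implied_corr(structure, "specific", subscale)
        )
    else:
        raise ValueError(which)
    tau = [np.asarray(structure.thresholds[i]) for i in idx]
    num = 0.0
    den = 0.0
    for a in range(len(idx)):
        for b in range(len(idx)):
            i, j = idx[a], idx[b]
            num += _cat_cov(tau[a], tau[b], R_num[i, j])
            rho_den = 1.0 if i == j else R_full[i, j]
            den += _cat_cov(tau[a], tau[b], rho_den)
    if den <= 0:
        raise ValueError("non-positive implied total variance")
    return float(num / den)


@dataclasses.dataclass
class BifactorIndices:
    omega_t: float
    omega_h: float
    omega_s: dict
    omega_hs: dict
    ecv: float
    item_ecv: dict
    s_ecv: dict
    puc: float


def bifactor_indices(structure: BifactorStructure) -> BifactorIndices:
    """The full coefficient set for one structure."""
    e = ecv(structure)
    return BifactorIndices(
        omega_t=omega_categorical(structure, "total"),
        omega_h=omega_categorical(structure, "hierarchical"),
        omega_s={
            f: omega_categorical(structure, "subscale", f)
            for f in structure.factor_names()
        },
        omega_hs={
            f: omega_categorical(structure, "hier_subscale", f)
            for f in structure.factor_names()
        },
        ecv=e.ecv,
        item_ecv=e.item_ecv,
        s_ecv=e.s_ecv,
        puc=puc(structure),
    )


# ---------------------------------------------------------------------------
# polychoric correlation
# ---------------------------------------------------------------------------

def _thresholds_from_margins(x: np.ndarray):
    cats, counts = np.unique(x, return_counts=True)
    if cats.size < 2:
        raise ValueError("need at least 2 observed categories")
    cum = np.cumsum(counts)[:-1] / x.size
    return cats, norm.ppf(cum)


def polychoric(x, y) -> float:
    """Two-step polychoric correlation of two ordinal vectors.

    Thresholds come from the inverse-normal marginal proportions; the
    latent correlation maximizes the bivariate-normal contingency-table
    likelihood by bounded 1-D search.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    ok = np.isfinite(x.astype(float)) & np.isfinite(y.astype(float))
    x, y = x[ok], y[ok]
    cats_x, tx = _thresholds_from_margins(x)
    cats_y, ty = _thresholds_from_margins(y)
    ix = np.searchsorted(cats_x, x)
    iy = np.searchsorted(cats_y, y)
    table = np.zeros((cats_x.size, cats_y.size))
    np.add.at(table, (ix, iy), 1.0)
    tx_pad = np.concatenate([[-np.inf], tx, [np.inf]])
    ty_pad = np.concatenate([[-np.inf], ty, [np.inf]])

    def negll(rho):
        big = 8.0
        cdf = _bvn_cdf_grid(np.clip(tx_pad, -big, big),
                            np.clip(ty_pad, -big, big), rho)
        cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
        return -float(np.sum(table * np.log(np.maximum(cell, 1e-12))))

    res = minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-5})
    return float(res.x)


def read_structure(path) -> BifactorStructure:
    """Read a structure file: columns item, lambda_general, specific_factor,
    lambda_specific, method_factor, lambda_method, t1..tK-1 (threshold and
    loading columns optional)."""
    df = pd.read_csv(path)
    items = df["item"].tolist()
    lg = df.get("lambda_general", pd.Series(np.zeros(len(df)))).to_numpy(float)
    specifics = {}
    for _, row in df.iterrows():
        entry = []
        fac = row.get("specific_factor")
        if isinstance(fac, str) and fac:
            entry.append((fac, float(row.get("lambda_specific", 0.0) or 0.0)))
        mf = row.get("method_factor")
        if isinstance(mf, str) and mf:
            entry.append((mf, float(row.get("lambda_method", 0.0) or 0.0)))
        specifics[row["item"]] = entry
    tcols = sorted((c for c in df.columns if c.startswith("t") and c[1:].isdigit()),
                   key=lambda c: int(c[1:]))
    thresholds = None
    if tcols:
        thresholds = [row[tcols].dropna().to_numpy(float) for _, row in df.iterrows()]
    return BifactorStructure(items, lg, specifics, thresholds)
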