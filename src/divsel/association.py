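"""Environment-allele association scan and climate PCA.

Each (locus, environmental variable) pair is tested with a univariate
logistic regression of individual band presence/absence on the variable,
individuals inheriting the climate values of their population.  Significance
requires *both* the likelihood-ratio statistic G = 2(l_full - l_null) and
the Wald statistic (beta / SE)^2 to fall below a Bonferroni-corrected
threshold (alpha divided by the total number of models tested).  The climate
PCA condenses the 20 bioclimatic variables (plus coordinates, optionally)
into leading components PC1-PC3 that are added to the scanned variables.

The logistic fits run as a batched Newton/IRLS across all loci of a variable
simultaneously; every model has just two parameters, so the Hessian solves
are closed-form 2x2.  Complete separation is detected as a diverging slope
and flags the model as non-converged (its Wald test is unusable and it
cannot be called significant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .datatypes import MISSING, ClimateTable, MarkerMatrix

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Climate PCA
# ---------------------------------------------------------------------------

@dataclass
class ClimatePCA:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame    # populations x components
    pct_variance: np.ndarray
    variables: list[str]


def climate_pca(table: ClimateTable, include_coords: bool = True,
                n_components: int = 3) -> ClimatePCA:
    """PCA of standardized climate variables; deterministic sign convention.

    Columns are standardized to zero mean and unit variance; constant columns
    are dropped with a warning.  Each component's sign is chosen so its
    largest-magnitude loading is positive.
    """
    if len(table.population_ids) < 3:
        raise ValueError("need at least 3 populations for a climate PCA")
    cols = table.variables if include_coords else \
        [c for c in table.variables if c not in ("latitude", "longitude")]
    x = table.values_for(cols)
    keep = []
    for c in cols:
        if x[c].std(ddof=0) > 0:
            keep.append(c)
        else:
            log.warning("dropping constant climate column %r", c)
    x = x[keep]
    z = (x - x.mean()) / x.std(ddof=0)
    u, s, vt = np.linalg.svd(z.to_numpy(float), full_matrices=False)
    n_keep = min(n_components, s.size)
    load = vt[:n_keep].T
    for j in range(n_keep):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] *= -1.0
    scores = z.to_numpy(float) @ load
    eig = s ** 2
    pct = 100.0 * eig[:n_keep] / eig.sum()
    comp_names = [f"PC{i + 1}" for i in range(n_keep)]
    return ClimatePCA(
        loadings=pd.DataFrame(load, index=keep, columns=comp_names),
        scores=pd.DataFrame(scores, index=x.index, columns=comp_names),
        pct_variance=pct,
        variables=keep,
    )


# ---------------------------------------------------------------------------
# Batched logistic fits
# ---------------------------------------------------------------------------

def _batch_logistic(x: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                    max_iter: int = 50, slope_cap: float = 30.0):
    """Newton fits of y_l ~ intercept + slope * x for all columns of y.

    Returns (intercept, slope, G, wald, converged) arrays of length L.
    ``slope_cap`` bounds |slope| * sd(x); hitting it marks the model
    non-converged (complete or quasi-complete separation).
    """
    n, L = y.shape
    xm, xs = x.mean(), x.std()
    if xs == 0:
        zeros = np.zeros(L)
        return zeros, zeros, zeros, zeros, np.ones(L, dtype=bool)
    xz = (x - xm) / xs  # standardized for conditioning; back-transform at end
    ybar = y.mean(axis=0)
    b0 = np.log(np.clip(ybar, 1e-9, 1 - 1e-9) / np.clip(1 - ybar, 1e-9, 1))
    b1 = np.zeros(L)
    converged = np.zeros(L, dtype=bool)
    for _ in range(max_iter):
        eta = b0[None, :] + b1[None, :] * xz[:, None]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = y - mu
        g0 = r.sum(axis=0)
        g1 = (xz[:, None] * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (xz[:, None] * w).sum(axis=0)
        h11 = ((xz ** 2)[:, None] * w).sum(axis=0)
        det = np.maximum(h00 * h11 - h01 ** 2, 1e-12)
        step0 = (h11 * g0 - h01 * g1) / det
        step1 = (h00 * g1 - h01 * g0) / det
        b0 = b0 + step0
        b1 = np.clip(b1 + step1, -slope_cap, slope_cap)
        converged = (np.abs(step0) < tol) & (np.abs(step1) < tol)
        if converged.all():
            break
    capped = np.abs(b1) >= slope_cap - 1e-6
    converged = converged & ~capped
    eta = b0[None, :] + b1[None, :] * xz[:, None]
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    ll_full = (y * np.log(mu) + (1 - y) * np.log1p(-mu)).sum(axis=0)
    p0 = np.clip(ybar, 1e-12, 1 - 1e-12)
    ll_null = n * (p0 * np.log(p0) + (1 - p0) * np.log1p(-p0))
    g_stat = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    # Wald on the standardized slope (invariant to the rescaling)
    w = mu * (1.0 - mu)
    h00 = w.sum(axis=0)
    h01 = (xz[:, None] * w).sum(axis=0)
    h11 = ((xz ** 2)[:, None] * w).sum(axis=0)
    det = np.maximum(h00 * h11 - h01 ** 2, 1e-12)
    var_b1 = h00 / det
    wald = np.where(var_b1 > 0, b1 ** 2 / var_b1, 0.0)
    return b0 - b1 * xm / xs, b1 / xs, g_stat, wald, converged


def logistic_scan(matrix: MarkerMatrix, climate: ClimateTable,
                  variables: list[str] | None = None,
                  pca_components: pd.DataFrame | None = None,
                  alpha: float = 0.05, rule: str = "both") -> pd.DataFrame:
    """Univariate logistic scans of every polymorphic locus on every variable.

    Returns a long-format frame with one row per (locus, variable): fitted
    intercept/slope, G and Wald statistics with chi-square(1) p-values, the
    Bonferroni-corrected significance flag (threshold alpha / total models),
    and the convergence flag.  ``pca_components`` may add derived variables
    (e.g. climate PC1-PC3, indexed by population).  With ``rule="both"``
    (default) significance requires both tests; ``rule="g"`` uses G alone.
    """
    if np.any(matrix.bands == MISSING):
        raise ValueError("missing band scores present; resolve them first")
    env = climate.values_for(variables)
    if pca_components is not None:
        env = env.join(pca_components, how="left")
    pops = [matrix.pop_of[i] for i in matrix.individual_ids]
    missing_pops = set(pops) - set(env.index)
    if missing_pops:
        raise ValueError(f"no climate values for populations {sorted(missing_pops)}")
    env_ind = env.loc[pops]

    mono = set(matrix.zero_variance_loci())
    poly = [l for l in matrix.locus_ids if l not in mono]
    sub = matrix.subset_loci(poly)
    y = sub.bands.astype(float)

    frames = []
    usable_vars = []
    for var in env_ind.columns:
        x = env_ind[var].to_numpy(float)
        if np.ptp(x) == 0:
            log.warning("skipping constant environmental variable %r", var)
            continue
        usable_vars.append(var)
        b0, b1, g_stat, wald, conv = _batch_logistic(x, y)
        frames.append(pd.DataFrame({
            "locus": poly, "variable": var,
            "intercept": b0, "beta": b1,
            "g": g_stat, "wald": wald, "converged": conv,
        }))
    if not frames:
        raise ValueError("no usable environmental variables")
    out = pd.concat(frames, ignore_index=True)
    n_models = len(out)
    thresh = alpha / n_models
    out["p_g"] = stats.chi2.sf(out["g"], df=1)
    out["p_wald"] = np.where(out["converged"],
                             stats.chi2.sf(out["wald"], df=1), np.nan)
    if rule == "both":
        out["significant"] = (out["p_g"] <= thresh) & out["converged"] & \
            (out["p_wald"] <= thresh)
    elif rule == "g":
        out["significant"] = out["p_g"] <= thresh
    else:
        raise ValueError(f"unknown significance rule {rule!r}")
    out.attrs["bonferroni_threshold"] = thresh
    out.attrs["n_models"] = n_models
    out.attrs["variables"] = usable_vars
    return out


def scan_selected_loci(scan: pd.DataFrame) -> dict[str, list[str]]:
    """Loci flagged by the scan, with the variables that flagged each.

    A locus is "selected by scan" when any variable passes both tests.
    """
    sig = scan[scan["significant"]]
    return {locus: grp["variable"].tolist()
            for locus, grp in sig.groupby("locus", sort=False)}
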