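"""Subsampling maximum-mean-discrepancy alignment (SMA).

Each source site's marginal feature distributions are mapped onto a chosen
target site by a per-feature affine transform y -> a*y + b (a > 0) chosen to
minimize the squared maximum mean discrepancy (MMD) between the transformed
source sample and the target sample, under an RBF kernel with median-heuristic
bandwidth.  When site and biology covary, subjects are stratified into
subgroups (Zcut rules) and the transform is fitted on repeated
subgroup-frequency-matched subsamples, so the comparison between source and
target is not confounded by their different covariate mixes; the final
parameters are the per-feature median over draws.

The affine transform family is this package's operationalization of marginal
distribution shifting: it is the minimal family that can null both additive
and multiplicative site effects, and the moment-matching start makes the
optimizer's accepted-improvement path deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import FeatureMatrix, HarmonizationError, ValidatedDemographics
from ._parallel import parallel_map

OPT_TOL = 1e-6
OPT_MAX_ITER = 500


@dataclass
class SubgroupSpec:
    """Stratification rules: per covariate, 0 (categorical -> strata by
    distinct value) or ascending numeric cutpoints (continuous -> half-open
    upper-inclusive bins (-inf, c1], (c1, c2], ...)."""

    z_variables: list
    zcuts: dict  # name -> 0 or ascending list of floats

    def __post_init__(self):
        for var in self.z_variables:
            if var not in self.zcuts:
                raise HarmonizationError(f"no Zcut supplied for variable {var!r}")
            cuts = self.zcuts[var]
            if cuts != 0:
                cuts = [float(c) for c in cuts]
                if any(b <= a for a, b in zip(cuts, cuts[1:])):
                    raise HarmonizationError(
                        f"cutpoints for {var!r} must be strictly ascending: {cuts}")
                self.zcuts[var] = cuts


@dataclass
class SMATransform:
    """Per-(source site, feature) affine alignment parameters."""

    scale: dict = field(default_factory=dict)   # site -> (p,) array a_v > 0
    shift: dict = field(default_factory=dict)   # site -> (p,) array b_v
    kernel: str = "rbf"
    bandwidth: str | float = "median"
    n_subsamples: int = 100
    fit_type: str = "no_subsampling"
    target_site: str = ""


def assign_subgroups(demographics: ValidatedDemographics, spec: SubgroupSpec):
    """Per-subject subgroup label (tuple of stratum indices) + occupancy table.

    The occupancy table maps (site, label) -> subject count.
    """
    n = demographics.n_subjects
    strata_per_var = []
    for var in spec.z_variables:
        if var not in demographics.table.columns:
            raise HarmonizationError(f"unknown subgroup variable {var!r}")
        col = demographics.table[var]
        cuts = spec.zcuts[var]
        if cuts == 0:
            levels = list(dict.fromkeys(col.astype(str)))
            lookup = {lev: i for i, lev in enumerate(levels)}
            strata_per_var.append([lookup[v] for v in col.astype(str)])
        else:
            vals = col.astype(float).to_numpy()
            # bin index: count of cutpoints strictly below the value
            # (upper-inclusive: value == cut stays in the lower bin)
            strata_per_var.append(
                [int(np.searchsorted(cuts, v, side="left")) for v in vals])
    labels = [tuple(sv[j] for sv in strata_per_var) for j in range(n)]
    occupancy: dict = {}
    for site, lab in zip(demographics.site, labels):
        occupancy[(site, lab)] = occupancy.get((site, lab), 0) + 1
    return labels, occupancy


def recommend_target_site(demographics: ValidatedDemographics,
                          occupancy: dict | None = None) -> list:
    """Rank candidate target sites.

    A good target is large and covers many covariate subgroups; the score is
    n_site * (occupied cells / total cells).  Without subgrouping the ranking
    is by site size alone.  Ties break by larger n then first-appearance order.
    """
    sizes = demographics.site_sizes()
    if occupancy is None:
        coverage = {s: 1.0 for s in sizes}
    else:
        all_cells = sorted({lab for (_, lab) in occupancy})
        total = len(all_cells)
        coverage = {
            s: sum(1 for lab in all_cells if occupancy.get((s, lab), 0) > 0) / total
            for s in sizes
        }
    order = {s: i for i, s in enumerate(demographics.site_order)}
    ranked = sorted(
        sizes,
        key=lambda s: (-sizes[s] * coverage[s], -sizes[s], order[s]),
    )
    return ranked


# ---------------------------------------------------------------------------
# MMD

def median_bandwidth(pooled: np.ndarray) -> float:
    """Median pairwise distance of the pooled sample (median heuristic)."""
    pooled = np.asarray(pooled, dtype=float)
    if pooled.ndim == 1:
        pooled = pooled[:, None]
    d2 = ((pooled[:, None, :] - pooled[None, :, :]) ** 2).sum(-1)
    iu = np.triu_indices(pooled.shape[0], k=1)
    med = np.median(np.sqrt(d2[iu]))
    return float(med) if med > 0 else 1.0


def mmd_statistic(sample_a: np.ndarray, sample_b: np.ndarray,
                  bandwidth: float | str = "median") -> float:
    """Biased V-statistic estimator of squared MMD with an RBF kernel.

    k(x, y) = exp(-||x - y||^2 / (2 h^2)); h defaults to the median pairwise
    distance of the pooled sample.  Zero for identical samples; approaches 2
    as the samples separate.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise HarmonizationError("MMD requires two non-empty samples")
    if bandwidth == "median":
        bandwidth = median_bandwidth(np.vstack([a, b]))
    h2 = 2.0 * float(bandwidth) ** 2

    def kmean(x, y):
        d2 = ((x[:, None, :] - y[None, :, :]) ** 2).sum(-1)
        return np.exp(-d2 / h2).mean()

    return float(kmean(a, a) + kmean(b, b) - 2.0 * kmean(a, b))


def _mmd_and_grad(src: np.ndarray, tgt: np.ndarray, a: float, b: float, h: float):
    """MMD^2 between a*src+b and tgt, with analytic gradient w.r.t. (a, b)."""
    x = a * src + b
    h2 = 2.0 * h * h
    dxx = x[:, None] - x[None, :]
    dxt = x[:, None] - tgt[None, :]
    kxx = np.exp(-dxx ** 2 / h2)
    kxt = np.exp(-dxt ** 2 / h2)
    ktt = np.exp(-((tgt[:, None] - tgt[None, :]) ** 2) / h2)
    n, m = x.size, tgt.size
    mmd2 = kxx.mean() + ktt.mean() - 2.0 * kxt.mean()
    # d k(xi,xj)/d xi = -(xi-xj)/h^2 * k ; each xi appears in rows and cols
    gxx = (-dxx / (h * h)) * kxx
    gxt = (-dxt / (h * h)) * kxt
    dmmd_dx = 2.0 * gxx.sum(axis=1) / (n * n) - 2.0 * gxt.sum(axis=1) / (n * m)
    da = float(dmmd_dx @ src)
    db = float(dmmd_dx.sum())
    return float(mmd2), da, db


def _fit_affine_1d(src: np.ndarray, tgt: np.ndarray) -> tuple[float, float]:
    """Minimize MMD^2(a*src+b, tgt) by first-order descent with backtracking,
    starting from moment matching.  Only improving steps are accepted, so the
    final MMD never exceeds the moment-matching start's."""
    s_src = src.std()
    a = tgt.std() / s_src if s_src > 0 else 1.0
    if a <= 0:
        a = 1e-6
    b = tgt.mean() - a * src.mean()
    h = median_bandwidth(np.concatenate([a * src + b, tgt]))
    f, da, db = _mmd_and_grad(src, tgt, a, b, h)
    step = 0.1
    for _ in range(OPT_MAX_ITER):
        gnorm = np.hypot(da, db)
        if gnorm < OPT_TOL:
            break
        a_new = a - step * da
        b_new = b - step * db
        if a_new <= 0:
            a_new = a / 2.0
        f_new, da_new, db_new = _mmd_and_grad(src, tgt, a_new, b_new, h)
        if f_new < f - 1e-15:
            if abs(f - f_new) < OPT_TOL * max(1.0, abs(f)):
                a, b, f, da, db = a_new, b_new, f_new, da_new, db_new
                break
            a, b, f, da, db = a_new, b_new, f_new, da_new, db_new
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-12:
                break
    return float(a), float(b)


# ---------------------------------------------------------------------------
# harmonization driver

def _matched_draw(rng: np.random.Generator, src_cells: dict, tgt_cells: dict,
                  usable: list) -> tuple[np.ndarray, np.ndarray]:
    """Index draw matching the target's subgroup mix across usable cells."""
    tgt_total = sum(len(tgt_cells[c]) for c in usable)
    src_total = sum(len(src_cells[c]) for c in usable)
    draw_total = min(src_total, tgt_total)
    src_idx, tgt_idx = [], []
    for cell in usable:
        frac = len(tgt_cells[cell]) / tgt_total
        k = max(1, int(round(frac * draw_total)))
        src_idx.append(rng.choice(src_cells[cell], size=k, replace=True))
        tgt_idx.append(rng.choice(tgt_cells[cell], size=k, replace=True))
    return np.concatenate(src_idx), np.concatenate(tgt_idx)


def sma_harmonize(Y: FeatureMatrix, demographics: ValidatedDemographics,
                  fit_type: str = "no_subsampling",
                  spec: SubgroupSpec | None = None,
                  target_site: str = "auto", n_subsamples: int = 100,
                  seed: int = 0, workers: int = 0):
    """Align every source site's marginals to the target site.

    ``no_subsampling`` fits one affine per (site, feature) on the full
    samples; ``subsampling`` repeats the fit on ``n_subsamples``
    subgroup-matched draws and takes the per-feature median.  Target-site
    subjects pass through bit-identical.
    """
    if fit_type not in ("no_subsampling", "subsampling"):
        raise HarmonizationError(f"unknown fit_type {fit_type!r}")
    if fit_type == "subsampling" and spec is None:
        raise HarmonizationError("subsampling requires a SubgroupSpec")

    labels, occupancy = (None, None)
    if spec is not None:
        labels, occupancy = assign_subgroups(demographics, spec)
    if target_site == "auto":
        target_site = recommend_target_site(demographics, occupancy)[0]
    if target_site not in demographics.site_order:
        raise HarmonizationError(f"target site {target_site!r} not present in the data")
    sizes = demographics.site_sizes()
    small = [s for s, n in sizes.items() if n < 3]
    if small:
        raise HarmonizationError(f"site(s) with < 3 subjects cannot be aligned: {small}")

    values = Y.values
    site = np.asarray(demographics.site)
    tgt_rows = np.flatnonzero(site == target_site)
    transform = SMATransform(fit_type=fit_type, target_site=target_site,
                             n_subsamples=n_subsamples)
    out = values.copy()
    p = values.shape[1]
    rng_root = np.random.default_rng(seed)

    for src_site in demographics.site_order:
        if src_site == target_site:
            transform.scale[src_site] = np.ones(p)
            transform.shift[src_site] = np.zeros(p)
            continue
        src_rows = np.flatnonzero(site == src_site)
        if fit_type == "no_subsampling":
            ab = parallel_map(
                lambda v: _fit_affine_1d(values[src_rows, v], values[tgt_rows, v]),
                range(p), workers)
            a = np.array([t[0] for t in ab])
            b = np.array([t[1] for t in ab])
        else:
            src_cells: dict = {}
            tgt_cells: dict = {}
            for r in src_rows:
                src_cells.setdefault(labels[r], []).append(r)
            for r in tgt_rows:
                tgt_cells.setdefault(labels[r], []).append(r)
            usable = sorted(c for c in src_cells if c in tgt_cells)
            skipped = sorted(c for c in src_cells if c not in tgt_cells)
            if skipped:
                warnings.warn(
                    f"site {src_site!r}: subgroup cells {skipped} are empty at the "
                    f"target site and were excluded from fitting", UserWarning)
            if not usable:
                raise HarmonizationError(
                    f"site {src_site!r} shares no subgroup cells with the target site")
            src_cells = {c: np.asarray(v) for c, v in src_cells.items()}
            tgt_cells = {c: np.asarray(v) for c, v in tgt_cells.items()}
            draws = []
            for r in range(n_subsamples):
                rng = np.random.default_rng(rng_root.integers(2 ** 31))
                draws.append(_matched_draw(rng, src_cells, tgt_cells, usable))

            def fit_draw(draw):
                si, ti = draw
                return [_fit_affine_1d(values[si, v], values[ti, v]) for v in range(p)]

            results = parallel_map(fit_draw, draws, workers)
            ab = np.array(results)          # (R, p, 2)
            a = np.median(ab[:, :, 0], axis=0)
            b = np.median(ab[:, :, 1], axis=0)
        transform.scale[src_site] = a
        transform.shift[src_site] = b
        out[src_rows] = values[src_rows] * a[None, :] + b[None, :]

    return Y.with_values(out), transform
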