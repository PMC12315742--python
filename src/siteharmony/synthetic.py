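"""Synthetic multi-site data with known ground truth.

The generator follows the same location/scale model the harmonization
methods assume: per feature v and site i,

    y = intercept + X.beta_v + gamma_i + delta_i * eps,   eps ~ N(0, sd^2)

optionally with site-specific correlation inside chosen feature blocks
(covariance site effects, the CovBat scenario) and with site-dependent
covariate distributions (confounding, the SMA subsampling scenario).
Ground-truth parameters are returned with the data so recovery tests never
re-estimate them.  A scaled-t noise option exercises the nonparametric
ComBat rationale for non-normal site effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .core import (FeatureMatrix, HarmonizationError, MaskSpec, SITE_COLUMN,
                   validate_demographics)


@dataclass
class SyntheticSpec:
    n_sites: int = 3
    n_per_site: int = 50
    n_features: int = 100
    gamma: tuple = (-1.0, 0.0, 1.0)      # per-site additive offsets (prior means)
    #: per-feature spread of the additive site effect around gamma_i; the
    #: empirical-Bayes model itself assumes gamma_iv ~ N(gamma_i, tau_i^2).
    #: 0 gives a constant offset per site.
    gamma_tau: float = 0.0
    delta: tuple = (1.0, 1.0, 1.0)       # per-site scale factors
    #: per-site correlation within the leading `cov_block` features, split
    #: into `cov_subblocks` independent equicorrelated subsets (several
    #: subsets give the covariance site effect more than one direction)
    cov_block: int = 0
    cov_rho: tuple = ()
    cov_subblocks: int = 1
    #: shared (site-independent) low-rank structure: number of latent factors
    #: and the fraction of noise variance they explain.  Imaging features are
    #: strongly inter-correlated; 0 disables.
    latent_factors: int = 0
    factor_share: float = 0.5
    #: per-covariate site-wise sampler specs, e.g.
    #: {"Age": {"kind": "normal", "mean": (30, 40, 50), "sd": 5},
    #:  "Group": {"kind": "binary", "p": (0.5, 0.5, 0.5)}}
    covariates: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)   # covariate -> effect size
    intercept: float = 0.0
    noise_sd: float = 1.0
    noise: str = "gaussian"              # gaussian | t
    t_df: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if len(self.gamma) != self.n_sites or len(self.delta) != self.n_sites:
            raise HarmonizationError(
                "gamma and delta must provide one value per site")
        if self.cov_block and len(self.cov_rho) != self.n_sites:
            raise HarmonizationError("cov_rho must provide one value per site")
        if self.n_sites < 2 or self.n_per_site < 2 or self.n_features < 1:
            raise HarmonizationError("invalid synthetic dimensions")


def _per_site(value, site_idx):
    return value if np.isscalar(value) else value[site_idx]


def _draw_covariate(rng, spec, site_idx, n):
    kind = spec.get("kind", "normal")
    if kind == "normal":
        return rng.normal(_per_site(spec["mean"], site_idx),
                          _per_site(spec.get("sd", 1.0), site_idx), size=n)
    if kind == "binary":
        return rng.binomial(1, _per_site(spec["p"], site_idx), size=n).astype(float)
    raise HarmonizationError(f"unknown covariate kind {kind!r}")


def generate_multisite_dataset(spec: SyntheticSpec):
    """Returns (FeatureMatrix, ValidatedDemographics, ground_truth dict)."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_sites * spec.n_per_site
    p = spec.n_features
    site_labels = np.repeat([f"site{i+1}" for i in range(spec.n_sites)],
                            spec.n_per_site)
    demo = {SITE_COLUMN: site_labels}
    cov_values = {}
    for name, cspec in spec.covariates.items():
        col = np.empty(n_total)
        for i in range(spec.n_sites):
            rows = slice(i * spec.n_per_site, (i + 1) * spec.n_per_site)
            col[rows] = _draw_covariate(rng, cspec, i, spec.n_per_site)
        cov_values[name] = col
        demo[name] = col

    Y = np.full((n_total, p), spec.intercept, dtype=float)
    for name, b in spec.beta.items():
        Y += np.outer(cov_values[name], np.full(p, b))

    gamma_iv = np.array([
        rng.normal(spec.gamma[i], spec.gamma_tau, size=p)
        for i in range(spec.n_sites)])

    factor_loadings = None
    if spec.latent_factors:
        k = spec.latent_factors
        W = rng.standard_normal((k, p))
        W /= np.linalg.norm(W, axis=0, keepdims=True)  # unit variance per feature
        factor_loadings = W

    for i in range(spec.n_sites):
        rows = slice(i * spec.n_per_site, (i + 1) * spec.n_per_site)
        n_i = spec.n_per_site
        if spec.noise == "t":
            raw = rng.standard_t(spec.t_df, size=(n_i, p))
            raw /= np.sqrt(spec.t_df / (spec.t_df - 2))  # unit variance
        else:
            raw = rng.standard_normal((n_i, p))
        if factor_loadings is not None:
            F = rng.standard_normal((n_i, spec.latent_factors))
            s = spec.factor_share
            raw = np.sqrt(s) * (F @ factor_loadings) + np.sqrt(1 - s) * raw
        eps = raw * spec.noise_sd
        if spec.cov_block:
            rho = spec.cov_rho[i]
            if rho:
                bounds = np.linspace(0, spec.cov_block,
                                     spec.cov_subblocks + 1).astype(int)
                for lo, hi in zip(bounds[:-1], bounds[1:]):
                    # equicorrelated sub-block via one shared factor
                    shared = rng.standard_normal((n_i, 1))
                    eps[:, lo:hi] = (np.sqrt(rho) * shared
                                     + np.sqrt(1 - rho) * raw[:, lo:hi]) * spec.noise_sd
        Y[rows] += gamma_iv[i][None, :] + spec.delta[i] * eps

    table = pd.DataFrame(demo)
    demographics = validate_demographics(table, n_total)
    matrix = FeatureMatrix(Y, [f"sub{j:04d}" for j in range(n_total)],
                           list(range(p)), "table")
    truth = dict(gamma=dict(zip(demographics.site_order, spec.gamma)),
                 gamma_iv=gamma_iv,
                 delta=dict(zip(demographics.site_order, spec.delta)),
                 beta=dict(spec.beta), intercept=spec.intercept,
                 noise_sd=spec.noise_sd, seed=spec.seed)
    return matrix, demographics, truth


def generate_toy_volume_dataset(out_dir, n_sites: int = 2, n_per_site: int = 3,
                                shape: tuple = (4, 4, 4), seed: int = 0,
                                route: str = "FunctionalConnectivity",
                                prefix: str = "FC_", gamma_gap: float = 1.0):
    """Materialize a site-organized NIfTI tree + mask + demographic CSV.

    Layout: `out_dir`/siteK/`route`/`prefix`subNNN.nii, a binary mask
    `mask.nii` and `demographics.csv` at the top level.  Valid input to
    :func:`siteharmony.io.discover_site_files`.
    """
    import nibabel as nib
    from pathlib import Path

    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    mask = np.zeros(shape, dtype=np.uint8)
    flat = rng.choice(int(np.prod(shape)), size=max(2, int(np.prod(shape)) // 2),
                      replace=False)
    mask.ravel()[flat] = 1
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(mask, affine), out_dir / "mask.nii")

    rows = []
    counter = 0
    for i in range(n_sites):
        site = f"site{i+1}"
        site_dir = out_dir / site / route
        site_dir.mkdir(parents=True, exist_ok=True)
        for _j in range(n_per_site):
            data = rng.standard_normal(shape) + i * gamma_gap
            name = f"{prefix}sub{counter:03d}.nii"
            nib.save(nib.Nifti1Image(data.astype(np.float64), affine),
                     site_dir / name)
            rows.append({SITE_COLUMN: site, "Age": float(rng.integers(20, 60))})
            counter += 1
    demo = pd.DataFrame(rows)
    demo.to_csv(out_dir / "demographics.csv", index=False)
    mask_spec = MaskSpec("volume", mask)
    return dict(root=out_dir, mask_path=out_dir / "mask.nii", mask=mask_spec,
                demographics_path=out_dir / "demographics.csv", route=route,
                identifier=f"{prefix}*",
                sites=[f"site{i+1}" for i in range(n_sites)])


def generate_toy_surface_dataset(out_dir, n_sites: int = 2, n_per_site: int = 3,
                                 n_vertices: int = 20, seed: int = 0,
                                 route: str = "Thickness"):
    """Paired left/right GIfTI files per subject plus per-hemisphere masks."""
    import nibabel as nib
    from pathlib import Path

    out_dir = Path(out_dir)
    rng = np.random.default_rng(seed)
    masks = {}
    for hemi in ("LH", "RH"):
        m = np.zeros(n_vertices, dtype=np.uint8)
        m[rng.choice(n_vertices, size=n_vertices // 2, replace=False)] = 1
        masks[hemi] = m
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(m.astype(np.float32))])
        nib.save(img, out_dir / f"mask_{hemi}.gii")
    rows = []
    counter = 0
    for i in range(n_sites):
        site = f"site{i+1}"
        site_dir = out_dir / site / route
        site_dir.mkdir(parents=True, exist_ok=True)
        for _j in range(n_per_site):
            row = {SITE_COLUMN: site}
            for hemi in ("LH", "RH"):
                data = (rng.standard_normal(n_vertices) + i).astype(np.float32)
                name = f"surf_{hemi}_sub{counter:03d}.gii"
                img = nib.gifti.GiftiImage(darrays=[nib.gifti.GiftiDataArray(data)])
                nib.save(img, site_dir / name)
                row[f"FileList{hemi}"] = str(site_dir / name)
            rows.append(row)
            counter += 1
    demo = pd.DataFrame(rows)
    demo.to_csv(out_dir / "demographics.csv", index=False)
    return dict(root=out_dir, masks=masks,
                mask_paths={h: out_dir / f"mask_{h}.gii" for h in ("LH", "RH")},
                demographics_path=out_dir / "demographics.csv", route=route)


def site_separability_score(matrix: FeatureMatrix | np.ndarray, site_labels,
                            seed: int = 0, quadratic: bool = False) -> dict:
    """Cross-validated linear-classifier accuracy predicting site.

    Stratified split-half CV with a logistic-regression classifier on
    standardized features.  Returns the accuracy and the chance level
    (largest site's frequency).  Near-chance accuracy after harmonization
    indicates the sites are no longer separable from the features.

    ``quadratic=True`` appends all pairwise feature products, making the
    (still linear) classifier sensitive to site differences in covariance:
    the site mean of x_i*x_j is the site covariance, so covariance site
    effects become mean shifts in the product map.  First-order site effects
    are invisible to no probe, but second-order ones are invisible to the
    plain linear probe.
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else np.asarray(matrix)
    screen_top = 0
    if quadratic:
        Xc = (X - X.mean(axis=0)) / X.std(axis=0)
        iu = np.triu_indices(X.shape[1], k=1)
        X = np.hstack([X, Xc[:, iu[0]] * Xc[:, iu[1]]])
        # the product map is wide; screen to the most discriminative
        # features inside each training fold (no test leakage)
        screen_top = 100
    y = np.asarray(site_labels)
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise HarmonizationError("separability needs >= 2 sites")
    if counts.min() < 2:
        raise HarmonizationError("every site needs >= 2 subjects for CV")
    cv = StratifiedKFold(n_splits=2, shuffle=True, random_state=seed)
    accs = []
    for train, test in cv.split(X, y):
        scaler = StandardScaler().fit(X[train])
        X_train = scaler.transform(X[train])
        X_test = scaler.transform(X[test])
        if screen_top and X_train.shape[1] > screen_top:
            grand = X_train.mean(axis=0)
            score = np.zeros(X_train.shape[1])
            for lab in labels:
                block = X_train[y[train] == lab]
                score += np.abs(block.mean(axis=0) - grand) / (block.std(axis=0) + 1e-12)
            keep = np.argsort(score)[::-1][:screen_top]
            X_train, X_test = X_train[:, keep], X_test[:, keep]
        clf = LogisticRegression(max_iter=2000, random_state=seed)
        clf.fit(X_train, y[train])
        accs.append(clf.score(X_test, y[test]))
    return dict(accuracy=float(np.mean(accs)),
                chance=float(counts.max() / counts.sum()))
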