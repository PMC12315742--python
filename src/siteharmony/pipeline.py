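"""End-to-end runner: read -> validate -> harmonize -> write -> report."""

from __future__ import annotations

import logging
from pathlib import Path

from . import io as io_layer
from .combat import combat_harmonize
from .config import HarmonizationConfig, save_config
from .core import (FeatureMatrix, HarmonizationError,
                   ValidatedDemographics, validate_demographics)
from .covbat import covbat_harmonize
from .icvae import ICVAEConfig, icvae_harmonize, save_params, train_icvae
from .linear import glm_harmonize, lmm_harmonize
from .report import build_report
from .sma import SubgroupSpec, sma_harmonize

logger = logging.getLogger("siteharmony")


def dispatch_method(Y: FeatureMatrix, demographics: ValidatedDemographics,
                    method: dict, seed: int = 0, workers: int = 0,
                    out_dir=None):
    """Run the configured harmonization method on an in-memory matrix."""
    name = method["name"]
    if name == "combat":
        mode = "parametric" if method.get("parametric", True) else "nonparametric"
        out, fit = combat_harmonize(
            Y, demographics, mode, adjusted=method.get("adjusted", False),
            adjust_vars=method.get("adjust_vars"), workers=workers)
    elif name == "covbat":
        mode = "parametric" if method.get("parametric", True) else "nonparametric"
        pc_mode = "parametric" if method.get("covbat_parametric", True) \
            else "nonparametric"
        out, fit = covbat_harmonize(
            Y, demographics, mode, adjusted=method.get("adjusted", False),
            adjust_vars=method.get("adjust_vars"), pc_mode=pc_mode,
            rule=method.get("retention"), workers=workers)
    elif name == "sma":
        spec = None
        if method.get("fit_type", "no_subsampling") == "subsampling":
            spec = SubgroupSpec(list(method.get("z_variables", [])),
                                dict(method.get("zcuts", {})))
        out, fit = sma_harmonize(
            Y, demographics, method.get("fit_type", "no_subsampling"), spec,
            method.get("target_site", "auto"),
            method.get("n_subsamples", 100), seed, workers)
    elif name == "linear":
        model = method.get("model", "glm")
        adjusted = method.get("adjusted", True)
        if model == "glm":
            out, fit = glm_harmonize(Y, demographics,
                                     method.get("adjust_vars"), adjusted)
        elif model == "lmm":
            out, fit = lmm_harmonize(Y, demographics,
                                     method.get("adjust_vars"), adjusted, workers)
        else:
            raise HarmonizationError(f"linear model must be glm|lmm, got {model!r}")
    elif name == "icvae":
        cfg = ICVAEConfig(
            epochs=method.get("epochs", 200),
            learning_rate=method.get("learning_rate", 1e-3),
            batch_size=method.get("batch_size", 64),
            seed=seed)
        models, traces = train_icvae(Y, demographics, cfg, workers)
        target = method.get("target_site")
        if target is None:
            raise HarmonizationError("icvae requires a target_site")
        out = icvae_harmonize(models, Y, demographics, target)
        fit = (models, traces)
        if out_dir is not None:
            save_params(models, str(out_dir))
    else:
        raise HarmonizationError(f"unknown method {name!r}")
    return out, fit


def _load_inputs(config: HarmonizationConfig):
    inp = config.input
    mode = inp["mode"]
    mask = None
    layout = None
    surface_pairs = None
    organized_source = None
    data_shape = None
    if mode == "organized":
        organized_source = inp["organized_file"]
        matrix = io_layer.read_feature_data(organized_source)
    elif mode == "sites":
        layout = io_layer.SiteFileLayout(
            parent_dirs=list(inp["parent_dirs"]), route=inp.get("route", ""),
            identifier=inp.get("identifier", "*"),
            exemplar=inp.get("exemplar"))
        resolved, _labels = io_layer.discover_site_files(layout)
        if inp.get("space") == "surface":
            raise HarmonizationError(
                "surface site trees need explicit FileListLH/FileListRH columns "
                "(input.mode=filelist)")
        if inp.get("mask"):
            mask = io_layer.read_volume_mask(inp["mask"])
        paths = [p for _, p in resolved]
        import nibabel as nib
        data_shape = nib.load(str(paths[0])).shape
        matrix = io_layer.read_feature_data(paths, mask)
    elif mode == "filelist":
        demo = io_layer.read_table(config.demographics)
        if {"FileListLH", "FileListRH"} <= set(demo.columns):
            pairs = [(lh, rh) for lh, rh in
                     zip(demo["FileListLH"], demo["FileListRH"])]
            if inp.get("mask_lh") and inp.get("mask_rh"):
                mask = io_layer.read_surface_mask_pair(inp["mask_lh"], inp["mask_rh"])
            matrix = io_layer.read_feature_data(None, mask, surface_pairs=pairs)
            surface_pairs = pairs
        elif "FileList" in demo.columns:
            paths = [Path(p) for p in demo["FileList"]]
            if inp.get("mask"):
                mask = io_layer.read_volume_mask(inp["mask"])
            import nibabel as nib
            data_shape = nib.load(str(paths[0])).shape
            matrix = io_layer.read_feature_data(paths, mask)
        else:
            raise HarmonizationError(
                "filelist mode needs a FileList (or FileListLH/FileListRH) column")
    else:  # pragma: no cover - guarded by config validation
        raise HarmonizationError(f"unknown input mode {mode!r}")
    return matrix, mask, layout, surface_pairs, organized_source, data_shape


def run_pipeline(config: HarmonizationConfig):
    """Execute one full harmonization run; returns (written paths, report)."""
    stage = "read inputs"
    try:
        matrix, mask, layout, surface_pairs, organized_source, data_shape = \
            _load_inputs(config)
        stage = "validate demographics"
        demo_table = io_layer.read_table(config.demographics)
        demographics = validate_demographics(demo_table, matrix.n_subjects)
        stage = "harmonize"
        out_dir = Path(config.output["out_dir"])
        harmonized, _fit = dispatch_method(
            matrix, demographics, config.method, config.seed, config.workers,
            out_dir=out_dir if config.method["name"] == "icvae" else None)
        stage = "write outputs"
        if surface_pairs is not None:
            pair_records = [((site, lh), (site, rh)) for (lh, rh), site in
                            zip(surface_pairs, demographics.site)]
            parent_dirs = sorted({Path(lh).parent.parent for lh, _ in surface_pairs})
            lay = io_layer.SiteFileLayout(parent_dirs=[str(d) for d in parent_dirs])
            lay.resolved = [(s, Path(lh)) for (s, lh), _ in pair_records]
            written = io_layer.write_harmonized(
                harmonized, out_dir, layout=lay,
                organize_csv=config.output.get("organize_csv", False),
                surface_pairs=pair_records, surface_mask=mask)
        else:
            written = io_layer.write_harmonized(
                harmonized, out_dir, layout=layout,
                organized_source=organized_source, mask=mask,
                data_shape=data_shape,
                organize_csv=config.output.get("organize_csv", False),
                network_output=config.output.get("network_output", "upper"))
        stage = "report"
        report = build_report(
            matrix, harmonized, demographics, config.method, config.seed,
            extra_provenance={"workers": config.workers})
        written += report.write(out_dir)
        save_config(config, out_dir / "HarmonizationConfig.yml")
        logger.info("harmonization finished: %d output files", len(written))
        return written, report
    except HarmonizationError as err:
        raise HarmonizationError(f"[stage: {stage}] {err}") from err
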