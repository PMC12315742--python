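"""File discovery, reading and writing for all supported formats.

Input modalities: NIfTI volumes (.nii/.nii.gz) with a NIfTI mask, GIfTI
surface scalars (.gii, one file per hemisphere) with GIfTI masks, square
network matrices (delimited text; .mat behind the ``enable_mat`` flag), and
organized subject-by-feature tables (.csv/.tsv/.txt/.xlsx; .mat optional).
The output layout mirrors the input: per-file inputs come back under the
same ``site/route/filename`` tree, organized tables come back with a
``Harmonized_`` filename prefix, and the optional consolidated
``HarmonizationResults.csv`` holds subjects as rows and features as columns.
Headers/affines of input images are copied unchanged to the outputs.
"""

from __future__ import annotations

import fnmatch
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (FeatureMatrix, HarmonizationError, MaskSpec,
                   apply_mask, network_feature_index,
                   vectorize_network, rebuild_network)

TABLE_EXTENSIONS = (".csv", ".tsv", ".txt", ".xlsx")
VOLUME_EXTENSIONS = (".nii", ".nii.gz")
SURFACE_EXTENSIONS = (".gii",)


@dataclass
class SiteFileLayout:
    """Site-organized input tree: one parent directory per site (directory
    basename = site name), a shared relative route, and a filename pattern."""

    parent_dirs: list
    route: str = ""
    identifier: str = "*"
    exemplar: str | None = None   # when set and identifier empty, match its extension
    resolved: list = field(default_factory=list)  # [(site, Path), ...]


def _extension(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def discover_site_files(layout: SiteFileLayout):
    """Resolve (site, path) pairs: sites in given order, files lexicographic.

    Every site must expose the same relative route; a site resolving zero
    files is an error (a silent drop would desynchronize demographics).
    """
    pattern = layout.identifier or "*"
    if layout.exemplar and layout.identifier in (None, "", "*"):
        pattern = "*" + _extension(Path(layout.exemplar))
    resolved, labels = [], []
    for parent in layout.parent_dirs:
        parent = Path(parent)
        site = parent.name
        base = parent / layout.route if layout.route else parent
        if not base.is_dir():
            raise HarmonizationError(
                f"route {layout.route!r} is missing under site {site!r}")
        files = sorted(
            f for f in base.iterdir()
            if f.is_file() and (fnmatch.fnmatch(f.name, pattern)
                                or fnmatch.fnmatch(f.name, pattern + ".gz"))
        )
        if not files:
            raise HarmonizationError(
                f"site {site!r} resolved zero files for pattern {pattern!r}")
        for f in files:
            resolved.append((site, f))
            labels.append(site)
    layout.resolved = resolved
    return resolved, labels


def _space_of(path: Path) -> str:
    ext = _extension(path)
    if ext in VOLUME_EXTENSIONS:
        return "volume"
    if ext in SURFACE_EXTENSIONS:
        return "surface"
    if ext in TABLE_EXTENSIONS or ext == ".mat":
        return "table"
    raise HarmonizationError(f"unsupported file extension {ext!r} ({path})")


def read_table(path, enable_mat: bool = False) -> pd.DataFrame:
    path = Path(path)
    ext = _extension(path)
    if ext == ".csv":
        return pd.read_csv(path)
    if ext in (".tsv", ".txt"):
        return pd.read_csv(path, sep=None, engine="python")
    if ext == ".xlsx":
        return pd.read_excel(path)
    if ext == ".mat":
        if not enable_mat:
            raise HarmonizationError(
                ".mat support is disabled; pass enable_mat=True or convert to CSV")
        from scipy.io import loadmat
        mat = loadmat(path)
        arrays = {k: v for k, v in mat.items() if not k.startswith("__")}
        if len(arrays) != 1:
            raise HarmonizationError(
                f".mat file {path} must hold exactly one array, found {list(arrays)}")
        return pd.DataFrame(next(iter(arrays.values())))
    raise HarmonizationError(f"unsupported table extension {ext!r}")


def _read_gifti_data(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, dtype=float)


def read_surface_mask_pair(lh_path, rh_path) -> MaskSpec:
    """Surface masks are accepted in .gii format only."""
    for p in (lh_path, rh_path):
        if _extension(Path(p)) != ".gii":
            raise HarmonizationError(
                f"surface masks are only accepted in .gii format, got {p}")
    return MaskSpec("surface_pair", (_read_gifti_data(lh_path),
                                     _read_gifti_data(rh_path)))


def read_volume_mask(path) -> MaskSpec:
    return MaskSpec("volume", np.asanyarray(nib.load(str(path)).dataobj))


def read_feature_data(source, mask: MaskSpec | None = None,
                      enable_mat: bool = False,
                      surface_pairs: list | None = None) -> FeatureMatrix:
    """Read per-subject files (list of paths) or one organized table.

    Per-file inputs must all live in one space — mixing volume and surface
    files in a run is rejected, mirroring the mutually exclusive general and
    surface spaces.  Surface runs pass ``surface_pairs`` = list of
    ``(lh_path, rh_path)`` with a :class:`MaskSpec` of kind ``surface_pair``;
    features are LH-masked then RH-masked, concatenated.
    """
    if surface_pairs is not None:
        return _read_surfaces(surface_pairs, mask)
    if isinstance(source, (str, Path)):
        return _read_organized_table(Path(source), enable_mat)

    paths = [Path(p) for p in source]
    spaces = {_space_of(p) for p in paths}
    if len(spaces) > 1:
        raise HarmonizationError(
            f"mixed input spaces {sorted(spaces)}: volume and surface spaces "
            "are mutually exclusive in one run")
    space = spaces.pop()
    if space == "volume":
        stack, headers = [], []
        for p in paths:
            img = nib.load(str(p))
            stack.append(np.asanyarray(img.dataobj, dtype=float))
        if mask is None:
            mask = MaskSpec("none")
        matrix = apply_mask(stack, mask, subject_ids=[p.name for p in paths])
        return matrix
    if space == "surface":
        raise HarmonizationError(
            "surface inputs must be supplied as (LH, RH) pairs via surface_pairs")
    # per-subject network / table files: square matrices -> upper triangle;
    # raw numeric matrices carry no header row
    rows, n_side = [], None
    for p in paths:
        ext = _extension(p)
        if ext in (".csv", ".tsv", ".txt"):
            arr = np.asarray(pd.read_csv(p, header=None, sep=None,
                                         engine="python"), dtype=float)
        else:
            arr = read_table(p, enable_mat).to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise HarmonizationError(
                f"{p} is not a square network matrix (shape {arr.shape})")
        if n_side is None:
            n_side = arr.shape[0]
        elif arr.shape[0] != n_side:
            raise HarmonizationError("network matrices differ in size across subjects")
        rows.append(vectorize_network(arr))
    return FeatureMatrix(np.vstack(rows), [p.name for p in paths],
                         network_feature_index(n_side), "network")


def _read_surfaces(pairs, mask: MaskSpec | None) -> FeatureMatrix:
    lh_stack = [_read_gifti_data(lh) for lh, _ in pairs]
    rh_stack = [_read_gifti_data(rh) for _, rh in pairs]
    n_lh, n_rh = lh_stack[0].size, rh_stack[0].size
    if mask is None or mask.kind == "none":
        import warnings
        warnings.warn("no surface mask: including every vertex is not recommended",
                      UserWarning)
        lh_mask = np.ones(n_lh, dtype=bool)
        rh_mask = np.ones(n_rh, dtype=bool)
    else:
        if mask.kind != "surface_pair":
            raise HarmonizationError("surface runs need a surface_pair mask")
        lh_mask, rh_mask = mask.grid
        if lh_mask.size != n_lh or rh_mask.size != n_rh:
            raise HarmonizationError(
                "surface mask sizes do not match the data "
                f"({lh_mask.size}/{rh_mask.size} vs {n_lh}/{n_rh} vertices)")
    values, ids = [], []
    for (lh_path, _rh), lh, rh in zip(pairs, lh_stack, rh_stack):
        if lh.size != n_lh or rh.size != n_rh:
            raise HarmonizationError("surface files differ in vertex count")
        values.append(np.concatenate([lh[lh_mask], rh[rh_mask]]))
        ids.append(Path(lh_path).name)
    index = [("L", int(v)) for v in np.flatnonzero(lh_mask)] + \
            [("R", int(v)) for v in np.flatnonzero(rh_mask)]
    return FeatureMatrix(np.vstack(values), ids, index, "surface")


def _read_organized_table(path: Path, enable_mat: bool) -> FeatureMatrix:
    df = read_table(path, enable_mat)
    first = df.columns[0]
    id_col = None
    try:
        pd.to_numeric(df[first])
    except (ValueError, TypeError):
        id_col = first
    if id_col is not None:
        ids = df[id_col].astype(str).tolist()
        data = df.drop(columns=[id_col])
    else:
        ids = [f"sub{j:04d}" for j in range(len(df))]
        data = df
    return FeatureMatrix(data.to_numpy(dtype=float), ids,
                         list(data.columns), "table")


# ---------------------------------------------------------------------------
# writing

def _check_out_dir(out_dir: Path, input_dirs) -> None:
    out_res = out_dir.resolve()
    for d in input_dirs:
        if Path(d).resolve() == out_res:
            raise HarmonizationError(
                f"output directory {out_dir} equals an input directory; "
                "outputs must not cover the inputs")


def write_harmonized(matrix: FeatureMatrix, out_dir,
                     layout: SiteFileLayout | None = None,
                     organized_source=None, mask: MaskSpec | None = None,
                     data_shape: tuple | None = None,
                     organize_csv: bool = False,
                     network_output: str = "upper",
                     surface_pairs: list | None = None,
                     surface_mask: MaskSpec | None = None) -> list:
    """Write harmonized outputs mirroring the input layout.

    Per-file input -> same filename and type under ``out_dir/site/route``;
    organized table -> same extension with a ``Harmonized_`` prefix; with
    ``organize_csv`` an additional ``HarmonizationResults.csv`` (rows =
    subjects, columns = features, first column = subject ID).
    """
    out_dir = Path(out_dir)
    written = []
    if layout is not None and layout.resolved:
        _check_out_dir(out_dir, {p.parent for _, p in layout.resolved})
        if surface_pairs is not None:
            written += _write_surfaces(matrix, out_dir, layout, surface_pairs,
                                       surface_mask)
        else:
            written += _write_per_file(matrix, out_dir, layout, mask,
                                       data_shape, network_output)
    elif organized_source is not None:
        src = Path(organized_source)
        _check_out_dir(out_dir, [src.parent])
        out_dir.mkdir(parents=True, exist_ok=True)
        target = out_dir / f"Harmonized_{src.name}"
        df = pd.DataFrame(matrix.values, columns=[str(c) for c in matrix.feature_index])
        df.insert(0, "SubjectID", matrix.subject_ids)
        ext = _extension(src)
        if ext == ".csv":
            df.to_csv(target, index=False)
        elif ext in (".tsv", ".txt"):
            df.to_csv(target, sep="\t", index=False)
        elif ext == ".xlsx":
            df.to_excel(target, index=False)
        else:
            raise HarmonizationError(f"cannot write organized output as {ext!r}")
        written.append(target)
    else:
        out_dir.mkdir(parents=True, exist_ok=True)

    if organize_csv:
        out_dir.mkdir(parents=True, exist_ok=True)
        target = out_dir / "HarmonizationResults.csv"
        df = pd.DataFrame(matrix.values, columns=[str(c) for c in matrix.feature_index])
        df.insert(0, "SubjectID", matrix.subject_ids)
        df.to_csv(target, index=False)
        written.append(target)
    return written


def _site_route_target(out_dir: Path, layout: SiteFileLayout, site: str,
                       path: Path) -> Path:
    parent = next(Path(d) for d in layout.parent_dirs if Path(d).name == site)
    rel = path.relative_to(parent)
    target = out_dir / site / rel
    target.parent.mkdir(parents=True, exist_ok=True)
    return target


def _write_per_file(matrix, out_dir, layout, mask, data_shape, network_output):
    written = []
    for row, (site, path) in zip(range(matrix.n_subjects), layout.resolved):
        target = _site_route_target(out_dir, layout, site, path)
        ext = _extension(path)
        if ext in VOLUME_EXTENSIONS:
            src_img = nib.load(str(path))
            shape = data_shape or src_img.shape
            vol = _unmask_row(matrix.values[row], mask or MaskSpec("none"), shape)
            out_img = nib.Nifti1Image(vol, src_img.affine, src_img.header)
            # compressed iff the input was compressed (same extension)
            nib.save(out_img, str(target))
        elif ext in TABLE_EXTENSIONS:
            n_side = _network_side(matrix.n_features)
            net = rebuild_network(matrix.values[row], n_side, network_output)
            sep = "," if ext == ".csv" else "\t"
            np.savetxt(target, net, delimiter=sep)
        else:
            raise HarmonizationError(f"cannot write per-file output as {ext!r}")
        written.append(target)
    return written


def _write_surfaces(matrix, out_dir, layout, surface_pairs, surface_mask):
    written = []
    lh_mask, rh_mask = surface_mask.grid
    n_lh = int(lh_mask.sum())
    for row, ((site_lh, lh_path), (site_rh, rh_path)) in enumerate(surface_pairs):
        feats = matrix.values[row]
        for (site, path, hemimask, vals) in (
                (site_lh, Path(lh_path), lh_mask, feats[:n_lh]),
                (site_rh, Path(rh_path), rh_mask, feats[n_lh:])):
            full = np.zeros(hemimask.size, dtype=np.float32)
            full[hemimask] = vals
            target = _site_route_target(out_dir, layout, site, path)
            img = nib.gifti.GiftiImage(darrays=[nib.gifti.GiftiDataArray(full)])
            nib.save(img, str(target))
            written.append(target)
    return written


def _unmask_row(row: np.ndarray, mask: MaskSpec, shape: tuple) -> np.ndarray:
    if mask.kind == "volume":
        sel = mask.grid.ravel(order="C")
    else:
        sel = np.ones(int(np.prod(shape)), dtype=bool)
    if row.size != int(sel.sum()):
        raise HarmonizationError(
            f"row has {row.size} features but mask selects {int(sel.sum())} cells")
    flat = np.zeros(sel.shape, dtype=float)
    flat[sel] = row
    return flat.reshape(shape)


def _network_side(n_features: int) -> int:
    n = int((1 + np.sqrt(1 + 8 * n_features)) / 2)
    if n * (n - 1) // 2 != n_features:
        raise HarmonizationError(
            f"{n_features} features do not form a strict upper triangle")
    return n


def create_filelist(demographics_path, resolved, surface: bool = False):
    """Augment a demographic file with FileList column(s); save as New_<name>.

    ``resolved`` is the (site, path) list from :func:`discover_site_files`
    (or, for surfaces, a list of ((site, lh), (site, rh)) pairs).
    """
    demographics_path = Path(demographics_path)
    table = read_table(demographics_path)
    if surface:
        if len(table) != len(resolved):
            raise HarmonizationError(
                f"{len(table)} demographic rows but {len(resolved)} file pairs")
        table = table.copy()
        table["FileListLH"] = [str(Path(lh)) for ((_, lh), _) in resolved]
        table["FileListRH"] = [str(Path(rh)) for (_, (_, rh)) in resolved]
    else:
        if len(table) != len(resolved):
            raise HarmonizationError(
                f"{len(table)} demographic rows but {len(resolved)} files")
        table = table.copy()
        table["FileList"] = [str(Path(p)) for (_, p) in resolved]
    target = demographics_path.with_name("New_" + demographics_path.name)
    ext = _extension(demographics_path)
    if ext == ".csv":
        table.to_csv(target, index=False)
    elif ext == ".xlsx":
        table.to_excel(target, index=False)
    else:
        table.to_csv(target, sep="\t", index=False)
    return target, table
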