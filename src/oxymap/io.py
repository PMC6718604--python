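"""File formats for every pipeline object.

Phantoms travel as a pair of single-page 32-bit float TIFFs (pO2, density)
plus a YAML sidecar; tissue images as 8-bit RGB PNG with boolean-mask and
class-truth PNGs; projection sets as a YAML header plus a float32 ``.npy``
matrix; cubes as multi-page float32 TIFF (one page per spectral plane) plus a
YAML header; calibrations as a 3-column whitespace table with a fitted-
coefficient sidecar; map statistics as a one-row CSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .acquisition import AcquisitionScheme, ProjectionSet, build_scheme
from .oximetry import MapStats, OxygenMap
from .phantom import OxygenPhantom, TissueImage
from .recon import ReconConfig, SpectralImageCube
from .spectral import CalibrationCurve, Spectrum, fit_calibration

__all__ = [
    "save_phantom", "load_phantom",
    "save_tissue_image", "load_tissue_image",
    "save_projections", "load_projections",
    "save_cube", "load_cube",
    "save_calibration", "load_calibration",
    "save_spectrum", "load_spectrum",
    "save_oxygen_map", "stats_to_frame",
]


def _write_yaml(path, payload):
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_phantom(phantom: OxygenPhantom, basepath: str) -> None:
    """Write ``<base>_po2.tif``, ``<base>_density.tif``, ``<base>_mask.png``, ``<base>.yaml``."""
    tifffile.imwrite(basepath + "_po2.tif", phantom.po2_grid.astype(np.float32))
    tifffile.imwrite(basepath + "_density.tif", phantom.density_grid.astype(np.float32))
    Image.fromarray((phantom.tumor_mask * 255).astype(np.uint8)).save(basepath + "_mask.png")
    _write_yaml(basepath + ".yaml", {
        "pixel_size_cm": float(phantom.pixel_size),
        "fov_cm": float(phantom.fov),
        "seed": phantom.seed,
    })


def load_phantom(basepath: str) -> OxygenPhantom:
    meta = _read_yaml(basepath + ".yaml")
    po2 = tifffile.imread(basepath + "_po2.tif").astype(float)
    density = tifffile.imread(basepath + "_density.tif").astype(float)
    mask = np.asarray(Image.open(basepath + "_mask.png")) > 127
    return OxygenPhantom(po2, density, mask, meta["pixel_size_cm"], meta.get("seed"))


def save_tissue_image(image: TissueImage, basepath: str) -> None:
    Image.fromarray(image.rgb).save(basepath + ".png")
    if image.roi_mask is not None:
        Image.fromarray((image.roi_mask * 255).astype(np.uint8)).save(basepath + "_roi.png")
    if image.class_truth is not None:
        Image.fromarray(image.class_truth).save(basepath + "_truth.png")


def load_tissue_image(basepath: str) -> TissueImage:
    rgb = np.asarray(Image.open(basepath + ".png").convert("RGB"))
    roi = None
    truth = None
    if os.path.exists(basepath + "_roi.png"):
        roi = np.asarray(Image.open(basepath + "_roi.png")) > 127
    if os.path.exists(basepath + "_truth.png"):
        truth = np.asarray(Image.open(basepath + "_truth.png"))
    return TissueImage(rgb=rgb, roi_mask=roi, class_truth=truth)


def save_projections(ps: ProjectionSet, basepath: str) -> None:
    sch = ps.scheme
    _write_yaml(basepath + ".yaml", {
        "n_spatial": sch.n_spatial, "n_spectral": sch.n_spectral,
        "g_max": sch.g_max, "fov_spatial": sch.fov_spatial,
        "fov_spectral": sch.fov_spectral, "n_points": sch.n_points,
        "center_field": sch.center_field,
        "noise_sd": float(ps.noise_sd), "seed": ps.seed,
    })
    np.save(basepath + ".npy", ps.spectra.astype(np.float32))


def load_projections(basepath: str) -> ProjectionSet:
    meta = _read_yaml(basepath + ".yaml")
    scheme = build_scheme(
        n_spatial=meta["n_spatial"], n_spectral=meta["n_spectral"],
        g_max=meta["g_max"], fov_spatial=meta["fov_spatial"],
        fov_spectral=meta["fov_spectral"], n_points=meta["n_points"],
        center_field=meta["center_field"],
    )
    spectra = np.load(basepath + ".npy").astype(float)
    return ProjectionSet(scheme=scheme, spectra=spectra,
                         noise_sd=meta.get("noise_sd", 0.0), seed=meta.get("seed"))


def save_cube(cube: SpectralImageCube, basepath: str) -> None:
    # one TIFF page per spectral plane
    pages = np.moveaxis(cube.values.astype(np.float32), 2, 0)
    tifffile.imwrite(basepath + ".tif", pages)
    cfg = cube.config
    _write_yaml(basepath + ".yaml", {
        "fov_spatial": float(cube.fov_spatial),
        "fov_spectral": float(cube.fov_spectral),
        "center_field": float(cube.center_field),
        "n_out_spectrum": cfg.n_out_spectrum,
        "interp_factor": cfg.interp_factor,
        "filter_name": cfg.filter_name,
        "filter_cutoff": cfg.filter_cutoff,
        "image_size": cfg.image_size,
        "missing_cone": cfg.missing_cone,
    })


def load_cube(basepath: str) -> SpectralImageCube:
    meta = _read_yaml(basepath + ".yaml")
    pages = tifffile.imread(basepath + ".tif").astype(float)
    values = np.moveaxis(pages, 0, 2)
    config = ReconConfig(
        n_out_spectrum=meta["n_out_spectrum"], interp_factor=meta["interp_factor"],
        filter_name=meta["filter_name"], filter_cutoff=meta["filter_cutoff"],
        image_size=meta["image_size"], missing_cone=meta["missing_cone"],
    )
    return SpectralImageCube(values=values, fov_spatial=meta["fov_spatial"],
                             fov_spectral=meta["fov_spectral"],
                             center_field=meta["center_field"], config=config)


def save_calibration(curve: CalibrationCurve, basepath: str) -> None:
    """3-column text table (pO2_torr, linewidth_G, weight) + coefficient sidecar."""
    with open(basepath + ".tsv", "w") as fh:
        fh.write("po2_torr\tlinewidth_G\tweight\n")
        for p, w in curve.fit_points:
            fh.write(f"{p:.6g}\t{w:.6g}\t1\n")
    _write_yaml(basepath + ".yaml", {
        "intercept_G": float(curve.intercept),
        "slope_G_per_torr": float(curve.slope),
        "residual_rms_G": float(curve.residual_rms),
    })


def load_calibration(basepath: str) -> CalibrationCurve:
    tab = pd.read_csv(basepath + ".tsv", sep="\t")
    return fit_calibration(list(zip(tab["po2_torr"], tab["linewidth_G"])))


def save_spectrum(spectrum: Spectrum, path: str) -> None:
    np.savetxt(path, np.column_stack([spectrum.field_axis, spectrum.intensity]),
               header="field_G intensity", comments="# ")


def load_spectrum(path: str) -> Spectrum:
    data = np.loadtxt(path)
    return Spectrum(field_axis=data[:, 0], intensity=data[:, 1])


def save_oxygen_map(omap: OxygenMap, basepath: str) -> None:
    tifffile.imwrite(basepath + "_po2.tif", omap.po2.astype(np.float32))
    Image.fromarray((omap.valid_mask * 255).astype(np.uint8)).save(basepath + "_mask.png")


def stats_to_frame(stats: MapStats) -> pd.DataFrame:
    """One-row table of the summary statistics (histogram as its own columns)."""
    row = {
        "mean_po2_torr": stats.mean_po2,
        "median_po2_torr": stats.median_po2,
        "hf10": stats.hf10,
        "n_valid": stats.n_valid,
    }
    for lo, hi, c in zip(stats.bin_edges[:-1], stats.bin_edges[1:], stats.histogram):
        row[f"hist_{lo:g}_{hi:g}"] = int(c)
    return pd.DataFrame([row])
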