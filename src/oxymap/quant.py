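"""Class-pixel fraction quantification of tumor tissue images.

Operationalizes the standard figure-caption quantities: the Doppler flow
fraction (red pixels / tumor area), the pimonidazole-positive hypoxic
fraction (green pixels / tumor area) and the endothelial vessel fraction
(dark pixels / total pixels).  Pixels are classified by simple per-channel
threshold rules with an optional dominance margin; the default rules are
tuned to the synthetic fixture palette and are fully configurable for real
images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .phantom import TissueImage

__all__ = [
    "ColorClassRule",
    "PixelFractionReport",
    "FLOW_RULE",
    "POSITIVE_RULE",
    "VESSEL_RULE",
    "DEFAULT_RULES",
    "classify_pixels",
    "flow_fraction",
    "positive_fraction",
    "vessel_fraction",
    "summarize_reports",
    "quantify_batch",
]


@dataclass(frozen=True)
class ColorClassRule:
    """Per-channel inclusive RGB thresholds plus an optional dominance margin.

    A pixel belongs to the class when every channel lies in
    [mins[c], maxs[c]] and, if ``dominant_channel`` is set, that channel
    exceeds each other channel by at least ``margin``.
    """

    class_name: str
    mins: tuple = (0, 0, 0)
    maxs: tuple = (255, 255, 255)
    dominant_channel: Optional[int] = None
    margin: int = 0

    def __post_init__(self):
        for v in (*self.mins, *self.maxs):
            if not 0 <= v <= 255:
                raise ValueError("thresholds must be within [0, 255]")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")


FLOW_RULE = ColorClassRule("flow", mins=(150, 0, 0), dominant_channel=0, margin=50)
POSITIVE_RULE = ColorClassRule("positive", mins=(0, 150, 0), dominant_channel=1, margin=50)
VESSEL_RULE = ColorClassRule("vessel", maxs=(60, 60, 60))

DEFAULT_RULES = {"flow": FLOW_RULE, "positive": POSITIVE_RULE, "vessel": VESSEL_RULE}


@dataclass(frozen=True)
class PixelFractionReport:
    """One image's class-pixel fraction: n_class / n_roi."""

    class_name: str
    n_class: int
    n_roi: int
    fraction: float
    image_id: str = ""
    rule: Optional[ColorClassRule] = None


def classify_pixels(image: TissueImage, rule: ColorClassRule) -> np.ndarray:
    """Boolean per-pixel class membership; deterministic, ROI-independent."""
    rgb = image.rgb.astype(np.int16)
    ok = np.ones(image.shape, dtype=bool)
    for c in range(3):
        ok &= (rgb[..., c] >= rule.mins[c]) & (rgb[..., c] <= rule.maxs[c])
    if rule.dominant_channel is not None:
        d = rule.dominant_channel
        for c in range(3):
            if c != d:
                ok &= rgb[..., d] - rgb[..., c] >= rule.margin
    return ok


def _fraction(image: TissueImage, rule: ColorClassRule, image_id: str,
              whole_image_fallback: bool) -> PixelFractionReport:
    members = classify_pixels(image, rule)
    if image.roi_mask is not None:
        roi = image.roi_mask
    elif whole_image_fallback:
        roi = np.ones(image.shape, dtype=bool)
    else:
        raise ValueError("image has no ROI mask")
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("empty ROI")
    n_class = int(np.count_nonzero(members & roi))
    return PixelFractionReport(
        class_name=rule.class_name, n_class=n_class, n_roi=n_roi,
        fraction=n_class / n_roi, image_id=image_id, rule=rule,
    )


def flow_fraction(image: TissueImage, rule: ColorClassRule = FLOW_RULE,
                  image_id: str = "") -> PixelFractionReport:
    """Doppler blood-flow fraction: flow-class pixels within the tumor ROI."""
    return _fraction(image, rule, image_id, whole_image_fallback=False)


def positive_fraction(image: TissueImage, rule: ColorClassRule = POSITIVE_RULE,
                      image_id: str = "") -> PixelFractionReport:
    """Hypoxia-marker-positive fraction: green pixels within the tumor ROI."""
    return _fraction(image, rule, image_id, whole_image_fallback=False)


def vessel_fraction(image: TissueImage, rule: ColorClassRule = VESSEL_RULE,
                    image_id: str = "") -> PixelFractionReport:
    """Endothelial vessel fraction: dark pixels over the whole image, or over
    the ROI when one is present."""
    return _fraction(image, rule, image_id, whole_image_fallback=True)


def quantify_batch(manifest_path: str, class_name: str, rule: Optional[ColorClassRule] = None):
    """Quantify a manifest of stored images: one report row each + group summary.

    The manifest is a CSV/TSV table with columns ``image_base`` (base path as
    written by :func:`oxymap.io.save_tissue_image`), optional ``group`` and
    ``timepoint``.  Returns (per-image DataFrame, group-summary DataFrame).
    """
    from . import io as oio  # deferred: keeps the module import light

    rule = rule or DEFAULT_RULES[class_name]
    fn = {"flow": flow_fraction, "positive": positive_fraction, "vessel": vessel_fraction}[class_name]
    table = pd.read_csv(manifest_path, sep=None, engine="python")
    reports = []
    rows = []
    groups = {}
    for _, entry in table.iterrows():
        base = str(entry["image_base"])
        rep = fn(oio.load_tissue_image(base), rule, image_id=base)
        reports.append(rep)
        group = str(entry.get("group", "all")) if "group" in table.columns else "all"
        groups[base] = group
        rows.append({
            "image_base": base,
            "group": group,
            "timepoint": entry.get("timepoint", ""),
            "class_name": rep.class_name,
            "n_class": rep.n_class,
            "n_roi": rep.n_roi,
            "fraction": rep.fraction,
        })
    per_image = pd.DataFrame(rows)
    summary = summarize_reports(reports, group_keys=groups)
    return per_image, summary


def summarize_reports(reports, group_keys=None) -> pd.DataFrame:
    """Aggregate per-image reports into mean fraction +/- SEM per class.

    ``group_keys`` optionally maps image_id -> group label; without it all
    reports of one class form a single group (mirroring per-figure averages).
    """
    rows = [
        {
            "image_id": r.image_id,
            "class_name": r.class_name,
            "fraction": r.fraction,
            "group": (group_keys or {}).get(r.image_id, "all"),
        }
        for r in reports
    ]
    df = pd.DataFrame(rows)
    grouped = df.groupby(["group", "class_name"])["fraction"]
    out = grouped.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_fraction", "sem": "sem_fraction", "count": "n_images"})
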