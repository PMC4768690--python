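"""End-to-end helpers: image -> contour signal -> STFT features -> DataFrame.

These functions glue the contour and spectral stages together under one
:class:`~otolithid.config.RunConfig`, and are what the CLI commands call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig
from .contour import ContourSignal, binarize, clean_mask, extract_outline, radius_signal
from .spectral import FeatureVector, extract_features, feature_names, resample_fft, stft

__all__ = [
    "image_to_signal",
    "image_to_features",
    "records_to_features",
    "select_feature_columns",
]


def image_to_signal(img: np.ndarray, config: RunConfig | None = None) -> ContourSignal:
    """Grayscale image -> polar radius signature of the largest object."""
    config = config or RunConfig()
    mask = clean_mask(binarize(img, config.threshold), config.min_area)
    outline = extract_outline(mask)
    return radius_signal(outline, ordering=config.ordering)


def features_from_signal(signal: ContourSignal, config: RunConfig | None = None) -> FeatureVector:
    config = config or RunConfig()
    x = resample_fft(signal, config.resample_n)
    spec = stft(x, config.window, nfft=config.nfft)
    return extract_features(spec, ddof=config.zscore_ddof)


def image_to_features(img: np.ndarray, config: RunConfig | None = None) -> FeatureVector:
    """Full single-image pipeline: segment, trace, resample, STFT, features."""
    return features_from_signal(image_to_signal(img, config), config)


def select_feature_columns(df: pd.DataFrame, feature_set: str, n_segments: int) -> pd.DataFrame:
    """Restrict a feature table to the requested feature subset."""
    keep = [c for c in df.columns if not (c.startswith("f") and c[1:].isdigit())]
    return df[keep + feature_names(n_segments, feature_set)]


def records_to_features(records, config: RunConfig | None = None) -> pd.DataFrame:
    """Feature table for synthetic specimen records (image_id, species, split, f01..)."""
    config = config or RunConfig()
    rows = []
    for rec in records:
        fv = image_to_features(rec.image, config)
        row = {"image_id": rec.image_id, "label": rec.species, "split": rec.split}
        names = feature_names(fv.max_abs.size, "combined")
        row.update(dict(zip(names, fv.combined)))
        rows.append(row)
    return pd.DataFrame(rows)
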