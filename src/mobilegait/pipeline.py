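"""End-to-end convenience: dataset -> windows -> feature matrix."""

from __future__ import annotations

import pandas as pd

from .containers import AnalysisWindow
from .features.catalog import FeatureCatalog
from .features.matrix import compute_feature_matrix, window_meta
from .preprocess import preprocess_and_window
from .simulate import GaitDataset


def dataset_windows(dataset: GaitDataset) -> list[AnalysisWindow]:
    """Preprocess and window every video of a dataset (manifest order)."""
    windows: list[AnalysisWindow] = []
    for vid in dataset.manifest["video_id"]:
        windows.extend(preprocess_and_window(dataset.sequences[vid]))
    return windows


def dataset_features(dataset: GaitDataset,
                     catalog: FeatureCatalog | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full front half of the pipeline: (feature matrix, row metadata)."""
    windows = dataset_windows(dataset)
    X = compute_feature_matrix(windows, catalog)
    meta = window_meta(windows)
    return X, meta
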