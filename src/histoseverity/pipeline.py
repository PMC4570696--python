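"""End-to-end convenience: cutouts -> pooled responses -> feature matrix."""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .features import FeatureVector, extract_features, feature_names
from .gaborbank import FilterBank, build_bank, pooled_response_stack

__all__ = ["compute_features", "compute_feature_matrix"]


def compute_features(
    cutout,
    bank: FilterBank | None = None,
    bins: int = 256,
    cutout_id: str = "",
) -> FeatureVector:
    """Full feature extraction for one cutout (convolution, pooling, stats)."""
    bank = bank if bank is not None else build_bank()
    cutout_id = cutout_id or getattr(cutout, "cutout_id", "")
    stack = pooled_response_stack(cutout, bank)
    return extract_features(stack, bins=bins, cutout_id=cutout_id)


def compute_feature_matrix(
    cutouts: Iterable,
    bank: FilterBank | None = None,
    bins: int = 256,
    progress: bool = False,
) -> pd.DataFrame:
    """Feature matrix (rows = cutouts) for a collection of cutouts.

    Cutout ids are taken from each object's ``cutout_id`` attribute when
    present, else the enumeration index.  Column order is the canonical
    bank layout.
    """
    bank = bank if bank is not None else build_bank()
    names = feature_names(bank)
    rows, ids = [], []
    for i, cut in enumerate(cutouts):
        cid = getattr(cut, "cutout_id", "") or str(i)
        fv = compute_features(cut, bank=bank, bins=bins, cutout_id=cid)
        rows.append(fv.values)
        ids.append(cid)
        if progress:
            print(f"  features {i + 1}: {cid}", flush=True)
    return pd.DataFrame(np.vstack(rows), index=ids, columns=list(names))
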