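"""End-to-end glue: cohort -> segmentation -> 80-column feature table."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import schema
from ._types import EpochSet, LabelSequence, Recording, TemplateSet
from .dynamics import complexity_vector, higher_order_vector
from .microstates import assign_labels, extract_peak_maps, learn_templates
from .preprocess import epoch_recording, reject_epochs
from .spectral import spectral_vector
from .temporal import temporal_vector

__all__ = ["segment_cohort", "subject_features", "extract_features"]


def segment_cohort(recordings: list[Recording], K: int = 4, seed: int = 42,
                   window: float = 2.0, overlap: float = 0.5,
                   reject: bool = False, amp_limit: float = 100.0,
                   var_z_limit: float = 3.0, min_peak_distance: int = 2,
                   ignore_polarity: bool = False
                   ) -> tuple[TemplateSet, list[EpochSet], list[LabelSequence]]:
    """Epoch every recording, learn pooled templates, back-fit labels.

    Templates are learned group-blind from GFP-peak maps pooled across all
    subjects and epochs; each subject is then labeled sample-by-sample.
    """
    epochsets = [epoch_recording(r, window=window, overlap=overlap)
                 for r in recordings]
    if reject:
        epochsets = [reject_epochs(es, amp_limit=amp_limit,
                                   var_z_limit=var_z_limit)
                     for es in epochsets]
    maps = np.vstack([extract_peak_maps(es, min_peak_distance=min_peak_distance)
                      for es in epochsets])
    templates = learn_templates(maps, K=K, seed=seed,
                                ignore_polarity=ignore_polarity,
                                ch_names=list(recordings[0].ch_names))
    labels = [assign_labels(es, templates, ignore_polarity=ignore_polarity)
              for es in epochsets]
    return templates, epochsets, labels


def subject_features(es: EpochSet, labels: LabelSequence,
                     K: int = schema.N_STATES) -> dict[str, float]:
    """One subject's 80 canonical features, in schema column order."""
    vals: dict[str, float] = {}
    vals.update(temporal_vector(labels, K=K))
    vals.update(spectral_vector(es, labels, K=K))
    vals.update(complexity_vector(labels))
    vals.update(higher_order_vector(labels, K=K))
    return {name: vals[name] for name in schema.FEATURE_NAMES}


def extract_features(recordings: list[Recording], groups=None, K: int = 4,
                     seed: int = 42, reject: bool = False,
                     ignore_polarity: bool = False) -> pd.DataFrame:
    """Full pipeline to a subjects x (80 features + group) table.

    Returns a DataFrame indexed by subject id whose first 80 columns are
    the canonical feature schema, plus a trailing ``group`` column (empty
    strings when ``groups`` is None).
    """
    _, epochsets, labels = segment_cohort(recordings, K=K, seed=seed,
                                          reject=reject,
                                          ignore_polarity=ignore_polarity)
    rows = []
    index = []
    for i, (es, lab) in enumerate(zip(epochsets, labels)):
        rows.append(subject_features(es, lab, K=K))
        index.append(es.subject or f"subject{i:03d}")
    table = pd.DataFrame(rows, index=pd.Index(index, name="subject"))
    table["group"] = list(groups) if groups is not None else ""
    return table
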