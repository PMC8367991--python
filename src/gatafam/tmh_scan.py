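"""Hydropathy-based transmembrane-helix (TMH) flagging.

A sliding Kyte-Doolittle window marks candidate membrane-bound family
members (MTFs).  This is a deliberately simple, fully documented
predictor; externally produced TMH spans (e.g. from a dedicated HMM
predictor) can be imported as a TSV instead for real-data runs.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._util import KYTE_DOOLITTLE


def hydropathy_profile(protein: str, window: int = 19) -> np.ndarray:
    """Centered moving average of Kyte-Doolittle values.

    Positions without a full window are NaN (ends truncated, no padding).
    Unknown residues take the scale's mean value.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(protein):
        raise ValueError("window longer than protein")
    mean_kd = float(np.mean(list(KYTE_DOOLITTLE.values())))
    vals = np.array([KYTE_DOOLITTLE.get(a, mean_kd) for a in protein.upper()])
    kernel = np.ones(window) / window
    core = np.convolve(vals, kernel, mode="valid")
    half = window // 2
    out = np.full(len(protein), np.nan)
    out[half: len(protein) - half] = core
    return out


def predict_tmh(
    profile: np.ndarray, threshold: float = 1.6, min_len: int = 15
) -> list:
    """Maximal runs of window-centre positions >= threshold, of length
    >= min_len, as [start, end) spans."""
    above = np.nan_to_num(profile, nan=-np.inf) >= threshold
    spans = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                spans.append((start, i))
            start = None
    if start is not None and len(above) - start >= min_len:
        spans.append((start, len(above)))
    return spans


def scan_tmh(
    proteins: dict, window: int = 19, threshold: float = 1.6, min_len: int = 15
) -> pd.DataFrame:
    """Per-isoform TMH spans over a protein dict (id -> sequence)."""
    rows = []
    for pid, seq in proteins.items():
        if len(seq) < window:
            continue
        prof = hydropathy_profile(seq, window)
        for s, e in predict_tmh(prof, threshold, min_len):
            rows.append(
                {
                    "protein_id": pid,
                    "start": s,
                    "end": e,
                    "mean_hydropathy": float(np.nanmean(prof[s:e])),
                }
            )
    return pd.DataFrame(rows, columns=["protein_id", "start", "end", "mean_hydropathy"])


def import_external_tmh(path: str) -> pd.DataFrame:
    """Read externally predicted TMH spans (TSV: protein_id, start, end)."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"external TMH table must have columns {sorted(required)}")
    return df
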