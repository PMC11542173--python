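"""Electrode montage utilities: 64-channel 10/20 layout, 2D projection, topographic weights.

Coordinates come from MNE's idealized ``standard_1005`` head positions and are
projected to the plane with an azimuthal-equidistant projection (the standard
"topomap" flattening), so that planar distances approximate along-scalp
distances. The projected frame keeps the EEG convention: +x toward the right
ear, +y toward the nose.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

# 64-channel actiCAP-style extension of the international 10/20 system
# (the layout used with 64 active Ag/AgCl electrode caps).
CHANNELS_64 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
)


# Classic 19-electrode 10/20 subset; a lighter montage for simulation studies.
CHANNELS_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)


def _azimuthal_project(xyz: np.ndarray) -> np.ndarray:
    """Project 3D scalp positions onto the plane, preserving angular distance
    from the vertex. Rows are (x, y, z) in head coordinates; output is (n, 2)."""
    xyz = np.asarray(xyz, dtype=float)
    norms = np.linalg.norm(xyz, axis=1, keepdims=True)
    unit = xyz / norms
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))  # polar angle from vertex
    phi = np.arctan2(unit[:, 1], unit[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


def montage_positions(labels: tuple[str, ...] | list[str] = CHANNELS_64) -> pd.DataFrame:
    """Return a (label, x, y) table of 2D-projected electrode positions.

    Positions are looked up in MNE's ``standard_1005`` montage (a superset of
    the 10/20 and 10/10 systems), head-centered, then azimuthally projected.
    """
    import mne  # deferred: only needed when the built-in layout is requested

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1005")
    pos3d = montage.get_positions()["ch_pos"]
    missing = [lab for lab in labels if lab not in pos3d]
    if missing:
        raise KeyError(f"labels not in the standard 10/05 montage: {missing}")
    xyz = np.array([pos3d[lab] for lab in labels])
    # Head-center so the vertex projection is well defined.
    xyz = xyz - xyz.mean(axis=0, keepdims=True) * np.array([1.0, 1.0, 0.0])
    xy = _azimuthal_project(xyz)
    return pd.DataFrame({"label": list(labels), "x": xy[:, 0], "y": xy[:, 1]})


def load_positions(path) -> pd.DataFrame:
    """Read a tab-separated (label, x, y) electrode table."""
    df = pd.read_csv(path, sep="\t")
    expected = {"label", "x", "y"}
    if not expected.issubset(df.columns):
        raise ValueError(f"montage table must have columns {sorted(expected)}")
    return df[["label", "x", "y"]]


def export_scalp_map(values: dict[str, float], positions: pd.DataFrame,
                     path) -> pd.DataFrame:
    """Write a per-electrode scalar map as a (label, x, y, value) TSV —
    the minimal export for external topographic plotting."""
    table = positions.copy()
    table["value"] = [values.get(lab, np.nan) for lab in table["label"]]
    table.to_csv(path, sep="\t", index=False)
    return table


def posterior_weights(positions: pd.DataFrame, w_min: float = 0.4) -> np.ndarray:
    """Per-channel multipliers implementing a posterior alpha gradient.

    Weights rise linearly from ``w_min`` at the most frontal electrode to 1.0
    at the most posterior one (occipital alpha dominance). Used as the default
    topography for simulated alpha peak heights.
    """
    y = positions["y"].to_numpy(dtype=float)
    span = y.max() - y.min()
    if span <= 0:
        return np.ones_like(y)
    posteriorness = (y.max() - y) / span  # 1 at the back, 0 at the front
    return w_min + (1.0 - w_min) * posteriorness
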