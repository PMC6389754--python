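"""Standard 19-electrode 10-20 montage and 2-D scalp layout.

Electrode positions follow the idealized spherical 10-20 scheme: the vertex
(Cz) at polar angle 0, the mid-coronal ring (Fz, C3, C4, Pz) at 36 deg, and
the circumferential ring (Fp1/2, F7/8, T3/4, T5/6, O1/2) at 72 deg, i.e.
10% above the nasion-inion equator.  F3/F4 and P3/P4 sit midway along the
great-circle arcs Fz-F7 / Fz-F8 and Pz-T5 / Pz-T6, as in the 10-20
placement rules.  Positions are flattened with an azimuthal-equidistant
projection from the vertex (arc length preserved along meridians), so the
head circle (equator, polar 90 deg) maps to a circle of ``head_radius`` mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical 19-channel 10-20 label set, frontal to occipital.
CHANNELS_1020 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

# Modern (10-10) names for the temporal row map onto the classic ones.
_ALIASES = {"t7": "t3", "t8": "t4", "p7": "t5", "p8": "t6"}
_CANONICAL_BY_LOWER = {c.lower(): c for c in CHANNELS_1020}


def normalize_label(label: str) -> str:
    """Map a channel label to its canonical 10-20 name.

    Case-insensitive; modern temporal-row aliases (T7->T3, T8->T4, P7->T5,
    P8->T6) are accepted.  Raises ``ValueError`` for labels outside the
    19-channel set.
    """
    key = label.strip().lower().replace("eeg ", "")
    key = _ALIASES.get(key, key)
    if key not in _CANONICAL_BY_LOWER:
        raise ValueError(f"unknown 10-20 channel label: {label!r}")
    return _CANONICAL_BY_LOWER[key]


@dataclass(frozen=True)
class MontageLayout:
    """2-D electrode layout: labels, positions in mm, and head radius."""

    labels: tuple[str, ...]
    xy: np.ndarray  # (n_channels, 2), mm; +y anterior, +x right
    head_radius: float = 100.0

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float)
        if xy.shape != (len(self.labels), 2):
            raise ValueError("xy must be (n_channels, 2)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate channel labels in layout")
        r = np.hypot(xy[:, 0], xy[:, 1])
        if np.any(r > self.head_radius + 1e-9):
            raise ValueError("electrode outside head circle")
        object.__setattr__(self, "xy", xy)

    def position(self, label: str) -> np.ndarray:
        return self.xy[self.labels.index(normalize_label(label))]

    def index(self, label: str) -> int:
        return self.labels.index(normalize_label(label))


# (polar angle from vertex, azimuth from anterior midline; left negative), deg
_SPHERICAL = {
    "Fp1": (72, -18), "Fp2": (72, 18),
    "F7": (72, -54), "F8": (72, 54),
    "T3": (72, -90), "T4": (72, 90),
    "T5": (72, -126), "T6": (72, 126),
    "O1": (72, -162), "O2": (72, 162),
    "Fz": (36, 0), "Cz": (0, 0), "Pz": (36, 180),
    "C3": (36, -90), "C4": (36, 90),
}
# Parasagittal sites defined as great-circle midpoints.
_MIDPOINTS = {
    "F3": ("Fz", "F7"), "F4": ("Fz", "F8"),
    "P3": ("Pz", "T5"), "P4": ("Pz", "T6"),
}


def _unit_vector(polar_deg: float, az_deg: float) -> np.ndarray:
    p, a = np.deg2rad(polar_deg), np.deg2rad(az_deg)
    return np.array([np.sin(p) * np.sin(a), np.sin(p) * np.cos(a), np.cos(p)])


def _to_polar_az(v: np.ndarray) -> tuple[float, float]:
    v = v / np.linalg.norm(v)
    return float(np.rad2deg(np.arccos(np.clip(v[2], -1, 1)))), float(
        np.rad2deg(np.arctan2(v[0], v[1]))
    )


def standard_1020_layout(head_radius: float = 100.0) -> MontageLayout:
    """The default idealized 19-channel layout (azimuthal-equidistant, mm)."""
    sph = dict(_SPHERICAL)
    for lbl, (a, b) in _MIDPOINTS.items():
        sph[lbl] = _to_polar_az(_unit_vector(*sph[a]) + _unit_vector(*sph[b]))
    xy = np.empty((len(CHANNELS_1020), 2))
    for i, lbl in enumerate(CHANNELS_1020):
        polar, az = sph[lbl]
        r = head_radius * polar / 90.0
        xy[i] = (r * np.sin(np.deg2rad(az)), r * np.cos(np.deg2rad(az)))
    return MontageLayout(labels=CHANNELS_1020, xy=xy, head_radius=head_radius)
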