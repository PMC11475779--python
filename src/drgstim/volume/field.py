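"""Gridded transfer field: volts per 1 mA of electrode current."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class OutsideFieldError(ValueError):
    pass


@dataclass
class PotentialField:
    """Regular-grid potential field, linear in the source current.

    ``values`` are volts per 1 mA at voxel centers; queries interpolate
    trilinearly.  ``contact_center`` (mm) is the centroid of the contact
    surface, used for electrode-to-site distances.
    """

    values: np.ndarray
    axes: tuple
    electrode_kind: str = "custom"
    shift: tuple = (0.0, 0.0, 0.0)
    contact_center: tuple = (0.0, 0.0, 0.0)

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of V-per-mA at points (n, 3) in mm."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.empty(pts.shape[0])
        idx = []
        frac = []
        for d in range(3):
            ax = self.axes[d]
            c = pts[:, d]
            if c.min() < ax[0] - 1e-9 or c.max() > ax[-1] + 1e-9:
                bad = pts[(c < ax[0] - 1e-9) | (c > ax[-1] + 1e-9)][0]
                raise OutsideFieldError(
                    f"point {tuple(bad)} lies outside the solved volume"
                )
            i = np.clip(np.searchsorted(ax, c) - 1, 0, ax.size - 2)
            idx.append(i)
            frac.append((c - ax[i]) / (ax[i + 1] - ax[i]))
        i, j, k = idx
        fx, fy, fz = [np.clip(f, 0.0, 1.0) for f in frac]
        v = self.values
        out = (
            v[i, j, k] * (1 - fx) * (1 - fy) * (1 - fz)
            + v[i + 1, j, k] * fx * (1 - fy) * (1 - fz)
            + v[i, j + 1, k] * (1 - fx) * fy * (1 - fz)
            + v[i, j, k + 1] * (1 - fx) * (1 - fy) * fz
            + v[i + 1, j + 1, k] * fx * fy * (1 - fz)
            + v[i + 1, j, k + 1] * fx * (1 - fy) * fz
            + v[i, j + 1, k + 1] * (1 - fx) * fy * fz
            + v[i + 1, j + 1, k + 1] * fx * fy * fz
        )
        return out

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("phi", data=self.values)
            f.create_dataset("axis_x", data=self.axes[0])
            f.create_dataset("axis_y", data=self.axes[1])
            f.create_dataset("axis_z", data=self.axes[2])
            f.attrs["electrode_kind"] = self.electrode_kind
            f.attrs["shift"] = np.asarray(self.shift)
            f.attrs["contact_center"] = np.asarray(self.contact_center)
            f.attrs["units"] = "V per mA"

    @classmethod
    def load(cls, path) -> "PotentialField":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                values=f["phi"][...],
                axes=(f["axis_x"][...], f["axis_y"][...], f["axis_z"][...]),
                electrode_kind=str(f.attrs["electrode_kind"]),
                shift=tuple(f.attrs["shift"]),
                contact_center=tuple(f.attrs["contact_center"]),
            )


def potential_at(
    field: PotentialField,
    points: np.ndarray,
    amplitude_ua: float,
    phase_sign: int = -1,
) -> np.ndarray:
    """Extracellular potential (V) at points for a stimulation amplitude.

    The stored field is per +1 mA; the cathodic phase uses ``phase_sign``
    -1.  Output scales exactly linearly with amplitude.
    """
    if phase_sign not in (-1, 1):
        raise ValueError("phase_sign must be -1 or +1")
    return field.interpolate(points) * phase_sign * (amplitude_ua * 1e-3)
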