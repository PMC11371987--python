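"""Quantitative CT aeration analysis.

Converts Hounsfield-unit volumes into per-voxel gas and nongaseous
(tissue + fluid) content. The conversion treats fully aerated parenchyma
as air (-1000 HU) and fully consolidated parenchyma as water (0 HU), so
the gas fraction of a voxel is -HU/1000, and gas volume is that fraction
of the voxel volume. The nongaseous volume is the exact complement, so
gas + nongaseous always partitions the voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CTVolume", "AerationMap", "gas_fraction", "aeration_map"]

logger = logging.getLogger(__name__)

#: HU of pure gas (air) and pure nongaseous content (water).
HU_GAS = -1000.0
HU_WATER = 0.0


@dataclass
class CTVolume:
    """A CT volume in Hounsfield units with voxel geometry.

    Parameters
    ----------
    hu : ndarray
        3-D array of Hounsfield units.
    voxel_volume : float
        Volume of one voxel in microliters. Must be positive.
    affine : ndarray, optional
        4x4 voxel-to-world affine (NIfTI convention). Defaults to identity.
    gravity_axis : int
        Array axis aligned with gravity; the dependent (dorsal, in supine
        position) side is the high-index end.
    """

    hu: np.ndarray
    voxel_volume: float
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]
    gravity_axis: int = 1

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=float)
        if self.hu.ndim != 3:
            raise ValueError(f"hu must be 3-D, got ndim={self.hu.ndim}")
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("hu contains non-finite values")
        if not self.voxel_volume > 0:
            raise ValueError(f"voxel_volume must be > 0, got {self.voxel_volume}")
        if self.affine is None:
            self.affine = np.eye(4)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not 0 <= self.gravity_axis < 3:
            raise ValueError(f"gravity_axis must index a volume axis, got {self.gravity_axis}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.hu.shape


@dataclass
class AerationMap:
    """Per-voxel gas and nongaseous volumes (µl) over a lung mask."""

    gas_volume: np.ndarray
    nongaseous_volume: np.ndarray
    mask: np.ndarray
    voxel_volume: float
    n_clamped: int = 0

    @property
    def gas_fraction(self) -> np.ndarray:
        return self.gas_volume / self.voxel_volume


def gas_fraction(hu: np.ndarray | float) -> np.ndarray | float:
    """Gas fraction of a voxel from its CT number.

    Linear between air (-1000 HU, fraction 1) and water (0 HU, fraction 0);
    values outside that physical range are clamped to the nearest boundary,
    so the result always lies in [0, 1].

    Raises
    ------
    ValueError
        If any HU value is non-finite.
    """
    arr = np.asarray(hu, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("HU input contains non-finite values")
    frac = np.clip(-arr / 1000.0, 0.0, 1.0)
    if np.isscalar(hu) or arr.ndim == 0:
        return float(frac)
    return frac


def aeration_map(ct: CTVolume, mask: np.ndarray) -> AerationMap:
    """Decompose a CT volume into gas and nongaseous content maps.

    Per voxel, ``gas = voxel_volume * gas_fraction(HU)`` and
    ``nongaseous = voxel_volume - gas``. Voxels whose HU falls outside
    [-1000, 0] are clamped before conversion; their count is logged and
    recorded on the returned map.

    Parameters
    ----------
    ct : CTVolume
    mask : ndarray of bool
        Lung voxels; must match the CT grid shape.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != ct.hu.shape:
        raise ValueError(f"mask shape {mask.shape} != CT shape {ct.hu.shape}")
    n_clamped = int(np.count_nonzero((ct.hu[mask] < HU_GAS) | (ct.hu[mask] > HU_WATER)))
    if n_clamped:
        logger.warning("aeration_map: %d masked voxels outside [-1000, 0] HU were clamped", n_clamped)
    frac = np.clip(-ct.hu / 1000.0, 0.0, 1.0)
    gas = ct.voxel_volume * frac
    nongas = ct.voxel_volume - gas
    return AerationMap(
        gas_volume=gas,
        nongaseous_volume=nongas,
        mask=mask,
        voxel_volume=ct.voxel_volume,
        n_clamped=n_clamped,
    )
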