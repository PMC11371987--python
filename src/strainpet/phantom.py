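"""Synthetic supine-lung phantoms for end-to-end pipeline testing.

Each phantom is a pair of co-registered CT volumes (reference/ZEEP and an
inflated state), a PET activity volume with a left-ventricle-like blood
pool, a lung mask, and the ground-truth strain and macrophage-activation
fields the generator used — everything the analysis consumes, on a common
grid.

The phantom emulates the statistical structure of a supine, mechanically
ventilated lung:

* a ventral-to-dorsal (gravitational) aeration gradient — gas fraction
  decreases linearly with normalized gravitational depth;
* dependent atelectasis — a dorsal fraction of the lung is completely
  gasless at the reference state (the injured condition uses a deep
  atelectatic zone, healthy lungs a shallow or absent one);
* multiplicative inflation — ventilated voxels multiply their gas content
  by ``inflation_factor`` at the inflated state, capped at gas fraction 1
  (the cap makes the relative expansion, hence the strain, grow toward
  the dependent regions); atelectatic voxels are recruited at high
  inflation pressure and reopen to a fixed gas fraction by default;
* a macrophage-activation field coupled to local strain through a
  saturating link, activation = baseline + kappa * s/(s + s0), with
  tunable coupling strength kappa;
* additive Gaussian CT noise (HU) and additive truncated-at-zero Gaussian
  PET noise.

The geometry is deliberately simple (an ellipsoidal lung, a spherical
blood pool); anatomical realism is a non-goal.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .aeration import CTVolume
from .strain import DEFAULT_FLOOR_FRACTION

__all__ = ["PhantomParams", "Phantom", "generate_phantom", "write_phantom", "read_phantom"]

#: CT numbers for the non-lung background (soft tissue) and the blood pool.
HU_SOFT_TISSUE = 40.0
HU_BLOOD = 45.0


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of a synthetic lung phantom.

    Attributes
    ----------
    grid_shape : tuple of int
        Voxels per axis, ordered (apico-basal, gravitational, lateral).
    voxel_volume : float
        Voxel volume in microliters.
    gravity_axis : int
        Axis aligned with gravity; dependent (dorsal) side at the
        high-index end. Layer index 1 = nondependent.
    aeration_top : float
        Gas fraction at the nondependent boundary, in [0, 1].
    aeration_gradient : float
        Gas-fraction decrease per unit normalized gravitational depth.
    atelectasis_depth_fraction : float
        Fraction of the dependent lung that is fully consolidated at the
        reference state, in [0, 1].
    inflation_factor : float
        Multiplicative gas increase from reference to inflated state in
        ventilated voxels (>= 1); capped at gas fraction 1.
    reopen_atelectasis : bool
        Whether consolidated voxels receive gas at the inflated state
        (recruitment at high inflation pressure). Default True.
    reopened_gas_fraction : float
        Gas fraction of reopened voxels at the inflated state.
    coupling_kappa : float
        Strength, in [0, 1], of the macrophage-signal dependence on local
        strain (MBq/mL at full saturation).
    activation_baseline : float
        Strain-independent lung activity, MBq/mL.
    strain_saturation : float
        Half-saturation strain s0 of the activation link function.
    blood_pool_activity : float
        Mean activity in the blood-pool reference ROI, MBq/mL.
    background_activity : float
        Activity outside lung and blood pool, MBq/mL.
    pet_noise_sd, ct_noise_sd : float
        Additive noise scales (MBq/mL and HU).
    seed : int
        RNG seed; identical seeds give identical phantoms.
    """

    grid_shape: tuple[int, int, int] = (24, 128, 48)
    voxel_volume: float = 3.6
    gravity_axis: int = 1
    aeration_top: float = 0.6
    aeration_gradient: float = 0.45
    atelectasis_depth_fraction: float = 0.0
    inflation_factor: float = 2.0
    reopen_atelectasis: bool = True
    reopened_gas_fraction: float = 0.3
    coupling_kappa: float = 0.1
    activation_baseline: float = 0.5
    strain_saturation: float = 1.0
    blood_pool_activity: float = 1.0
    background_activity: float = 0.05
    pet_noise_sd: float = 0.05
    ct_noise_sd: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.aeration_top <= 1.0:
            raise ValueError(f"aeration_top must be in [0,1], got {self.aeration_top}")
        if not 0.0 <= self.atelectasis_depth_fraction <= 1.0:
            raise ValueError(
                f"atelectasis_depth_fraction must be in [0,1], got {self.atelectasis_depth_fraction}"
            )
        if not 0.0 <= self.coupling_kappa <= 1.0:
            raise ValueError(f"coupling_kappa must be in [0,1], got {self.coupling_kappa}")
        if self.inflation_factor < 1.0:
            raise ValueError(f"inflation_factor must be >= 1, got {self.inflation_factor}")
        if self.pet_noise_sd < 0 or self.ct_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.aeration_gradient < 0:
            raise ValueError(f"aeration_gradient must be >= 0, got {self.aeration_gradient}")
        if not 0.0 <= self.reopened_gas_fraction <= 1.0:
            raise ValueError("reopened_gas_fraction must be in [0,1]")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be > 0")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes of at least 4 voxels")
        if not 0 <= self.gravity_axis < 3:
            raise ValueError("gravity_axis must be 0, 1 or 2")
        if self.blood_pool_activity <= 0:
            raise ValueError("blood_pool_activity must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomParams":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def with_seed(self, seed: int) -> "PhantomParams":
        return replace(self, seed=int(seed))


@dataclass
class Phantom:
    """A generated phantom: images, masks and ground truth on one grid."""

    ct_ref: CTVolume
    ct_inflated: CTVolume
    pet: np.ndarray
    lung_mask: np.ndarray
    ref_roi_mask: np.ndarray
    truth_strain: np.ndarray
    truth_activation: np.ndarray
    params: PhantomParams = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def affine(self) -> np.ndarray:
        return self.ct_ref.affine


def _ellipsoid_mask(shape: tuple[int, int, int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return d2 <= 1.0


def _geometry(params: PhantomParams) -> tuple[np.ndarray, np.ndarray]:
    """Lung ellipsoid and disjoint blood-pool sphere (ventral mediastinum)."""
    shape = np.array(params.grid_shape, dtype=float)
    center = shape * 0.5
    semi = shape * np.array([0.45, 0.42, 0.42])
    # lung center shifted slightly dorsal to leave room for the heart
    lung_center = center.copy()
    lung_center[params.gravity_axis] = shape[params.gravity_axis] * 0.55
    lung = _ellipsoid_mask(params.grid_shape, lung_center, semi)

    roi_center = center.copy()
    roi_center[params.gravity_axis] = shape[params.gravity_axis] * 0.2
    r = max(2.0, 0.07 * min(params.grid_shape))
    roi = _ellipsoid_mask(params.grid_shape, roi_center, np.full(3, r))
    # carve the blood pool plus a one-voxel margin out of the lung
    margin = _ellipsoid_mask(params.grid_shape, roi_center, np.full(3, r + 1.5))
    lung &= ~margin
    return lung, roi


def _gravitational_depth(mask: np.ndarray, gravity_axis: int) -> np.ndarray:
    """Normalized depth in (0, 1) of every voxel's plane within the masked
    extent along the gravity axis (0 = nondependent boundary)."""
    planes = np.any(mask, axis=tuple(a for a in range(mask.ndim) if a != gravity_axis))
    lo = int(np.argmax(planes))
    hi = mask.shape[gravity_axis] - 1 - int(np.argmax(planes[::-1]))
    extent = hi - lo + 1
    g = np.arange(mask.shape[gravity_axis], dtype=float)
    depth_1d = (g - lo + 0.5) / extent
    shape = [1, 1, 1]
    shape[gravity_axis] = mask.shape[gravity_axis]
    return np.broadcast_to(depth_1d.reshape(shape), mask.shape).copy()


def generate_phantom(params: PhantomParams) -> Phantom:
    """Generate a phantom realizing the supplied parameters.

    The reference gas fraction decreases linearly with gravitational
    depth; voxels in the dependent ``atelectasis_depth_fraction`` of the
    lung (and any voxel whose gradient-derived gas fraction falls below
    the 0.01% strain floor) are fully degassed. HU values are the exact
    inverse of the gas-fraction transform (HU = -1000 * gas fraction)
    before CT noise is added, so a noise-free phantom round-trips through
    the aeration analysis to machine precision.
    """
    rng = np.random.default_rng(params.seed)
    lung, roi = _geometry(params)
    depth = _gravitational_depth(lung, params.gravity_axis)

    f_ref = np.clip(params.aeration_top - params.aeration_gradient * depth, 0.0, 1.0)
    atelectatic = depth > (1.0 - params.atelectasis_depth_fraction)
    f_ref = np.where(atelectatic, 0.0, f_ref)
    # gradient-derived fractions below the strain floor are physically
    # indistinguishable from gasless; degas them so ventilated voxels are
    # never floored downstream
    f_ref = np.where(f_ref < DEFAULT_FLOOR_FRACTION, 0.0, f_ref)
    f_ref = np.where(lung, f_ref, 0.0)

    gasless = lung & (f_ref == 0.0)
    f_inf = np.minimum(f_ref * params.inflation_factor, 1.0)
    if params.reopen_atelectasis:
        f_inf = np.where(gasless, params.reopened_gas_fraction, f_inf)
    f_inf = np.where(lung, f_inf, 0.0)

    # ground-truth strain with the same 0.01% floor convention the
    # estimator uses; still-closed voxels carry zero physical strain
    f_ref_floored = np.maximum(f_ref, DEFAULT_FLOOR_FRACTION)
    truth_strain = (f_inf - f_ref_floored) / (3.0 * f_ref_floored)
    truth_strain = np.where(gasless & (f_inf == 0.0), 0.0, truth_strain)
    truth_strain = np.where(lung, truth_strain, 0.0)

    s = np.clip(truth_strain, 0.0, None)
    truth_activation = np.where(
        lung,
        params.activation_baseline
        + params.coupling_kappa * s / (s + params.strain_saturation),
        0.0,
    )

    pet = np.full(params.grid_shape, params.background_activity, dtype=float)
    pet[lung] = truth_activation[lung]
    pet[roi] = params.blood_pool_activity
    if params.pet_noise_sd > 0:
        pet = pet + rng.normal(0.0, params.pet_noise_sd, size=pet.shape)
    pet = np.clip(pet, 0.0, None)

    hu_ref = np.where(lung, -1000.0 * f_ref, HU_SOFT_TISSUE)
    hu_inf = np.where(lung, -1000.0 * f_inf, HU_SOFT_TISSUE)
    hu_ref = np.where(roi, HU_BLOOD, hu_ref)
    hu_inf = np.where(roi, HU_BLOOD, hu_inf)
    if params.ct_noise_sd > 0:
        hu_ref = hu_ref + rng.normal(0.0, params.ct_noise_sd, size=hu_ref.shape)
        hu_inf = hu_inf + rng.normal(0.0, params.ct_noise_sd, size=hu_inf.shape)

    # isotropic-equivalent voxel edge in mm (1 µl = 1 mm^3)
    edge = params.voxel_volume ** (1.0 / 3.0)
    affine = np.diag([edge, edge, edge, 1.0])

    return Phantom(
        ct_ref=CTVolume(hu_ref, params.voxel_volume, affine, params.gravity_axis),
        ct_inflated=CTVolume(hu_inf, params.voxel_volume, affine, params.gravity_axis),
        pet=pet,
        lung_mask=lung,
        ref_roi_mask=roi,
        truth_strain=truth_strain,
        truth_activation=truth_activation,
        params=params,
    )


_VOLUME_FILES = {
    "ct_ref": "ct_ref.nii.gz",
    "ct_inflated": "ct_inflated.nii.gz",
    "pet": "pet.nii.gz",
    "lung_mask": "lung_mask.nii.gz",
    "ref_roi_mask": "ref_roi_mask.nii.gz",
    "truth_strain": "truth_strain.nii.gz",
    "truth_activation": "truth_activation.nii.gz",
}


def write_phantom(phantom: Phantom, directory: str | Path) -> dict[str, Path]:
    """Serialize a phantom as NIfTI volumes plus a YAML parameter sidecar.

    All volumes share the phantom's affine; masks are written as uint8.
    Returns the mapping from volume name to file path. The directory must
    already exist.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    affine = phantom.affine
    arrays = {
        "ct_ref": phantom.ct_ref.hu,
        "ct_inflated": phantom.ct_inflated.hu,
        "pet": phantom.pet,
        "lung_mask": phantom.lung_mask.astype(np.uint8),
        "ref_roi_mask": phantom.ref_roi_mask.astype(np.uint8),
        "truth_strain": phantom.truth_strain,
        "truth_activation": phantom.truth_activation,
    }
    paths: dict[str, Path] = {}
    for name, fname in _VOLUME_FILES.items():
        p = directory / fname
        nib.save(nib.Nifti1Image(arrays[name], affine), p)
        paths[name] = p
    with open(directory / "params.yaml", "w") as fh:
        yaml.safe_dump(phantom.params.to_dict(), fh, sort_keys=True)
    return paths


def read_phantom(directory: str | Path) -> Phantom:
    """Load a phantom written by :func:`write_phantom`."""
    directory = Path(directory)
    with open(directory / "params.yaml") as fh:
        params = PhantomParams.from_dict(yaml.safe_load(fh))
    vols = {}
    affine = None
    for name, fname in _VOLUME_FILES.items():
        img = nib.load(directory / fname)
        vols[name] = np.asarray(img.dataobj, dtype=float)
        affine = img.affine if affine is None else affine
    return Phantom(
        ct_ref=CTVolume(vols["ct_ref"], params.voxel_volume, affine, params.gravity_axis),
        ct_inflated=CTVolume(vols["ct_inflated"], params.voxel_volume, affine, params.gravity_axis),
        pet=vols["pet"],
        lung_mask=vols["lung_mask"].astype(bool),
        ref_roi_mask=vols["ref_roi_mask"].astype(bool),
        truth_strain=vols["truth_strain"],
        truth_activation=vols["truth_activation"],
        params=params,
    )
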