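"""Reading parametric maps and ROI masks, NAWM normalization, voxel-pair extraction.

Maps (ADC, rCBV) and masks (contrast-enhancing tumor, contralateral
normal-appearing white matter) must arrive co-registered on a shared voxel
grid; no resampling is attempted here, and a grid mismatch is a hard error.
Each map is normalized by the mean value inside the patient's NAWM mask, so
downstream values are dimensionless ratios to normal white matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ModalityLabel = Literal["ADC", "rCBV", "other"]
MaskRole = Literal["tumor", "NAWM"]

#: Required columns of a patient manifest CSV.
MANIFEST_COLUMNS = (
    "patient_id",
    "adc_path",
    "rcbv_path",
    "tumor_mask_path",
    "nawm_mask_path",
)


@dataclass
class ParametricMap:
    """A 3-D scalar volume (ADC or rCBV) with its spatial metadata."""

    values: np.ndarray
    affine: np.ndarray
    modality_label: ModalityLabel = "other"

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(
                f"ParametricMap must be 3-D, got shape {self.values.shape}"
            )


@dataclass
class ROIMask:
    """A binary region-of-interest mask; any nonzero voxel counts as inside."""

    values: np.ndarray
    role: MaskRole
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"ROIMask must be 3-D, got shape {arr.shape}")
        self.values = (arr != 0)
        if not self.values.any():
            raise ValueError(f"ROIMask with role={self.role!r} is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass
class VoxelPairSample:
    """Paired, NAWM-normalized ADC/rCBV values at the tumor voxels of one patient."""

    adc: np.ndarray
    rcbv: np.ndarray
    patient_id: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.adc = np.asarray(self.adc, dtype=float).ravel()
        self.rcbv = np.asarray(self.rcbv, dtype=float).ravel()
        if self.adc.size != self.rcbv.size:
            raise ValueError("adc and rcbv must have identical length")
        if self.adc.size < 1:
            raise ValueError("VoxelPairSample needs at least one voxel pair")

    @property
    def n_voxels(self) -> int:
        return self.adc.size


def load_map(path: str | Path, modality_label: ModalityLabel = "other") -> ParametricMap:
    """Load a NIfTI-1/2 volume as a :class:`ParametricMap`.

    A 4-D volume with a trailing singleton dimension is squeezed to 3-D;
    any other non-3-D shape is rejected as ambiguous.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D volume, got shape {data.shape}"
        )
    return ParametricMap(values=data, affine=np.asarray(img.affine), modality_label=modality_label)


def load_mask(path: str | Path, role: MaskRole) -> ROIMask:
    """Load a NIfTI mask, binarizing any nonzero voxel to 1."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got shape {data.shape}")
    return ROIMask(values=data, role=role, affine=np.asarray(img.affine))


def normalize_to_nawm(pmap: ParametricMap, nawm: ROIMask) -> ParametricMap:
    """Divide every voxel by the map's mean value inside the NAWM mask.

    The NAWM mean must be finite and strictly positive; anything else signals
    a bad map/mask pairing. Normalization is idempotent over the NAWM region:
    after one pass the NAWM mean is exactly 1.
    """
    if pmap.grid_shape != nawm.grid_shape:
        raise ValueError(
            f"grid mismatch: map {pmap.grid_shape} vs NAWM mask {nawm.grid_shape}"
        )
    ref = float(np.mean(pmap.values[nawm.values]))
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError(
            f"NAWM mean of {pmap.modality_label} map is {ref!r}; "
            "expected a finite positive value"
        )
    logger.debug("NAWM mean for %s map: %g", pmap.modality_label, ref)
    return ParametricMap(
        values=pmap.values / ref,
        affine=pmap.affine,
        modality_label=pmap.modality_label,
    )


def extract_pairs(
    adc: ParametricMap,
    rcbv: ParametricMap,
    tumor: ROIMask,
    patient_id: str,
) -> VoxelPairSample:
    """Extract paired (ADC, rCBV) values at tumor voxels in lexicographic scan order.

    Voxels where either map is non-finite are dropped with a warning (the
    dropped count is kept on the sample); no other outlier removal is applied.
    The fixed scan order makes outputs bit-reproducible, though downstream
    rank statistics are insensitive to it.
    """
    shapes = {adc.grid_shape, rcbv.grid_shape, tumor.grid_shape}
    if len(shapes) != 1:
        raise ValueError(f"grid mismatch among inputs: {sorted(shapes)}")
    # boolean fancy indexing of a C-ordered array follows lexicographic index order
    a = adc.values[tumor.values]
    r = rcbv.values[tumor.values]
    finite = np.isfinite(a) & np.isfinite(r)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.warning(
            "patient %s: dropped %d non-finite tumor voxel(s) of %d",
            patient_id, n_dropped, a.size,
        )
    a, r = a[finite], r[finite]
    if a.size == 0:
        raise ValueError(f"patient {patient_id}: no finite tumor voxels survive")
    return VoxelPairSample(adc=a, rcbv=r, patient_id=patient_id, n_dropped=n_dropped)


def load_patient(
    adc_path: str | Path,
    rcbv_path: str | Path,
    tumor_mask_path: str | Path,
    nawm_mask_path: str | Path,
    patient_id: str,
) -> VoxelPairSample:
    """Load, normalize and pair one patient's maps: the full per-patient ingest."""
    adc = load_map(adc_path, "ADC")
    rcbv = load_map(rcbv_path, "rCBV")
    tumor = load_mask(tumor_mask_path, "tumor")
    nawm = load_mask(nawm_mask_path, "NAWM")
    adc = normalize_to_nawm(adc, nawm)
    rcbv = normalize_to_nawm(rcbv, nawm)
    return extract_pairs(adc, rcbv, tumor, patient_id)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a patient manifest CSV (see :data:`MANIFEST_COLUMNS`)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"manifest {path} has duplicate patient_id(s): {dupes}")
    return df


def load_cohort(manifest: pd.DataFrame | str | Path) -> list[VoxelPairSample]:
    """Load every patient listed in a manifest, in manifest order."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    samples = []
    for row in manifest.itertuples(index=False):
        try:
            samples.append(
                load_patient(
                    row.adc_path, row.rcbv_path,
                    row.tumor_mask_path, row.nawm_mask_path,
                    patient_id=str(row.patient_id),
                )
            )
        except Exception as exc:
            raise RuntimeError(
                f"failed loading patient {row.patient_id}: {exc}"
            ) from exc
    return samples
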