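"""Reading, writing and geometric slicing of VMAT RT-Plan / RT-Dose data.

The in-memory containers here (:class:`ArcPlan`, :class:`DoseGrid`,
:class:`DosePlaneSet`) are what the rest of the package consumes: the MLC
leaf-position map is built from an :class:`ArcPlan`, and the CNN's dose-image
inputs are fixed-size planes cut from a :class:`DoseGrid` through the plan
isocenter.

Conventions
-----------
* All geometry is in mm, dose in Gy.
* Leaf coordinates are the raw DICOM leaf-tip positions along the leaf-travel
  axis (IEC 61217 X), signed; bank A is stored before bank B, 60 leaves each.
* ``DoseGrid.values`` is indexed ``[ix, iy, iz]`` with x = left-right,
  y = anterior-posterior, z = superior-inferior (DICOM patient axes).
* Plane orientation: sagittal = (rows y, cols z), coronal = (rows x, cols z),
  axial = (rows y, cols x).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import map_coordinates

from .errors import FormatError, GeometryError, ParameterError, UnsupportedPlanError

N_LEAF_PAIRS = 60

#: A leaf pair is considered closed when its tip gap is at most this (mm);
#: this is the scale of a typical dosimetric leaf gap.
CLOSURE_TOL_MM = 0.5

RTPLAN_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.5"
RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"

#: Fixed-size plane shapes used as CNN inputs at clinical scale.
DEFAULT_PLANE_SHAPES = {
    "sagittal": (68, 146),
    "coronal": (64, 200),
    "axial": (143, 242),
}
DEFAULT_SURFACE_SHAPE = (220, 680)


@dataclass(frozen=True)
class ControlPoint:
    """Machine state snapshot along the arc.

    ``bank_a`` / ``bank_b`` hold the 60 leaf-tip coordinates (mm) of the two
    opposing MLC banks; the aperture gap of pair ``p`` is
    ``bank_b[p] - bank_a[p]`` and must be non-negative up to the closure
    tolerance.
    """

    index: int
    gantry_angle: float
    meterset_weight: float
    bank_a: np.ndarray
    bank_b: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.bank_a, dtype=float)
        b = np.asarray(self.bank_b, dtype=float)
        object.__setattr__(self, "bank_a", a)
        object.__setattr__(self, "bank_b", b)
        if a.shape != (N_LEAF_PAIRS,) or b.shape != (N_LEAF_PAIRS,):
            raise FormatError(
                f"each MLC bank must have exactly {N_LEAF_PAIRS} leaves, "
                f"got {a.shape} / {b.shape}"
            )
        gaps = b - a
        if np.any(gaps < -CLOSURE_TOL_MM):
            raise FormatError(
                f"control point {self.index}: negative aperture gap "
                f"(min {gaps.min():.3f} mm) beyond closure tolerance"
            )

    @property
    def gaps(self) -> np.ndarray:
        """Signed aperture opening per leaf pair (mm)."""
        return self.bank_b - self.bank_a


@dataclass(frozen=True)
class ArcPlan:
    """A single-arc VMAT plan as an ordered control-point sequence."""

    plan_id: str
    control_points: tuple[ControlPoint, ...]
    isocenter: np.ndarray
    prescription_dose: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_points", tuple(self.control_points))
        object.__setattr__(
            self, "isocenter", np.asarray(self.isocenter, dtype=float).reshape(3)
        )
        if len(self.control_points) < 2:
            raise FormatError("an arc plan needs at least 2 control points")
        weights = np.array([cp.meterset_weight for cp in self.control_points])
        if np.any(np.diff(weights) < 0):
            raise FormatError("cumulative meterset weights must be non-decreasing")
        if weights[0] < -1e-9 or weights[-1] > 1 + 1e-9:
            raise FormatError("cumulative meterset weights must lie in [0, 1]")

    @property
    def n_control_points(self) -> int:
        return len(self.control_points)

    def meterset_weights(self) -> np.ndarray:
        return np.array([cp.meterset_weight for cp in self.control_points])

    def gantry_angles(self) -> np.ndarray:
        return np.array([cp.gantry_angle for cp in self.control_points])

    def bank_stack(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (bank_a, bank_b) arrays of shape (60, n_control_points)."""
        a = np.stack([cp.bank_a for cp in self.control_points], axis=1)
        b = np.stack([cp.bank_b for cp in self.control_points], axis=1)
        return a, b


@dataclass(frozen=True)
class DoseGrid:
    """3D dose on a regular grid; ``values[ix, iy, iz]`` in Gy."""

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float).reshape(3))
        if v.ndim != 3:
            raise FormatError("dose grid must be 3D")
        if np.any(self.spacing <= 0):
            raise FormatError("grid spacing must be positive on every axis")
        if np.any(v < 0):
            raise FormatError("dose values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def world_to_index(self, point: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of a world point."""
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing

    def contains(self, point: np.ndarray) -> bool:
        idx = self.world_to_index(point)
        upper = np.array(self.shape) - 1
        return bool(np.all(idx >= -1e-9) and np.all(idx <= upper + 1e-9))


@dataclass(frozen=True)
class DosePlaneSet:
    """Fixed-size isocenter dose planes used as CNN inputs."""

    sagittal: np.ndarray
    coronal: np.ndarray
    axial: np.ndarray
    pixel_spacing: float
    surface: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# DICOM I/O
# ---------------------------------------------------------------------------

def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def write_rtplan(plan: ArcPlan, path) -> None:
    """Write an :class:`ArcPlan` as a minimal DICOM RT Plan.

    Intended for fixtures and for exporting synthetic plans; the file carries
    one arc beam with an MLCX position sequence per control point.
    """
    sop_instance = generate_uid()
    ds = Dataset()
    ds.SOPClassUID = RTPLAN_SOP_CLASS
    ds.SOPInstanceUID = sop_instance
    ds.Modality = "RTPLAN"
    ds.RTPlanLabel = plan.plan_id
    ds.PatientID = plan.plan_id
    ds.PatientName = plan.plan_id

    if np.isfinite(plan.prescription_dose):
        ref = Dataset()
        ref.DoseReferenceNumber = 1
        ref.DoseReferenceStructureType = "SITE"
        ref.DoseReferenceType = "TARGET"
        ref.TargetPrescriptionDose = float(plan.prescription_dose)
        ds.DoseReferenceSequence = [ref]

    beam = Dataset()
    beam.BeamNumber = 1
    beam.BeamName = "ARC1"
    beam.BeamType = "DYNAMIC"
    beam.RadiationType = "PHOTON"
    beam.NumberOfControlPoints = plan.n_control_points
    beam.FinalCumulativeMetersetWeight = 1.0

    cps = []
    for cp in plan.control_points:
        item = Dataset()
        item.ControlPointIndex = cp.index
        item.GantryAngle = float(cp.gantry_angle) % 360.0
        item.CumulativeMetersetWeight = float(cp.meterset_weight)
        mlc = Dataset()
        mlc.RTBeamLimitingDeviceType = "MLCX"
        mlc.LeafJawPositions = [float(v) for v in cp.bank_a] + [
            float(v) for v in cp.bank_b
        ]
        item.BeamLimitingDevicePositionSequence = [mlc]
        if cp.index == plan.control_points[0].index:
            item.IsocenterPosition = [float(v) for v in plan.isocenter]
        cps.append(item)
    beam.ControlPointSequence = cps
    ds.BeamSequence = [beam]

    ds.file_meta = _file_meta(RTPLAN_SOP_CLASS, sop_instance)
    ds.save_as(str(path), enforce_file_format=True)


def read_rtplan(path) -> ArcPlan:
    """Read a single-arc RT Plan with a 120-leaf (60-pair) MLC.

    Control points are taken in file order (which DICOM requires to follow
    cumulative meterset weight); leaf coordinates are preserved in mm without
    rescaling.  Per the DICOM data model, MLC positions and gantry angle may
    be omitted at control points where they do not change; the last seen
    values are carried forward.
    """
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise FormatError(f"{path}: not an RT Plan (Modality={getattr(ds, 'Modality', None)})")
    beams = getattr(ds, "BeamSequence", None)
    if not beams:
        raise FormatError(f"{path}: RT Plan has no BeamSequence")
    if len(beams) != 1:
        raise UnsupportedPlanError(
            f"{path}: {len(beams)} beams; only single-arc plans are supported"
        )
    beam = beams[0]

    final_w = float(getattr(beam, "FinalCumulativeMetersetWeight", 1.0) or 1.0)
    isocenter = None
    gantry = None
    positions = None
    cps = []
    for i, item in enumerate(beam.ControlPointSequence):
        if hasattr(item, "IsocenterPosition"):
            isocenter = np.asarray(item.IsocenterPosition, dtype=float)
        if hasattr(item, "GantryAngle"):
            gantry = float(item.GantryAngle)
        for bld in getattr(item, "BeamLimitingDevicePositionSequence", []):
            if str(bld.RTBeamLimitingDeviceType).startswith("MLC"):
                positions = np.asarray(bld.LeafJawPositions, dtype=float)
        if positions is None:
            raise FormatError(f"{path}: control point {i} has no MLC leaf positions")
        if positions.size != 2 * N_LEAF_PAIRS:
            raise UnsupportedPlanError(
                f"{path}: MLC has {positions.size} leaves; expected {2 * N_LEAF_PAIRS}"
            )
        if gantry is None:
            raise FormatError(f"{path}: control point {i} has no gantry angle")
        weight = float(item.CumulativeMetersetWeight) / final_w
        cps.append(
            ControlPoint(
                index=i,
                gantry_angle=gantry,
                meterset_weight=weight,
                bank_a=positions[:N_LEAF_PAIRS].copy(),
                bank_b=positions[N_LEAF_PAIRS:].copy(),
            )
        )
    if isocenter is None:
        isocenter = np.zeros(3)
    prescription = float("nan")
    for ref in getattr(ds, "DoseReferenceSequence", []):
        if hasattr(ref, "TargetPrescriptionDose"):
            prescription = float(ref.TargetPrescriptionDose)
    plan_id = str(getattr(ds, "RTPlanLabel", "") or getattr(ds, "PatientID", "plan"))
    return ArcPlan(
        plan_id=plan_id,
        control_points=tuple(cps),
        isocenter=isocenter,
        prescription_dose=prescription,
    )


def write_rtdose(grid: DoseGrid, path, dose_grid_scaling: Optional[float] = None) -> None:
    """Write a :class:`DoseGrid` as a DICOM RT Dose (32-bit pixels).

    Stored pixel values are ``round(dose / scaling)``; dose that is an exact
    integer multiple of ``dose_grid_scaling`` round-trips bit-exactly.  When
    ``dose_grid_scaling`` is None a scaling that spans the grid maximum is
    chosen.
    """
    vmax = float(grid.values.max())
    if dose_grid_scaling is None:
        dose_grid_scaling = vmax / (2**32 - 1) if vmax > 0 else 1e-8
    pixels = np.round(grid.values / dose_grid_scaling)
    if np.any(pixels < 0) or np.any(pixels > 2**32 - 1):
        raise ParameterError("dose_grid_scaling cannot represent the dose range")
    # values[ix, iy, iz] -> frames along z, rows along y, cols along x
    pixels = pixels.astype(np.uint32).transpose(2, 1, 0)

    sop_instance = generate_uid()
    ds = Dataset()
    ds.SOPClassUID = RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = sop_instance
    ds.Modality = "RTDOSE"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = float(dose_grid_scaling)
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    nz, ny, nx = pixels.shape
    ds.NumberOfFrames = nz
    ds.Rows = ny
    ds.Columns = nx
    ds.PixelSpacing = [float(grid.spacing[1]), float(grid.spacing[0])]
    ds.ImagePositionPatient = [float(v) for v in grid.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.GridFrameOffsetVector = [float(i * grid.spacing[2]) for i in range(nz)]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.PixelData = pixels.tobytes()

    ds.file_meta = _file_meta(RTDOSE_SOP_CLASS, sop_instance)
    ds.save_as(str(path), enforce_file_format=True)


def read_rtdose(path) -> DoseGrid:
    """Read a DICOM RT Dose into a :class:`DoseGrid` (values in Gy)."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError(f"{path}: not an RT Dose (Modality={getattr(ds, 'Modality', None)})")
    scaling = getattr(ds, "DoseGridScaling", None)
    if scaling is None:
        raise FormatError(f"{path}: RT Dose has no DoseGridScaling")
    pixels = ds.pixel_array.astype(float)  # (frames=z, rows=y, cols=x)
    if pixels.ndim == 2:
        pixels = pixels[None]
    values = (pixels * float(scaling)).transpose(2, 1, 0)
    origin = np.asarray(ds.ImagePositionPatient, dtype=float)
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    dz = float(offsets[1] - offsets[0]) if offsets.size > 1 else 1.0
    return DoseGrid(values=values, origin=origin, spacing=np.array([col_spacing, row_spacing, dz]))


# ---------------------------------------------------------------------------
# Plane extraction
# ---------------------------------------------------------------------------

def _center_crop_pad(image: np.ndarray, center: tuple[int, int], shape: tuple[int, int]) -> np.ndarray:
    """Crop/zero-pad ``image`` so ``center`` lands on the output center pixel."""
    out = np.zeros(shape, dtype=image.dtype)
    for_axes = []
    for ax in range(2):
        c_out = shape[ax] // 2
        start_in = center[ax] - c_out
        lo_in = max(start_in, 0)
        hi_in = min(start_in + shape[ax], image.shape[ax])
        if lo_in >= hi_in:
            return out
        lo_out = lo_in - start_in
        hi_out = lo_out + (hi_in - lo_in)
        for_axes.append((slice(lo_in, hi_in), slice(lo_out, hi_out)))
    out[for_axes[0][1], for_axes[1][1]] = image[for_axes[0][0], for_axes[1][0]]
    return out


def extract_isocenter_planes(
    grid: DoseGrid,
    isocenter: np.ndarray,
    target_shapes: Optional[dict[str, tuple[int, int]]] = None,
    surface: Optional[np.ndarray] = None,
) -> DosePlaneSet:
    """Cut the three anatomical planes through the isocenter.

    Each plane is the grid slice at the voxel nearest the isocenter along the
    fixed axis, center-cropped or zero-padded so that the isocenter pixel maps
    to the output center.  Pixel values are kept at native spacing; no
    resampling is done, so dose-gradient magnitudes are preserved.
    """
    if target_shapes is None:
        target_shapes = DEFAULT_PLANE_SHAPES
    if not grid.contains(isocenter):
        raise GeometryError("isocenter lies outside the dose grid")
    idx = np.round(grid.world_to_index(isocenter)).astype(int)
    idx = np.clip(idx, 0, np.array(grid.shape) - 1)
    ix, iy, iz = (int(v) for v in idx)

    sag = _center_crop_pad(grid.values[ix, :, :], (iy, iz), target_shapes["sagittal"])
    cor = _center_crop_pad(grid.values[:, iy, :], (ix, iz), target_shapes["coronal"])
    axi = _center_crop_pad(grid.values[:, :, iz].T, (iy, ix), target_shapes["axial"])
    return DosePlaneSet(
        sagittal=sag,
        coronal=cor,
        axial=axi,
        pixel_spacing=float(grid.spacing[0]),
        surface=surface,
    )


def extract_surface_dose(
    grid: DoseGrid,
    isocenter: np.ndarray,
    radius: float = 105.0,
    n_angles: int = DEFAULT_SURFACE_SHAPE[1],
    n_axial: int = DEFAULT_SURFACE_SHAPE[0],
    axial_spacing: float = 1.0,
) -> np.ndarray:
    """Sample dose on an unrolled cylinder around the superior-inferior axis.

    Emulates the dose map seen by a cylindrical diode array: rows are axial
    (z) positions centered on the isocenter, columns sweep azimuth; values are
    trilinear interpolations of the grid, zero outside it.

    Returns an ``(n_axial, n_angles)`` image.
    """
    if radius <= 0:
        raise ParameterError("cylinder radius must be positive")
    iso = np.asarray(isocenter, dtype=float).reshape(3)
    z = iso[2] + (np.arange(n_axial) - (n_axial - 1) / 2.0) * axial_spacing
    phi = 2.0 * np.pi * np.arange(n_angles) / n_angles
    x = iso[0] + radius * np.cos(phi)
    y = iso[1] + radius * np.sin(phi)

    xx = np.broadcast_to(x, (n_axial, n_angles))
    yy = np.broadcast_to(y, (n_axial, n_angles))
    zz = np.broadcast_to(z[:, None], (n_axial, n_angles))
    coords = np.stack(
        [
            (xx - grid.origin[0]) / grid.spacing[0],
            (yy - grid.origin[1]) / grid.spacing[1],
            (zz - grid.origin[2]) / grid.spacing[2],
        ]
    )
    return map_coordinates(grid.values, coords, order=1, mode="constant", cval=0.0)
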