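"""Synthetic VMAT plans, toy dose delivery, and gamma-labelled datasets.

Clinical patient-QA cohorts are not publicly available, so this module
generates datasets with the statistical structure the prediction method
assumes: single-arc plans with smooth leaf trajectories and a set of leaf
pairs that never open, a planned dose grid, a "delivered" dose grid obtained
by perturbing the plan with a parameterized delivery-error model, and GPR
labels computed by the package's own gamma engine on the detector plane.

The forward dose model is deliberately simple — gantry-angle-weighted
accumulation of the binary MLC aperture projected through an isocentric
grid, followed by a Gaussian penumbra blur.  It is not a transport
calculation; it exists to create realistic couplings between plan geometry,
delivery errors and gamma passing rates.

Two properties give the data its learnable signal:

* dose perturbations scale with the per-plan delivery-error magnitude, drawn
  from a long-tailed mixture, so GPR labels span the range patient QA data
  shows (loose criteria near 90-100%, strict criteria spreading to ~70%);
* per-leaf positional errors grow with leaf speed between control points (a
  documented behaviour of dynamic MLC delivery), so plans with fast, complex
  leaf motion — visible in the MLC leaf position map — lose more GPR than
  their dose distributions alone reveal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .errors import ParameterError
from .gamma import NINE_CRITERIA, gpr_vector
from .mlpm import (
    LeafPositionMatrix,
    build_leaf_matrix,
    build_mlpm,
    find_always_closed_pairs,
    normalize_maps,
)
from .rtplan_io import (
    N_LEAF_PAIRS,
    ArcPlan,
    ControlPoint,
    DoseGrid,
    DosePlaneSet,
    extract_isocenter_planes,
    extract_surface_dose,
)

LEAF_WIDTH_MM = 2.5
#: Penumbra blur of the toy beam model (mm, sigma).
BASE_BLUR_MM = 2.5
#: Leaf speed (mm per control point) at which velocity-coupled noise doubles.
SPEED_REF_MM = 5.0


@dataclass(frozen=True)
class PlanGenParams:
    """Knobs of the synthetic plan generator.

    Defaults emulate a single-arc prostate VMAT plan: 178 control points,
    60 leaf pairs of which 5 peripheral pairs never open (leaving 110 MLPM
    rows), a mean aperture gap around 25 mm with smooth per-control-point
    jitter, and leaf travel limited per control point.
    """

    n_control_points: int = 178
    n_pairs: int = N_LEAF_PAIRS
    n_always_closed_pairs: int = 5
    mean_gap_mm: float = 25.0
    gap_jitter_sd_mm: float = 4.0
    max_travel_mm: float = 5.0
    prescription_dose: float = 74.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs != N_LEAF_PAIRS:
            raise ParameterError(f"the modeled MLC has exactly {N_LEAF_PAIRS} leaf pairs")
        if self.n_control_points < 2:
            raise ParameterError("need at least 2 control points")
        if not 0 <= self.n_always_closed_pairs <= self.n_pairs - 2:
            raise ParameterError("n_always_closed_pairs leaves too few open pairs")
        if self.mean_gap_mm <= 0:
            raise ParameterError("mean_gap_mm must be positive")
        if self.gap_jitter_sd_mm < 0 or self.max_travel_mm < 0:
            raise ParameterError("jitter sd and max travel must be non-negative")

    @property
    def closed_pairs(self) -> frozenset[int]:
        """Designated always-closed pairs (1-based): split between the two ends."""
        lo = (self.n_always_closed_pairs + 1) // 2
        hi = self.n_always_closed_pairs - lo
        return frozenset(range(1, lo + 1)) | frozenset(
            range(self.n_pairs - hi + 1, self.n_pairs + 1)
        )


@dataclass(frozen=True)
class ErrorModel:
    """Parameterized difference between planned and delivered dose.

    ``gap_offset_mm`` moves both tips of every pair outward (a systematic
    MLC calibration error: the gap widens by twice the offset); leaf noise
    is independent per leaf and control point with a standard deviation that
    grows with leaf speed; ``output_scale`` rescales machine output; and
    ``blur_sd_mm`` is added in quadrature to the delivery penumbra.  The
    all-zero model reproduces the planned dose exactly.
    """

    gap_offset_mm: float = 0.0
    leaf_noise_sd_mm: float = 0.0
    velocity_coupling: float = 1.0
    output_scale: float = 1.0
    blur_sd_mm: float = 0.0
    seed: int = 0

    @property
    def is_zero(self) -> bool:
        return (
            self.gap_offset_mm == 0.0
            and self.leaf_noise_sd_mm == 0.0
            and self.output_scale == 1.0
            and self.blur_sd_mm == 0.0
        )


@dataclass(frozen=True)
class GridSpec:
    """Isocentric dose-grid geometry: ``shape`` voxels at ``spacing`` mm."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: float = 2.0

    def origin(self, isocenter: np.ndarray) -> np.ndarray:
        iso = np.asarray(isocenter, dtype=float).reshape(3)
        return iso - (np.asarray(self.shape) - 1) / 2.0 * self.spacing


def _limited_walk(rng: np.random.Generator, n_rows: int, n_cols: int,
                  sd: float, max_step: float) -> np.ndarray:
    """Smooth zero-mean noise with per-column steps bounded by ``max_step``."""
    if sd == 0 or n_cols < 2:
        return np.zeros((n_rows, n_cols))
    white = rng.normal(0.0, 1.0, (n_rows, n_cols))
    smooth = gaussian_filter1d(white, sigma=3.0, axis=1, mode="nearest")
    scale = smooth.std(axis=1, keepdims=True)
    smooth = smooth / np.maximum(scale, 1e-12) * sd
    steps = np.clip(np.diff(smooth, axis=1), -max_step, max_step)
    return np.concatenate([smooth[:, :1], smooth[:, :1] + np.cumsum(steps, axis=1)], axis=1)


def generate_plan(params: PlanGenParams) -> ArcPlan:
    """Generate one synthetic single-arc plan, deterministic given the seed.

    Active leaf pairs follow an elliptic aperture envelope across the bank
    (wide centrally, narrow peripherally) with smooth random gap and midline
    wander; designated always-closed pairs never open; leaf travel per
    control point is bounded by ``max_travel_mm``.
    """
    rng = np.random.default_rng(params.seed)
    n_cp = params.n_control_points
    n_pairs = params.n_pairs
    closed = params.closed_pairs
    active = np.array([p for p in range(1, n_pairs + 1) if p not in closed])

    # closed-state junction coordinate per pair, constant over the arc
    junction = rng.uniform(-10.0, 10.0, n_pairs)

    center_idx = 0.5 * (active.min() + active.max())
    half_width = max(0.5 * (active.max() - active.min()), 1.0)
    envelope = np.sqrt(np.clip(1.0 - ((active - center_idx) / half_width) ** 2, 0.0, None))
    envelope = np.maximum(envelope, 0.12)
    base_gap = params.mean_gap_mm * envelope / envelope.mean()

    gap_noise = _limited_walk(rng, active.size, n_cp, params.gap_jitter_sd_mm,
                              params.max_travel_mm)
    center_noise = _limited_walk(rng, active.size, n_cp, params.gap_jitter_sd_mm,
                                 params.max_travel_mm / 2.0)

    gaps = np.clip(base_gap[:, None] + gap_noise, 2.0, 80.0)
    centers = junction[active - 1][:, None] + center_noise

    bank_a = np.tile(junction[:, None], (1, n_cp))
    bank_b = bank_a.copy()
    bank_a[active - 1] = centers - gaps / 2.0
    bank_b[active - 1] = centers + gaps / 2.0

    angles = (181.0 - 362.0 * np.arange(n_cp) / (n_cp - 1)) % 360.0
    increments = rng.uniform(0.5, 1.5, n_cp - 1)
    weights = np.concatenate([[0.0], np.cumsum(increments)])
    weights /= weights[-1]

    cps = tuple(
        ControlPoint(
            index=j,
            gantry_angle=float(angles[j]),
            meterset_weight=float(weights[j]),
            bank_a=bank_a[:, j],
            bank_b=bank_b[:, j],
        )
        for j in range(n_cp)
    )
    return ArcPlan(
        plan_id=f"synth-{params.seed}",
        control_points=cps,
        isocenter=np.zeros(3),
        prescription_dose=params.prescription_dose,
    )


def apply_errors(plan: ArcPlan, error: Optional[ErrorModel]) -> ArcPlan:
    """Perturb leaf positions per the error model (identity for a zero model)."""
    if error is None or error.is_zero:
        return plan
    rng = np.random.default_rng(error.seed)
    bank_a, bank_b = plan.bank_stack()

    speed_a = np.abs(np.diff(bank_a, axis=1, prepend=bank_a[:, :1]))
    speed_b = np.abs(np.diff(bank_b, axis=1, prepend=bank_b[:, :1]))
    sd_a = error.leaf_noise_sd_mm * (1.0 + error.velocity_coupling * speed_a / SPEED_REF_MM)
    sd_b = error.leaf_noise_sd_mm * (1.0 + error.velocity_coupling * speed_b / SPEED_REF_MM)

    a = bank_a - error.gap_offset_mm + rng.normal(0.0, 1.0, bank_a.shape) * sd_a
    b = bank_b + error.gap_offset_mm + rng.normal(0.0, 1.0, bank_b.shape) * sd_b
    # collapse any crossed pair onto its midpoint (physical leaves cannot cross)
    crossed = b < a
    mid = 0.5 * (a + b)
    a = np.where(crossed, mid, a)
    b = np.where(crossed, mid, b)

    cps = tuple(
        ControlPoint(
            index=cp.index,
            gantry_angle=cp.gantry_angle,
            meterset_weight=cp.meterset_weight,
            bank_a=a[:, j],
            bank_b=b[:, j],
        )
        for j, cp in enumerate(plan.control_points)
    )
    return ArcPlan(
        plan_id=plan.plan_id,
        control_points=cps,
        isocenter=plan.isocenter,
        prescription_dose=plan.prescription_dose,
    )


def simulate_dose(
    plan: ArcPlan,
    error: Optional[ErrorModel] = None,
    grid: GridSpec = GridSpec(),
) -> DoseGrid:
    """Toy forward dose model on an isocentric grid.

    For each control point the binary aperture (open between the two leaf
    tips, leaf rows mapped to 2.5 mm strips along z) is projected through the
    grid along the beam direction at that gantry angle and accumulated with
    the control point's meterset increment; the result is blurred with a
    Gaussian penumbra kernel and scaled to the prescription dose.  A zero
    error model reproduces the planned dose bit-for-bit.
    """
    delivered = apply_errors(plan, error)
    nx, ny, nz = grid.shape
    sp = grid.spacing
    origin = grid.origin(plan.isocenter)
    iso = plan.isocenter

    x = origin[0] + np.arange(nx) * sp - iso[0]
    y = origin[1] + np.arange(ny) * sp - iso[1]
    z = origin[2] + np.arange(nz) * sp - iso[2]

    pair_idx = np.floor(z / LEAF_WIDTH_MM + N_LEAF_PAIRS / 2.0).astype(int)
    valid_z = (pair_idx >= 0) & (pair_idx < N_LEAF_PAIRS)
    rows = pair_idx[valid_z]

    bank_a, bank_b = delivered.bank_stack()
    weights = delivered.meterset_weights()
    dws = np.diff(weights)
    angles = np.deg2rad(delivered.gantry_angles())

    xx = x[:, None]
    yy = y[None, :]
    accum = np.zeros((nx, ny, int(valid_z.sum())))
    for j in range(1, delivered.n_control_points):
        dw = dws[j - 1]
        if dw <= 0:
            continue
        t = xx * np.cos(angles[j]) + yy * np.sin(angles[j])  # leaf-travel coordinate
        a = bank_a[rows, j]
        b = bank_b[rows, j]
        open_mask = (t[:, :, None] > a) & (t[:, :, None] < b)
        accum += dw * open_mask

    values = np.zeros(grid.shape)
    values[:, :, valid_z] = accum

    blur = BASE_BLUR_MM
    scale = 1.0
    if error is not None and not error.is_zero:
        blur = float(np.hypot(BASE_BLUR_MM, error.blur_sd_mm))
        scale = error.output_scale
    values = gaussian_filter(values, sigma=blur / sp, mode="constant")
    values *= plan.prescription_dose * scale
    return DoseGrid(values=values, origin=origin, spacing=np.full(3, sp))


def detector_plane(grid: DoseGrid, isocenter: np.ndarray) -> np.ndarray:
    """Coronal isocenter slice used as the synthetic QA detector plane."""
    idx = np.round(grid.world_to_index(isocenter)).astype(int)
    iy = int(np.clip(idx[1], 0, grid.shape[1] - 1))
    return grid.values[:, iy, :]


@dataclass(frozen=True)
class ErrorDistribution:
    """Per-plan sampling distribution of :class:`ErrorModel` magnitudes.

    A latent per-plan severity — mostly small, occasionally large — scales
    all error components together (a poorly delivered plan is poor in
    several ways at once), producing the long lower GPR tail that patient-QA
    cohorts show.  The systematic gap error has a random *sign* but a
    narrowly distributed *magnitude*: every delivery carries a comparable
    calibration-scale gap error whose dosimetric impact grows as apertures
    shrink, so plan complexity — not the error draw — carries most of the
    label variance.  ``zero()`` gives the degenerate distribution with no
    errors.
    """

    severity_sd: float = 0.25
    p_large: float = 0.15
    large_severity_range: tuple[float, float] = (0.3, 1.0)
    gap_offset_base_mm: float = 0.4
    gap_offset_per_severity_mm: float = 0.28
    noise_floor_mm: float = 0.28
    noise_per_severity_mm: float = 0.3
    output_scale_sd: float = 0.004
    velocity_coupling: float = 1.5

    @classmethod
    def zero(cls) -> "ErrorDistribution":
        return cls(
            severity_sd=0.0,
            p_large=0.0,
            large_severity_range=(0.0, 0.0),
            gap_offset_base_mm=0.0,
            gap_offset_per_severity_mm=0.0,
            noise_floor_mm=0.0,
            noise_per_severity_mm=0.0,
            output_scale_sd=0.0,
            velocity_coupling=0.0,
        )

    def draw(self, rng: np.random.Generator) -> ErrorModel:
        severity = abs(rng.normal(0.0, self.severity_sd)) if self.severity_sd else 0.0
        if self.p_large and rng.random() < self.p_large:
            severity += rng.uniform(*self.large_severity_range)
        offset_mag = self.gap_offset_base_mm + self.gap_offset_per_severity_mm * severity
        scale_noise = rng.normal(0.0, self.output_scale_sd) if self.output_scale_sd else 0.0
        return ErrorModel(
            gap_offset_mm=float(rng.choice([-1.0, 1.0])) * offset_mag if offset_mag else 0.0,
            leaf_noise_sd_mm=self.noise_floor_mm + self.noise_per_severity_mm * severity,
            velocity_coupling=self.velocity_coupling,
            output_scale=1.0 + scale_noise * (1.0 + severity),
            blur_sd_mm=0.0,
            seed=int(rng.integers(2**31)),
        )


@dataclass
class SyntheticDataset:
    """A labelled cohort: MLPMs, dose planes and nine-criterion GPR labels.

    ``mlpm`` and the entries of ``planes`` are normalized to [0, 1] by the
    recorded dataset-wide constants; ``labels`` are GPR percentages ordered
    as :data:`vmatqa.gamma.NINE_CRITERIA`.
    """

    ids: list[str]
    leaf_matrices: list[LeafPositionMatrix]
    excluded_pairs: frozenset[int]
    mlpm: np.ndarray
    mlpm_norm_mm: float
    planes: dict[str, np.ndarray]
    plane_norms: dict[str, float]
    plane_spacing: float
    labels: np.ndarray
    mean_leaf_perturbation_mm: np.ndarray
    seed: int
    degenerate_labels: bool = False

    @property
    def n(self) -> int:
        return len(self.ids)

    def branch_inputs(self, variant: str) -> dict[str, np.ndarray]:
        """Normalized input stacks keyed by branch name for a model variant."""
        from .network import MODEL_BRANCHES

        out = {}
        for name in MODEL_BRANCHES[variant]:
            if name == "mlpm":
                out[name] = self.mlpm
            else:
                out[name] = self.planes[name]
        return out

    def branch_shapes(self, variant: str) -> dict[str, tuple[int, int]]:
        return {name: arr.shape[1:] for name, arr in self.branch_inputs(variant).items()}


def desk_scale_kwargs(seed: int = 0) -> dict:
    """Reduced problem sizes for desk-scale experiments.

    Keeps the full 60-pair MLC but shortens the arc to 60 control points and
    shrinks grids so end-to-end training experiments run in minutes on one
    CPU: 44^3 dose grid at 2 mm, 51x51 dose planes (the smallest side length
    the three conv+pool branch stages admit) and a 110x60 MLPM.
    """
    return dict(
        plan_params=PlanGenParams(n_control_points=60),
        grid=GridSpec(shape=(44, 44, 44), spacing=2.0),
        plane_shapes={"sagittal": (51, 51), "coronal": (51, 51), "axial": (51, 51)},
        mlpm_shape=(110, 60),
        seed=seed,
    )


def generate_dataset(
    n_plans: int,
    plan_params: Optional[PlanGenParams] = None,
    error_dist: Optional[ErrorDistribution] = None,
    grid: GridSpec = GridSpec(),
    plane_shapes: Optional[dict[str, tuple[int, int]]] = None,
    mlpm_shape: Optional[tuple[int, int]] = None,
    include_surface: bool = False,
    surface_radius_mm: float = 105.0,
    surface_shape: tuple[int, int] = (220, 680),
    mean_gap_range_mm: Optional[tuple[float, float]] = (9.0, 40.0),
    jitter_range_mm: Optional[tuple[float, float]] = (2.0, 8.0),
    seed: int = 0,
) -> SyntheticDataset:
    """Generate a labelled synthetic cohort, deterministic given ``seed``.

    Per plan: draw aperture-complexity parameters (mean gap and jitter, from
    the given ranges) and an error model, simulate planned and delivered
    dose, compute the nine-criterion GPR label on the detector plane, extract
    isocenter planes (optionally the cylindrical surface map) from the
    planned dose, and build the MLPM after dataset-level exclusion of
    always-closed pairs.  Pass ``mean_gap_range_mm=None`` /
    ``jitter_range_mm=None`` to keep these fixed at ``plan_params`` values.
    """
    if n_plans < 8:
        raise ParameterError("a dataset needs at least 8 plans")
    if plan_params is None:
        plan_params = PlanGenParams()
    if error_dist is None:
        error_dist = ErrorDistribution()

    rng = np.random.default_rng(seed)
    plan_seeds = rng.integers(2**31, size=n_plans)

    matrices: list[LeafPositionMatrix] = []
    plane_sets: list[DosePlaneSet] = []
    labels = np.zeros((n_plans, len(NINE_CRITERIA)))
    perturbation = np.zeros(n_plans)
    ids = []

    for i in range(n_plans):
        params_i = replace(plan_params, seed=int(plan_seeds[i]))
        if mean_gap_range_mm is not None:
            params_i = replace(params_i, mean_gap_mm=float(rng.uniform(*mean_gap_range_mm)))
        if jitter_range_mm is not None:
            params_i = replace(params_i, gap_jitter_sd_mm=float(rng.uniform(*jitter_range_mm)))
        plan = generate_plan(params_i)
        ids.append(plan.plan_id)
        matrices.append(build_leaf_matrix(plan))

        error = error_dist.draw(rng)
        planned = simulate_dose(plan, None, grid)
        delivered = simulate_dose(plan, error, grid)

        pa, pb = plan.bank_stack()
        da, db = apply_errors(plan, error).bank_stack()
        perturbation[i] = 0.5 * (np.mean(np.abs(da - pa)) + np.mean(np.abs(db - pb)))

        label = gpr_vector(
            detector_plane(planned, plan.isocenter),
            detector_plane(delivered, plan.isocenter),
            spacing=grid.spacing,
        )
        labels[i] = label.as_array()

        surface = None
        if include_surface:
            surface = extract_surface_dose(
                planned,
                plan.isocenter,
                radius=surface_radius_mm,
                n_axial=surface_shape[0],
                n_angles=surface_shape[1],
            )
        plane_sets.append(
            extract_isocenter_planes(planned, plan.isocenter, plane_shapes, surface=surface)
        )

    excluded = find_always_closed_pairs(matrices)
    if mlpm_shape is None:
        mlpm_shape = (2 * (N_LEAF_PAIRS - len(excluded)), plan_params.n_control_points)
    maps = [build_mlpm(m, excluded, mlpm_shape) for m in matrices]
    mlpm_stack, mlpm_norm = normalize_maps(maps)

    planes: dict[str, np.ndarray] = {}
    plane_norms: dict[str, float] = {}
    plane_names = ["sagittal", "coronal", "axial"] + (["surface"] if include_surface else [])
    for name in plane_names:
        stack = np.stack([getattr(ps, name) for ps in plane_sets])
        norm = float(stack.max()) or 1.0
        planes[name] = (stack / norm).astype(np.float32)
        plane_norms[name] = norm

    degenerate = bool(np.all(np.ptp(labels, axis=0) < 1e-9))
    if degenerate:
        warnings.warn(
            "error distribution produced constant GPR labels; correlation "
            "metrics will be undefined downstream",
            stacklevel=2,
        )

    return SyntheticDataset(
        ids=ids,
        leaf_matrices=matrices,
        excluded_pairs=excluded,
        mlpm=mlpm_stack.astype(np.float32),
        mlpm_norm_mm=mlpm_norm,
        planes=planes,
        plane_norms=plane_norms,
        plane_spacing=grid.spacing,
        labels=labels,
        mean_leaf_perturbation_mm=perturbation,
        seed=seed,
        degenerate_labels=degenerate,
    )
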