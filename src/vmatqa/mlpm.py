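"""MLC leaf position map (MLPM) construction.

The MLPM turns the leaf trajectories of a VMAT arc into a 2D image the CNN
can consume: each column is one control point, rows run from bank A leaf 1
through bank B leaf 60, and every cell holds the distance (mm) of that leaf
tip from its pair's closed-state coordinate — so a closed leaf maps to
exactly 0.  Leaf pairs that stay closed across the whole dataset carry no
information and are dropped, which at clinical scale reduces the 120 leaf
rows to the 110-row map the network expects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ParameterError
from .rtplan_io import CLOSURE_TOL_MM, N_LEAF_PAIRS, ArcPlan

#: MLPM shape at clinical scale: 110 retained rows x 178 control points.
DEFAULT_MLPM_SHAPE = (110, 178)


@dataclass(frozen=True)
class LeafPositionMatrix:
    """Raw 120 x n_cp leaf coordinates plus per-pair closed references.

    Rows 0..59 are bank A leaves 1..60, rows 60..119 bank B leaves 1..60,
    columns follow control-point order.  ``closed_reference[p]`` is the
    coordinate at which pair ``p+1`` has zero gap (the pair junction).
    """

    values: np.ndarray
    closed_reference: np.ndarray
    plan_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        r = np.asarray(self.closed_reference, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "closed_reference", r)
        if v.ndim != 2 or v.shape[0] != 2 * N_LEAF_PAIRS:
            raise ConfigurationError(
                f"leaf matrix must have exactly {2 * N_LEAF_PAIRS} rows, got {v.shape}"
            )
        if r.shape != (N_LEAF_PAIRS,):
            raise ConfigurationError("closed_reference must have one entry per pair")

    @property
    def n_control_points(self) -> int:
        return self.values.shape[1]

    def gaps(self) -> np.ndarray:
        """(60, n_cp) aperture openings (bank B minus bank A)."""
        return self.values[N_LEAF_PAIRS:] - self.values[:N_LEAF_PAIRS]


@dataclass(frozen=True)
class MLPMap:
    """Non-negative leaf displacement-from-closed map, excluded rows removed."""

    values: np.ndarray
    excluded_pairs: frozenset[int]
    n_control_points: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "excluded_pairs", frozenset(self.excluded_pairs))
        if np.any(v < 0):
            raise ConfigurationError("MLPM values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_leaf_matrix(plan: ArcPlan, tol: float = CLOSURE_TOL_MM) -> LeafPositionMatrix:
    """Stack a plan's leaf coordinates into a 120 x n_cp matrix.

    The closed reference of each pair is the pair midline averaged over the
    control points at which the pair is closed (gap <= ``tol``); for a pair
    that never closes within the plan the midline averaged over all control
    points is used as the junction estimate.
    """
    bank_a, bank_b = plan.bank_stack()
    values = np.concatenate([bank_a, bank_b], axis=0)
    mid = 0.5 * (bank_a + bank_b)
    closed = (bank_b - bank_a) <= tol
    closed_ref = np.where(
        closed.any(axis=1),
        np.sum(mid * closed, axis=1) / np.maximum(closed.sum(axis=1), 1),
        mid.mean(axis=1),
    )
    return LeafPositionMatrix(values=values, closed_reference=closed_ref, plan_id=plan.plan_id)


def find_always_closed_pairs(
    matrices: Iterable[LeafPositionMatrix], tol: float = CLOSURE_TOL_MM
) -> frozenset[int]:
    """Leaf pairs (1-based) closed at every control point of every matrix.

    A pair is returned only if its gap never exceeds ``tol`` anywhere in the
    collection — opening once, in any plan, removes it from the set.
    """
    matrices = list(matrices)
    if not matrices:
        raise ParameterError("need at least one leaf matrix")
    always_closed = np.ones(N_LEAF_PAIRS, dtype=bool)
    for m in matrices:
        always_closed &= np.all(m.gaps() <= tol, axis=1)
    return frozenset(int(p) + 1 for p in np.nonzero(always_closed)[0])


def build_mlpm(
    matrix: LeafPositionMatrix,
    excluded: Iterable[int] = (),
    fixed_shape: tuple[int, int] = DEFAULT_MLPM_SHAPE,
) -> MLPMap:
    """Map leaf coordinates to displacement-from-closed and fix the shape.

    Each retained cell becomes ``|coordinate - closed_reference|`` so the
    closed state reads exactly 0.  Rows of excluded pairs are removed from
    both bank blocks; plans shorter than ``fixed_shape[1]`` control points
    are right-padded with zeros (padding must not fabricate leaf motion),
    longer plans are rejected.
    """
    excluded = frozenset(int(p) for p in excluded)
    if not excluded <= set(range(1, N_LEAF_PAIRS + 1)):
        raise ParameterError(f"excluded pairs must be within 1..{N_LEAF_PAIRS}")
    keep = np.array([p + 1 not in excluded for p in range(N_LEAF_PAIRS)])

    disp = np.abs(matrix.values - np.tile(matrix.closed_reference, 2)[:, None])
    disp = np.concatenate([disp[: N_LEAF_PAIRS][keep], disp[N_LEAF_PAIRS:][keep]], axis=0)

    rows, width = fixed_shape
    if disp.shape[0] != rows:
        raise ConfigurationError(
            f"{disp.shape[0]} retained rows do not match the configured map "
            f"height {rows}; check the exclusion set"
        )
    n_cp = disp.shape[1]
    if n_cp > width:
        raise ConfigurationError(
            f"plan has {n_cp} control points but the map width is {width}"
        )
    out = np.zeros((rows, width), dtype=float)
    out[:, :n_cp] = disp
    return MLPMap(values=out, excluded_pairs=excluded, n_control_points=n_cp)


def normalize_maps(maps: Sequence[MLPMap]) -> tuple[np.ndarray, float]:
    """Stack maps and scale by the collection-wide maximum displacement.

    Returns ``(stack in [0, 1], max_displacement_mm)``; an all-zero
    collection is returned unscaled with max 1 to avoid division by zero.
    """
    stack = np.stack([m.values for m in maps])
    vmax = float(stack.max())
    if vmax <= 0:
        return stack, 1.0
    return stack / vmax, vmax


def save_mlpm_png(mlpm: MLPMap, path) -> None:
    """Export a map as a grayscale PNG for visual inspection."""
    import matplotlib.image

    v = mlpm.values
    vmax = v.max() if v.max() > 0 else 1.0
    matplotlib.image.imsave(str(path), v / vmax, cmap="gray", vmin=0.0, vmax=1.0)
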