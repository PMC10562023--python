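"""Global gamma-index evaluation and gamma passing rates (GPR).

The gamma index compares an evaluated (e.g. delivered/measured) dose image
against a reference (planned) image by combining dose difference and
distance-to-agreement (DTA): for each reference point ``r``,

    gamma(r) = min over positions q of
               sqrt( ((E(q) - R(r)) / (dose_tol% * Dmax))^2 + (|q - r| / dta)^2 )

with ``Dmax`` the reference maximum ("global" normalization) and the search
restricted to a disk of ``search_radius_mult * dta`` around ``r``.  A point
passes when gamma <= 1; the GPR is the passing percentage over reference
points at or above a dose threshold (default 10% of Dmax).

Patient-specific QA conventionally reports GPR at the nine criteria
{1, 2, 3}% x {1, 2, 3} mm, which is also the output vocabulary of the
prediction network in this package.

Numerics: the evaluated image is bilinearly upsampled onto a fine lattice
whose step is the largest integer subdivision of the pixel spacing not
exceeding ``0.1 * dta``, and the DTA search is an exhaustive minimum over all
fine-lattice offsets inside the search disk (with an early exit once the
spatial term alone exceeds the current worst-case minimum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np

from .errors import DegenerateInputError, ParameterError


class GammaCriterion(NamedTuple):
    """A %/mm gamma criterion: dose tolerance (% of Dmax) and DTA (mm)."""

    dose_pct: float
    dta_mm: float

    def __str__(self) -> str:  # e.g. "2%/2mm"
        return f"{self.dose_pct:g}%/{self.dta_mm:g}mm"


#: The nine standard criteria, loosest last: {1,2,3}% x {1,2,3} mm.
NINE_CRITERIA: tuple[GammaCriterion, ...] = tuple(
    GammaCriterion(float(d), float(t)) for d in (1, 2, 3) for t in (1, 2, 3)
)


@dataclass(frozen=True)
class GprLabel:
    """GPR (%) at each of the nine criteria."""

    gpr: Mapping[GammaCriterion, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "gpr", dict(self.gpr))
        if set(self.gpr) != set(NINE_CRITERIA):
            raise ParameterError("a GPR label must contain exactly the nine criteria")
        for crit, value in self.gpr.items():
            if not (0.0 <= value <= 100.0):
                raise ParameterError(f"GPR at {crit} out of [0, 100]: {value}")

    def __getitem__(self, crit: GammaCriterion) -> float:
        return self.gpr[crit]

    def as_array(self) -> np.ndarray:
        """Values ordered as :data:`NINE_CRITERIA`."""
        return np.array([self.gpr[c] for c in NINE_CRITERIA])

    @classmethod
    def from_array(cls, values) -> "GprLabel":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(NINE_CRITERIA),):
            raise ParameterError("expected nine GPR values")
        return cls(gpr=dict(zip(NINE_CRITERIA, values.tolist())))

    def is_monotone(self, atol: float = 1e-9) -> bool:
        """GPR must not decrease when either tolerance loosens."""
        for d1, t1 in NINE_CRITERIA:
            for d2, t2 in NINE_CRITERIA:
                if d2 >= d1 and t2 >= t1:
                    a = self.gpr[GammaCriterion(d1, t1)]
                    b = self.gpr[GammaCriterion(d2, t2)]
                    if b < a - atol:
                        return False
        return True


def _fine_step(spacing: float, step_mm: float) -> tuple[int, float]:
    """Integer subdivision k of the pixel spacing with spacing/k <= step_mm."""
    k = max(1, math.ceil(spacing / step_mm - 1e-9))
    return k, spacing / k


def _upsample_bilinear(image: np.ndarray, k: int) -> np.ndarray:
    """Bilinear upsampling keeping original nodes at indices i*k."""
    if k == 1:
        return np.asarray(image, dtype=float)
    n0, n1 = image.shape
    f0 = np.arange((n0 - 1) * k + 1) / k
    f1 = np.arange((n1 - 1) * k + 1) / k
    i0 = np.minimum(f0.astype(int), n0 - 2)
    i1 = np.minimum(f1.astype(int), n1 - 2)
    w0 = (f0 - i0)[:, None]
    w1 = (f1 - i1)[None, :]
    a = image[np.ix_(i0, i1)]
    b = image[np.ix_(i0, i1 + 1)]
    c = image[np.ix_(i0 + 1, i1)]
    d = image[np.ix_(i0 + 1, i1 + 1)]
    return (1 - w0) * ((1 - w1) * a + w1 * b) + w0 * ((1 - w1) * c + w1 * d)


def gamma_map(
    reference: np.ndarray,
    evaluated: np.ndarray,
    spacing: float,
    crit: GammaCriterion,
    threshold_pct: float = 10.0,
    search_radius_mult: float = 3.0,
    fine_step_mm: float | None = None,
) -> np.ndarray:
    """Gamma values over above-threshold reference points (NaN elsewhere).

    ``reference`` and ``evaluated`` are 2D images on the same frame with
    isotropic pixel ``spacing`` (mm).  Points below ``threshold_pct`` of the
    reference maximum are excluded from the domain and returned as NaN.
    ``fine_step_mm`` overrides the default ``0.1 * dta`` interpolation step;
    :func:`gpr_vector` passes a common step for all criteria so that looser
    criteria search supersets of tighter criteria's candidate positions.
    """
    reference = np.asarray(reference, dtype=float)
    evaluated = np.asarray(evaluated, dtype=float)
    if reference.shape != evaluated.shape or reference.ndim != 2:
        raise ParameterError("reference and evaluated must be 2D images of equal shape")
    if crit.dose_pct <= 0 or crit.dta_mm <= 0:
        raise ParameterError("gamma criterion tolerances must be positive")
    dmax = float(reference.max())
    if dmax <= 0:
        raise DegenerateInputError("reference has no positive dose")
    mask = reference >= threshold_pct / 100.0 * dmax
    if not mask.any():
        raise DegenerateInputError("no reference points above the dose threshold")

    if fine_step_mm is None:
        fine_step_mm = 0.1 * crit.dta_mm
    k, h = _fine_step(spacing, fine_step_mm)
    fine = _upsample_bilinear(evaluated, k)
    pi, pj = np.nonzero(mask)
    fi = pi * k
    fj = pj * k
    ref_vals = reference[mask]
    dose_norm = crit.dose_pct / 100.0 * dmax

    radius_units = int(math.floor(search_radius_mult * crit.dta_mm / h + 1e-9))
    offs = np.arange(-radius_units, radius_units + 1)
    di, dj = np.meshgrid(offs, offs, indexing="ij")
    dist2 = (di.ravel() ** 2 + dj.ravel() ** 2).astype(float)
    inside = dist2 * h * h <= (search_radius_mult * crit.dta_mm) ** 2 + 1e-12
    order = np.argsort(dist2[inside], kind="stable")
    di = di.ravel()[inside][order]
    dj = dj.ravel()[inside][order]
    spatial2 = dist2[inside][order] * (h / crit.dta_mm) ** 2

    n0, n1 = fine.shape
    gamma2 = np.full(ref_vals.shape, np.inf)
    # offsets are distance-sorted: a point whose current minimum is already
    # below the spatial term alone can never improve and is retired.
    active = np.arange(ref_vals.size)
    for s2, oi, oj in zip(spatial2, di, dj):
        active = active[gamma2[active] > s2]
        if active.size == 0:
            break
        qi = fi[active] + oi
        qj = fj[active] + oj
        valid = (qi >= 0) & (qi < n0) & (qj >= 0) & (qj < n1)
        if not valid.any():
            continue
        sel = active[valid]
        dd = (fine[qi[valid], qj[valid]] - ref_vals[sel]) / dose_norm
        gamma2[sel] = np.minimum(gamma2[sel], dd * dd + s2)

    out = np.full(reference.shape, np.nan)
    out[mask] = np.sqrt(gamma2)
    return out


def gpr(gamma_field: np.ndarray) -> float:
    """Passing rate (%) of a gamma field: fraction of points with gamma <= 1."""
    values = np.asarray(gamma_field, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise DegenerateInputError("gamma field has no evaluated points")
    return 100.0 * float(np.mean(values <= 1.0))


def gpr_vector(
    reference: np.ndarray,
    evaluated: np.ndarray,
    spacing: float,
    threshold_pct: float = 10.0,
    search_radius_mult: float = 3.0,
) -> GprLabel:
    """GPR at all nine criteria for one reference/evaluated pair.

    All criteria share the interpolation lattice of the tightest DTA, so a
    looser criterion always searches a superset of a tighter criterion's
    candidate positions and the returned label is monotone by construction.
    """
    fine_step = 0.1 * min(c.dta_mm for c in NINE_CRITERIA)
    values = {}
    for crit in NINE_CRITERIA:
        field = gamma_map(
            reference,
            evaluated,
            spacing,
            crit,
            threshold_pct=threshold_pct,
            search_radius_mult=search_radius_mult,
            fine_step_mm=fine_step,
        )
        values[crit] = gpr(field)
    return GprLabel(gpr=values)
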