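"""Steady advection-diffusion transport of autoinducer in a perfusion chamber.

Verifies that autoinducer (AI) released by cells adhered to the lower
window of a parallel-plate flow chamber does not accumulate appreciably at
the window: under slow perfusion the released AI is carried away by the
flow and diluted by diffusion, keeping the self-generated concentration far
below the induction threshold.

Geometry is reduced to a 2-D channel cross-section (along-flow x, wall-
normal z); the transverse width enters through the mean velocity of the
plane-Poiseuille profile. The steady equation 0 = D lap(c) - u(z) dc/dx is
discretized with a finite-volume scheme (central diffusion, upwind
advection) and solved directly, so global mass balance holds to
discretization tolerance and the discrete maximum principle keeps the
solution non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.sparse import lil_matrix
from scipy.sparse.linalg import spsolve

__all__ = ["ChamberSpec", "ConcentrationField", "solve_steady_state", "grid_convergence"]

#: mol/mm^3 per pM  (1 pM = 1e-12 mol/L, 1 L = 1e6 mm^3)
_MOL_PER_MM3_PER_PM = 1e-18


class ChamberSpec(BaseModel):
    """Perfusion chamber geometry, flow, and AI source parameters.

    Defaults describe the experimental configuration: 25 mm coverslips
    spaced 5 mm apart, 0.2 ml/hr perfusion, cells confined to a small patch
    (a few mm) on the lower window, each releasing AI (3OC6HSL,
    213.2 g/mol) at 1e-21 g/s, diffusivity 100 um^2/s.
    """

    model_config = {"extra": "forbid"}

    gap: float = Field(gt=0, default=5.0, description="plate spacing (mm)")
    width: float = Field(gt=0, default=25.0, description="transverse extent (mm)")
    length: float = Field(gt=0, default=25.0, description="along-flow domain (mm)")
    flow_rate: float = Field(ge=0, default=0.2, description="ml/hr")
    patch_center: float = Field(gt=0, default=12.5, description="mm from inflow")
    patch_length: float = Field(gt=0, default=2.0, description="mm")
    n_cells: int = Field(gt=0, default=1000)
    release_rate: float = Field(ge=0, default=1e-21, description="g/s per cell")
    molar_mass: float = Field(gt=0, default=213.2, description="g/mol")
    diffusivity: float = Field(gt=0, default=100.0, description="um^2/s")

    @model_validator(mode="after")
    def _patch_inside(self) -> "ChamberSpec":
        if self.patch_center - self.patch_length / 2 < 0 or \
           self.patch_center + self.patch_length / 2 > self.length:
            raise ValueError("patch must lie within the along-flow domain")
        return self

    @property
    def mean_velocity(self) -> float:
        """Mean flow speed in mm/s: Q / (gap * width)."""
        q_mm3_per_s = self.flow_rate * 1000.0 / 3600.0
        return q_mm3_per_s / (self.gap * self.width)

    @property
    def diffusivity_mm2(self) -> float:
        return self.diffusivity * 1e-6

    @property
    def source_flux(self) -> float:
        """Molar flux density over the patch, mol/(s mm^2)."""
        total_mol_per_s = self.n_cells * self.release_rate / self.molar_mass
        return total_mol_per_s / (self.patch_length * self.width)


@dataclass
class ConcentrationField:
    x: np.ndarray               # cell-center coordinates along flow (mm)
    z: np.ndarray               # cell-center coordinates across gap (mm)
    c_pM: np.ndarray            # concentration, shape (nz, nx)
    wall_pM: np.ndarray         # concentration extrapolated to the lower wall
    max_at_window: float        # pM
    mass_balance_error: float   # |out - in| / in

    def to_frame(self) -> pd.DataFrame:
        xx, zz = np.meshgrid(self.x, self.z)
        return pd.DataFrame({
            "x_mm": xx.ravel(), "z_mm": zz.ravel(), "c_pM": self.c_pM.ravel(),
        })


def solve_steady_state(
    spec: ChamberSpec,
    grid_resolution: tuple[int, int] = (250, 100),
) -> ConcentrationField:
    """Solve 0 = D lap(c) - u(z) dc/dx on the (x, z) cross-section.

    ``grid_resolution`` is (nx, nz) finite-volume cells. Boundary
    conditions: inflow (x=0) c = 0; outflow zero diffusive flux (advective
    outflow only); top wall zero flux; bottom wall zero flux except a
    constant molar influx over the cell patch. Requires the gap to be
    resolved by >= 50 cells and the patch by >= 10.
    """
    nx, nz = grid_resolution
    dx = spec.length / nx
    dz = spec.gap / nz
    if nz < 50:
        raise ValueError("grid must resolve the gap with at least 50 cells")
    if spec.patch_length / dx < 10:
        raise ValueError("grid must resolve the patch with at least 10 cells")

    D = spec.diffusivity_mm2
    x = (np.arange(nx) + 0.5) * dx
    z = (np.arange(nz) + 0.5) * dz
    # plane-Poiseuille profile with mean velocity u_bar
    u = 6.0 * spec.mean_velocity * (z / spec.gap) * (1.0 - z / spec.gap)

    J = spec.source_flux                      # mol/(s mm^2) into the domain
    # exact overlap of each bottom-wall cell with the patch, so the injected
    # mass is grid-independent
    x_lo, x_hi = x - dx / 2, x + dx / 2
    p_lo = spec.patch_center - spec.patch_length / 2
    p_hi = spec.patch_center + spec.patch_length / 2
    overlap = np.clip(np.minimum(x_hi, p_hi) - np.maximum(x_lo, p_lo), 0.0, dx)
    on_patch = overlap > 0

    n = nx * nz
    A = lil_matrix((n, n))
    b = np.zeros(n)

    def idx(i: int, j: int) -> int:          # i along x, j along z
        return j * nx + i

    for j in range(nz):
        uj = u[j]
        for i in range(nx):
            k = idx(i, j)
            diag = 0.0
            # x-direction faces -----------------------------------------
            # west face: advective (upwind, u >= 0) + diffusive
            if i > 0:
                A[k, idx(i - 1, j)] += (-uj - D / dx) * dz
                diag += (D / dx) * dz
            else:
                # inflow: advects c_in = 0 in; diffusion to Dirichlet c = 0
                diag += (D / (dx / 2)) * dz
            # east face
            if i < nx - 1:
                diag += (uj + D / dx) * dz
                A[k, idx(i + 1, j)] += (-D / dx) * dz
            else:
                diag += uj * dz               # outflow: advective only
            # z-direction faces (diffusive) -----------------------------
            if j > 0:
                A[k, idx(i, j - 1)] += -(D / dz) * dx
                diag += (D / dz) * dx
            elif on_patch[i]:
                b[k] += J * overlap[i]        # source influx at bottom wall
            if j < nz - 1:
                A[k, idx(i, j + 1)] += -(D / dz) * dx
                diag += (D / dz) * dx
            A[k, k] += diag

    c = spsolve(A.tocsr(), b)                 # mol/mm^3
    if not np.all(np.isfinite(c)):
        raise RuntimeError("linear solve failed to produce a finite solution")
    c = c.reshape(nz, nx)

    # mass balance: source vs (advective outflow + diffusive inflow leak)
    total_in = J * spec.patch_length          # per unit width, mol/(s mm)
    out_adv = float(np.sum(u * c[:, -1] * dz))
    out_diff_inlet = float(np.sum(D * c[:, 0] / (dx / 2) * dz))
    balance = abs(out_adv + out_diff_inlet - total_in) / total_in if total_in > 0 else 0.0

    # wall value: extrapolate using the imposed flux, c_w = c_0 + J dz/(2D)
    wall = c[0] + J * (overlap / dx) * (dz / 2) / D
    c_pM = c / _MOL_PER_MM3_PER_PM
    wall_pM = wall / _MOL_PER_MM3_PER_PM
    return ConcentrationField(
        x=x, z=z, c_pM=c_pM, wall_pM=wall_pM,
        max_at_window=float(wall_pM.max()),
        mass_balance_error=float(balance),
    )


def grid_convergence(
    spec: ChamberSpec,
    resolutions: list[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Window-maximum concentration versus grid resolution.

    Reports, for each (nx, nz), ``max_at_window`` and the relative change
    from the previous (coarser) level; the two finest levels should agree
    within a few percent for a trustworthy solve.
    """
    if resolutions is None:
        resolutions = [(125, 50), (250, 100), (375, 150)]
    if len(resolutions) < 3:
        raise ValueError("need at least 3 resolutions")
    cells = [nx * nz for nx, nz in resolutions]
    if any(b <= a for a, b in zip(cells, cells[1:])):
        raise ValueError("resolutions must be monotonically increasing")
    rows = []
    prev = None
    for nx, nz in resolutions:
        field = solve_steady_state(spec, (nx, nz))
        change = abs(field.max_at_window - prev) / prev if prev else np.nan
        rows.append({
            "nx": nx, "nz": nz, "max_at_window_pM": field.max_at_window,
            "rel_change": change, "mass_balance_error": field.mass_balance_error,
        })
        prev = field.max_at_window
    return pd.DataFrame(rows)
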