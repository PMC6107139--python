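"""Fused compiled time-stepping kernel.

The explicit update only does work where the phase field is neither
exactly 0 nor saturated at 1: the surface-tension, area and active terms
all vanish away from the interface, and the polarity dynamics are
confined to the cell interior.  The engine therefore partitions the
lattice into

* ``band``  -- interface cells (phi within (thr, 1-thr), dilated by a few
  pixels): phi, c and the noise field xi are updated here;
* ``core``  -- saturated interior cells outside the band: only c is
  updated (phi is stationary there to below the band threshold);
* frozen    -- everything else: no update (the exact fixed point).

Membership is refreshed every few hundred steps by the engine, with a
dilation margin that far exceeds the distance the interface can travel
in between.  Within a chunk the kernel performs plain Jacobi updates in
the order: threshold delta -> noise xi -> polarity c (using the updated
xi and pre-update phi) -> phase field phi (using pre-update c), exactly
matching the per-module reference operators.

Partial sums of phi and c*phi over the non-updated cells are passed in
as constants so the global integrals (area and c budget) entering the
area constraint and the threshold feedback are exact every step.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_chunk"]


@njit(cache=True, fastmath=True)
def run_chunk(
    phi,
    c,
    xi,
    band_i,
    band_j,
    core_i,
    core_j,
    normals,  # (n_steps, n_band) standard normal draws
    dx,
    dt,
    tau,
    gamma,
    eps2,
    beta,
    A_o,
    alpha,
    k_a,
    delta_o,
    C_o,
    M,
    rho,
    D,
    phi_floor,
    a_ou,  # OU decay factor 1 - k_eta * dt
    s_ou,  # OU increment std sqrt(2 sigma^2 dt / dx^2)
    sum_phi_const,  # sum of phi over cells not in the band
    sum_cphi_const,  # sum of c*phi over frozen (never-updated) cells
):
    """Advance (phi, c, xi) in place by normals.shape[0] steps.

    Returns (last_area, last_amount, last_delta) diagnostics from the
    final step.
    """
    n_steps = normals.shape[0]
    nb = band_i.shape[0]
    nc = core_i.shape[0]
    ny, nx = phi.shape
    dx2 = dx * dx
    inv_dx2 = 1.0 / dx2
    inv_2dx = 0.5 / dx

    dphi = np.empty(nb)
    dc_b = np.empty(nb)
    dc_c = np.empty(nc)

    # running sums over the updated sets
    s_phi_band = 0.0
    s_cphi_band = 0.0
    s_cphi_core = 0.0
    for k in range(nb):
        i = band_i[k]
        j = band_j[k]
        s_phi_band += phi[i, j]
        s_cphi_band += c[i, j] * phi[i, j]
    for k in range(nc):
        i = core_i[k]
        j = core_j[k]
        s_cphi_core += c[i, j] * phi[i, j]

    area = 0.0
    amount = 0.0
    delta = 0.0
    for step in range(n_steps):
        area = (s_phi_band + sum_phi_const) * dx2
        amount = (s_cphi_band + s_cphi_core + sum_cphi_const) * dx2
        delta = delta_o + M * (amount - C_o)
        apref = beta * (area - A_o)

        # (1) OU noise update, independent per cell
        for k in range(nb):
            i = band_i[k]
            j = band_j[k]
            xi[i, j] = xi[i, j] * a_ou + s_ou * normals[step, k]

        # (2) increments on the interface band: both c and phi
        for k in range(nb):
            i = band_i[k]
            j = band_j[k]
            ip = i + 1 if i + 1 < ny else 0
            im = i - 1 if i > 0 else ny - 1
            jp = j + 1 if j + 1 < nx else 0
            jm = j - 1 if j > 0 else nx - 1

            p0 = phi[i, j]
            pN = phi[im, j]
            pS = phi[ip, j]
            pW = phi[i, jm]
            pE = phi[i, jp]
            c0 = c[i, j]

            # polarity: reaction + degradation + masked diffusion + noise
            fN = 0.5 * (p0 + pN)
            fS = 0.5 * (p0 + pS)
            fW = 0.5 * (p0 + pW)
            fE = 0.5 * (p0 + pE)
            div = (
                fE * (c[i, jp] - c0)
                - fW * (c0 - c[i, jm])
                + fS * (c[ip, j] - c0)
                - fN * (c0 - c[im, j])
            )
            pmax = p0 if p0 > phi_floor else phi_floor
            diff = D * div * inv_dx2 / pmax
            if (
                p0 < phi_floor
                and fN < phi_floor
                and fS < phi_floor
                and fW < phi_floor
                and fE < phi_floor
            ):
                diff = 0.0
            react = k_a * c0 * (1.0 - c0) * (c0 - delta)
            dc_b[k] = dt * (react - rho * c0 + diff + xi[i, j] * p0 * (1.0 - p0))

            # phase field: surface tension + area constraint + active tension
            lap = (pE + pW + pN + pS - 4.0 * p0) * inv_dx2
            gprime = 36.0 * p0 * (1.0 - p0) * (1.0 - 2.0 * p0)
            gx = (pE - pW) * inv_2dx
            gy = (pS - pN) * inv_2dx
            gmag = np.sqrt(gx * gx + gy * gy)
            rhs = gamma * (lap - gprime / eps2) - apref * gmag + alpha * c0 * gmag
            dphi[k] = (dt / tau) * rhs

        # (3) increments on the saturated core: c only
        for k in range(nc):
            i = core_i[k]
            j = core_j[k]
            ip = i + 1 if i + 1 < ny else 0
            im = i - 1 if i > 0 else ny - 1
            jp = j + 1 if j + 1 < nx else 0
            jm = j - 1 if j > 0 else nx - 1
            p0 = phi[i, j]
            c0 = c[i, j]
            fN = 0.5 * (p0 + phi[im, j])
            fS = 0.5 * (p0 + phi[ip, j])
            fW = 0.5 * (p0 + phi[i, jm])
            fE = 0.5 * (p0 + phi[i, jp])
            div = (
                fE * (c[i, jp] - c0)
                - fW * (c0 - c[i, jm])
                + fS * (c[ip, j] - c0)
                - fN * (c0 - c[im, j])
            )
            pmax = p0 if p0 > phi_floor else phi_floor
            diff = D * div * inv_dx2 / pmax
            react = k_a * c0 * (1.0 - c0) * (c0 - delta)
            dc_c[k] = dt * (react - rho * c0 + diff + xi[i, j] * p0 * (1.0 - p0))

        # (4) apply and rebuild running sums
        s_phi_band = 0.0
        s_cphi_band = 0.0
        for k in range(nb):
            i = band_i[k]
            j = band_j[k]
            pn = phi[i, j] + dphi[k]
            cn = c[i, j] + dc_b[k]
            phi[i, j] = pn
            c[i, j] = cn
            s_phi_band += pn
            s_cphi_band += cn * pn
        s_cphi_core = 0.0
        for k in range(nc):
            i = core_i[k]
            j = core_j[k]
            cn = c[i, j] + dc_c[k]
            c[i, j] = cn
            s_cphi_core += cn * phi[i, j]

    return area, amount, delta
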