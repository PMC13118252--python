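"""Numba kernels for ray-driven cone-beam projection.

The forward projector samples the volume with trilinear interpolation at a
fixed step along each source->pixel ray (Joseph-style); the back projector
scatters with the identical weights, so the pair is an exact matched
transpose of one discrete linear operator.

Axis conventions (shared with :mod:`vmatct.geometry`):

* world x lateral, y vertical (source at +y for gantry angle 0), z axial;
* gantry angle ``theta`` in degrees, source at ``SAD * (sin t, cos t, 0)``;
* detector u axis transverse ``(cos t, -sin t, 0)``, v axis ``(0, 0, 1)``;
* projection images are ``(n_u, n_v)`` arrays.
"""

import numpy as np
from numba import njit

__all__ = [
    "forward_view",
    "back_view",
    "fdk_back_view",
    "view_vectors",
]


def view_vectors(angle_deg, sad, sdd):
    """Source position, detector center, and (u, v) unit vectors for a view."""
    t = np.deg2rad(angle_deg)
    e = np.array([np.sin(t), np.cos(t), 0.0])
    source = sad * e
    det_center = source - sdd * e
    u_hat = np.array([np.cos(t), -np.sin(t), 0.0])
    v_hat = np.array([0.0, 0.0, 1.0])
    return source, det_center, u_hat, v_hat


@njit(cache=True, fastmath=True)
def _ray_aabb(sx, sy, sz, dx, dy, dz, lo0, lo1, lo2, hi0, hi1, hi2):
    """Slab intersection of a ray with an axis-aligned box; (t0, t1)."""
    t0 = -1.0e30
    t1 = 1.0e30
    eps = 1.0e-12
    # x slab
    if abs(dx) < eps:
        if sx < lo0 or sx > hi0:
            return 1.0, 0.0
    else:
        ta = (lo0 - sx) / dx
        tb = (hi0 - sx) / dx
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    if abs(dy) < eps:
        if sy < lo1 or sy > hi1:
            return 1.0, 0.0
    else:
        ta = (lo1 - sy) / dy
        tb = (hi1 - sy) / dy
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    if abs(dz) < eps:
        if sz < lo2 or sz > hi2:
            return 1.0, 0.0
    else:
        ta = (lo2 - sz) / dz
        tb = (hi2 - sz) / dz
        if ta > tb:
            ta, tb = tb, ta
        if ta > t0:
            t0 = ta
        if tb < t1:
            t1 = tb
    if t0 < 0.0:
        t0 = 0.0
    return t0, t1


@njit(cache=True, fastmath=True)
def forward_view(vol, voxel, ox, oy, oz, src, det_c, u_hat, v_hat,
                 n_u, n_v, pitch, step):
    """Line integrals of ``vol`` for one view; returns an (n_u, n_v) image."""
    nx, ny, nz = vol.shape
    lo0 = ox - 0.5 * voxel
    lo1 = oy - 0.5 * voxel
    lo2 = oz - 0.5 * voxel
    hi0 = ox + (nx - 0.5) * voxel
    hi1 = oy + (ny - 0.5) * voxel
    hi2 = oz + (nz - 0.5) * voxel
    proj = np.zeros((n_u, n_v))
    cu = 0.5 * (n_u - 1)
    cv = 0.5 * (n_v - 1)
    for iu in range(n_u):
        du = (iu - cu) * pitch
        for iv in range(n_v):
            dv = (iv - cv) * pitch
            px = det_c[0] + du * u_hat[0] + dv * v_hat[0]
            py = det_c[1] + du * u_hat[1] + dv * v_hat[1]
            pz = det_c[2] + du * u_hat[2] + dv * v_hat[2]
            rx = px - src[0]
            ry = py - src[1]
            rz = pz - src[2]
            rn = np.sqrt(rx * rx + ry * ry + rz * rz)
            rx /= rn
            ry /= rn
            rz /= rn
            t0, t1 = _ray_aabb(src[0], src[1], src[2], rx, ry, rz,
                               lo0, lo1, lo2, hi0, hi1, hi2)
            if t1 <= t0:
                continue
            nsteps = int(np.ceil((t1 - t0) / step))
            dt = (t1 - t0) / nsteps
            acc = 0.0
            for k in range(nsteps):
                t = t0 + (k + 0.5) * dt
                gx = (src[0] + t * rx - ox) / voxel
                gy = (src[1] + t * ry - oy) / voxel
                gz = (src[2] + t * rz - oz) / voxel
                i0 = int(np.floor(gx))
                j0 = int(np.floor(gy))
                k0 = int(np.floor(gz))
                fx = gx - i0
                fy = gy - j0
                fz = gz - k0
                for ci in range(2):
                    ii = i0 + ci
                    if ii < 0 or ii >= nx:
                        continue
                    wx = fx if ci == 1 else 1.0 - fx
                    for cj in range(2):
                        jj = j0 + cj
                        if jj < 0 or jj >= ny:
                            continue
                        wy = fy if cj == 1 else 1.0 - fy
                        for ck in range(2):
                            kk = k0 + ck
                            if kk < 0 or kk >= nz:
                                continue
                            wz = fz if ck == 1 else 1.0 - fz
                            acc += wx * wy * wz * vol[ii, jj, kk]
            proj[iu, iv] = acc * dt
    return proj


@njit(cache=True, fastmath=True)
def back_view(proj, vol_shape, voxel, ox, oy, oz, src, det_c, u_hat, v_hat,
              pitch, step):
    """Exact transpose of :func:`forward_view`; returns a volume array."""
    nx, ny, nz = vol_shape
    n_u, n_v = proj.shape
    lo0 = ox - 0.5 * voxel
    lo1 = oy - 0.5 * voxel
    lo2 = oz - 0.5 * voxel
    hi0 = ox + (nx - 0.5) * voxel
    hi1 = oy + (ny - 0.5) * voxel
    hi2 = oz + (nz - 0.5) * voxel
    vol = np.zeros((nx, ny, nz))
    cu = 0.5 * (n_u - 1)
    cv = 0.5 * (n_v - 1)
    for iu in range(n_u):
        du = (iu - cu) * pitch
        for iv in range(n_v):
            val = proj[iu, iv]
            if val == 0.0:
                continue
            dv = (iv - cv) * pitch
            px = det_c[0] + du * u_hat[0] + dv * v_hat[0]
            py = det_c[1] + du * u_hat[1] + dv * v_hat[1]
            pz = det_c[2] + du * u_hat[2] + dv * v_hat[2]
            rx = px - src[0]
            ry = py - src[1]
            rz = pz - src[2]
            rn = np.sqrt(rx * rx + ry * ry + rz * rz)
            rx /= rn
            ry /= rn
            rz /= rn
            t0, t1 = _ray_aabb(src[0], src[1], src[2], rx, ry, rz,
                               lo0, lo1, lo2, hi0, hi1, hi2)
            if t1 <= t0:
                continue
            nsteps = int(np.ceil((t1 - t0) / step))
            dt = (t1 - t0) / nsteps
            w = val * dt
            for k in range(nsteps):
                t = t0 + (k + 0.5) * dt
                gx = (src[0] + t * rx - ox) / voxel
                gy = (src[1] + t * ry - oy) / voxel
                gz = (src[2] + t * rz - oz) / voxel
                i0 = int(np.floor(gx))
                j0 = int(np.floor(gy))
                k0 = int(np.floor(gz))
                fx = gx - i0
                fy = gy - j0
                fz = gz - k0
                for ci in range(2):
                    ii = i0 + ci
                    if ii < 0 or ii >= nx:
                        continue
                    wx = fx if ci == 1 else 1.0 - fx
                    for cj in range(2):
                        jj = j0 + cj
                        if jj < 0 or jj >= ny:
                            continue
                        wy = fy if cj == 1 else 1.0 - fy
                        for ck in range(2):
                            kk = k0 + ck
                            if kk < 0 or kk >= nz:
                                continue
                            wz = fz if ck == 1 else 1.0 - fz
                            vol[ii, jj, kk] += w * wx * wy * wz
    return vol


@njit(cache=True, fastmath=True)
def fdk_back_view(filtered, vol_shape, voxel, ox, oy, oz, sad, sdd,
                  sin_t, cos_t, pitch, dbeta):
    """Voxel-driven FDK-weighted backprojection of one filtered view.

    Applies the classic cone-beam distance weight (SAD / l)^2, where l is
    the voxel's depth from the source along the central-ray direction, and
    bilinear detector interpolation.
    """
    nx, ny, nz = vol_shape
    n_u, n_v = filtered.shape
    vol = np.zeros((nx, ny, nz))
    cu = 0.5 * (n_u - 1)
    cv = 0.5 * (n_v - 1)
    for i in range(nx):
        x = ox + i * voxel
        for j in range(ny):
            y = oy + j * voxel
            # depth from source along central ray; transverse offset
            l = sad - (x * sin_t + y * cos_t)
            if l <= 1.0e-6:
                continue
            u_mm = (x * cos_t - y * sin_t) * sdd / l
            gu = u_mm / pitch + cu
            iu0 = int(np.floor(gu))
            fu = gu - iu0
            if iu0 < -1 or iu0 > n_u - 1:
                continue
            w2 = (sad / l) * (sad / l)
            for k in range(nz):
                z = oz + k * voxel
                v_mm = z * sdd / l
                gv = v_mm / pitch + cv
                iv0 = int(np.floor(gv))
                fv = gv - iv0
                if iv0 < -1 or iv0 > n_v - 1:
                    continue
                acc = 0.0
                for ci in range(2):
                    iu = iu0 + ci
                    if iu < 0 or iu >= n_u:
                        continue
                    wu = fu if ci == 1 else 1.0 - fu
                    for cj in range(2):
                        iv = iv0 + cj
                        if iv < 0 or iv >= n_v:
                            continue
                        wv = fv if cj == 1 else 1.0 - fv
                        acc += wu * wv * filtered[iu, iv]
                vol[i, j, k] += w2 * acc * dbeta
    return vol
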