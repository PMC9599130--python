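"""Numba kernels: spatial hash grid, point classification, specular-reflection
random walk and hazard-based binding.

All lengths are in μm, all times in ms. Sphere kinds are encoded as
0 = neuronal, 1 = astroglial. The uniform grid stores, for every cell, the ids
of all spheres whose axis-aligned bounding box *inflated by the grid margin*
overlaps that cell; a single-cell lookup therefore returns every sphere whose
surface lies within ``margin`` of any point inside the cell.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# status codes for the placement loop
PLACE_OK = 0
PLACE_MAX_SPHERES = 1
PLACE_MAX_ATTEMPTS = 2

INF = np.inf


# ---------------------------------------------------------------------------
# uniform grid
# ---------------------------------------------------------------------------

@njit(cache=True)
def _cell_coord(x, h, nc):
    i = int(x / h)
    if i < 0:
        i = 0
    elif i >= nc:
        i = nc - 1
    return i


@njit(cache=True)
def build_grid(centers, radii, margin, cell_edge, arena_edge):
    """CSR spatial index: cell -> candidate sphere ids.

    Each sphere is registered in every cell overlapped by its bounding box
    inflated by ``margin``.
    """
    n = centers.shape[0]
    nc = max(1, int(math.ceil(arena_edge / cell_edge)))
    ncells = nc * nc * nc
    counts = np.zeros(ncells + 1, dtype=np.int64)

    lo = np.empty((n, 3), dtype=np.int64)
    hi = np.empty((n, 3), dtype=np.int64)
    for s in range(n):
        reach = radii[s] + margin
        for k in range(3):
            lo[s, k] = _cell_coord(centers[s, k] - reach, cell_edge, nc)
            hi[s, k] = _cell_coord(centers[s, k] + reach, cell_edge, nc)
        for i in range(lo[s, 0], hi[s, 0] + 1):
            for j in range(lo[s, 1], hi[s, 1] + 1):
                for k in range(lo[s, 2], hi[s, 2] + 1):
                    counts[(i * nc + j) * nc + k + 1] += 1

    cell_start = np.empty(ncells + 1, dtype=np.int64)
    cell_start[0] = 0
    for c in range(ncells):
        cell_start[c + 1] = cell_start[c] + counts[c + 1]

    entries = np.empty(cell_start[ncells], dtype=np.int64)
    cursor = cell_start[:-1].copy()
    for s in range(n):
        for i in range(lo[s, 0], hi[s, 0] + 1):
            for j in range(lo[s, 1], hi[s, 1] + 1):
                for k in range(lo[s, 2], hi[s, 2] + 1):
                    c = (i * nc + j) * nc + k
                    entries[cursor[c]] = s
                    cursor[c] += 1
    return cell_start, entries, nc


@njit(cache=True, inline="always")
def _cell_id(x, y, z, h, nc):
    return (_cell_coord(x, h, nc) * nc + _cell_coord(y, h, nc)) * nc \
        + _cell_coord(z, h, nc)


# ---------------------------------------------------------------------------
# point queries
# ---------------------------------------------------------------------------

@njit(cache=True)
def classify_points(pts, centers, radii, kinds, cell_start, entries, h, nc):
    """0 = extracellular, 1 = inside >=1 astroglial sphere, 2 = neuronal only."""
    npts = pts.shape[0]
    out = np.zeros(npts, dtype=np.int8)
    for p in range(npts):
        x, y, z = pts[p, 0], pts[p, 1], pts[p, 2]
        c = _cell_id(x, y, z, h, nc)
        inside_neuronal = False
        code = np.int8(0)
        for e in range(cell_start[c], cell_start[c + 1]):
            s = entries[e]
            dx = x - centers[s, 0]
            dy = y - centers[s, 1]
            dz = z - centers[s, 2]
            if dx * dx + dy * dy + dz * dz <= radii[s] * radii[s]:
                if kinds[s] == 1:
                    code = np.int8(1)
                    break
                inside_neuronal = True
        if code == 0 and inside_neuronal:
            code = np.int8(2)
        out[p] = code
    return out


@njit(cache=True)
def min_cover_label(pts, centers, radii, labels, cell_start, entries, h, nc):
    """Per point: min sphere label u over covering spheres (inf if uncovered)."""
    npts = pts.shape[0]
    out = np.full(npts, INF)
    for p in range(npts):
        x, y, z = pts[p, 0], pts[p, 1], pts[p, 2]
        c = _cell_id(x, y, z, h, nc)
        best = INF
        for e in range(cell_start[c], cell_start[c + 1]):
            s = entries[e]
            dx = x - centers[s, 0]
            dy = y - centers[s, 1]
            dz = z - centers[s, 2]
            if dx * dx + dy * dy + dz * dz <= radii[s] * radii[s]:
                if labels[s] < best:
                    best = labels[s]
        out[p] = best
    return out


@njit(cache=True)
def surface_query_batch(pts, centers, radii, kinds, cell_start, entries,
                        h, nc, max_radius):
    """Signed distance to the union cell surface within ``max_radius``.

    Returns (distance, nearest_id, astro_distance, astro_id); distances are
    +inf (ids -1) when no sphere surface lies within max_radius.  Scans every
    grid cell overlapping the cube point +- max_radius, which is guaranteed to
    contain all qualifying spheres for any max_radius (insertion uses the
    sphere bounding box, itself inflated by the grid margin).
    """
    npts = pts.shape[0]
    dist = np.full(npts, INF)
    idx = np.full(npts, -1, dtype=np.int64)
    adist = np.full(npts, INF)
    aidx = np.full(npts, -1, dtype=np.int64)
    for p in range(npts):
        x, y, z = pts[p, 0], pts[p, 1], pts[p, 2]
        i0 = _cell_coord(x - max_radius, h, nc)
        i1 = _cell_coord(x + max_radius, h, nc)
        j0 = _cell_coord(y - max_radius, h, nc)
        j1 = _cell_coord(y + max_radius, h, nc)
        k0 = _cell_coord(z - max_radius, h, nc)
        k1 = _cell_coord(z + max_radius, h, nc)
        best = INF
        best_id = np.int64(-1)
        abest = INF
        abest_id = np.int64(-1)
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                for k in range(k0, k1 + 1):
                    c = (i * nc + j) * nc + k
                    for e in range(cell_start[c], cell_start[c + 1]):
                        s = entries[e]
                        dx = x - centers[s, 0]
                        dy = y - centers[s, 1]
                        dz = z - centers[s, 2]
                        sd = math.sqrt(dx * dx + dy * dy + dz * dz) - radii[s]
                        if sd > max_radius:
                            continue
                        if sd < best:
                            best = sd
                            best_id = s
                        if kinds[s] == 1 and sd < abest:
                            abest = sd
                            abest_id = s
        dist[p] = best
        idx[p] = best_id
        adist[p] = abest
        aidx[p] = abest_id
    return dist, idx, adist, aidx


# ---------------------------------------------------------------------------
# geometry generation
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _cleft_clearance(cx, cy, cz, clx, cly, clz, cl_r, cl_h):
    """Distance from a point to the solid cleft cylinder (0 inside)."""
    rho = math.sqrt((cx - clx) ** 2 + (cy - cly) ** 2)
    dr = rho - cl_r
    if dr < 0.0:
        dr = 0.0
    dz = abs(cz - clz) - cl_h
    if dz < 0.0:
        dz = 0.0
    return math.sqrt(dr * dr + dz * dz)


@njit(cache=True)
def place_spheres(pts, arena_edge, r_min, r_max, alpha_target,
                  clx, cly, clz, cl_r, cl_h, exclusion,
                  seed, max_spheres):
    """Rejection-sample overlapping spheres until the test-point ECS fraction
    drops to alpha_target; candidates violating the cleft exclusion zone are
    redrawn.  Returns (centers, radii, labels, n_spheres, n_uncovered, status).
    """
    np.random.seed(seed)
    npts = pts.shape[0]
    active = np.arange(npts)
    n_act = npts
    centers = np.empty((max_spheres, 3))
    radii = np.empty(max_spheres)
    labels = np.empty(max_spheres)
    n_sph = 0
    attempts = 0
    max_attempts = 100 * max_spheres + 1000
    status = PLACE_OK
    target_uncovered = alpha_target * npts
    while n_act > target_uncovered:
        if attempts >= max_attempts:
            status = PLACE_MAX_ATTEMPTS
            break
        attempts += 1
        cx = np.random.random() * arena_edge
        cy = np.random.random() * arena_edge
        cz = np.random.random() * arena_edge
        r = r_min + (r_max - r_min) * np.random.random()
        u = np.random.random()
        if _cleft_clearance(cx, cy, cz, clx, cly, clz, cl_r, cl_h) \
                < r + exclusion:
            continue
        if n_sph >= max_spheres:
            status = PLACE_MAX_SPHERES
            break
        centers[n_sph, 0] = cx
        centers[n_sph, 1] = cy
        centers[n_sph, 2] = cz
        radii[n_sph] = r
        labels[n_sph] = u
        n_sph += 1
        r2 = r * r
        j = 0
        while j < n_act:
            k = active[j]
            dx = pts[k, 0] - cx
            dy = pts[k, 1] - cy
            dz = pts[k, 2] - cz
            if dx * dx + dy * dy + dz * dz <= r2:
                n_act -= 1
                active[j] = active[n_act]
            else:
                j += 1
    return centers[:n_sph], radii[:n_sph], labels[:n_sph], n_sph, n_act, status


# ---------------------------------------------------------------------------
# motion: specular reflection walk
# ---------------------------------------------------------------------------

@njit(cache=True)
def _first_hit(px, py, pz, dx, dy, dz, cand, centers, radii,
               arena_edge, clx, cly, clz, cl_r, cl_h, reflect_cleft):
    """Earliest parametric intersection t in (eps, 1] of the segment
    p -> p+d with candidate spheres, the six arena walls and (optionally)
    the two cleft membrane disks.  Returns (t, nx, ny, nz, hit) with the
    surface normal pointing back toward the incoming side.
    """
    eps = 1e-12
    tmin = 2.0
    nx = 0.0
    ny = 0.0
    nz = 0.0
    hit = False

    a = dx * dx + dy * dy + dz * dz
    if a > 0.0:
        # spheres
        for q in range(cand.shape[0]):
            s = cand[q]
            mx = centers[s, 0] - px
            my = centers[s, 1] - py
            mz = centers[s, 2] - pz
            b = dx * mx + dy * my + dz * mz
            if b <= 0.0:
                continue
            c2 = mx * mx + my * my + mz * mz - radii[s] * radii[s]
            if c2 <= 0.0:
                continue  # already inside: handled by containment rejection
            disc = b * b - a * c2
            if disc <= 0.0:
                continue
            t = (b - math.sqrt(disc)) / a
            if eps < t <= 1.0 and t < tmin:
                hx = px + t * dx - centers[s, 0]
                hy = py + t * dy - centers[s, 1]
                hz = pz + t * dz - centers[s, 2]
                norm = math.sqrt(hx * hx + hy * hy + hz * hz)
                if norm > 0.0:
                    tmin = t
                    nx = hx / norm
                    ny = hy / norm
                    nz = hz / norm
                    hit = True

        # arena walls
        for k in range(3):
            if k == 0:
                p0 = px
                dk = dx
            elif k == 1:
                p0 = py
                dk = dy
            else:
                p0 = pz
                dk = dz
            if dk > 0.0:
                t = (arena_edge - p0) / dk
                sgn = -1.0
            elif dk < 0.0:
                t = -p0 / dk
                sgn = 1.0
            else:
                continue
            if eps < t <= 1.0 and t < tmin:
                tmin = t
                nx = 0.0
                ny = 0.0
                nz = 0.0
                if k == 0:
                    nx = sgn
                elif k == 1:
                    ny = sgn
                else:
                    nz = sgn
                hit = True

        # cleft membrane disks (two reflecting faces; rim open)
        if reflect_cleft and dz != 0.0:
            for face in range(2):
                zp = clz - cl_h if face == 0 else clz + cl_h
                t = (zp - pz) / dz
                if eps < t <= 1.0 and t < tmin:
                    hx = px + t * dx - clx
                    hy = py + t * dy - cly
                    if hx * hx + hy * hy <= cl_r * cl_r:
                        tmin = t
                        nx = 0.0
                        ny = 0.0
                        nz = -1.0 if dz > 0.0 else 1.0
                        hit = True
    return tmin, nx, ny, nz, hit


@njit(cache=True)
def _move(px, py, pz, dx, dy, dz, cand, centers, radii,
          arena_edge, clx, cly, clz, cl_r, cl_h, reflect_cleft,
          max_reflections):
    """Advance one particle by d with specular reflections.

    Returns (x, y, z, ok); ok=False means the step could not be completed
    (reflection budget exhausted or residual penetration) and must be
    rejected by the caller.
    """
    nudge = 1e-9
    x, y, z = px, py, pz
    vx, vy, vz = dx, dy, dz
    done = False
    for _ in range(max_reflections + 1):
        t, nx, ny, nz, hit = _first_hit(
            x, y, z, vx, vy, vz, cand, centers, radii,
            arena_edge, clx, cly, clz, cl_r, cl_h, reflect_cleft)
        if not hit:
            x += vx
            y += vy
            z += vz
            done = True
            break
        # advance to the contact point, nudged back along the normal
        x += t * vx + nudge * nx
        y += t * vy + nudge * ny
        z += t * vz + nudge * nz
        rx = (1.0 - t) * vx
        ry = (1.0 - t) * vy
        rz = (1.0 - t) * vz
        dot = rx * nx + ry * ny + rz * nz
        vx = rx - 2.0 * dot * nx
        vy = ry - 2.0 * dot * ny
        vz = rz - 2.0 * dot * nz
    if not done:
        return px, py, pz, False
    # verify: inside arena, outside every candidate sphere
    if x < 0.0 or x > arena_edge or y < 0.0 or y > arena_edge \
            or z < 0.0 or z > arena_edge:
        return px, py, pz, False
    for q in range(cand.shape[0]):
        s = cand[q]
        ddx = x - centers[s, 0]
        ddy = y - centers[s, 1]
        ddz = z - centers[s, 2]
        if ddx * ddx + ddy * ddy + ddz * ddz < radii[s] * radii[s] * (1.0 - 1e-12):
            return px, py, pz, False
    return x, y, z, True


@njit(cache=True)
def _segment_candidates(px, py, pz, qx, qy, qz, cell_start, entries,
                        h, nc, buf):
    """Collect sphere ids from every grid cell overlapping the segment AABB.

    Duplicates are possible and harmless; returns the fill count (capped at
    the buffer size).
    """
    x0 = min(px, qx)
    x1 = max(px, qx)
    y0 = min(py, qy)
    y1 = max(py, qy)
    z0 = min(pz, qz)
    z1 = max(pz, qz)
    i0 = _cell_coord(x0, h, nc)
    i1 = _cell_coord(x1, h, nc)
    j0 = _cell_coord(y0, h, nc)
    j1 = _cell_coord(y1, h, nc)
    k0 = _cell_coord(z0, h, nc)
    k1 = _cell_coord(z1, h, nc)
    n = 0
    cap = buf.shape[0]
    for i in range(i0, i1 + 1):
        for j in range(j0, j1 + 1):
            for k in range(k0, k1 + 1):
                c = (i * nc + j) * nc + k
                for e in range(cell_start[c], cell_start[c + 1]):
                    if n < cap:
                        buf[n] = entries[e]
                        n += 1
    return n


@njit(cache=True)
def resolve_motion_batch(old, proposed, centers, radii,
                         cell_start, entries, h, nc,
                         arena_edge, clx, cly, clz, cl_r, cl_h,
                         reflect_cleft, max_reflections):
    """Vectorised specular-reflection resolution for arbitrary segments."""
    n = old.shape[0]
    out = old.copy()
    rejected = np.zeros(n, dtype=np.bool_)
    buf = np.empty(65536, dtype=np.int64)
    for i in range(n):
        ncand = _segment_candidates(
            old[i, 0], old[i, 1], old[i, 2],
            proposed[i, 0], proposed[i, 1], proposed[i, 2],
            cell_start, entries, h, nc, buf)
        cand = buf[:ncand]
        x, y, z, ok = _move(
            old[i, 0], old[i, 1], old[i, 2],
            proposed[i, 0] - old[i, 0],
            proposed[i, 1] - old[i, 1],
            proposed[i, 2] - old[i, 2],
            cand, centers, radii,
            arena_edge, clx, cly, clz, cl_r, cl_h, reflect_cleft,
            max_reflections)
        out[i, 0] = x
        out[i, 1] = y
        out[i, 2] = z
        rejected[i] = not ok
    return out, rejected


# ---------------------------------------------------------------------------
# full simulation loop
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _disk_distance(x, y, z, clx, cly, clz, cl_r, zp):
    rho = math.sqrt((x - clx) ** 2 + (y - cly) ** 2)
    dz = z - zp
    if rho <= cl_r:
        return abs(dz)
    dr = rho - cl_r
    return math.sqrt(dr * dr + dz * dz)


@njit(cache=True, fastmath=True)
def run_sim(pos, state, clock, bound_time,
            centers, radii, kinds,
            cell_start, entries, h, nc, margin,
            astro_centers, astro_radii, astro_cell_start, astro_entries,
            arena_edge, clx, cly, clz, cl_r, cl_h, reflect_cleft,
            delta, dt, p_bind, shell, n_steps,
            snap_steps, record_every,
            seed, max_reflections, gaussian, gauss_sigma):
    """Fixed-step Brownian walk with reflecting obstacles and irreversible
    hazard binding within ``shell`` of astroglial surfaces.

    Mutates pos/state/clock/bound_time in place and returns snapshot copies
    plus the bound-count series.  Candidate spheres for each step are read
    from the grid cell of the step's start point; this is exhaustive because
    the grid margin exceeds step length + shell.

    A per-particle "safe step" budget skips collision and shell tests while
    the particle is provably farther than (shell + steps*delta) from every
    surface; this changes nothing observable, only the cost per step.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    nsnap = snap_steps.shape[0]
    snap_pos = np.empty((nsnap, n, 3))
    snap_state = np.empty((nsnap, n), dtype=np.int8)
    snap_clock = np.empty((nsnap, n))
    snap_bt = np.empty((nsnap, n))
    nrec = n_steps // record_every + 1
    bound_counts = np.zeros(nrec, dtype=np.int64)
    rec_times = np.empty(nrec)
    n_rejected = 0
    n_bound = 0
    for i in range(n):
        if state[i] == 1:
            n_bound += 1
    rec_times[0] = 0.0
    bound_counts[0] = n_bound

    si = 0
    # snapshot at step 0 if requested
    while si < nsnap and snap_steps[si] == 0:
        snap_pos[si] = pos
        snap_state[si] = state
        snap_clock[si] = clock
        snap_bt[si] = bound_time
        si += 1

    safe = np.zeros(n, dtype=np.int64)
    # gaussian steps have unbounded length: disable the safe-step shortcut
    use_safe = not gaussian

    for step in range(1, n_steps + 1):
        for i in range(n):
            if state[i] == 1:
                continue
            if gaussian:
                dx = np.random.normal() * gauss_sigma
                dy = np.random.normal() * gauss_sigma
                dz = np.random.normal() * gauss_sigma
            else:
                zc = 1.0 - 2.0 * np.random.random()
                phi = 2.0 * math.pi * np.random.random()
                sc = math.sqrt(max(0.0, 1.0 - zc * zc))
                dx = delta * sc * math.cos(phi)
                dy = delta * sc * math.sin(phi)
                dz = delta * zc
            if safe[i] > 0:
                pos[i, 0] += dx
                pos[i, 1] += dy
                pos[i, 2] += dz
                safe[i] -= 1
                clock[i] = 0.0
                continue
            px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
            c = _cell_id(px, py, pz, h, nc)
            cand = entries[cell_start[c]:cell_start[c + 1]]
            if use_safe:
                # certified clearance to every surface, capped at the margin
                dmin = margin
                for q in range(cand.shape[0]):
                    s = cand[q]
                    ddx = px - centers[s, 0]
                    ddy = py - centers[s, 1]
                    ddz = pz - centers[s, 2]
                    d2 = ddx * ddx + ddy * ddy + ddz * ddz
                    thr = dmin + radii[s]
                    if d2 < thr * thr:
                        sd = math.sqrt(d2) - radii[s]
                        if sd < dmin:
                            dmin = sd
                for k in range(3):
                    w = pos[i, k]
                    if w < dmin:
                        dmin = w
                    if arena_edge - w < dmin:
                        dmin = arena_edge - w
                if reflect_cleft:
                    d1 = _disk_distance(px, py, pz, clx, cly, clz, cl_r,
                                        clz - cl_h)
                    if d1 < dmin:
                        dmin = d1
                    d2 = _disk_distance(px, py, pz, clx, cly, clz, cl_r,
                                        clz + cl_h)
                    if d2 < dmin:
                        dmin = d2
                m = int((dmin - shell) / delta)
                if m >= 1:
                    pos[i, 0] = px + dx
                    pos[i, 1] = py + dy
                    pos[i, 2] = pz + dz
                    safe[i] = m - 1
                    clock[i] = 0.0
                    continue
            x, y, z, ok = _move(
                px, py, pz, dx, dy, dz,
                cand, centers, radii,
                arena_edge, clx, cly, clz, cl_r, cl_h, reflect_cleft,
                max_reflections)
            if ok:
                pos[i, 0] = x
                pos[i, 1] = y
                pos[i, 2] = z
            else:
                n_rejected += 1
            # binding hazard within the astroglial proximity shell
            ca = _cell_id(pos[i, 0], pos[i, 1], pos[i, 2], h, nc)
            in_shell = False
            for q in range(astro_cell_start[ca], astro_cell_start[ca + 1]):
                s = astro_entries[q]
                ddx = pos[i, 0] - astro_centers[s, 0]
                ddy = pos[i, 1] - astro_centers[s, 1]
                ddz = pos[i, 2] - astro_centers[s, 2]
                thr = shell + astro_radii[s]
                if ddx * ddx + ddy * ddy + ddz * ddz <= thr * thr:
                    in_shell = True
                    break
            if in_shell:
                clock[i] += dt
                if np.random.random() < p_bind:
                    state[i] = 1
                    bound_time[i] = step * dt
                    n_bound += 1
            else:
                clock[i] = 0.0
        if step % record_every == 0:
            r = step // record_every
            bound_counts[r] = n_bound
            rec_times[r] = step * dt
        while si < nsnap and snap_steps[si] == step:
            snap_pos[si] = pos
            snap_state[si] = state
            snap_clock[si] = clock
            snap_bt[si] = bound_time
            si += 1
    return (snap_pos, snap_state, snap_clock, snap_bt,
            bound_counts, rec_times, n_rejected)
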