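"""Numba kernels for polygonal-chain topology: KMT reduction and crossings.

All geometry is done on raw (N, 3) float64 arrays.  The KMT pass is
conservative: any doubtful triangle/segment test blocks vertex removal, so
the worst case is an under-reduced (never topology-changed) chain.
"""

import numpy as np
from numba import njit

_EPS = 1e-9


@njit(cache=True)
def _seg_triangle_hit(p0, p1, a, b, c, sx, sy, sz):
    """Does segment p0-p1 hit triangle (a,b,c)?

    ``(sx, sy, sz)`` is a triangle corner the segment legitimately touches
    (a shared polygon vertex); an intersection within 1e-7 of it does not
    count.  Pass a far-away point when no corner is shared.  Tolerances are
    inclusive: in doubt, report a hit.
    """
    d = p1 - p0
    e1 = b - a
    e2 = c - a
    h = np.cross(d, e2)
    det = np.dot(e1, h)
    if abs(det) < 1e-12:
        # segment parallel to the triangle plane
        n = np.cross(e1, e2)
        nn = np.dot(n, n)
        if nn < 1e-18:
            return False  # degenerate triangle spans no area
        inv = 1.0 / np.sqrt(nn)
        if abs(np.dot(p0 - a, n)) * inv > 1e-7 and abs(np.dot(p1 - a, n)) * inv > 1e-7:
            return False
        # coplanar: project onto the triangle plane and test in 2D.
        # basis in the plane
        u = e1 / np.sqrt(np.dot(e1, e1))
        w = np.cross(n, u)
        w = w / np.sqrt(np.dot(w, w))
        ax, ay = 0.0, 0.0
        bx2, by2 = np.dot(e1, u), np.dot(e1, w)
        cx2, cy2 = np.dot(e2, u), np.dot(e2, w)
        p0x, p0y = np.dot(p0 - a, u), np.dot(p0 - a, w)
        p1x, p1y = np.dot(p1 - a, u), np.dot(p1 - a, w)
        # endpoint inside the triangle (a shared corner does not count)?
        for (px, py, p3) in ((p0x, p0y, p0), (p1x, p1y, p1)):
            ddx = p3[0] - sx
            ddy = p3[1] - sy
            ddz = p3[2] - sz
            if ddx * ddx + ddy * ddy + ddz * ddz < 1e-14:
                continue
            d1 = (bx2 - ax) * (py - ay) - (by2 - ay) * (px - ax)
            d2 = (cx2 - bx2) * (py - by2) - (cy2 - by2) * (px - bx2)
            d3 = (ax - cx2) * (py - cy2) - (ay - cy2) * (px - cx2)
            neg = (d1 < -1e-9) or (d2 < -1e-9) or (d3 < -1e-9)
            pos = (d1 > 1e-9) or (d2 > 1e-9) or (d3 > 1e-9)
            if not (neg and pos):
                return True
        # proper crossing with any triangle edge (excluding the shared corner)
        tex = (ax, bx2, cx2)
        tey = (ay, by2, cy2)
        for e in range(3):
            qx, qy = tex[e], tey[e]
            rx, ry = tex[(e + 1) % 3] - qx, tey[(e + 1) % 3] - qy
            sx2, sy2 = p1x - p0x, p1y - p0y
            den = rx * sy2 - ry * sx2
            if abs(den) < 1e-14:
                continue
            t2 = ((p0x - qx) * sy2 - (p0y - qy) * sx2) / den
            u2 = ((p0x - qx) * ry - (p0y - qy) * rx) / den
            if -1e-9 < t2 < 1 + 1e-9 and 1e-7 < u2 < 1 - 1e-7:
                # exclude hits at the allowed shared corner
                hpx = a + (p0x + u2 * sx2) * u + (p0y + u2 * sy2) * w
                ddx = hpx[0] - sx
                ddy = hpx[1] - sy
                ddz = hpx[2] - sz
                if ddx * ddx + ddy * ddy + ddz * ddz >= 1e-14:
                    return True
        return False
    f = 1.0 / det
    s = p0 - a
    u = f * np.dot(s, h)
    if u < -_EPS or u > 1.0 + _EPS:
        return False
    q = np.cross(s, e1)
    v = f * np.dot(d, q)
    if v < -_EPS or u + v > 1.0 + _EPS:
        return False
    t = f * np.dot(e2, q)
    if t < -_EPS or t > 1.0 + _EPS:
        return False
    hx = a[0] + u * e1[0] + v * e2[0] - sx
    hy = a[1] + u * e1[1] + v * e2[1] - sy
    hz = a[2] + u * e1[2] + v * e2[2] - sz
    if hx * hx + hy * hy + hz * hz < 1e-14:
        return False
    return True


@njit(cache=True)
def _removable(pts, v, closed):
    """Can vertex v of the (compacted) polygon be KMT-eliminated?"""
    m = pts.shape[0]
    p = (v - 1) % m
    nx = (v + 1) % m
    a = pts[p]
    b = pts[v]
    c = pts[nx]
    n_edges = m if closed else m - 1
    for e in range(n_edges):
        e2 = (e + 1) % m
        if e == p or e == v:  # the two triangle edges themselves
            continue
        # a neighbouring edge may share corner a (vertex p) or c (vertex nx)
        if e2 == p:
            sx, sy, sz = a[0], a[1], a[2]
        elif e == nx:
            sx, sy, sz = c[0], c[1], c[2]
        else:
            sx, sy, sz = 1e12, 1e12, 1e12
        if _seg_triangle_hit(pts[e], pts[e2], a, b, c, sx, sy, sz):
            return False
    return True


@njit(cache=True)
def kmt_reduce_kernel(coords, closed):
    """Iterated KMT triangle elimination until no vertex can be removed."""
    pts = coords.copy()
    min_pts = 3 if closed else 2
    changed = True
    while changed and pts.shape[0] > min_pts:
        changed = False
        v = 0
        while v < pts.shape[0]:
            m = pts.shape[0]
            if m <= min_pts:
                break
            if not closed and (v == 0 or v == m - 1):
                v += 1
                continue
            if _removable(pts, v, closed):
                out = np.empty((m - 1, 3))
                out[:v] = pts[:v]
                out[v:] = pts[v + 1:]
                pts = out
                changed = True
            else:
                v += 1
    return pts


@njit(cache=True)
def find_crossings(pts):
    """Projected crossings of a closed polygon (projection along +z).

    Returns an (n, 3) array with rows ``(under_pos, over_pos, sign)`` where
    positions are ``segment_index + parameter`` along the polygon, plus a
    degeneracy flag.  Sign convention matches the Gauss-integral writhe:
    the sum of signs is the directional writhe of the projection.
    """
    m = pts.shape[0]
    max_cross = 6 * m + 16
    out = np.zeros((max_cross, 3))
    n = 0
    degenerate = False
    for i in range(m):
        i2 = (i + 1) % m
        for j in range(i + 2, m):
            j2 = (j + 1) % m
            if j2 == i:
                continue
            p = pts[i]
            r0 = pts[i2][0] - p[0]
            r1 = pts[i2][1] - p[1]
            q = pts[j]
            s0 = pts[j2][0] - q[0]
            s1 = pts[j2][1] - q[1]
            denom = r0 * s1 - r1 * s0
            if abs(denom) < 1e-12:
                continue
            dx = q[0] - p[0]
            dy = q[1] - p[1]
            t = (dx * s1 - dy * s0) / denom
            u = (dx * r1 - dy * r0) / denom
            if t <= 0.0 or t >= 1.0 or u <= 0.0 or u >= 1.0:
                continue
            if t < 1e-7 or t > 1 - 1e-7 or u < 1e-7 or u > 1 - 1e-7:
                degenerate = True
            zi = p[2] + t * (pts[i2][2] - p[2])
            zj = q[2] + u * (pts[j2][2] - q[2])
            if abs(zi - zj) < 1e-7:
                degenerate = True
            if n >= max_cross:
                return out[:n], True
            if zi > zj:
                under_pos = j + u
                over_pos = i + t
                o0, o1 = r0, r1
                u0, u1 = s0, s1
            else:
                under_pos = i + t
                over_pos = j + u
                o0, o1 = s0, s1
                u0, u1 = r0, r1
            out[n, 0] = under_pos
            out[n, 1] = over_pos
            out[n, 2] = -1.0 if o0 * u1 - o1 * u0 > 0 else 1.0
            n += 1
    return out[:n], degenerate
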