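import numpy as np
import pytest

from pinclust.datatypes import PlaneImage


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def random_plane(rng):
    """A seeded 16x16 plane with continuous values (no ties)."""
    return PlaneImage(data=rng.normal(10.0, 2.0, size=(16, 16)), pixel_size_um=(0.089, 0.089))


# ---------------------------------------------------------------------------
# brute-force oracles, independent of the implementation under test
# ---------------------------------------------------------------------------

def brute_local_maxima(a):
    """Scan every interior 3x3 neighbourhood with explicit loops."""
    peaks = []
    for r in range(1, a.shape[0] - 1):
        for c in range(1, a.shape[1] - 1):
            vals = [
                a[r + dr, c + dc]
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if not (dr == 0 and dc == 0)
            ]
            if all(a[r, c] > v for v in vals):
                peaks.append((r, c))
    return peaks


def brute_window_size(a, peak, n_cap):
    """Grow windows by explicit enumeration; return (n_max, capped)."""
    r, c = peak
    n_max, capped = 1, False
    for n in range(2, n_cap + 1):
        if r - n < 0 or c - n < 0 or r + n >= a.shape[0] or c + n >= a.shape[1]:
            capped = True
            break
        brighter = False
        for rr in range(r - n, r + n + 1):
            for cc in range(c - n, c + n + 1):
                if a[rr, cc] > a[r, c]:
                    brighter = True
        if brighter:
            break
        n_max = n
    else:
        capped = True
    return n_max, capped


def brute_linkage_partition(xy, dmax):
    """All-pairs union-find over the <= dmax graph."""
    n = len(xy)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = ((xy[i][0] - xy[j][0]) ** 2 + (xy[i][1] - xy[j][1]) ** 2) ** 0.5
            if d <= dmax:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(m) for m in comps.values()}
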