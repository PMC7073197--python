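import numpy as np
import pytest


@pytest.fixture
def square_chain():
    """Rasterized axis-aligned square boundary, side 20 px, closed chain."""
    pts = []
    s = 20
    for i in range(s):
        pts.append((0, i))
    for i in range(s):
        pts.append((i, s))
    for i in range(s):
        pts.append((s, s - i))
    for i in range(s):
        pts.append((s - i, 0))
    return np.array(pts, dtype=float)


@pytest.fixture
def circle_chain():
    """Boundary chain of a rasterized disk of radius ~30 px."""
    from skimage.draw import disk
    from skimage.measure import find_contours

    img = np.zeros((80, 80))
    rr, cc = disk((40, 40), 30.5)
    img[rr, cc] = 1
    chain = max(find_contours(img, 0.5), key=len)
    if np.allclose(chain[0], chain[-1]):
        chain = chain[:-1]
    return chain


def ellipse_points(center=(3.0, 4.0), a=10.0, b=5.0, theta_deg=30.0, n=12):
    """Exact (row, col) samples on an ellipse (center given as (x, y))."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    th = np.deg2rad(theta_deg)
    x = center[0] + a * np.cos(th) * np.cos(t) - b * np.sin(th) * np.sin(t)
    y = center[1] + a * np.sin(th) * np.cos(t) + b * np.cos(th) * np.sin(t)
    return np.column_stack([y, x])


def sphere_on_plane_spec(radius_um=3.0, plane_z_um=5.0, offset_um=0.0, seed=1):
    """Invasion phantom: one sphere whose centre sits ``offset_um`` above the
    upper membrane plane."""
    from mechanoinvade.phantoms import EllipsoidCell, InvasionPhantomSpec

    cz = plane_z_um + offset_um
    nz = int(np.ceil((cz + radius_um + 1.0) / 0.2)) + 2
    return InvasionPhantomSpec(
        cells=(EllipsoidCell((7.2, 7.2, cz), (radius_um,) * 3),),
        membrane_z_upper_um=plane_z_um,
        membrane_z_lower_um=plane_z_um - 0.8,
        shape_zyx=(nz, 96, 96),
        seed=seed,
    )
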