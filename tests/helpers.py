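"""Independent closed-form oracles used by several test modules."""

import numpy as np


def homo_sphere_closed(sigma, R, r0, m, e):
    """Surface potential of a dipole in a homogeneous sphere (infinity ref).

    Closed form obtained by summing the boundary-corrected Legendre series
    with generating functions; independent of the package's per-degree
    series implementation.
    """
    r0 = np.asarray(r0, float)
    m = np.asarray(m, float)
    e = np.asarray(e, float)
    b = np.linalg.norm(r0)
    rhat = r0 / b
    x = float(e @ rhat)
    d_vec = R * e - r0
    d = np.linalg.norm(d_vec)
    m_r = float(m @ rhat)
    t = b / R
    delta = d / R
    term1 = 2.0 * float(m @ d_vec) / d**3
    term2 = m_r * (1.0 / (b * d) - 1.0 / (b * R))
    term3 = (
        float(m @ (e - x * rhat))
        * (delta + 1.0)
        / (R**2 * delta * (1.0 - t * x + delta))
    )
    return (term1 + term2 + term3) / (4.0 * np.pi * sigma)
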