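"""Deterministic bivariate standard-normal probabilities.

The polychoric likelihood needs Phi2(h, k, rho) — the CDF of a standard
bivariate normal — evaluated many thousands of times per correlation
matrix, reproducibly to high absolute accuracy.  We integrate Owen's
single-integral representation

    Phi2(h, k, rho) = Phi(h) Phi(k)
        + (1/2pi) * int_0^{asin(rho)} exp(-(h^2 + k^2 - 2 h k sin t)
                                          / (2 cos^2 t)) dt

with a fixed 64-node Gauss–Legendre rule.  The arcsine substitution
removes the 1/sqrt(1-r^2) endpoint singularity of the naive form, so the
integrand is smooth and the fixed rule is accurate to well below 1e-10
for |rho| <= 0.999 (checked against scipy's multivariate normal CDF in
the test suite).  Everything is vectorised over (h, k) arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

# Gauss-Legendre nodes/weights on [0, 1]; fixed at import => bitwise
# reproducible across runs and platforms that share an IEEE libm.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W

_RHO_LIMIT = 0.999999


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k) for standard bivariate normal with correlation rho.

    ``h`` and ``k`` broadcast; +/-inf limits are handled exactly.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = float(np.clip(rho, -_RHO_LIMIT, _RHO_LIMIT))

    hb, kb = np.broadcast_arrays(h, k)
    out = ndtr(hb) * ndtr(kb)
    if rho != 0.0:
        alpha = np.arcsin(rho)
        t = alpha * _GL_X  # (64,)
        sint = np.sin(t)
        cos2t = np.cos(t) ** 2
        hf = hb[..., None]
        kf = kb[..., None]
        # exp underflows harmlessly to 0 for extreme limits; silence it
        with np.errstate(over="ignore", invalid="ignore"):
            num = hf * hf + kf * kf - 2.0 * hf * kf * sint
            integrand = np.exp(-num / (2.0 * cos2t))
        integrand = np.where(np.isfinite(integrand), integrand, 0.0)
        out = out + (alpha / (2.0 * np.pi)) * (integrand * _GL_W).sum(axis=-1)
    out = np.clip(out, 0.0, 1.0)
    return out if out.shape else float(out)


def bvn_rectangle(lo1, hi1, lo2, hi2, rho: float):
    """P(lo1 < X <= hi1, lo2 < Y <= hi2); limits may be +/-inf."""
    p = (
        bvn_cdf(hi1, hi2, rho)
        - bvn_cdf(lo1, hi2, rho)
        - bvn_cdf(hi1, lo2, rho)
        + bvn_cdf(lo1, lo2, rho)
    )
    return np.clip(p, 0.0, 1.0)
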