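"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: the Landau tail is
integrated from the explicit density integral with mpmath's adaptive
quadrature at elevated precision, and the conditional FDR is counted with a
literal O(N^2) double loop.
"""

import mpmath as mp
import numpy as np


def landau_sf_quadrature(x: float, loc: float = 0.0, scale: float = 1.0) -> float:
    """Upper tail of the Landau distribution by direct numerical quadrature.

    Integrates the classic density integral
    ``f(u) = (1/pi) * int_0^inf exp(-t ln t - u t) sin(pi t) dt`` after the
    affine change of variable that maps the stable-law (loc, scale)
    parameterization onto it; the tail integral over u is folded into the
    quadrature analytically (``int_x^inf e^{-ut} du = e^{-xt}/t``).
    Accurate to far better than 1e-8 for (x - loc)/scale >= -1.
    """
    with mp.workdps(40):
        z = (mp.mpf(x) - mp.mpf(loc)) / mp.mpf(scale)
        u = mp.pi / 2 * z + mp.log(mp.pi / 2)

        def integrand(t):
            return mp.e ** (-t * mp.log(t) - u * t) * mp.sin(mp.pi * t) / (mp.pi * t)

        val = mp.quad(integrand, [0, 1, 10, mp.inf])
    return float(val)


def brute_force_cfdr(p_principal, p_conditional):
    """Literal double-loop plug-in conditional FDR estimate."""
    pi = list(map(float, p_principal))
    pj = list(map(float, p_conditional))
    n = len(pi)
    out = []
    for g in range(n):
        num = 0
        den = 0
        for h in range(n):
            if pj[h] <= pj[g]:
                num += 1
                if pi[h] <= pi[g]:
                    den += 1
        out.append(min(1.0, pi[g] * num / den))
    return np.array(out)
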