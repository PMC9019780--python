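"""Independent semi-analytic oracles used by the test suite.

These deliberately avoid the package's FEM machinery: the thick-sphere
inflation relation is evaluated by direct quadrature of the classical
incompressible shell equilibrium integral.
"""

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq


def sphere_inflation_pressure(a_def, a_ref, b_ref, mat_a, mat_b):
    """Cavity pressure (kPa) inflating an incompressible isotropic shell.

    Shell with reference inner/outer radii ``a_ref``/``b_ref`` (mm) of a
    one-term exponential material W = a/(2b) (exp(b (I1-3)) - 1), deformed
    inner radius ``a_def``.  Incompressibility maps R -> r with
    r^3 = R^3 + a_def^3 - a_ref^3; equilibrium gives
    p = int_{a'}^{b'} 2 (sigma_theta - sigma_r) / r dr with
    sigma_theta - sigma_r = 2 W'(I1) (lambda^2 - lambda^-4), lambda = r/R.
    """
    shift = a_def ** 3 - a_ref ** 3
    b_def = (b_ref ** 3 + shift) ** (1.0 / 3.0)

    def integrand(r):
        R = (r ** 3 - shift) ** (1.0 / 3.0)
        lam = r / R
        I1 = 2.0 * lam ** 2 + lam ** -4
        Wp = 0.5 * mat_a * np.exp(mat_b * (I1 - 3.0))
        return 2.0 * (2.0 * Wp * (lam ** 2 - lam ** -4)) / r

    val, _ = quad(integrand, a_def, b_def, limit=200)
    return val


def sphere_inflation_radius(p, a_ref, b_ref, mat_a, mat_b):
    """Deformed inner radius at cavity pressure ``p`` (inverse of the above)."""
    return brentq(lambda a: sphere_inflation_pressure(a, a_ref, b_ref,
                                                      mat_a, mat_b) - p,
                  a_ref + 1e-9, 2.5 * a_ref, xtol=1e-10)
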