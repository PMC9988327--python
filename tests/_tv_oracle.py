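"""Independent reference solver for the TV proximal problem (tests only)."""

import numpy as np
from scipy.optimize import minimize

from sidedmri.tv import _weighted_grad


def smoothed_tv_oracle(x, weights, strength):
    """Prox solve independent of the dual algorithm under test:
    L-BFGS on eps-smoothed TV with eps-continuation and warm starts."""
    g = weights.as_tuple()
    uf = x.ravel().copy()
    for eps in (1e-4, 1e-6, 1e-8, 1e-10, 1e-12, 1e-14):
        def f(u_flat):
            u = u_flat.reshape(x.shape)
            grads = _weighted_grad(u, g)
            mag = np.sqrt(sum(gr**2 for gr in grads) + eps)
            return 0.5 * ((u - x) ** 2).sum() + strength * mag.sum()

        uf = minimize(f, uf, method="L-BFGS-B",
                      options=dict(maxiter=20000, ftol=1e-16, gtol=1e-12)).x
    return uf.reshape(x.shape)
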