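import numpy as np
import pytest

import txtlkit as tk


@pytest.fixture(scope="session")
def bestfit() -> tk.TXTLParameters:
    """Bundled best-fit constants, plasmid at 0 nM."""
    return tk.best_fit_parameters()


def bisect_root(f, lo, hi, tol=1e-12, maxit=200):
    """Plain bisection, used as an independent oracle for the conservation solves."""
    flo = f(lo)
    assert flo * f(hi) <= 0, "oracle root not bracketed"
    for _ in range(maxit):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if hi - lo < tol:
            return mid
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


def rnap_balance_residual(E0, p):
    """Conservation residual for core RNA polymerase, written independently."""
    e70 = E0 * p.S70_total / (p.K70 + E0)
    em = (
        E0 * p.S70_total * p.P70
        / (p.KM_70 * (p.K70 + E0) + E0 * p.S70_total)
        * (1.0 + p.kcat_m * p.Lm / p.Cm)
    )
    return E0 + e70 + em - p.E_total


def ribosome_balance_residual(R0, m, p):
    return R0 + R0 * m / (p.KM_R + R0) * (1.0 + p.kcat_p * p.Lm / p.Cp) - p.R_total
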