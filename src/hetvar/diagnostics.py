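"""Geweke convergence diagnostic for MCMC chains.

Compares the mean of an early window (first 10% by default) against a late
window (last 50%), standardized by spectral-density-at-zero estimates of
each window's variance:

    z = (m_first - m_last) / sqrt(S_first(0)/n_first + S_last(0)/n_last)

z is asymptotically standard normal for a stationary chain; the two-sided
p-value is the chain-validity criterion (converged iff p > alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr


@dataclass
class GewekeResult:
    z: float
    p: float
    frac_first: float
    frac_last: float
    degenerate: bool = False

    def converged(self, alpha: float = 0.05) -> bool:
        return self.p > alpha


def spectral_density_zero(x: np.ndarray, method: str = "spectral") -> float:
    """Estimate S(0) of a (mean-removed) window.

    ``spectral``: mean of the periodogram over the lowest ceil(sqrt(n))
    nonzero frequencies.  ``batch-means``: variance of ceil(sqrt(n)) batch
    means scaled by the batch length.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    xc = x - x.mean()
    if method == "spectral":
        per = np.abs(np.fft.rfft(xc)) ** 2 / n
        m = min(int(np.ceil(np.sqrt(n))), len(per) - 1)
        if m < 1:
            return 0.0
        return float(per[1 : m + 1].mean())
    if method == "batch-means":
        nb = int(np.ceil(np.sqrt(n)))
        blen = n // nb
        if blen < 1:
            return float(xc.var())
        means = xc[: nb * blen].reshape(nb, blen).mean(axis=1)
        return float(means.var(ddof=1) * blen)
    raise ValueError(f"unknown method {method!r}")


def geweke(
    chain,
    frac_first: float = 0.1,
    frac_last: float = 0.5,
    method: str = "spectral",
) -> GewekeResult:
    """Geweke z and two-sided p for one monitored chain.

    Windows must not overlap (frac_first + frac_last <= 1).  A chain whose
    two windows are both constant is reported as converged-degenerate with
    p = 1 rather than NaN.
    """
    x = np.asarray(chain, dtype=float)
    n = len(x)
    if n < 100:
        raise ValueError(f"chain too short for the diagnostic: {n} < 100")
    if not (0 < frac_first < 1 and 0 < frac_last < 1):
        raise ValueError("window fractions must lie in (0, 1)")
    if frac_first + frac_last > 1:
        raise ValueError("windows overlap: frac_first + frac_last > 1")
    n1 = int(np.floor(frac_first * n))
    n2 = int(np.floor(frac_last * n))
    first, last = x[:n1], x[n - n2 :]
    s1 = spectral_density_zero(first, method)
    s2 = spectral_density_zero(last, method)
    denom2 = s1 / n1 + s2 / n2
    dmean = float(first.mean() - last.mean())
    if denom2 <= 0:
        if abs(dmean) <= 1e-12 * max(1.0, abs(float(x.mean()))):
            return GewekeResult(z=0.0, p=1.0, frac_first=frac_first, frac_last=frac_last, degenerate=True)
        return GewekeResult(z=np.inf, p=0.0, frac_first=frac_first, frac_last=frac_last, degenerate=True)
    z = dmean / np.sqrt(denom2)
    p = float(2.0 * (1.0 - ndtr(abs(z))))
    return GewekeResult(z=float(z), p=p, frac_first=frac_first, frac_last=frac_last)


def diagnose_chains(chains: dict, alpha: float = 0.05, **kwargs) -> dict:
    """Geweke per monitored parameter; returns the diagnostics.json payload."""
    out = {}
    for name, chain in chains.items():
        res = geweke(chain, **kwargs)
        out[name] = {
            "z": res.z,
            "p": res.p,
            "converged": bool(res.converged(alpha)),
            "degenerate": res.degenerate,
        }
    return out
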