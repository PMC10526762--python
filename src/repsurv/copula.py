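"""Clayton copula machinery for dependent-censoring survival analysis.

The Clayton family is the working model throughout: it is Archimedean with
generator

    phi_alpha(s) = (s**(-alpha) - 1) / alpha        (alpha > 0)
    phi_0(s)     = -log(s)                          (independence limit)

and Kendall's tau = alpha / (alpha + 2), so the dependence between the
latent death time T and censoring time U is a single nonnegative number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ClaytonCopula", "clayton_tools"]


@dataclass(frozen=True)
class ClaytonCopula:
    """Clayton copula with dependence parameter ``alpha`` >= 0.

    ``alpha = 0`` is the independence copula (by continuity the generator
    becomes ``-log``); ``alpha -> inf`` approaches comonotonicity.
    """

    alpha: float = 0.0

    # below this the copula is numerically indistinguishable from
    # independence and the -log generator is used directly
    _ALPHA_TINY = 1e-12

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha < 0:
            raise ValueError(f"Clayton alpha must be finite and >= 0, got {self.alpha}")

    @property
    def _independent(self) -> bool:
        return self.alpha < self._ALPHA_TINY

    # ------------------------------------------------------------------
    @property
    def kendall_tau(self) -> float:
        """Closed-form Kendall's tau, alpha / (alpha + 2)."""
        return self.alpha / (self.alpha + 2.0)

    def generator(self, s):
        """Archimedean generator phi(s), decreasing with phi(1) = 0."""
        s = np.asarray(s, dtype=float)
        with np.errstate(divide="ignore"):
            if self._independent:
                return -np.log(s)
            # (s^-alpha - 1)/alpha via expm1 for small-alpha stability
            return np.expm1(-self.alpha * np.log(s)) / self.alpha

    def inverse_generator(self, t):
        """phi^{-1}(t); maps [0, inf] back onto (0, 1]."""
        t = np.asarray(t, dtype=float)
        if self._independent:
            return np.exp(-t)
        with np.errstate(over="ignore"):
            out = np.exp(-np.log1p(self.alpha * t) / self.alpha)
        # phi(0) = inf for alpha > 0; map inf -> 0 rather than nan
        return np.where(np.isinf(t), 0.0, out)

    def cdf(self, u, v):
        """Joint survival-scale copula C(u, v)."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        return self.inverse_generator(self.generator(u) + self.generator(v))

    # ------------------------------------------------------------------
    def conditional_sample(self, u, w):
        """Second coordinate given the first, by conditional inversion.

        ``u`` is the first uniform coordinate, ``w`` an independent U(0,1);
        returns v such that (u, v) ~ Clayton(alpha).
        """
        u = np.asarray(u, dtype=float)
        w = np.asarray(w, dtype=float)
        a = self.alpha
        if self._independent:
            return w
        # v = [u^-a (w^(-a/(1+a)) - 1) + 1]^(-1/a), in log1p/expm1 form so
        # the independence limit is approached smoothly
        t = np.exp(-a * np.log(u)) * np.expm1(-a / (1.0 + a) * np.log(w))
        return np.exp(-np.log1p(t) / a)

    def sample(self, n: int, rng: np.random.Generator):
        """Draw ``n`` pairs (u, v) from the copula."""
        u = rng.uniform(size=n)
        w = rng.uniform(size=n)
        return u, self.conditional_sample(u, w)


def clayton_tools(alpha: float) -> ClaytonCopula:
    """Bundle generator, inverse, conditional sampler and Kendall tau."""
    return ClaytonCopula(alpha)
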