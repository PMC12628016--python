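"""Single-mediator mediation with a percentile bootstrap.

Quantifies how much of the effect of a predictor x (e.g. positive-network
connectivity strength) on an outcome y (a creativity score) flows through a
mediator m (a search-pattern count):

* path a — regression of m on x;
* path b — regression of y on m, controlling for x;
* path c — total effect of x on y;
* path c' — direct effect of x on y, controlling for m;
* indirect effect = a * b, with c = c' + a*b holding exactly for nested OLS.

All variables are z-scored once on the full sample; the bootstrap resamples
the standardized rows with replacement and the confidence interval is the
percentile interval of the resampled indirect effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError, NumericError

__all__ = ["Mediation", "MediationResults", "indirect_effect"]


def indirect_effect(a: float, b: float) -> float:
    """Indirect (mediated) effect: the product of paths a and b."""
    return a * b


def _zscore(v: np.ndarray, name: str) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise DataError(f"variable {name!r} is constant")
    return (v - v.mean()) / sd


@dataclass
class MediationResults:
    """Point estimates, path p-values, and the bootstrap interval."""

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    p_a: float
    p_b: float
    p_c: float
    p_c_prime: float
    n: int
    n_boot: int = 0
    ci_low: float = np.nan
    ci_high: float = np.nan
    ci_level: float = 0.95
    boot_indirect: np.ndarray | None = None

    @property
    def significant(self) -> bool:
        """True when the bootstrap CI excludes zero."""
        if np.isnan(self.ci_low):
            return False
        return not (self.ci_low <= 0.0 <= self.ci_high)

    def summary(self) -> str:
        def star(p):
            return "***" if p < .001 else "**" if p < .01 else "*" if p < .05 else ""

        lines = [
            f"Single-mediator model (n = {self.n}, standardized paths)",
            "",
            f"            a = {self.a: .3f}{star(self.p_a)}        b = {self.b: .3f}{star(self.p_b)}",
            "        x ----------> m ----------> y",
            f"        x ------------------------> y   c  = {self.c: .3f}{star(self.p_c)}",
            f"                                        c' = {self.c_prime: .3f}{star(self.p_c_prime)}",
            "",
            f"  indirect effect a*b = {self.indirect: .4f}",
        ]
        if self.n_boot:
            lines.append(
                f"  {int(self.ci_level * 100)}% percentile bootstrap CI "
                f"[{self.ci_low:.4f}, {self.ci_high:.4f}] "
                f"({self.n_boot} resamples) -> "
                f"{'significant' if self.significant else 'not significant'}")
        lines.append("  *p<.05 **p<.01 ***p<.001 (per-path OLS t-tests)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c, "c_prime": self.c_prime,
            "indirect": self.indirect, "p_a": self.p_a, "p_b": self.p_b,
            "p_c": self.p_c, "p_c_prime": self.p_c_prime, "n": self.n,
            "n_boot": self.n_boot, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "ci_level": self.ci_level,
            "significant": self.significant,
        }


class Mediation:
    """Single-mediator model linking a predictor, a mediator, and an outcome.

    Parameters are per-subject vectors; use :meth:`from_dataframe` to build
    from a merged table.  ``fit`` computes standardized path coefficients
    and, when ``n_boot > 0``, a percentile bootstrap CI for the indirect
    effect.
    """

    def __init__(self, x, m, y):
        self.x = np.asarray(x, dtype=float)
        self.m = np.asarray(m, dtype=float)
        self.y = np.asarray(y, dtype=float)
        n = len(self.x)
        if len(self.m) != n or len(self.y) != n:
            raise DataError("x, m, y must have equal length")
        if n < 4:
            raise DataError("mediation needs >= 4 subjects")
        self.n = n

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, x: str, m: str, y: str) -> "Mediation":
        sub = df[[x, m, y]].dropna()
        return cls(sub[x].to_numpy(), sub[m].to_numpy(), sub[y].to_numpy())

    def fit(self, n_boot: int = 5000, seed: int | None = None,
            ci_level: float = 0.95) -> MediationResults:
        x = _zscore(self.x, "x")
        m = _zscore(self.m, "m")
        y = _zscore(self.y, "y")

        fit_a = sm.OLS(m, sm.add_constant(x)).fit()
        fit_by = sm.OLS(y, sm.add_constant(np.column_stack([m, x]))).fit()
        fit_c = sm.OLS(y, sm.add_constant(x)).fit()
        a = float(fit_a.params[1])
        b = float(fit_by.params[1])
        c_prime = float(fit_by.params[2])
        c = float(fit_c.params[1])
        res = MediationResults(
            a=a, b=b, c=c, c_prime=c_prime, indirect=indirect_effect(a, b),
            p_a=float(fit_a.pvalues[1]), p_b=float(fit_by.pvalues[1]),
            p_c=float(fit_c.pvalues[1]), p_c_prime=float(fit_by.pvalues[2]),
            n=self.n, ci_level=ci_level)
        if n_boot:
            if n_boot < 100:
                raise ValueError("n_boot must be >= 100 (or 0 to skip)")
            if self.n < 10:
                raise DataError("bootstrap needs >= 10 subjects")
            boot = self._bootstrap_indirect(x, m, y, n_boot, seed)
            lo = 100 * (1 - ci_level) / 2
            res.n_boot = n_boot
            res.ci_low = float(np.percentile(boot, lo))
            res.ci_high = float(np.percentile(boot, 100 - lo))
            res.boot_indirect = boot
        return res

    @staticmethod
    def _bootstrap_indirect(x, m, y, n_boot, seed, chunk: int = 2000) -> np.ndarray:
        """Vectorized percentile bootstrap of the indirect effect.

        Resamples rows of the standardized data; a resample in which any
        variable is constant is redrawn (at most 10 rounds).
        """
        rng = np.random.default_rng(seed)
        n = len(x)
        out = np.empty(n_boot)
        done = 0
        while done < n_boot:
            k = min(chunk, n_boot - done)
            idx = rng.integers(0, n, size=(k, n))
            for _ in range(10):
                xb, mb, yb = x[idx], m[idx], y[idx]
                mx, mm, my = xb.mean(1), mb.mean(1), yb.mean(1)
                s_xx = (xb * xb).mean(1) - mx * mx
                s_mm = (mb * mb).mean(1) - mm * mm
                s_xm = (xb * mb).mean(1) - mx * mm
                s_xy = (xb * yb).mean(1) - mx * my
                s_my = (mb * yb).mean(1) - mm * my
                det = s_mm * s_xx - s_xm * s_xm
                bad = (s_xx <= 0) | (s_mm <= 0) | (yb.std(axis=1) == 0) | (det <= 0)
                if not bad.any():
                    break
                idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
            else:
                raise NumericError("bootstrap resamples degenerate after 10 "
                                   "redraw rounds")
            a_b = s_xm / s_xx
            b_b = (s_my * s_xx - s_xy * s_xm) / det
            out[done:done + k] = a_b * b_b
            done += k
        return out
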