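"""Tail probabilities of central chi-square mixtures Q = sum_j lambda_j * chi2(n_j).

Numerical inversion of the characteristic function following the classic
quadratic-form algorithm (characteristic-function integration with adaptive
truncation bounds and an optional Gaussian convergence factor). Each
distinct eigenvalue carries an integer multiplicity ``n_j``, so a spectrum
with one huge near-degenerate block (the projected-identity bulk that
arises in variance-component tests) costs the same as a single eigenvalue.

The implementation handles signed (indefinite) mixtures; noncentralities
are not supported (the interaction statistic is a central form).

``qf_cdf`` returns P(Q < q) together with a fault code and round-off
diagnostics; callers wanting an upper tail use ``davies_sf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["DaviesResult", "qf_cdf", "davies_sf"]

_PI = math.pi
_LOG28 = math.log(2.0) / 8.0


class _FaultError(Exception):
    def __init__(self, code: int):
        self.code = code


@dataclass
class DaviesResult:
    value: float  # P(Q < q)
    fault: int  # 0 ok; 1 truncation-term limit; 2 round-off; 3 invalid input; 4 no convergence
    abssum: float  # accumulated absolute integrand sum (round-off diagnostic)
    terms: int  # bound/integration evaluations used


def _exp1(x: float) -> float:
    return math.exp(x) if x > -50.0 else 0.0


class _QF:
    def __init__(self, lb: np.ndarray, n: np.ndarray, q: float, lim: int, acc: float):
        self.lb = np.asarray(lb, dtype=float)
        self.n = np.asarray(n, dtype=float)
        self.r = len(self.lb)
        self.c = float(q)
        self.lim = int(lim)
        self.acc = float(acc)
        self.sigsq = 0.0  # accumulated convergence-factor variance
        self.count = 0
        self.intl = 0.0
        self.ersm = 0.0
        self.fail = False
        self.th = np.argsort(-np.abs(self.lb))  # decreasing |lambda|

    def _counter(self):
        self.count += 1
        if self.count > self.lim:
            raise _FaultError(4)

    # --- tail bound machinery -------------------------------------------
    def errbd(self, u: float) -> tuple[float, float]:
        """Bound on tail probability via the mgf at u; returns (bound, cutoff)."""
        self._counter()
        xconst = u * self.sigsq
        sum1 = u * xconst
        u2 = 2.0 * u
        x = u2 * self.lb
        y = 1.0 - x
        if np.any(y <= 0):
            raise _FaultError(3)
        xconst += float(np.sum(self.lb * self.n / y))
        # log1p(-x) + x: accurate to ~ulp(log1p) even for tiny x
        sum1 += float(np.sum(self.n * (x * x / y + (np.log1p(-x) + x))))
        return _exp1(-0.5 * sum1), xconst

    def ctff(self, accx: float, upn: float) -> tuple[float, float]:
        """Cutoff c2 such that P(Q > c2) < accx (upn > 0) or lower analogue."""
        u2 = upn
        u1 = 0.0
        c1 = self.mean
        rb = 2.0 * (self.lmax if u2 > 0.0 else self.lmin)
        u = u2 / (1.0 + u2 * rb)
        bd, c2 = self.errbd(u)
        while bd > accx:
            u1 = u2
            c1 = c2
            u2 = 2.0 * u2
            u = u2 / (1.0 + u2 * rb)
            bd, c2 = self.errbd(u)
        u = (c1 - self.mean) / (c2 - self.mean)
        while u < 0.9:
            u = (u1 + u2) / 2.0
            bd, xconst = self.errbd(u / (1.0 + u * rb))
            if bd > accx:
                u1 = u
                c1 = xconst
            else:
                u2 = u
                c2 = xconst
            u = (c1 - self.mean) / (c2 - self.mean)
        return c2, u2

    def truncation(self, u: float, tausq: float) -> float:
        """Bound on the error from truncating the integral at u."""
        self._counter()
        sum2 = (self.sigsq + tausq) * u * u
        prod1 = 2.0 * sum2
        u2 = 2.0 * u
        x = (u2 * self.lb) ** 2
        big = x > 1.0
        prod2 = float(np.sum(self.n[big] * np.log(x[big])))
        prod3 = float(np.sum(self.n[big] * np.log1p(x[big])))
        s = float(np.sum(self.n[big]))
        prod1 += float(np.sum(self.n[~big] * np.log1p(x[~big])))
        sum1 = 0.0  # no noncentrality
        prod2 = prod1 + prod2
        prod3 = prod1 + prod3
        x_ = _exp1(-sum1 - 0.25 * prod2) / _PI
        y_ = _exp1(-sum1 - 0.25 * prod3) / _PI
        err1 = 1.0 if s == 0 else x_ * 2.0 / s
        err2 = 2.5 * y_ if prod3 > 1.0 else 1.0
        if err2 < err1:
            err1 = err2
        x_ = 0.5 * sum2
        err2 = 1.0 if x_ <= y_ else y_ / x_
        return err1 if err1 < err2 else err2

    def findu(self, utx: float, accx: float) -> float:
        """Smallest practical truncation point u with truncation error < accx."""
        divis = (2.0, 1.4, 1.2, 1.1)
        ut = utx
        u = ut / 4.0
        if self.truncation(u, 0.0) > accx:
            u = ut
            while self.truncation(u, 0.0) > accx:
                ut *= 4.0
                u = ut
        else:
            ut = u
            u = u / 4.0
            while self.truncation(u, 0.0) <= accx:
                ut = u
                u = u / 4.0
        for d in divis:
            u = ut / d
            if self.truncation(u, 0.0) <= accx:
                ut = u
        return ut

    def cfe(self, x: float) -> float:
        """Coefficient of tausq in the error when a convergence factor is used."""
        self._counter()
        axl = abs(x)
        sxl = 1.0 if x > 0.0 else -1.0
        sum1 = 0.0
        ordered = self.th  # decreasing |lambda|
        for j in range(self.r - 1, -1, -1):
            t = ordered[j]
            if self.lb[t] * sxl > 0.0:
                lj = abs(self.lb[t])
                axl1 = axl - lj * self.n[t]
                axl2 = lj / _LOG28
                if axl1 > axl2:
                    axl = axl1
                else:
                    if axl > axl2:
                        axl = axl2
                    sum1 = (axl - axl1) / lj
                    for k in range(j - 1, -1, -1):
                        sum1 += self.n[ordered[k]]
                    break
        if sum1 > 100.0:
            self.fail = True
            return 1.0
        return 2.0 ** (sum1 / 4.0) / (_PI * axl * axl)

    def integrate(self, nterm: int, interv: float, tausq: float, mainx: bool):
        """Add the contribution of nterm+1 integration terms (vectorised)."""
        k = np.arange(nterm, -1, -1, dtype=float)
        u = (k + 0.5) * interv
        sum1 = -2.0 * u * self.c
        sum2 = np.abs(sum1)
        sum3 = -0.5 * self.sigsq * u * u
        x = 2.0 * np.outer(u, self.lb)  # (terms, r)
        y = x * x
        sum3 = sum3 - 0.25 * (self.n * np.log1p(y)).sum(axis=1)
        z = self.n * np.arctan(x)
        sum1 = sum1 + z.sum(axis=1)
        sum2 = sum2 + np.abs(z).sum(axis=1)
        with np.errstate(under="ignore"):
            fac = np.where(sum3 > -50.0, np.exp(np.maximum(sum3, -745.0)), 0.0)
        xv = (interv / _PI) * fac / u
        if not mainx:
            xv = xv * (1.0 - np.where(-0.5 * tausq * u * u > -50.0, np.exp(-0.5 * tausq * u * u), 0.0))
        self.intl += float(np.sum(np.sin(0.5 * sum1) * xv))
        self.ersm += float(np.sum(0.5 * sum2 * xv))

    # --- main routine ---------------------------------------------------
    def run(self) -> DaviesResult:
        acc1 = self.acc
        xlim = float(self.lim)
        if self.r == 0:
            return DaviesResult(1.0 if self.c > 0 else 0.0, 0, 0.0, 0)

        sd = float(np.sum(2.0 * self.n * self.lb**2))
        self.mean = float(np.sum(self.n * self.lb))
        self.lmax = max(float(np.max(self.lb)), 0.0)
        self.lmin = min(float(np.min(self.lb)), 0.0)
        if sd == 0.0:
            return DaviesResult(1.0 if self.c > 0 else 0.0, 0, 0.0, 0)
        if self.lmax == 0.0 and self.lmin == 0.0:
            raise _FaultError(3)
        sd = math.sqrt(sd)
        almx = max(self.lmax, -self.lmin)

        utx = 16.0 / sd
        up = 4.5 / sd
        un = -up
        utx = self.findu(utx, 0.5 * acc1)
        # convergence factor helps when the largest |lambda| dominates
        if self.c != 0.0 and almx > 0.07 * sd:
            self.fail = False
            tausq = 0.25 * acc1 / self.cfe(self.c)
            if self.fail:
                self.fail = False
            elif self.truncation(utx, tausq) < 0.2 * acc1:
                self.sigsq += tausq
                utx = self.findu(utx, 0.25 * acc1)
        acc1 *= 0.5

        while True:
            # range of the distribution
            c2_up, up = self.ctff(acc1, up)
            d1 = c2_up - self.c
            if d1 < 0.0:
                return DaviesResult(1.0, 0, self.ersm, self.count)
            c2_dn, un = self.ctff(acc1, un)
            d2 = self.c - c2_dn
            if d2 < 0.0:
                return DaviesResult(0.0, 0, self.ersm, self.count)
            intv = 2.0 * _PI / max(d1, d2)
            xnt = utx / intv
            xntm = 3.0 / math.sqrt(acc1)
            if xnt <= xntm * 1.5:
                break
            # auxiliary integration with a convergence factor
            if xntm > xlim:
                raise _FaultError(1)
            ntm = int(math.floor(xntm + 0.5))
            intv1 = utx / ntm
            x = 2.0 * _PI / intv1
            if x <= abs(self.c):
                break
            self.fail = False
            tausq = 0.33 * acc1 / (1.1 * (self.cfe(self.c - x) + self.cfe(self.c + x)))
            if self.fail:
                break
            acc1 *= 0.67
            self.integrate(ntm, intv1, tausq, False)
            xlim -= xntm
            self.sigsq += tausq
            utx = self.findu(utx, 0.25 * acc1)
            acc1 *= 0.75

        # main integration
        if xnt > xlim:
            raise _FaultError(1)
        nt = int(math.floor(xnt + 0.5))
        self.integrate(nt, intv, 0.0, True)
        qfval = 0.5 - self.intl
        fault = 0
        # round-off check on the accumulated |integrand|
        upv = self.ersm
        x = upv + self.acc / 10.0
        for rat in (1.0, 2.0, 4.0, 8.0):
            if rat * x == rat * upv:
                fault = 2
        return DaviesResult(qfval, fault, self.ersm, self.count)


def qf_cdf(eigenvalues, multiplicities, q: float, lim: int = 1_000_000, acc: float = 1e-6) -> DaviesResult:
    """P(sum_j lambda_j chi2(n_j) < q) by characteristic-function inversion.

    Parameters
    ----------
    eigenvalues, multiplicities
        Distinct eigenvalues and their (positive integer) multiplicities.
    q
        Evaluation point.
    lim
        Cap on integration/bound evaluations.
    acc
        Target absolute accuracy.
    """
    lb = np.asarray(eigenvalues, dtype=float)
    n = np.asarray(multiplicities, dtype=float)
    if lb.shape != n.shape or lb.ndim != 1:
        return DaviesResult(math.nan, 3, 0.0, 0)
    if np.any(n <= 0) or not np.all(np.isfinite(lb)):
        return DaviesResult(math.nan, 3, 0.0, 0)
    solver = _QF(lb, n, q, lim, acc)
    try:
        return solver.run()
    except _FaultError as e:
        return DaviesResult(math.nan, e.code, solver.ersm, solver.count)


def davies_sf(eigenvalues, multiplicities, q: float, lim: int = 1_000_000, acc: float = 1e-6) -> DaviesResult:
    """Upper tail P(Q > q); ``value`` is the survival probability."""
    res = qf_cdf(eigenvalues, multiplicities, q, lim=lim, acc=acc)
    if math.isnan(res.value):
        return res
    return DaviesResult(1.0 - res.value, res.fault, res.abssum, res.terms)
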