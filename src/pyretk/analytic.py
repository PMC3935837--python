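"""Closed-form urinary excretion after a single bolus.

For a single oral or dermal bolus the model is a cascade of linear stages:
first-order depot absorption (rate ``ka``) drives the two-state blood/storage
subsystem, whose response is a sum of two exponentials (eigenvalues of the
2x2 exchange matrix); the metabolite pool adds one more first-order stage.
Every observable is therefore a finite sum of exponentials:

    B(t)  = sum_j c_j exp(r_j t)                       (r_j < 0)
    M(t)  = sum_j k_BM c_j (exp(r_j t) - exp(-k_elim t)) / (k_elim + r_j)
    QU(t) = k_MU M(t)
    U(t)  = U(inf) + sum_k (q_k / r_k) exp(r_k t)

with the asymptotic urinary yield

    U(inf) = f_abs * dose_isomer * omega / (k_metabolism * k_elim).

The 3-PBA pool is driven by both isomers' blood curves and has its own
elimination rate.  When two cascade rates (near-)coincide the partial-fraction
coefficients blow up; the evaluator then switches automatically to the exact
matrix-exponential limit form instead of failing.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .errors import ParameterError
from .model import N_STATE, STATE_NAMES, _EigPropagator, build_system_matrix
from .params import ParameterSet

__all__ = ["analytic_bolus_solution", "BolusSolution"]

ANALYTES = ("cisDCCA", "transDCCA", "PBA3")

#: relative rate separation below which the limit form is used
_DEGENERACY_RTOL = 1e-7


def _blood_exponential_terms(iso, ka: float, x0: float):
    """B(t) of one isomer as {rate: coefficient} for a depot bolus x0."""
    A2 = np.array([[-(iso.k_BS + iso.k_metabolism), iso.k_SB],
                   [iso.k_BS, -iso.k_SB]])
    lam, V = np.linalg.eig(A2)
    lam = np.real(lam)
    V = np.real(V)
    # particular solution w e^{-ka t} for the driven system
    M = A2 + ka * np.eye(2)
    w = -np.linalg.solve(M, np.array([ka * x0, 0.0]))
    alpha = np.linalg.solve(V, -w)
    terms = {-ka: w[0]}
    for i in range(2):
        terms[lam[i]] = terms.get(lam[i], 0.0) + alpha[i] * V[0, i]
    return terms


def _metabolite_terms(b_terms: dict[float, float], k_bm: float, k_elim: float):
    """M(t) terms given blood terms, formation rate and metabolite elimination."""
    out: dict[float, float] = {}
    tail = 0.0
    for r, c in b_terms.items():
        coeff = k_bm * c / (k_elim + r)
        out[r] = out.get(r, 0.0) + coeff
        tail -= coeff
    out[-k_elim] = out.get(-k_elim, 0.0) + tail
    return out


def _min_separation(rates: list[float]) -> float:
    rates = sorted(rates)
    scale = max(abs(r) for r in rates)
    gaps = [abs(b - a) for a, b in zip(rates, rates[1:])]
    return (min(gaps) / scale) if gaps else np.inf


class _ExpSum:
    """Evaluate sum_k c_k exp(r_k t) and its running integral."""

    def __init__(self, terms: dict[float, float]):
        self.r = np.array(list(terms.keys()))
        self.c = np.array(list(terms.values()))

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.exp(np.multiply.outer(t, self.r)) @ self.c

    def integral(self, t):
        """int_0^t of the sum; all rates are strictly negative here."""
        t = np.asarray(t, dtype=float)
        return (np.exp(np.multiply.outer(t, self.r)) - 1.0) @ (self.c / self.r)

    @property
    def integral_to_inf(self) -> float:
        return float(-(self.c / self.r).sum())


class BolusSolution:
    """Closed-form QU(t)/U(t) evaluators for a single bolus.

    Obtained from :func:`analytic_bolus_solution`; do not construct directly.
    """

    def __init__(self, params: ParameterSet, route: str, dose: float,
                 cis_fraction: float):
        if route not in ("oral", "dermal"):
            raise ParameterError(
                f"analytic solution supports oral/dermal routes, got {route!r}")
        if dose < 0:
            raise ParameterError("dose must be >= 0")
        self.params, self.route = params, route
        self.dose, self.cis_fraction = float(dose), float(cis_fraction)
        self._pba_factor = (params.shared.dermal_3PBA_factor
                            if route == "dermal" else 1.0)
        self._qu: dict[str, _ExpSum] = {}
        self._asym: dict[str, float] = {}
        self._fallback = None
        try:
            self._build()
        except _Degenerate:
            self._fallback = _MatrixExponentialLimit(
                params, route, dose, cis_fraction)

    def _build(self) -> None:
        p = self.params
        pba_terms: dict[float, float] = {}
        rate_pool: list[float] = [-p.shared.k_elim_3PBA]
        for which, frac in (("cis", self.cis_fraction),
                            ("trans", 1.0 - self.cis_fraction)):
            iso = p.isomer(which)
            ka = iso.k_abs_oral if self.route == "oral" else iso.k_abs_dermal
            f_abs = iso.f_abs_oral if self.route == "oral" else iso.f_abs_dermal
            x0 = f_abs * self.dose * frac
            b_terms = _blood_exponential_terms(iso, ka, x0)
            rates = list(b_terms.keys())
            if _min_separation(rates + [-iso.k_elim]) < _DEGENERACY_RTOL:
                raise _Degenerate
            rate_pool.extend(rates)
            m_terms = _metabolite_terms(b_terms, iso.k_BM, iso.k_elim)
            analyte = f"{which}DCCA"
            self._qu[analyte] = _ExpSum(
                {r: iso.k_MU * c for r, c in m_terms.items()})
            self._asym[analyte] = x0 * iso.dcca_yield_per_absorbed
            for r, c in b_terms.items():
                pba_terms[r] = pba_terms.get(r, 0.0) + p.k_BM_3PBA(which) * c
        if _min_separation(rate_pool) < _DEGENERACY_RTOL:
            raise _Degenerate
        m3 = _metabolite_terms(pba_terms, 1.0, p.shared.k_elim_3PBA)
        self._qu["PBA3"] = _ExpSum(
            {r: self._pba_factor * p.shared.k_MU_3PBA * c for r, c in m3.items()})
        asym3 = 0.0
        for which, frac in (("cis", self.cis_fraction),
                            ("trans", 1.0 - self.cis_fraction)):
            iso = p.isomer(which)
            f_abs = iso.f_abs_oral if self.route == "oral" else iso.f_abs_dermal
            asym3 += f_abs * self.dose * frac * p.pba3_yield_per_absorbed(which)
        self._asym["PBA3"] = self._pba_factor * asym3

    # -- public surface ------------------------------------------------------
    def urinary_rate(self, analyte: str, t):
        """QU(t), mol/h, for t >= 0 (scalar or array)."""
        self._check(analyte, t)
        if self._fallback is not None:
            return self._fallback.urinary_rate(analyte, t)
        return self._qu[analyte](t)

    def cumulative(self, analyte: str, t):
        """U(t), mol, for t >= 0 (scalar or array)."""
        self._check(analyte, t)
        if self._fallback is not None:
            return self._fallback.cumulative(analyte, t)
        return self._qu[analyte].integral(t)

    def asymptote(self, analyte: str) -> float:
        """U(inf): the closed-form asymptotic urinary yield, mol."""
        if analyte not in ANALYTES:
            raise KeyError(f"unknown analyte {analyte!r}")
        if self._fallback is not None:
            return self._fallback.asymptote(analyte)
        return self._asym[analyte]

    @property
    def used_limit_form(self) -> bool:
        """True when near-coincident rates forced the matrix-exponential form."""
        return self._fallback is not None

    @staticmethod
    def _check(analyte: str, t) -> None:
        if analyte not in ANALYTES:
            raise KeyError(f"unknown analyte {analyte!r}; known: {ANALYTES}")
        if np.any(np.asarray(t) < 0):
            raise ParameterError("t must be >= 0")


class _Degenerate(Exception):
    pass


class _MatrixExponentialLimit:
    """Exact limit form: evaluate the full linear system via expm/eig."""

    _U_IDX = {"cisDCCA": STATE_NAMES.index("U_cisDCCA"),
              "transDCCA": STATE_NAMES.index("U_transDCCA"),
              "PBA3": STATE_NAMES.index("U_3PBA")}
    _M_IDX = {"cisDCCA": STATE_NAMES.index("M_cisDCCA"),
              "transDCCA": STATE_NAMES.index("M_transDCCA"),
              "PBA3": STATE_NAMES.index("M_3PBA")}

    def __init__(self, params: ParameterSet, route: str, dose: float,
                 cis_fraction: float):
        self.params = params
        self._pba_factor = (params.shared.dermal_3PBA_factor
                            if route == "dermal" else 1.0)
        self.A = build_system_matrix(params)
        self.x0 = np.zeros(N_STATE)
        depot = {"oral": 0, "dermal": 1}[route]
        amounts = {}
        for which, frac, off in (("cis", cis_fraction, 0),
                                 ("trans", 1.0 - cis_fraction, 9)):
            iso = params.isomer(which)
            f_abs = iso.f_abs_oral if route == "oral" else iso.f_abs_dermal
            amounts[which] = f_abs * dose * frac
            self.x0[off + depot] = amounts[which]
        self._x0_cis, self._x0_trans = amounts["cis"], amounts["trans"]
        try:
            self._prop = _EigPropagator(self.A)
        except Exception:
            self._prop = None

    def _states(self, t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self._prop is not None:
            return self._prop.states(self.x0, t)
        return np.array([expm(self.A * ti) @ self.x0 for ti in t])

    def urinary_rate(self, analyte, t):
        k = {"cisDCCA": self.params.cis.k_MU,
             "transDCCA": self.params.trans.k_MU,
             "PBA3": self.params.shared.k_MU_3PBA}[analyte]
        factor = self._pba_factor if analyte == "PBA3" else 1.0
        out = factor * k * self._states(t)[:, self._M_IDX[analyte]]
        return out if np.ndim(t) else float(out[0])

    def cumulative(self, analyte, t):
        factor = self._pba_factor if analyte == "PBA3" else 1.0
        out = factor * self._states(t)[:, self._U_IDX[analyte]]
        return out if np.ndim(t) else float(out[0])

    def asymptote(self, analyte) -> float:
        p = self.params
        total = 0.0
        for which, x0 in (("cis", self._x0_cis), ("trans", self._x0_trans)):
            iso = p.isomer(which)
            if analyte == f"{which}DCCA":
                total += x0 * iso.dcca_yield_per_absorbed
            elif analyte == "PBA3":
                total += x0 * p.pba3_yield_per_absorbed(which)
        factor = self._pba_factor if analyte == "PBA3" else 1.0
        return factor * total


def analytic_bolus_solution(params: ParameterSet, route: str, dose: float,
                            cis_fraction: float = 0.5) -> BolusSolution:
    """Closed-form QU(t)/U(t) evaluators for a single oral or dermal bolus.

    No wash-off is supported here (use :func:`pyretk.model.simulate` for
    scenarios with wash-off or multiple events).  Near-degenerate rate
    constants trigger an automatic switch to the exact matrix-exponential
    limit form (``sol.used_limit_form`` reports this).
    """
    return BolusSolution(params, route, dose, cis_fraction)
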