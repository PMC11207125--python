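"""Rational transfer functions, Routh–Hurwitz analysis and step-response metrics.

This module carries the linear-systems plumbing of the package: the rational
transfer-function container used for the identified radiofrequency-ablation
plant (voltage in, tissue impedance out), Routh–Hurwitz stability tables,
pole/zero extraction, exact zero-order-hold step simulation and the
MATLAB-``stepinfo``-style performance metrics (rise time, overshoot,
settling time) that the control design is judged by.

Conventions
-----------
* Polynomial coefficients are stored in **descending** powers of ``s`` (or
  ``z`` for discrete systems), NumPy style.
* Step metrics follow the MATLAB ``stepinfo`` definitions: rise time is the
  10→90% traversal of the span from the initial response value to the
  steady-state value; the settling band is 2% of the *largest* deviation
  ``|y - y_final|`` seen over the horizon; overshoot is expressed as a
  percentage of the steady-state value.  For responses that start at zero
  and overshoot by less than 100% these coincide with the textbook
  "2% of final value" conventions, but they differ (and matter) for the
  wildly-overshooting open-loop ablation plant and for the biproper
  PID closed loop.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy import linalg, signal

__all__ = [
    "RationalTF",
    "RouthTable",
    "StepMetrics",
    "PoleZeroSet",
    "StepSeries",
    "InfiniteDCGainError",
    "UnsettledError",
    "canonical_plant",
    "canonical_discrete_plant",
    "dc_gain",
    "step_response",
    "step_metrics",
    "routh_table",
    "poles_zeros",
    "d2c_convert",
    "c2d_convert",
    "refine_plant_from_routh",
]


class InfiniteDCGainError(ValueError):
    """The transfer function has a pole at s=0 (or z=1): no finite DC gain."""


class UnsettledError(ValueError):
    """The simulated horizon is too short for the response to settle."""


def _as_coeffs(c: Iterable[float]) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(c, dtype=float))
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("coefficient list must be a non-empty 1-D sequence")
    return arr


@dataclass(frozen=True)
class RationalTF:
    """Ratio of two real polynomials in ``s`` (continuous) or ``z`` (discrete).

    Parameters
    ----------
    num, den : sequence of float
        Coefficients in descending powers.  The leading denominator
        coefficient must be nonzero.
    domain : {"s", "z"}
    dt : float, optional
        Sample period in seconds; required iff ``domain == "z"``.
    """

    num: np.ndarray
    den: np.ndarray
    domain: str = "s"
    dt: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "num", _as_coeffs(self.num))
        object.__setattr__(self, "den", _as_coeffs(self.den))
        if self.den[0] == 0.0:
            raise ValueError("leading denominator coefficient must be nonzero")
        if self.domain not in ("s", "z"):
            raise ValueError(f"domain must be 's' or 'z', got {self.domain!r}")
        if self.domain == "z":
            if self.dt is None or self.dt <= 0:
                raise ValueError("discrete transfer functions need dt > 0")
        elif self.dt is not None:
            raise ValueError("continuous transfer functions must not set dt")

    # -- basic structure ---------------------------------------------------
    @property
    def num_degree(self) -> int:
        nz = np.flatnonzero(self.num)
        return int(self.num.size - 1 - nz[0]) if nz.size else 0

    @property
    def den_degree(self) -> int:
        return int(self.den.size - 1)

    @property
    def is_proper(self) -> bool:
        return self.num_degree <= self.den_degree

    @property
    def is_strictly_proper(self) -> bool:
        return self.num_degree < self.den_degree

    def monic(self) -> "RationalTF":
        """Scale so the leading denominator coefficient is 1."""
        lead = self.den[0]
        return RationalTF(self.num / lead, self.den / lead, self.domain, self.dt)

    # -- alternative representations ---------------------------------------
    @classmethod
    def from_zinv(
        cls,
        num_zinv: Sequence[float],
        den_zinv: Sequence[float],
        dt: float,
    ) -> "RationalTF":
        """Build a discrete TF from polynomials in the delay operator z⁻¹.

        ``num_zinv[j]`` multiplies ``z^-j`` (same for the denominator).
        """
        b = _as_coeffs(num_zinv)
        a = _as_coeffs(den_zinv)
        n = max(b.size, a.size)
        num = np.concatenate([b, np.zeros(n - b.size)])
        den = np.concatenate([a, np.zeros(n - a.size)])
        nz = np.flatnonzero(num)
        num = num[nz[0] :] if nz.size else num[-1:]
        return cls(num, den, domain="z", dt=dt)

    def to_zinv(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(num, den)`` as coefficient series in z⁻¹ (z⁰ first)."""
        if self.domain != "z":
            raise ValueError("to_zinv is only defined for discrete TFs")
        pad = self.den.size - self.num.size
        num = np.concatenate([np.zeros(max(pad, 0)), self.num])
        return num, self.den.copy()

    def to_json_dict(self) -> dict:
        return {
            "num": self.num.tolist(),
            "den": self.den.tolist(),
            "domain": self.domain,
            "Ts": self.dt,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "RationalTF":
        return cls(d["num"], d["den"], domain=d["domain"], dt=d.get("Ts"))


@dataclass
class StepSeries:
    """A sampled step response on a uniform time grid."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("time and value arrays must have equal shape")


@dataclass
class StepMetrics:
    """MATLAB ``stepinfo``-style step-response characteristics."""

    rise_time: float
    peak_amplitude: float
    peak_time: float
    overshoot_pct: float
    settling_time: float
    final_value: float


@dataclass
class RouthTable:
    """Routh array of a real polynomial, top row first (s^n ... s^0)."""

    rows: list[list[float]]
    first_column: list[float]
    sign_changes: int
    stable: bool
    #: rows that came out identically zero and were replaced by the
    #: derivative of the auxiliary polynomial (imaginary-axis symmetry)
    auxiliary_rows: list[int] = field(default_factory=list)
    #: rows whose leading zero was epsilon-substituted to continue the table
    epsilon_rows: list[int] = field(default_factory=list)


@dataclass
class PoleZeroSet:
    poles: np.ndarray
    zeros: np.ndarray


# ---------------------------------------------------------------------------
# canonical plants (identified ex-vivo roll-off model)
# ---------------------------------------------------------------------------

_PLANT_FILES = {
    "as_printed": "plant_continuous_as_printed.json",
    "routh_refined": "plant_continuous_routh_refined.json",
}


def _load_fixture(name: str) -> RationalTF:
    text = resources.files("rfacontrol.data").joinpath(name).read_text()
    return RationalTF.from_json_dict(json.loads(text))


def canonical_plant(variant: str = "routh_refined") -> RationalTF:
    """The identified 9th-order continuous plant P(s): volts in, ohms out.

    ``variant="as_printed"`` uses the coefficients at the precision they are
    usually quoted; ``"routh_refined"`` replaces the denominator with the
    higher-precision values recoverable from the first two rows of its Routh
    array (which interleave the polynomial coefficients), fixing in
    particular the constant term 0.5032 whose rounding to 0.5 shifts the
    DC gain visibly (0.81/0.5032 = 1.61).
    """
    try:
        return _load_fixture(_PLANT_FILES[variant])
    except KeyError:
        raise ValueError(
            f"unknown plant variant {variant!r}; expected one of {sorted(_PLANT_FILES)}"
        ) from None


def canonical_discrete_plant() -> RationalTF:
    """The identified discrete plant P_D(z⁻¹) at a 1 s sample period."""
    return _load_fixture("plant_discrete.json")


# ---------------------------------------------------------------------------
# elementary analysis
# ---------------------------------------------------------------------------


def dc_gain(tf: RationalTF) -> float:
    """Steady-state gain: num(0)/den(0) in s, num(1)/den(1) in z."""
    if tf.domain == "s":
        n0, d0 = tf.num[-1], tf.den[-1]
    else:
        n0, d0 = np.polyval(tf.num, 1.0), np.polyval(tf.den, 1.0)
    if d0 == 0.0:
        raise InfiniteDCGainError("infinite DC gain: pole at s=0 (or z=1)")
    return float(n0 / d0)


def poles_zeros(tf: RationalTF) -> PoleZeroSet:
    """Roots of denominator and numerator with conjugate symmetry enforced."""
    return PoleZeroSet(
        poles=_symmetrized_roots(tf.den), zeros=_symmetrized_roots(tf.num)
    )


def _symmetrized_roots(coeffs: np.ndarray) -> np.ndarray:
    c = np.trim_zeros(np.asarray(coeffs, dtype=float), "f")
    if c.size <= 1:
        return np.zeros(0, dtype=complex)
    r = np.roots(c)
    tol = 1e-8 * max(1.0, np.abs(r).max())
    real = np.abs(r.imag) <= tol
    r[real] = r[real].real
    # pair each upper-half root with its closest lower-half partner and average
    upper = np.flatnonzero(r.imag > tol)
    lower = list(np.flatnonzero(r.imag < -tol))
    for i in upper:
        if not lower:
            break
        j = min(lower, key=lambda j: abs(r[j] - np.conj(r[i])))
        lower.remove(j)
        mean = 0.5 * (r[i] + np.conj(r[j]))
        r[i], r[j] = mean, np.conj(mean)
    return np.sort_complex(r)


# ---------------------------------------------------------------------------
# Routh–Hurwitz
# ---------------------------------------------------------------------------


def routh_table(poly_coeffs: Sequence[float], zero_tol: float = 1e-12) -> RouthTable:
    """Build the Routh array and count sign changes in its first column.

    The number of sign changes equals the number of roots in the open right
    half-plane.  Two classical degeneracies are handled: an isolated zero
    leading element is epsilon-substituted (treated as +0⁺ when counting
    signs), and an all-zero row is replaced by the derivative of the
    auxiliary polynomial formed from the row above it.
    """
    c = _as_coeffs(poly_coeffs)
    if np.all(c == 0.0):
        raise ValueError("all-zero polynomial has no Routh array")
    if c[0] == 0.0:
        raise ValueError("leading coefficient must be nonzero")
    deg = c.size - 1
    if deg < 1:
        raise ValueError("polynomial degree must be >= 1")

    scale = np.abs(c).max()
    tiny = zero_tol * scale
    width = (deg + 2) // 2
    # displayed rows keep genuine zeros; work rows carry the eps substitution
    shown: list[np.ndarray] = []
    work: list[np.ndarray] = []
    aux_rows: list[int] = []
    eps_rows: list[int] = []

    def _push(row: np.ndarray, index: int) -> None:
        """Record a row, epsilon-substituting an isolated zero pivot."""
        if np.all(np.abs(row) <= tiny) and index >= 1:
            # all-zero row: replace by the derivative of the auxiliary (even)
            # polynomial formed from the row above, leading power deg-(index-1)
            power = deg - (index - 1)
            aux_rows.append(index)
            prev = work[index - 1]
            row = np.array(
                [prev[j] * (power - 2 * j) for j in range(power // 2 + 1)],
                dtype=float,
            )
        row = np.concatenate([row, np.zeros(width - row.size)])
        shown.append(row.copy())
        w = row.copy()
        if abs(w[0]) <= tiny and np.any(np.abs(w) > tiny):
            eps_rows.append(index)
            w[0] = zero_tol * max(scale, 1.0)  # epsilon, treated as +0+
        work.append(w)

    _push(c[0::2], 0)
    _push(c[1::2], 1)

    for i in range(2, deg + 1):
        above, pivot_row = work[i - 2], work[i - 1]
        new = np.zeros(width)
        p = pivot_row[0]
        for j in range(width - 1):
            new[j] = (p * above[j + 1] - above[0] * pivot_row[j + 1]) / p
        _push(new, i)

    first = [float(r[0]) for r in shown]
    work_first = np.array([r[0] for r in work])
    signs = np.sign(work_first[np.abs(work_first) > 0])
    sign_changes = int(np.sum(signs[1:] != signs[:-1]))
    # an auxiliary row signals a root pattern symmetric about the origin
    # (imaginary-axis or mirrored roots): not asymptotically stable
    stable = (
        sign_changes == 0
        and not any(abs(v) <= tiny for v in first)
        and not aux_rows
    )
    return RouthTable(
        rows=[r.tolist() for r in shown],
        first_column=first,
        sign_changes=sign_changes,
        stable=stable,
        auxiliary_rows=aux_rows,
        epsilon_rows=eps_rows,
    )


def refine_plant_from_routh(
    char_rows: Sequence[Sequence[float]], degree: int
) -> np.ndarray:
    """Recover full-precision polynomial coefficients from the top two Routh rows.

    The first two rows of a Routh array are exactly the polynomial's
    coefficients at alternating powers, so published Routh tables often carry
    more digits than the polynomial as printed.  Returns the interleaved
    descending-power coefficient vector of length ``degree + 1``.
    """
    if len(char_rows) != 2:
        raise ValueError("expected exactly the first two Routh rows")
    top = _as_coeffs(char_rows[0])
    second = _as_coeffs(char_rows[1])
    n_even = (degree + 2) // 2  # entries at powers n, n-2, ...
    n_odd = (degree + 1) // 2
    if top.size != n_even or second.size != n_odd:
        raise ValueError(
            f"inconsistent row lengths for degree {degree}: "
            f"expected {n_even} and {n_odd}, got {top.size} and {second.size}"
        )
    out = np.zeros(degree + 1)
    out[0::2] = top
    out[1::2] = second
    return out


# ---------------------------------------------------------------------------
# step simulation (exact zero-order-hold propagation)
# ---------------------------------------------------------------------------


def _zoh_discretize(tf: RationalTF, dt: float):
    A, B, C, D = signal.tf2ss(tf.num, tf.den)
    Ad, Bd, Cd, Dd, _ = signal.cont2discrete((A, B, C, D), dt, method="zoh")
    return Ad, Bd[:, 0], Cd[0], float(np.atleast_2d(Dd)[0, 0])


def step_response(
    tf: RationalTF, horizon: float, dt: float = 1e-3, block: int = 256
) -> StepSeries:
    """Unit-step response of a continuous TF on a uniform grid over [0, horizon].

    The continuous system is discretized exactly under a zero-order hold
    (matrix exponential) and the state recursion is evaluated in blocks, so
    the result carries no time-stepping truncation error even for the stiff
    9th/10th-order ablation dynamics.  Biproper systems (degree of numerator
    equal to that of the denominator) are allowed; improper ones are not.
    """
    if tf.domain != "s":
        raise ValueError("step_response expects a continuous-domain TF")
    if not tf.is_proper:
        raise ValueError("improper transfer function (deg num > deg den)")
    if horizon <= 0 or dt <= 0:
        raise ValueError("horizon and dt must be positive")
    n = int(round(horizon / dt)) + 1
    Ad, b, c, d = _zoh_discretize(tf, dt)
    nx = Ad.shape[0]
    m = min(block, n)
    # y_{k+j} = c·Ad^j x_k + g_j with g_j = c·(sum_{i<j} Ad^i b) + d
    obs = np.empty((m, nx))
    g = np.empty(m)
    Apow = np.eye(nx)
    s = np.zeros(nx)
    for j in range(m):
        obs[j] = c @ Apow
        g[j] = c @ s + d
        s = Ad @ s + b
        Apow = Ad @ Apow
    Am, sm = Apow, s

    y = np.empty(n)
    x = np.zeros(nx)
    k = 0
    while k < n:
        mm = min(m, n - k)
        y[k : k + mm] = obs[:mm] @ x + g[:mm]
        x = Am @ x + sm
        k += mm
    t = np.arange(n) * dt
    return StepSeries(t=t, y=y)


def _first_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Time of first upward crossing of ``level``, linearly interpolated."""
    idx = np.flatnonzero(y >= level)
    if idx.size == 0:
        raise UnsettledError(f"response never reaches level {level!r} in horizon")
    i = idx[0]
    if i == 0 or y[i] == y[i - 1]:
        return float(t[i])
    return float(t[i - 1] + (level - y[i - 1]) / (y[i] - y[i - 1]) * (t[i] - t[i - 1]))


def step_metrics(
    series: StepSeries | tuple[np.ndarray, np.ndarray],
    final_value: float,
    settle_band: float = 0.02,
) -> StepMetrics:
    """Rise/peak/overshoot/settling characteristics of a step response.

    Follows the MATLAB ``stepinfo`` definitions (the workflow this package
    mirrors): rise time is the 10%→90% traversal of the span between the
    initial value ``y[0]`` and ``final_value``; overshoot is
    ``100·(peak − final)/|final|`` clipped at zero; settling time is the
    (interpolated) last instant the absolute error ``|y − final|`` exceeds
    ``settle_band`` times its own maximum over the horizon.  Threshold
    crossings are linearly interpolated between grid points.
    """
    if isinstance(series, StepSeries):
        t, y = series.t, series.y
    else:
        t, y = np.asarray(series[0], float), np.asarray(series[1], float)
    if t.size < 2:
        raise ValueError("need at least two samples")
    yf = float(final_value)
    if yf == 0.0:
        raise ValueError("final value must be nonzero for relative metrics")
    y0 = float(y[0])
    span = yf - y0
    if span == 0.0:
        raise ValueError("zero span between initial and final value")

    progress = (y - y0) / span
    t10 = _first_crossing(t, progress, 0.1)
    t90 = _first_crossing(t, progress, 0.9)
    rise = t90 - t10

    ipk = int(np.argmax(y)) if span > 0 else int(np.argmin(y))
    peak, peak_time = float(y[ipk]), float(t[ipk])
    overshoot = max(0.0, 100.0 * (peak - yf) / abs(yf))

    err = np.abs(y - yf)
    band = settle_band * err.max()
    outside = err > band
    if outside[-1]:
        raise UnsettledError("response does not settle within the horizon")
    if not outside.any():
        settling = float(t[0])
    else:
        i = int(np.max(np.nonzero(outside)[0]))
        # interpolate the band crossing between samples i and i+1
        de = err[i] - err[i + 1]
        frac = (err[i] - band) / de if de > 0 else 1.0
        settling = float(t[i] + frac * (t[i + 1] - t[i]))
    return StepMetrics(
        rise_time=rise,
        peak_amplitude=peak,
        peak_time=peak_time,
        overshoot_pct=overshoot,
        settling_time=settling,
        final_value=yf,
    )


# ---------------------------------------------------------------------------
# domain conversion
# ---------------------------------------------------------------------------


def _homogenize(coeffs: np.ndarray, P: np.ndarray, Q: np.ndarray, n: int) -> np.ndarray:
    """Σ c_i x^(n-i) with x = P/Q, multiplied through by Q^n."""
    padded = np.concatenate([np.zeros(n + 1 - coeffs.size), coeffs])
    out = np.zeros(1)
    for i, ci in enumerate(padded):
        term = np.array([ci])
        for _ in range(n - i):
            term = np.polymul(term, P)
        for _ in range(i):
            term = np.polymul(term, Q)
        out = np.polyadd(out, term)
    return out


def _trim_leading(coeffs: np.ndarray, ref: float) -> np.ndarray:
    tol = 1e-10 * max(ref, 1.0)
    nz = np.flatnonzero(np.abs(coeffs) > tol)
    return coeffs[nz[0] :] if nz.size else coeffs[-1:]


def _bilinear_map(tf: RationalTF, P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = max(tf.num_degree, tf.den_degree)
    num = _homogenize(np.trim_zeros(tf.num, "f"), P, Q, n)
    den = _homogenize(tf.den, P, Q, n)
    ref = max(np.abs(num).max(), np.abs(den).max())
    num, den = _trim_leading(num, ref), _trim_leading(den, ref)
    return num / den[0], den / den[0]


def c2d_convert(tf: RationalTF, dt: float, method: str = "zoh") -> RationalTF:
    """Discretize a continuous TF (zero-order hold or Tustin/bilinear)."""
    if tf.domain != "s":
        raise ValueError("c2d_convert expects a continuous TF")
    if method == "zoh":
        A, B, C, D = signal.tf2ss(tf.num, tf.den)
        Ad, Bd, Cd, Dd, _ = signal.cont2discrete((A, B, C, D), dt, method="zoh")
        num, den = signal.ss2tf(Ad, Bd, Cd, Dd)
        ref = max(np.abs(num).max(), np.abs(den).max())
        return RationalTF(_trim_leading(num[0], ref), den, domain="z", dt=dt)
    if method == "tustin":
        # z -> s via s = (2/dt)(z-1)/(z+1); substitute into H(s)
        P = np.array([2.0 / dt, -2.0 / dt])
        Q = np.array([1.0, 1.0])
        num, den = _bilinear_map(tf, P, Q)
        return RationalTF(num, den, domain="z", dt=dt)
    raise ValueError(f"unknown method {method!r}; expected 'zoh' or 'tustin'")


def d2c_convert(tf: RationalTF, method: str = "zoh") -> RationalTF:
    """Continuous-time equivalent of a discrete TF.

    ``zoh`` inverts the zero-order-hold map through the principal matrix
    logarithm; it therefore rejects systems with poles on the closed negative
    real axis of the z-plane (the log has no real principal branch there).
    ``tustin`` applies the inverse bilinear substitution
    z = (1 + s·dt/2)/(1 − s·dt/2), an involution with ``c2d_convert``.
    """
    if tf.domain != "z":
        raise ValueError("d2c_convert expects a discrete TF")
    dt = float(tf.dt)
    if method == "tustin":
        P = np.array([tf.dt / 2.0, 1.0])
        Q = np.array([-tf.dt / 2.0, 1.0])
        num, den = _bilinear_map(tf, P, Q)
        return RationalTF(num, den, domain="s")
    if method != "zoh":
        raise ValueError(f"unknown method {method!r}; expected 'zoh' or 'tustin'")

    Ad, Bd, Cd, Dd = signal.tf2ss(tf.num, tf.den)
    nx = Ad.shape[0]
    eig = np.linalg.eigvals(Ad)
    if np.any(np.abs(eig) < 1e-12):
        raise ValueError("pole at z=0: zero-order-hold inversion undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # logm warns about its own accuracy
        L = linalg.logm(Ad)
    if np.abs(np.imag(L)).max() > 1e-8 * max(1.0, np.abs(L).max()):
        raise ValueError(
            "negative real-axis pole in z: no real principal logarithm branch"
        )
    Ac = np.real(L) / dt
    # Gamma = ∫_0^dt expm(Ac τ) dτ via an augmented exponential; Bd = Gamma·Bc
    M = np.zeros((2 * nx, 2 * nx))
    M[:nx, :nx] = Ac * dt
    M[:nx, nx:] = np.eye(nx) * dt
    gamma = linalg.expm(M)[:nx, nx:]
    Bc = np.linalg.solve(gamma, Bd)
    num, den = signal.ss2tf(Ac, Bc, Cd, Dd)
    ref = max(np.abs(num).max(), np.abs(den).max())
    return RationalTF(_trim_leading(num[0], ref), den, domain="s")
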