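"""Forward and inverse impedance models for ECIS microelectrodes.

The forward model combines a constant-phase-element (CPE) description of the
bare gold/electrolyte interface with the classic disc-cell solution for a
cell-covered electrode.  A confluent layer of disc-shaped cells of radius
``rc`` hovering a distance ``h`` above the electrode modifies the specific
(per-area) electrode impedance ``Zn`` into

    1/Zc = (1/Zn) * [ Zn/(Zn+Zm)
                      + (Zm/(Zn+Zm)) / ( (g/2)*I0(g)/I1(g) + Rb*(1/Zn + 1/Zm) ) ]

with ``g = gamma*rc = alpha*sqrt(1/Zn + 1/Zm)``, membrane impedance
``Zm = 2/(j*omega*Cm)`` (apical and basal membranes in series, purely
capacitive), junctional resistance ``Rb`` (Ohm*cm^2) between neighbouring
cells, and ``alpha = rc*sqrt(rho/h)`` (Ohm^0.5*cm) encoding current
constriction in the cell-substrate channel.  ``I0``/``I1`` are modified Bessel
functions of the first kind evaluated at complex argument.

The inverse problem (:func:`fit_cell_params`) first calibrates the CPE
interface on a cell-free frequency scan and then recovers ``(Rb, alpha, Cm)``
from a cell-covered scan by seeded multi-start complex nonlinear least squares
on log-magnitude and phase.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special
from scipy.stats import qmc

__all__ = [
    "ElectrodeSpec",
    "CellParams",
    "FrequencyScan",
    "ModelSpectrum",
    "FitResult",
    "alpha_h_convert",
    "bessel_disc_factor",
    "cell_free_specific_impedance",
    "membrane_specific_impedance",
    "cell_covered_specific_impedance",
    "model_spectrum",
    "whole_well_impedance",
    "series_resistance_capacitance",
    "default_scan_frequencies",
    "fit_cell_params",
]

#: Frequency range of the instrument's frequency-scan mode (Hz).
SCAN_FREQ_MIN = 31.25
SCAN_FREQ_MAX = 100_000.0
SCAN_N_POINTS = 25


def default_scan_frequencies(n: int = SCAN_N_POINTS) -> np.ndarray:
    """Log-spaced scan grid from 31.25 Hz to 100 kHz (25 points by default)."""
    return np.geomspace(SCAN_FREQ_MIN, SCAN_FREQ_MAX, n)


# ---------------------------------------------------------------------------
# electrode / cell parameter containers
# ---------------------------------------------------------------------------

def _cpe_magnitude_for_capacitance(
    cap_f: float, area_cm2: float, freq: float, n_exp: float
) -> float:
    # series capacitance of a CPE: C = area / (A * w^(1-n) * sin(n*pi/2))
    w = 2.0 * math.pi * freq
    return area_cm2 / (cap_f * w ** (1.0 - n_exp) * math.sin(n_exp * math.pi / 2.0))


_SINGLE_AREA_CM2 = math.pi * (125e-4) ** 2  # 250-um diameter disc, ~4.909e-4 cm^2
_DEFAULT_CPE_EXP = 0.9
# tuned so the cell-free series capacitance at 64 kHz is 3.3 nF on one electrode
_DEFAULT_CPE_MAG = _cpe_magnitude_for_capacitance(
    3.3e-9, _SINGLE_AREA_CM2, 64_000.0, _DEFAULT_CPE_EXP
)


@dataclass(frozen=True)
class ElectrodeSpec:
    """Well/electrode geometry and the cell-free interface parameters.

    Defaults describe one 250-um diameter working electrode (8W1E array) with
    a CPE interface tuned so the cell-free well resistance at 40 kHz is about
    2000 Ohm; :meth:`for_array` builds the 8W10E variant (~300 Ohm).
    """

    electrode_radius_um: float = 125.0
    n_electrodes: int = 1
    well_area_cm2: float = 0.8
    cpe_magnitude: float = _DEFAULT_CPE_MAG  # Ohm*cm^2*s^-n
    cpe_exponent: float = _DEFAULT_CPE_EXP
    r_solution_ohm: float = 0.0
    medium_resistivity: float = 54.0  # Ohm*cm

    def __post_init__(self) -> None:
        if self.electrode_radius_um <= 0:
            raise ValueError("electrode_radius_um must be positive")
        if self.n_electrodes not in (1, 10):
            raise ValueError("n_electrodes must be 1 (8W1E) or 10 (8W10E)")
        if not 0.0 < self.cpe_exponent <= 1.0:
            raise ValueError("cpe_exponent must lie in (0, 1]")
        if self.cpe_magnitude <= 0:
            raise ValueError("cpe_magnitude must be positive")
        if self.r_solution_ohm < 0:
            raise ValueError("r_solution_ohm must be non-negative")

    @property
    def electrode_area_cm2(self) -> float:
        """Area of a single working electrode (cm^2)."""
        return math.pi * (self.electrode_radius_um * 1e-4) ** 2

    @property
    def total_area_cm2(self) -> float:
        """Total sensing area, scaling linearly with electrode count."""
        return self.n_electrodes * self.electrode_area_cm2

    @classmethod
    def for_array(
        cls,
        array_type: str,
        *,
        resistance_40khz_ohm: float | None = None,
        cpe_magnitude: float = _DEFAULT_CPE_MAG,
        cpe_exponent: float = _DEFAULT_CPE_EXP,
        medium_resistivity: float = 54.0,
    ) -> "ElectrodeSpec":
        """Tuned spec for an array type.

        ``r_solution_ohm`` is chosen so the cell-free whole-well resistance at
        40 kHz equals the instrument's nominal value (2000 Ohm for 8W1E,
        300 Ohm for 8W10E) unless overridden.
        """
        try:
            n_el = {"8W1E": 1, "8W10E": 10}[array_type]
        except KeyError:
            raise ValueError(f"unknown array type {array_type!r}") from None
        if resistance_40khz_ohm is None:
            resistance_40khz_ohm = {"8W1E": 2000.0, "8W10E": 300.0}[array_type]
        base = cls(
            n_electrodes=n_el,
            cpe_magnitude=cpe_magnitude,
            cpe_exponent=cpe_exponent,
            r_solution_ohm=0.0,
            medium_resistivity=medium_resistivity,
        )
        r_interface = (cell_free_specific_impedance(40_000.0, base) / base.total_area_cm2).real
        if r_interface >= resistance_40khz_ohm:
            raise ValueError("interface alone exceeds the requested 40 kHz resistance")
        return dataclasses.replace(base, r_solution_ohm=resistance_40khz_ohm - r_interface)


def alpha_h_convert(
    value: float, direction: str, rho: float, rc_um: float
) -> float:
    """Convert between the constraint parameter alpha and the gap height h.

    ``h = rho*rc^2/alpha^2`` with rho in Ohm*cm, rc in um, alpha in
    Ohm^0.5*cm, and h in nm; ``direction`` is ``"alpha_to_h"`` or
    ``"h_to_alpha"`` (the map is its own inverse up to the square root).
    """
    if rho <= 0 or rc_um <= 0:
        raise ValueError("rho and rc must be positive")
    if value <= 0:
        raise ValueError("alpha/h must be positive")
    # rho*(rc_um*1e-4 cm)^2 / x^2 in cm -> *1e7 nm; both directions share the constant
    const = 0.1 * rho * rc_um**2
    if direction == "alpha_to_h":
        return const / value**2
    if direction == "h_to_alpha":
        return math.sqrt(const / value)
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class CellParams:
    """Morphological parameters of the confluent layer.

    Exactly one of ``alpha`` (Ohm^0.5*cm) and ``h_nm`` may be supplied; the
    other is derived through ``h = rho*rc^2/alpha^2``.
    """

    rb: float  # junctional resistance, Ohm*cm^2
    cm: float = 1.0  # membrane capacitance, uF/cm^2
    rc_um: float = 11.0  # cell radius
    rho: float = 54.0  # medium resistivity, Ohm*cm
    alpha: float | None = None
    h_nm: float | None = None

    def __post_init__(self) -> None:
        if self.rb < 0 or self.cm < 0 or self.rc_um <= 0 or self.rho <= 0:
            raise ValueError("cell parameters must be non-negative (rc, rho positive)")
        if self.alpha is None and self.h_nm is None:
            raise ValueError("provide alpha or h_nm")
        if self.alpha is None:
            object.__setattr__(
                self, "alpha", alpha_h_convert(self.h_nm, "h_to_alpha", self.rho, self.rc_um)
            )
        elif self.h_nm is None:
            if self.alpha < 0:
                raise ValueError("alpha must be non-negative")
            h = (
                alpha_h_convert(self.alpha, "alpha_to_h", self.rho, self.rc_um)
                if self.alpha > 0
                else math.inf
            )
            object.__setattr__(self, "h_nm", h)
        else:
            expected = alpha_h_convert(self.h_nm, "h_to_alpha", self.rho, self.rc_um)
            if not math.isclose(self.alpha, expected, rel_tol=1e-9):
                raise ValueError("alpha and h_nm are inconsistent for the given rho, rc")

    @classmethod
    def from_h(cls, rb: float, h_nm: float, cm: float = 1.0, rc_um: float = 11.0,
               rho: float = 54.0) -> "CellParams":
        return cls(rb=rb, cm=cm, rc_um=rc_um, rho=rho, h_nm=h_nm)

    @classmethod
    def from_alpha(cls, rb: float, alpha: float, cm: float = 1.0, rc_um: float = 11.0,
                   rho: float = 54.0) -> "CellParams":
        return cls(rb=rb, cm=cm, rc_um=rc_um, rho=rho, alpha=alpha)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def cell_free_specific_impedance(freq, electrode: ElectrodeSpec):
    """Specific impedance Zn of the bare interface (Ohm*cm^2), CPE form.

    ``Zn = A*(j*omega)^(-n)``; with n = 1 this is a pure capacitor of
    specific capacitance 1/A.  Vectorised over ``freq``.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    jw = 1j * 2.0 * np.pi * f
    zn = electrode.cpe_magnitude * jw ** (-electrode.cpe_exponent)
    return zn if np.ndim(freq) else complex(zn)


def membrane_specific_impedance(freq, cells: CellParams):
    """Series impedance of apical+basal membranes, ``Zm = 2/(j*omega*Cm)`` (Ohm*cm^2)."""
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    zm = 2.0 / (1j * 2.0 * np.pi * f * cells.cm * 1e-6)
    return zm if np.ndim(freq) else complex(zm)


def bessel_disc_factor(z):
    """Robust evaluation of ``(z/2)*I0(z)/I1(z)`` for complex z.

    Uses exponentially scaled Bessel functions (the scaling cancels in the
    ratio) so the factor stays finite for |z| up to ~1e3; a two-term series
    covers the z -> 0 limit where the ratio tends to 1.
    """
    z = np.asarray(z, dtype=complex)
    scalar = z.ndim == 0
    z = np.atleast_1d(z)
    out = np.empty_like(z)
    small = np.abs(z) < 1e-6
    out[small] = 1.0 + z[small] ** 2 / 8.0
    zb = z[~small]
    if zb.size:
        out[~small] = 0.5 * zb * special.ive(0, zb) / special.ive(1, zb)
    return complex(out[0]) if scalar else out


def cell_covered_specific_impedance(freq, electrode: ElectrodeSpec, cells: CellParams):
    """Specific impedance Zc of the cell-covered interface (Ohm*cm^2)."""
    zn = cell_free_specific_impedance(freq, electrode)
    zm = membrane_specific_impedance(freq, cells)
    inv_sum = 1.0 / zn + 1.0 / zm
    gamma_rc = cells.alpha * np.sqrt(inv_sum)
    bracket = zn / (zn + zm) + (zm / (zn + zm)) / (
        bessel_disc_factor(gamma_rc) + cells.rb * inv_sum
    )
    return 1.0 / ((1.0 / zn) * bracket)


@dataclass(frozen=True)
class ModelSpectrum:
    """Forward-model quantities on a frequency grid (all specific, Ohm*cm^2)."""

    frequencies: np.ndarray
    zn: np.ndarray
    zm: np.ndarray
    zc: np.ndarray
    gamma_rc: np.ndarray


def model_spectrum(freqs, electrode: ElectrodeSpec, cells: CellParams) -> ModelSpectrum:
    freqs = np.asarray(freqs, dtype=float)
    zn = cell_free_specific_impedance(freqs, electrode)
    zm = membrane_specific_impedance(freqs, cells)
    gamma_rc = cells.alpha * np.sqrt(1.0 / zn + 1.0 / zm)
    zc = cell_covered_specific_impedance(freqs, electrode, cells)
    return ModelSpectrum(frequencies=freqs, zn=zn, zm=zm, zc=zc, gamma_rc=gamma_rc)


def whole_well_impedance(freq, electrode: ElectrodeSpec,
                         cells: CellParams | None = None, coverage: float = 1.0):
    """Measured (whole-well) impedance in Ohm at fractional cell coverage.

    Covered and free patches of the sensing area act in parallel, so specific
    admittances are mixed area-weighted; the solution/constriction resistance
    adds in series.
    """
    if not 0.0 <= coverage <= 1.0:
        raise ValueError("coverage must lie in [0, 1]")
    zn = cell_free_specific_impedance(freq, electrode)
    if cells is None or coverage == 0.0:
        y_spec = 1.0 / zn
    else:
        zc = cell_covered_specific_impedance(freq, electrode, cells)
        y_spec = (1.0 - coverage) / zn + coverage / zc
    return 1.0 / (electrode.total_area_cm2 * y_spec) + electrode.r_solution_ohm


def series_resistance_capacitance(freq, z):
    """Series-equivalent (R, C) convention of the instrument channels.

    R = Re(Z); C = -1/(omega*Im(Z)).
    """
    w = 2.0 * np.pi * np.asarray(freq, dtype=float)
    z = np.asarray(z, dtype=complex)
    return z.real, -1.0 / (w * z.imag)


# ---------------------------------------------------------------------------
# frequency scans and the inverse fit
# ---------------------------------------------------------------------------

@dataclass
class FrequencyScan:
    """Complex whole-well impedance vs. frequency for one well."""

    frequencies: np.ndarray
    impedance: np.ndarray
    coverage_state: str = "cell_covered"  # or "cell_free"
    well_id: str = "A1"

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.impedance = np.asarray(self.impedance, dtype=complex)
        if self.frequencies.shape != self.impedance.shape:
            raise ValueError("frequency and impedance vectors must have equal length")
        if self.frequencies.size < 2 or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if self.frequencies[0] < SCAN_FREQ_MIN - 1e-9 or self.frequencies[-1] > SCAN_FREQ_MAX + 1e-6:
            raise ValueError("frequencies must lie within the 31.25 Hz .. 100 kHz scan range")
        if np.any(self.impedance.real <= 0):
            raise ValueError("Re(Z) must be positive at every frequency")
        if np.any(self.impedance.imag >= 0):
            raise ValueError("Im(Z) must be negative for a capacitive interface")
        if self.coverage_state not in ("cell_free", "cell_covered"):
            raise ValueError(f"unknown coverage_state {self.coverage_state!r}")


@dataclass
class FitResult:
    """Outcome of the multi-start (Rb, alpha, Cm) fit."""

    params: CellParams
    electrode: ElectrodeSpec  # with calibrated CPE interface
    residual: float
    n_starts: int
    converged: bool
    spread: dict = field(default_factory=dict)  # per-parameter relative spread across starts


DEFAULT_FIT_BOUNDS = {
    "rb": (1e-4, 100.0),  # Ohm*cm^2
    "alpha": (0.05, 50.0),  # Ohm^0.5*cm
    "cm": (0.1, 10.0),  # uF/cm^2
}


def _logmag_phase_residual(z_model, z_obs):
    return np.concatenate([
        np.log(np.abs(z_model)) - np.log(np.abs(z_obs)),
        np.angle(z_model) - np.angle(z_obs),
    ])


def calibrate_cell_free(scan: FrequencyScan, electrode: ElectrodeSpec) -> ElectrodeSpec:
    """Fit (cpe_magnitude, cpe_exponent, r_solution) to a cell-free scan.

    Weighted least squares on log|Z| and phase; returns a copy of
    ``electrode`` with the calibrated interface.
    """
    f = scan.frequencies
    z_obs = scan.impedance
    area = electrode.total_area_cm2

    def resid(x):
        el = dataclasses.replace(
            electrode, cpe_magnitude=10.0 ** x[0], cpe_exponent=x[1], r_solution_ohm=x[2]
        )
        z = cell_free_specific_impedance(f, el) / area + el.r_solution_ohm
        return _logmag_phase_residual(z, z_obs)

    r0 = max(z_obs.real[-1] * 0.9, 1e-6)
    w0 = 2.0 * np.pi * f[0]
    a0 = max(abs(z_obs[0] - r0) * area * w0**0.9, 1e-12)
    x0 = [math.log10(a0), 0.9, r0]
    sol = optimize.least_squares(
        resid, x0,
        bounds=([-6.0, 0.3, 0.0], [12.0, 1.0, 1e7]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    return dataclasses.replace(
        electrode,
        cpe_magnitude=10.0 ** sol.x[0],
        cpe_exponent=float(sol.x[1]),
        r_solution_ohm=float(sol.x[2]),
    )


def fit_cell_params(
    covered: FrequencyScan,
    free: FrequencyScan,
    electrode: ElectrodeSpec,
    bounds: dict | None = None,
    n_starts: int = 8,
    seed: int = 0,
    rc_um: float = 11.0,
    rho: float | None = None,
) -> FitResult:
    """Extract (Rb, h, Cm) from a covered/free scan pair.

    The cell-free scan calibrates the CPE interface and series resistance;
    the covered scan is then fit in log-magnitude + phase by multi-start
    nonlinear least squares, starts drawn from a seeded Latin-hypercube
    spread in log-parameter space.  Deterministic given ``seed``.
    """
    if covered.frequencies.shape != free.frequencies.shape or not np.allclose(
        covered.frequencies, free.frequencies, rtol=1e-9
    ):
        raise ValueError("covered and free scans must share one frequency grid")
    bounds = dict(DEFAULT_FIT_BOUNDS, **(bounds or {}))
    lo = np.log10([bounds["rb"][0], bounds["alpha"][0], bounds["cm"][0]])
    hi = np.log10([bounds["rb"][1], bounds["alpha"][1], bounds["cm"][1]])
    if np.any(lo >= hi):
        raise ValueError("bounds box is empty")
    rho = electrode.medium_resistivity if rho is None else rho

    cal = calibrate_cell_free(free, electrode)
    f = covered.frequencies
    z_obs = covered.impedance

    def resid(x):
        cells = CellParams(
            rb=10.0 ** x[0], cm=10.0 ** x[2], rc_um=rc_um, rho=rho, alpha=10.0 ** x[1]
        )
        z = whole_well_impedance(f, cal, cells, coverage=1.0)
        return _logmag_phase_residual(z, z_obs)

    sampler = qmc.LatinHypercube(d=3, seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    best = None
    solutions = []
    for i, x0 in enumerate(starts):
        sol = optimize.least_squares(
            resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        solutions.append(sol)
        key = (sol.cost, i)
        if best is None or key < best[0]:
            best = (key, sol)
    sol = best[1]
    params = CellParams(
        rb=10.0 ** sol.x[0], cm=10.0 ** sol.x[2], rc_um=rc_um, rho=rho,
        alpha=10.0 ** sol.x[1],
    )
    xs = np.array([s.x for s in solutions if s.success])
    spread = {}
    if xs.size:
        vals = 10.0 ** xs  # (n_ok, 3)
        ref = np.array([params.rb, params.alpha, params.cm])
        rel = np.std(vals, axis=0) / ref
        spread = dict(zip(("rb", "alpha", "cm"), rel.tolist()))
    return FitResult(
        params=params,
        electrode=cal,
        residual=float(2.0 * sol.cost),  # sum of squared residuals
        n_starts=n_starts,
        converged=bool(any(s.success for s in solutions)),
        spread=spread,
    )
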