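"""SEC-MALLS forward simulation and Debye-Zimm molar-mass profiles.

A size-exclusion run with in-line UV, differential refractive index (RI) and
static light-scattering (LS) detectors yields, at each elution time, a solute
concentration and an excess Rayleigh ratio. In the dilute, zero-angle limit
the Debye-Zimm relation reduces to

    R(0, t) = K* · c(t) · M(t),        K* = 4π² n₀² (dn/dc)² / (λ⁴ N_A)

with c from the RI trace (c = ΔRI / (dn/dc)) so the molar mass across a peak
is M(t) = R(t) / (K* c(t)). The module simulates multi-detector traces for a
known species mixture (Gaussian elution peaks, optional inter-detector delays
and noise), inverts them back to a mass-versus-elution profile, detects peaks
and assigns each peak a complex species from a :class:`~dabengage.topology.
SpeciesCatalog` by mass matching.

Chromatograms read/write as 4-column delimited text (time, uv, ri, ls) with a
YAML header carrying the calibration.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.signal import find_peaks, peak_widths

from .topology import SpeciesCatalog, match_species

__all__ = [
    "MALLSCalibration",
    "Chromatogram",
    "MassProfile",
    "PeakAssignment",
    "SECMALLSError",
    "simulate_chromatogram",
    "align_detectors",
    "mass_profile",
    "detect_and_assign",
    "write_chromatogram",
    "read_chromatogram",
]

AVOGADRO = 6.022_140_76e23  # 1/mol


class SECMALLSError(ValueError):
    """Invalid chromatogram or calibration input."""


@dataclass(frozen=True)
class MALLSCalibration:
    """Detector calibration for the zero-angle Debye-Zimm inversion.

    ``dn_dc`` in mL/g (0.185 is the protein convention), ``wavelength`` in nm,
    ``solvent_ri`` dimensionless, ``uv_extinction`` in mL/(mg·cm),
    ``interdetector_delays`` in seconds per detector relative to UV. The
    optical constant K* is always recomputed from the current fields.
    """

    dn_dc: float = 0.185
    wavelength: float = 658.0
    solvent_ri: float = 1.331
    uv_extinction: float = 1.0
    interdetector_delays: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dn_dc <= 0:
            raise SECMALLSError("dn/dc must be positive")
        if self.wavelength <= 0:
            raise SECMALLSError("wavelength must be positive")

    @property
    def optical_constant(self) -> float:
        """K* = 4π² n₀² (dn/dc)² / (λ⁴ N_A) in mol·cm²/g² (c in g/mL, M in g/mol)."""
        lam_cm = self.wavelength * 1e-7
        return (
            4.0
            * math.pi**2
            * self.solvent_ri**2
            * (self.dn_dc) ** 2
            / (lam_cm**4 * AVOGADRO)
        )


@dataclass
class Chromatogram:
    time: np.ndarray  # s, uniform strictly increasing grid
    uv: np.ndarray  # absorbance units
    ri: np.ndarray  # refractive-index difference (dimensionless)
    ls: np.ndarray  # excess Rayleigh ratio at θ≈0, 1/cm
    flow_rate: float = 0.5  # mL/min
    injected: list = field(default_factory=list)  # [(mass_kda, amount_ug), ...]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.uv = np.asarray(self.uv, float)
        self.ri = np.asarray(self.ri, float)
        self.ls = np.asarray(self.ls, float)
        n = len(self.time)
        if not (len(self.uv) == len(self.ri) == len(self.ls) == n):
            raise SECMALLSError("detector traces must share the time grid length")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise SECMALLSError("time grid must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class MassProfile:
    time: np.ndarray  # s
    molar_mass: np.ndarray  # g/mol, NaN where masked
    valid_mask: np.ndarray  # bool


@dataclass
class PeakAssignment:
    interval: tuple  # (t_start, t_end) seconds
    mass_kda: float  # amount-weighted mean molar mass over the peak
    species_label: Optional[str]
    relative_error: Optional[float]


def _gaussian_conc(
    time: np.ndarray, amount_ug: float, retention_s: float, width_s: float, flow_ml_min: float
) -> np.ndarray:
    """Concentration trace in g/mL for one eluting species.

    The peak integrates (over elution volume) to the injected amount, so
    c(t) = m / (F σ √(2π)) · exp(−(t − t_r)²/2σ²) with F in mL/s.
    """
    flow_ml_s = flow_ml_min / 60.0
    peak_area_gs = amount_ug * 1e-6  # g of solute
    norm = peak_area_gs / (flow_ml_s * width_s * math.sqrt(2.0 * math.pi))
    return norm * np.exp(-0.5 * ((time - retention_s) / width_s) ** 2)


def _shift_trace(trace: np.ndarray, time: np.ndarray, delay_s: float) -> np.ndarray:
    """Delay a trace by ``delay_s`` (positive = appears later), edge-padded."""
    if delay_s == 0:
        return trace.copy()
    return np.interp(time - delay_s, time, trace, left=trace[0], right=trace[-1])


def simulate_chromatogram(
    species: Sequence[tuple],
    calibration: MALLSCalibration,
    *,
    time: Optional[np.ndarray] = None,
    t_end: float = 2400.0,
    dt: float = 1.0,
    flow_rate: float = 0.5,
    noise_sd: Optional[dict] = None,
    seed: Optional[int] = None,
) -> Chromatogram:
    """Forward-simulate a multi-detector SEC-MALLS run.

    ``species`` is a list of ``(mass_kda, amount_ug, retention_s, width_s)``.
    Each species elutes as a Gaussian concentration peak; detector responses
    are ri = c·(dn/dc), uv = c·ε·10³ (1 cm path, c in g/mL → mg/mL), and
    ls = K*·c·M (zero-angle Debye-Zimm, second virial coefficient neglected).
    Inter-detector delays from the calibration are applied to the RI and LS
    traces; Gaussian noise with per-detector standard deviations from
    ``noise_sd`` (keys "uv", "ri", "ls") is added using ``seed``.
    """
    if time is None:
        time = np.arange(0.0, t_end, dt)
    time = np.asarray(time, float)
    conc = np.zeros_like(time)
    ls = np.zeros_like(time)
    for mass_kda, amount_ug, retention_s, width_s in species:
        if amount_ug < 0 or width_s <= 0:
            raise SECMALLSError("species amounts must be >= 0 and widths > 0")
        c_i = _gaussian_conc(time, amount_ug, retention_s, width_s, flow_rate)
        conc += c_i
        ls += calibration.optical_constant * c_i * (mass_kda * 1000.0)
    ri = conc * calibration.dn_dc
    uv = conc * 1000.0 * calibration.uv_extinction  # c in mg/mL times ε·path

    delays = calibration.interdetector_delays or {}
    ri = _shift_trace(ri, time, float(delays.get("ri", 0.0)))
    ls = _shift_trace(ls, time, float(delays.get("ls", 0.0)))
    uv = _shift_trace(uv, time, float(delays.get("uv", 0.0)))

    if noise_sd:
        rng = np.random.default_rng(seed)
        uv = uv + rng.normal(0.0, float(noise_sd.get("uv", 0.0)), time.shape)
        ri = ri + rng.normal(0.0, float(noise_sd.get("ri", 0.0)), time.shape)
        ls = ls + rng.normal(0.0, float(noise_sd.get("ls", 0.0)), time.shape)

    return Chromatogram(
        time=time,
        uv=uv,
        ri=ri,
        ls=ls,
        flow_rate=flow_rate,
        injected=[(m, a) for (m, a, _r, _w) in species],
    )


def align_detectors(
    chrom: Chromatogram, calibration: MALLSCalibration, *, max_delay_s: float = 60.0
) -> tuple[Chromatogram, dict]:
    """Estimate and remove inter-detector delays by cross-correlation.

    The UV trace is the timing reference; the RI and LS traces are shifted by
    the lag maximising their cross-correlation with UV (within
    ``±max_delay_s``). When a trace carries no usable signal (flat correlation)
    it is left untouched and its reported delay is 0.
    """
    dt = chrom.dt
    max_lag = max(1, int(round(max_delay_s / dt)))
    ref = chrom.uv - np.mean(chrom.uv)
    estimated: dict[str, float] = {"uv": 0.0}
    out = {"ri": chrom.ri, "ls": chrom.ls}
    warnings: list[str] = []
    for name in ("ri", "ls"):
        trace = out[name]
        sig = trace - np.mean(trace)
        if np.allclose(sig, 0) or np.allclose(ref, 0):
            estimated[name] = 0.0
            warnings.append(f"{name}: no signal to correlate")
            continue
        lags = np.arange(-max_lag, max_lag + 1)
        corr = np.array([np.dot(ref, np.roll(sig, -lag)) for lag in lags])
        if np.ptp(corr) <= 1e-12 * max(1.0, float(np.max(np.abs(corr)))):
            estimated[name] = 0.0
            warnings.append(f"{name}: correlation too flat, left unchanged")
            continue
        best = lags[int(np.argmax(corr))]
        delay = best * dt
        estimated[name] = float(delay)
        out[name] = _shift_trace(trace, chrom.time, -delay)
    aligned = Chromatogram(
        time=chrom.time.copy(),
        uv=chrom.uv.copy(),
        ri=out["ri"],
        ls=out["ls"],
        flow_rate=chrom.flow_rate,
        injected=list(chrom.injected),
    )
    return aligned, {"delays_s": estimated, "warnings": warnings}


def mass_profile(
    chrom: Chromatogram,
    calibration: MALLSCalibration,
    conc_floor: float = 1e-9,
) -> MassProfile:
    """Invert aligned traces to molar mass versus elution time.

    c(t) = ri(t)/(dn/dc); M(t) = ls(t)/(K*·c(t)) wherever c ≥ ``conc_floor``
    (g/mL); everything below the floor is masked (NaN).
    """
    conc = chrom.ri / calibration.dn_dc
    valid = conc >= conc_floor
    mass = np.full_like(conc, np.nan)
    kstar = calibration.optical_constant
    mass[valid] = chrom.ls[valid] / (kstar * conc[valid])
    return MassProfile(time=chrom.time.copy(), molar_mass=mass, valid_mask=valid)


def detect_and_assign(
    profile: MassProfile,
    chrom: Chromatogram,
    catalog: SpeciesCatalog,
    rel_tol: float = 0.15,
    *,
    prominence_frac: float = 0.05,
) -> list[PeakAssignment]:
    """Detect elution peaks and assign each a complex species by mass.

    Peaks are found on the RI trace (the concentration proxy) with a
    prominence threshold of ``prominence_frac`` of its maximum; each peak's
    mass is the concentration-weighted mean of the Debye-Zimm profile over
    the peak's extent, matched against the catalog within ``rel_tol``.
    """
    if not catalog.species:
        raise SECMALLSError("species catalog is empty")
    ri = chrom.ri
    if not np.any(ri > 0):
        return []
    prominence = prominence_frac * float(np.max(ri))
    peaks, props = find_peaks(ri, prominence=prominence)
    if len(peaks) == 0:
        return []
    # peak extent at 95% height drop: keeps neighbouring peaks out of the average
    widths = peak_widths(ri, peaks, rel_height=0.95)
    assignments: list[PeakAssignment] = []
    for i, idx in enumerate(peaks):
        left = max(0, int(math.floor(widths[2][i])))
        right = min(len(ri) - 1, int(math.ceil(widths[3][i])))
        sl = slice(left, right + 1)
        weights = np.where(profile.valid_mask[sl], np.clip(ri[sl], 0.0, None), 0.0)
        masses = profile.molar_mass[sl]
        good = np.isfinite(masses) & (weights > 0)
        if not np.any(good):
            continue
        mean_mass_kda = float(np.average(masses[good], weights=weights[good])) / 1000.0
        ranked = match_species(catalog, mean_mass_kda, rel_tol)
        label, err = (ranked[0][0].label, ranked[0][1]) if ranked else (None, None)
        assignments.append(
            PeakAssignment(
                interval=(float(chrom.time[left]), float(chrom.time[right])),
                mass_kda=mean_mass_kda,
                species_label=label,
                relative_error=err,
            )
        )
    return assignments


# --------------------------------------------------------------------------
# delimited-text I/O
# --------------------------------------------------------------------------

def write_chromatogram(chrom: Chromatogram, calibration: MALLSCalibration, path: str) -> None:
    """Write a chromatogram as 4-column TSV with a YAML calibration header."""
    header = {
        "calibration": {
            "dn_dc": calibration.dn_dc,
            "wavelength": calibration.wavelength,
            "solvent_ri": calibration.solvent_ri,
            "uv_extinction": calibration.uv_extinction,
            "interdetector_delays": dict(calibration.interdetector_delays),
        },
        "flow_rate": chrom.flow_rate,
        "injected": [list(map(float, pair)) for pair in chrom.injected],
    }
    buf = io.StringIO()
    for line in yaml.safe_dump(header, sort_keys=True).splitlines():
        buf.write(f"# {line}\n")
    buf.write("# time_s\tuv\tri\tls\n")
    for row in zip(chrom.time, chrom.uv, chrom.ri, chrom.ls):
        buf.write("\t".join(f"{v:.10g}" for v in row) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_chromatogram(path: str) -> tuple[Chromatogram, MALLSCalibration]:
    """Read a chromatogram written by :func:`write_chromatogram`."""
    header_lines: list[str] = []
    data: list[list[float]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                # strip exactly the "# " prefix: YAML indentation must survive
                header_lines.append(line[2:] if line.startswith("# ") else line[1:])
            else:
                data.append([float(x) for x in line.split()])
    meta_text = "\n".join(l for l in header_lines if "\t" not in l)
    meta = yaml.safe_load(meta_text) or {}
    cal_meta = meta.get("calibration", {})
    calibration = MALLSCalibration(
        dn_dc=cal_meta.get("dn_dc", 0.185),
        wavelength=cal_meta.get("wavelength", 658.0),
        solvent_ri=cal_meta.get("solvent_ri", 1.331),
        uv_extinction=cal_meta.get("uv_extinction", 1.0),
        interdetector_delays=cal_meta.get("interdetector_delays", {}) or {},
    )
    if not data:
        raise SECMALLSError(f"{path}: no data rows")
    arr = np.array(data, float)
    chrom = Chromatogram(
        time=arr[:, 0],
        uv=arr[:, 1],
        ri=arr[:, 2],
        ls=arr[:, 3],
        flow_rate=float(meta.get("flow_rate", 0.5)),
        injected=[tuple(p) for p in meta.get("injected", [])],
    )
    return chrom, calibration
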