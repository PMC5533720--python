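"""Synthetic study generator: component spectra, longitudinal cohorts, stress traces.

Everything downstream of the instrument is testable against planted ground
truth produced here:

* pure-component Raman spectra (collagen I, water, adipose) built from
  Gaussian/Lorentzian band tables with literature-typical positions;
* a two-genotype longitudinal cohort (wild-type vs Cox-1 knockout sampling
  days) whose spectra are known non-negative mixtures of the components plus
  a smooth fluorescence baseline and shot-like noise, with an abrupt reversal
  of the lipid-vs-protein balance planted on the genotype's last gestation
  day (day 19 WT, day 20 KO) and a configurable fraction of planted QC and
  unmixing-residual violations;
* Maxwell-type stress-relaxation traces following the ramp/hold displacement
  protocol, with known exponential stiffness parameters A and B.

All randomness flows from the explicit ``seed`` argument of each generator;
equal seeds give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .spectra import DEFAULT_AXIS, SpectralDataset, _check_axis

# --------------------------------------------------------------------- bands


@dataclasses.dataclass(frozen=True)
class BandModel:
    """One vibrational band: ``center`` (cm^-1), ``width`` = FWHM (cm^-1),
    ``amplitude`` (counts, arbitrary), ``shape`` in {gaussian, lorentzian}."""

    center: float
    width: float
    amplitude: float
    shape: str = "gaussian"

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("band width (FWHM) must be > 0")
        if self.amplitude < 0:
            raise ValueError("band amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        x = np.asarray(axis, dtype=float) - self.center
        if self.shape == "gaussian":
            sigma = self.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return self.amplitude * np.exp(-0.5 * (x / sigma) ** 2)
        gamma = self.width / 2.0  # lorentzian HWHM
        return self.amplitude * gamma**2 / (x**2 + gamma**2)


#: Default band inventory per pure component.  Positions are literature-typical
#: for type-I collagen (amide I/III, phenylalanine ring, CH deformations),
#: adipose triglyceride (CH2 scissoring dominating 1440 cm^-1) and the broad
#: water bending mode near 1640 cm^-1.
DEFAULT_BAND_TABLE: dict[str, tuple[BandModel, ...]] = {
    "collagen": (
        BandModel(938, 18, 0.40),
        BandModel(1003, 10, 0.50, "lorentzian"),
        BandModel(1245, 22, 0.55),
        BandModel(1265, 18, 0.65),
        BandModel(1304, 16, 0.20),
        BandModel(1450, 20, 0.45),
        BandModel(1657, 26, 0.95),
    ),
    "water": (BandModel(1640, 95, 1.0),),
    "adipose": (
        BandModel(1078, 16, 0.25),
        BandModel(1267, 14, 0.30),
        BandModel(1303, 14, 0.75),
        BandModel(1440, 18, 1.00),
        BandModel(1657, 16, 0.40),
        BandModel(1745, 14, 0.35),
    ),
}

COMPONENT_NAMES = ("collagen", "water", "adipose")


@dataclasses.dataclass
class PureComponentLibrary:
    """Design matrix of reference spectra on a shared axis (unit maximum each)."""

    axis: np.ndarray
    X: pd.DataFrame  # (n_channels, n_components), columns named
    provenance: str = ""

    def __post_init__(self):
        self.axis = _check_axis(self.axis)
        if len(self.X) != self.axis.size:
            raise ValueError("component matrix rows must match axis length")
        if (self.X.to_numpy() < -1e-12).any():
            raise ValueError("component spectra must be non-negative")

    @property
    def names(self) -> list[str]:
        return list(self.X.columns)

    def matrix(self) -> np.ndarray:
        return self.X.to_numpy(float)


def gen_pure_components(
    axis: np.ndarray = DEFAULT_AXIS,
    band_models: dict[str, Sequence[BandModel]] | None = None,
    seed: int | None = None,
) -> PureComponentLibrary:
    """Build the pure-component library from band tables (noiseless, unit max).

    ``seed`` is accepted for interface symmetry; the default library is
    deterministic.  Raises if any requested band center lies outside ``axis``.
    """
    axis = _check_axis(axis)
    bands = band_models if band_models is not None else DEFAULT_BAND_TABLE
    cols = {}
    for name, comp_bands in bands.items():
        if len(comp_bands) == 0:
            raise ValueError(f"component {name!r} needs at least one band")
        for b in comp_bands:
            if not (axis[0] <= b.center <= axis[-1]):
                raise ValueError(
                    f"band at {b.center} cm^-1 of component {name!r} lies outside "
                    f"the axis range [{axis[0]}, {axis[-1]}]"
                )
        y = np.sum([b.evaluate(axis) for b in comp_bands], axis=0)
        cols[name] = y / y.max()
    return PureComponentLibrary(axis, pd.DataFrame(cols), provenance="synthetic band table")


# -------------------------------------------------------------------- cohort

WT_DAYS = ("NG", 4, 12, 15, 18, 19)
KO_DAYS = ("NG", 4, 12, 15, 19, 20)


@dataclasses.dataclass
class CohortDesign:
    """Sampling design of the longitudinal study.

    Defaults reproduce the study layout: WT measured non-gravid and on days
    4/12/15/18/19, KO on 4/12/15/19/20, 8 mice per genotype-day group, 5-10
    spectra per mouse, lipid-vs-protein reversal planted on day 19 (WT) /
    day 20 (KO).
    """

    gestation_days: dict[str, tuple] = dataclasses.field(
        default_factory=lambda: {"WT": WT_DAYS, "KO": KO_DAYS}
    )
    mice_per_group: int = 8
    spectra_per_mouse: tuple[int, int] = (5, 10)
    jump_day: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"WT": 19, "KO": 20}
    )
    seed: int = 0
    # planted-defect fractions
    qc_low_frac: float = 0.04
    qc_high_frac: float = 0.04
    bad_fit_frac: float = 0.04
    # signal model
    base_scale_counts: tuple[float, float] = (350.0, 900.0)  # per-spectrum uniform
    baseline_amp_counts: tuple[float, float] = (150.0, 600.0)
    noise_scale: float = 0.01  # sigma = noise_scale * sqrt(intensity)
    jump_magnitude: float = 1.0  # multiplier on the planted reversal size

    def __post_init__(self):
        if self.mice_per_group < 1:
            raise ValueError("mice_per_group must be >= 1")
        lo, hi = self.spectra_per_mouse
        if not (5 <= lo <= hi <= 10):
            raise ValueError("spectra_per_mouse must lie within 5-10")


# Smooth three-phase trajectories (softening / ripening / dilation) for the
# true mixing weights, relative units.  NG is mapped to day 0.
def _logistic(d, d0, rate):
    return 1.0 / (1.0 + np.exp(-rate * (d - d0)))


def _true_weights(day: float, jump_day: int, jump_magnitude: float):
    d = float(day)
    collagen = 1.00 - 0.65 * _logistic(d, 15.0, 0.8)      # declines from ~day 12
    water = 0.45 + 0.35 * _logistic(d, 13.0, 0.5)         # hydration rises
    adipose = 0.25 + 0.55 * _logistic(d, 14.0, 0.9)       # lipid signal rises
    if d >= jump_day:  # abrupt reversal of the lipid/protein balance at term
        adipose -= 0.45 * jump_magnitude
        collagen += 0.30 * jump_magnitude
    return np.array([collagen, water, adipose])


#: rogue bands added to planted bad-fit spectra (not in the 3-component library)
_ROGUE_BANDS = (BandModel(1160, 25, 1.0), BandModel(1525, 20, 0.8))


def _day_sort_key(day):
    return -1.0 if day == "NG" else float(day)


def gen_cohort(
    design: CohortDesign, library: PureComponentLibrary | None = None
) -> tuple[SpectralDataset, pd.DataFrame]:
    """Generate the longitudinal cohort and its per-spectrum ground truth.

    Returns ``(dataset, truth)`` where ``truth`` has one row per spectrum with
    the true mixing coefficients (counts scale), baseline polynomial
    coefficients, noise scale, the planted QC violation label
    (``"" | "low" | "high"``) and the planted bad-fit flag.
    """
    if library is None:
        library = gen_pure_components()
    rng = np.random.default_rng(design.seed)
    axis = library.axis
    X = library.matrix()
    names = library.names
    t = (axis - axis[0]) / (axis[-1] - axis[0])  # [0, 1] coordinate for baselines
    rogue = np.sum([b.evaluate(axis) for b in _ROGUE_BANDS], axis=0)
    i1440 = np.flatnonzero(np.abs(axis - 1440.0) <= 8.0)

    rows, spectra, truths = [], [], []
    sid = 0
    for genotype, days in design.gestation_days.items():
        for day in days:
            d = 0.0 if day == "NG" else float(day)
            for m in range(design.mice_per_group):
                mouse_id = f"{genotype}_d{day}_m{m:02d}"
                mouse_factor = rng.lognormal(0.0, 0.15)
                n_spec = int(rng.integers(design.spectra_per_mouse[0],
                                          design.spectra_per_mouse[1] + 1))
                for s in range(n_spec):
                    w = _true_weights(d, design.jump_day[genotype],
                                      design.jump_magnitude)
                    scale = rng.uniform(*design.base_scale_counts)
                    beta = w * scale * mouse_factor * rng.lognormal(0.0, 0.10)
                    beta = np.clip(beta, 0.0, None)
                    mixture = X @ beta

                    # planted defects ------------------------------------
                    u = rng.uniform()
                    qc_label = ""
                    if u < design.qc_low_frac:
                        qc_label = "low"
                        target = rng.uniform(20.0, 90.0)
                    elif u < design.qc_low_frac + design.qc_high_frac:
                        qc_label = "high"
                        target = rng.uniform(1900.0, 2600.0)
                    if qc_label:
                        peak = mixture[i1440].max()
                        beta = beta * (target / peak)
                        mixture = X @ beta
                    bad_fit = (not qc_label) and rng.uniform() < design.bad_fit_frac
                    if bad_fit:
                        mixture = mixture + 0.5 * mixture.max() * rogue

                    # baseline + noise -----------------------------------
                    amp = rng.uniform(*design.baseline_amp_counts)
                    bc = amp * np.array([1.0, -rng.uniform(0.4, 0.9),
                                         rng.uniform(0.0, 0.35)])
                    baseline = bc[0] + bc[1] * t + bc[2] * t**2
                    clean = mixture + baseline
                    noise = design.noise_scale * np.sqrt(np.clip(clean, 0.0, None) + 1.0)
                    y = clean + noise * rng.standard_normal(axis.size)

                    rows.append(
                        dict(spectrum_id=f"s{sid:05d}", mouse_id=mouse_id,
                             genotype=genotype, gestation_day=str(day), site=s)
                    )
                    truths.append(
                        dict(spectrum_id=f"s{sid:05d}",
                             **{f"beta_{n}": b for n, b in zip(names, beta)},
                             baseline_c0=bc[0], baseline_c1=bc[1], baseline_c2=bc[2],
                             noise_scale=design.noise_scale,
                             qc_violation=qc_label, bad_fit=bad_fit)
                    )
                    spectra.append(y)
                    sid += 1

    dataset = SpectralDataset(axis, np.vstack(spectra), pd.DataFrame(rows))
    truth = pd.DataFrame(truths)
    return dataset, truth


# ------------------------------------------------------------- stress traces


@dataclasses.dataclass
class StressRelaxationTrace:
    """One ex vivo stress-relaxation record: time (s), displacement (mm),
    force (N), cross-sectional area (mm^2) and unloaded initial dilation (mm)."""

    time: np.ndarray
    displacement: np.ndarray
    force: np.ndarray
    area_mm2: float
    initial_dilation_mm: float = 0.0
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, float)
        self.displacement = np.asarray(self.displacement, float)
        self.force = np.asarray(self.force, float)
        if not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.area_mm2 <= 0:
            raise ValueError("cross-sectional area must be > 0")

    def write(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "displacement_mm": self.displacement,
             "force_N": self.force}
        ).to_csv(path, index=False)

    @classmethod
    def read(cls, path, area_mm2: float, initial_dilation_mm: float = 0.0,
             meta: dict | None = None) -> "StressRelaxationTrace":
        tbl = pd.read_csv(path)
        return cls(tbl["time_s"].to_numpy(), tbl["displacement_mm"].to_numpy(),
                   tbl["force_N"].to_numpy(), area_mm2, initial_dilation_mm,
                   meta or {})


def exponential_stress(opening, A: float, B: float) -> np.ndarray:
    """Equilibrium stress law Stress = (A/B)*[exp(opening*B) - 1].

    A is the stiffness at small displacements (stress/mm), B the exponential
    rate (1/mm); the B -> 0 limit A*opening is evaluated stably via expm1.
    """
    opening = np.asarray(opening, dtype=float)
    if B < 1e-12:
        return A * opening
    return (A / B) * np.expm1(B * opening)


def gen_stress_trace(
    A: float,
    B: float,
    *,
    n_steps: int = 8,
    hold_s: float = 240.0,
    ramp_rate_mm_s: float = 0.1,
    step_mm: float = 1.0,
    relax_tau_s: float = 20.0,
    overshoot: float = 0.5,
    area_mm2: float = 1.0,
    initial_dilation_mm: float = 0.0,
    noise: float = 0.0,
    fs_hz: float = 10.0,
    failure_at_mm: float | None = None,
    seed: int | None = None,
) -> tuple[StressRelaxationTrace, dict]:
    """Simulate a ramp-and-hold stress-relaxation test with known stiffness.

    The displacement protocol is the study's: an unloaded 4-minute baseline,
    then repeated cycles of a 1 mm ramp at 0.1 mm/s (10 s) followed by a
    4-minute hold.  During each hold the stress relaxes exponentially with
    time constant ``relax_tau_s`` from the impulse peak
    ``(1+overshoot) * eq(x)`` toward the equilibrium value
    ``eq(x) = (A/B)[exp(xB)-1]``.  Multiplicative Gaussian noise of relative
    scale ``noise`` is applied to the force channel.  If ``failure_at_mm`` is
    set, the stress collapses at that displacement and the trace is truncated
    shortly after (sudden loss of stress under tensile loading).

    Returns ``(trace, truth)`` with the planted parameters in ``truth``.
    """
    if A <= 0 or B < 0:
        raise ValueError("require A > 0 and B >= 0")
    if relax_tau_s <= 0:
        raise ValueError("relax_tau_s must be > 0")
    if fs_hz <= 0:
        raise ValueError("sampling rate must be > 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / fs_hz
    ramp_s = step_mm / ramp_rate_mm_s

    t_chunks, d_chunks, s_chunks = [], [], []
    t0 = 0.0
    # unloaded baseline hold
    tt = np.arange(0.0, hold_s, dt)
    t_chunks.append(t0 + tt)
    d_chunks.append(np.zeros_like(tt))
    s_chunks.append(np.zeros_like(tt))
    t0 += hold_s
    x_prev = 0.0
    for j in range(1, n_steps + 1):
        # ramp: stress tracks the impulse curve at the instantaneous opening
        tt = np.arange(0.0, ramp_s, dt)
        x = x_prev + ramp_rate_mm_s * tt
        t_chunks.append(t0 + tt)
        d_chunks.append(x)
        s_chunks.append((1.0 + overshoot) * exponential_stress(x, A, B))
        t0 += ramp_s
        x_prev = j * step_mm
        # hold: exponential relaxation toward equilibrium
        tt = np.arange(0.0, hold_s, dt)
        eq = exponential_stress(x_prev, A, B)
        peak = (1.0 + overshoot) * eq
        t_chunks.append(t0 + tt)
        d_chunks.append(np.full_like(tt, x_prev))
        s_chunks.append(eq + (peak - eq) * np.exp(-tt / relax_tau_s))
        t0 += hold_s

    time = np.concatenate(t_chunks)
    disp = np.concatenate(d_chunks)
    stress = np.concatenate(s_chunks)

    failure_disp = None
    if failure_at_mm is not None:
        idx = np.flatnonzero(disp >= failure_at_mm)
        if idx.size:
            k = idx[0]
            failure_disp = disp[k]
            stress = stress.copy()
            stress[k:] = 0.05 * stress[max(k - 1, 0)]
            end = min(stress.size, k + int(5.0 * fs_hz))
            time, disp, stress = time[:end], disp[:end], stress[:end]

    force = stress * area_mm2
    if noise > 0:
        force = force * (1.0 + noise * rng.standard_normal(force.size))

    trace = StressRelaxationTrace(
        time, disp, force, area_mm2, initial_dilation_mm,
        meta=dict(protocol="ramp_hold", fs_hz=fs_hz),
    )
    truth = dict(A=A, B=B, relax_tau_s=relax_tau_s, overshoot=overshoot,
                 openings=[float(j * step_mm) for j in range(1, n_steps + 1)],
                 failure_displacement_mm=failure_disp, noise=noise)
    return trace, truth
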