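"""Seeded generators for stopped-flow traces and ESI peak lists.

No raw instrument data accompanies the study conditions this package
analyzes, so every stage is exercised on synthetic inputs carrying the
same statistical structure the fitters assume:

* superoxide decay traces — mixed-order decay in absorbance units with
  iid Gaussian photometric noise, an optional exponential mixing
  artifact confined to the first 5 ms, and an optional slowly decreasing
  baseline that emulates concurrent Ni(II)-peptide degradation at
  250-260 nm (a first-order component with half-life ~16 s);
* Ni(II)-peptide degradation traces — first-order chromophore decay;
* centroided ESI peak lists — theoretical species m/z with ppm jitter,
  relative intensity noise, decoy peaks, and optional isotope envelopes.

Every generator takes an integer seed; identical seeds give bit-identical
output.  Defaults follow the assay conditions: superoxide sampled at
1 kHz for up to 4 s, a0 ~ 1e-4 M at 250 nm (epsilon = 2000 M^-1 cm^-1),
noise sigma 0.002 AU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .fitting import DecayTrace
from .kinetics import (
    ActivityDecomposition,
    FirstOrderDecayParams,
    SuperoxideKineticParams,
    concentration_to_absorbance,
    first_order_decay,
    kobs_from_concentration,
    superoxide_decay_closed,
)
from .peptide import isotope_pattern
from .species import DegradationSpecies, PeakList, species_composition, species_mz

__all__ = [
    "DriftModel",
    "MixingArtifact",
    "TraceGeneratorConfig",
    "SpectrumGeneratorConfig",
    "simulate_superoxide_trace",
    "simulate_degradation_trace",
    "simulate_spectrum",
    "ActivityCampaign",
    "make_activity_dataset",
]

DEGRADATION_DRIFT_RATE = np.log(2.0) / 16.0  # s^-1, chromophore half-life ~16 s


@dataclass(frozen=True)
class DriftModel:
    """Baseline drift added to the absorbance signal.

    kind "none"; "linear" (slope AU/s, decreasing for negative slope);
    or "first-order" — amplitude * exp(-rate * t), a decreasing baseline
    mimicking the degradation of the absorbing Ni(II)-peptide itself.
    """

    kind: str = "none"
    amplitude: float = 0.0  # AU (first-order) | AU/s (linear slope)
    rate: float = DEGRADATION_DRIFT_RATE  # s^-1, first-order only

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(t)
        if self.kind == "linear":
            return self.amplitude * t
        if self.kind == "first-order":
            return self.amplitude * np.exp(-self.rate * t)
        raise ValueError(f"unknown drift kind {self.kind!r}")


@dataclass(frozen=True)
class MixingArtifact:
    """Exponential spike from the buffer/DMSO mixing, confined to t < 5 ms."""

    amplitude: float = 0.0  # AU at t = 0
    tau: float = 0.001  # s
    duration: float = 0.005  # s; zero beyond this

    def __post_init__(self):
        if self.duration > 0.005 + 1e-12:
            raise ValueError("mixing artifact must vanish within the first 5 ms")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        out = self.amplitude * np.exp(-t / self.tau)
        return np.where(t < self.duration, out, 0.0)


@dataclass(frozen=True)
class TraceGeneratorConfig:
    """Truth parameters and instrument model for one superoxide trace."""

    a0: float = 1e-4  # M
    k2: float = 2e4  # M^-1 s^-1
    k1: float = 5.0  # s^-1 background
    k_cat: float = 2e6  # M^-1 s^-1
    b: float = 0.0  # catalyst concentration, M
    C: float = 0.0  # offset, M
    epsilon: float = 2000.0
    path: float = 1.0
    sampling_rate: float = 1000.0  # Hz
    duration: float = 4.0  # s
    noise_sigma: float = 0.002  # AU
    artifact: MixingArtifact = MixingArtifact()
    drift: DriftModel = DriftModel()
    wavelength: float = 250.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate < 100:
            raise ValueError("sampling rate must be >= 100 Hz")

    @property
    def k_obs(self) -> float:
        return kobs_from_concentration(
            ActivityDecomposition(k1=self.k1, k3=self.k_cat, b=self.b)
        )


def simulate_superoxide_trace(cfg: TraceGeneratorConfig) -> DecayTrace:
    """One noisy stopped-flow superoxide decay trace in absorbance units.

    absorbance(t) = epsilon*path*a(t) + drift(t) + artifact(t) + noise,
    with a(t) the closed-form mixed-order decay at the truth parameters.
    The truth is recorded in the trace's ``meta``.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration * cfg.sampling_rate)) + 1
    t = np.arange(n) / cfg.sampling_rate
    p = SuperoxideKineticParams(a0=cfg.a0, k2=cfg.k2, k_obs=cfg.k_obs, C=cfg.C)
    clean = concentration_to_absorbance(
        superoxide_decay_closed(t, p), cfg.epsilon, cfg.path
    )
    signal = clean + cfg.drift.evaluate(t) + cfg.artifact.evaluate(t)
    if cfg.noise_sigma > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sigma, size=n)
    return DecayTrace(
        time=t,
        absorbance=signal,
        wavelength=cfg.wavelength,
        b=cfg.b,
        epsilon=cfg.epsilon,
        path=cfg.path,
        replicate=f"sim-{cfg.seed}",
        meta={
            "truth": {
                "a0": cfg.a0,
                "k2": cfg.k2,
                "k1": cfg.k1,
                "k_cat": cfg.k_cat,
                "k_obs": cfg.k_obs,
                "C": cfg.C,
            },
            "seed": cfg.seed,
        },
    )


def simulate_degradation_trace(
    A0: float,
    A_inf: float,
    k: float,
    sigma: float = 0.0,
    duration: float = 120.0,
    sampling_rate: float = 1.0,
    wavelength: float = 260.0,
    b: float = 0.0,
    seed: int = 0,
) -> DecayTrace:
    """First-order Ni(II)-peptide chromophore decay with Gaussian noise."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    y = first_order_decay(t, FirstOrderDecayParams(A0=A0, A_inf=A_inf, k=k))
    if sigma > 0:
        y = y + rng.normal(0.0, sigma, size=n)
    return DecayTrace(
        time=t,
        absorbance=y,
        wavelength=wavelength,
        b=b,
        replicate=f"sim-{seed}",
        meta={"truth": {"A0": A0, "A_inf": A_inf, "k": k}, "seed": seed},
    )


# --------------------------------------------------------------------------
# Peak lists
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SpectrumGeneratorConfig:
    """Truth species and noise model for a simulated centroided spectrum."""

    species: tuple[DegradationSpecies, ...] = ()
    intensities: tuple[float, ...] | None = None  # default: all 1.0
    mz_jitter_ppm: float = 1.0
    intensity_noise: float = 0.05  # relative
    n_decoys: int = 0
    decoy_mz_range: tuple[float, float] = (300.0, 3500.0)
    with_envelopes: bool = False
    envelope_bin_width: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.mz_jitter_ppm < 0:
            raise ValueError("jitter must be non-negative")
        if self.intensities is not None and len(self.intensities) != len(self.species):
            raise ValueError("one intensity per truth species required")


def simulate_spectrum(cfg: SpectrumGeneratorConfig) -> tuple[PeakList, list[DegradationSpecies]]:
    """Peak list at jittered theoretical m/z plus decoys; truth returned alongside.

    The truth list is ordered like the generated truth peaks (decoys are
    appended after it and carry no truth entry).
    """
    rng = np.random.default_rng(cfg.seed)
    mzs, ints, envs = [], [], []
    intensities = cfg.intensities or tuple(1.0 for _ in cfg.species)
    for sp, inten in zip(cfg.species, intensities):
        mz0 = species_mz(sp)
        jitter = rng.normal(0.0, cfg.mz_jitter_ppm) * 1e-6 if cfg.mz_jitter_ppm else 0.0
        mzs.append(mz0 * (1.0 + jitter))
        noisy = inten * max(1.0 + rng.normal(0.0, cfg.intensity_noise), 1e-3)
        ints.append(noisy if cfg.intensity_noise else inten)
        if cfg.with_envelopes:
            pat = isotope_pattern(
                species_composition(sp), z=sp.z,
                bin_width=cfg.envelope_bin_width, adduct=sp.adduct,
            )
            env_mz = pat.mz * (1.0 + jitter)
            env_int = pat.abundance * noisy
            envs.append((env_mz, env_int))
        else:
            envs.append(None)
    for _ in range(cfg.n_decoys):
        mzs.append(float(rng.uniform(*cfg.decoy_mz_range)))
        ints.append(float(rng.uniform(0.01, 0.5)))
        envs.append(None)
    return (
        PeakList(
            mz=np.array(mzs),
            intensity=np.array(ints),
            envelopes=envs if cfg.with_envelopes else None,
        ),
        list(cfg.species),
    )


# --------------------------------------------------------------------------
# Full activity campaigns
# --------------------------------------------------------------------------


@dataclass
class ActivityCampaign:
    """A background run plus replicate catalyzed traces per concentration."""

    background: list[DecayTrace]
    catalyzed: dict[float, list[DecayTrace]]  # b -> replicates
    truth: dict


def make_activity_dataset(
    k_cat: float = 2e6,
    k1: float = 5.0,
    k2: float = 2e4,
    b_list: Sequence[float] = (10e-6, 20e-6, 30e-6, 40e-6, 50e-6),
    replicates: int = 5,
    a0: float = 1e-4,
    noise_sigma: float = 0.002,
    duration: float = 1.0,
    drift: DriftModel = DriftModel(),
    seed: int = 0,
) -> ActivityCampaign:
    """A full five-concentration SOD activity campaign with truth attached.

    Produces ``replicates`` uncatalyzed background traces (b = 0) and
    ``replicates`` catalyzed traces at each concentration in ``b_list``.
    Child seeds are spawned deterministically from ``seed``.
    """
    if len(b_list) < 2:
        raise ValueError("need at least two catalyst concentrations")
    ss = np.random.SeedSequence(seed)
    base = TraceGeneratorConfig(
        a0=a0, k2=k2, k1=k1, k_cat=k_cat, b=0.0,
        noise_sigma=noise_sigma, duration=duration, drift=drift,
    )
    child_seeds = iter(int(s) % (2**31) for s in ss.generate_state((len(b_list) + 1) * replicates))
    background = [
        simulate_superoxide_trace(replace(base, b=0.0, seed=next(child_seeds)))
        for _ in range(replicates)
    ]
    catalyzed: dict[float, list[DecayTrace]] = {}
    for b in b_list:
        catalyzed[float(b)] = [
            simulate_superoxide_trace(replace(base, b=float(b), seed=next(child_seeds)))
            for _ in range(replicates)
        ]
    return ActivityCampaign(
        background=background,
        catalyzed=catalyzed,
        truth={
            "k_cat": k_cat, "k1": k1, "k2": k2, "a0": a0,
            "b_list": [float(b) for b in b_list],
            "replicates": replicates, "noise_sigma": noise_sigma, "seed": seed,
        },
    )
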