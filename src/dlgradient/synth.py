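"""Synthetic study data with known ground truth.

Generates stand-ins for everything the study measured — fixed-embryo Dl
gradient profiles, *sna*/*sog* expression profiles, live-embryo amplitude
time courses, and qPCR delta-CT tables — from planted truths, so every
quantification stage can be validated end to end without raw imaging data.

Defaults mirror the study conditions: dosage-proportional Gaussian-plus-tail
gradients with genotype widths 0.13 / 0.15 / 0.17, gene borders at the
measured 1x/2x/4x means, nc14 amplitude traces with per-genotype peak ratios
0.5 / 1 / 1.7, and a qPCR design of three runs x three biological x three
technical replicates per genotype.  The noise model is multiplicative
(Gaussian on log intensity, CV-parameterized) plus an additive Gaussian
floor, mimicking fluorescence measurement error.  Every generator is
deterministic under a fixed seed and emits its ground truth alongside the
data; no analysis stage may consume the truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .dosage_stats import AmplitudeTrace
from .empirical import EmpiricalGradientParams, eval_gradient
from .profiles import CanonicalProfile, EmbryoProfile

__all__ = [
    "SynthConfig",
    "synth_embryo_profiles",
    "synth_gene_profiles",
    "synth_amplitude_traces",
    "synth_qpcr",
]

GENOTYPE_DOSAGE = {"1x": 0.5, "2x": 1.0, "4x": 2.0}

# Table-1-style planted truths
DEFAULT_GRADIENT_TRUTH = {
    "1x": EmpiricalGradientParams(alpha=0.5, sigma=0.13, m=-0.1, b=0.4),
    "2x": EmpiricalGradientParams(alpha=1.0, sigma=0.15, m=-0.1, b=0.4),
    "4x": EmpiricalGradientParams(alpha=2.0, sigma=0.17, m=-0.1, b=0.4),
}
DEFAULT_GENE_TRUTH = {
    # sna: ventral domain [0, border]; sog: lateral domain [v, d]
    "sna": {"1x": (0.17,), "2x": (0.20,), "4x": (0.19,)},
    "sog": {"1x": (0.17, 0.45), "2x": (0.19, 0.47), "4x": (0.21, 0.51)},
}
DEFAULT_PEAK_TRUTH = {"1x": 0.5, "2x": 1.0, "4x": 1.7}


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_embryos: int = 40
    nuclei_per_profile: int = 100
    gradient_truth: dict = field(
        default_factory=lambda: dict(DEFAULT_GRADIENT_TRUTH)
    )
    gene_truth: dict = field(default_factory=lambda: dict(DEFAULT_GENE_TRUTH))
    multiplicative_cv: float = 0.05
    additive_sd: float = 0.01
    midline_jitter_sd: float = 0.02
    gene_edge_steepness: float = 0.02
    # live-trace truth
    peak_truth: dict = field(default_factory=lambda: dict(DEFAULT_PEAK_TRUTH))
    n_traces: int = 10
    t_nc14_range: tuple = (40.0, 70.0)
    trace_noise_cv: float = 0.05
    # qPCR truth
    qpcr_doses: dict = field(default_factory=lambda: dict(GENOTYPE_DOSAGE))
    n_runs: int = 3
    n_bio: int = 3
    n_tech: int = 3
    run_offset_sd: float = 0.2
    bio_noise_sd: float = 0.3
    tech_noise_sd: float = 0.15
    dropout_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in (
            "multiplicative_cv",
            "additive_sd",
            "midline_jitter_sd",
            "trace_noise_cv",
            "run_offset_sd",
            "bio_noise_sd",
            "tech_noise_sd",
            "dropout_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_embryos < 1:
            raise ValueError("n_embryos must be >= 1")


def _rng(config: SynthConfig, stream: int) -> np.random.Generator:
    # independent per-op stream keyed by (seed, stream id)
    return np.random.default_rng([config.seed, stream])


def _apply_noise(
    rng: np.random.Generator, values: np.ndarray, cv: float, add_sd: float
) -> np.ndarray:
    out = np.asarray(values, float)
    if cv > 0:
        out = out * np.exp(rng.normal(0.0, cv, out.shape))
    if add_sd > 0:
        out = out + rng.normal(0.0, add_sd, out.shape)
    return out


def synth_embryo_profiles(config: SynthConfig):
    """Dl-gradient intensity profiles per genotype with planted Eq-1 truths.

    Per embryo: sorted uniform nuclear positions on [-1, 1], the genotype's
    gradient truth evaluated at those positions, multiplicative then additive
    Gaussian noise, and a random midline jitter.  Returns
    ``(profiles, truth)`` where truth records the planted parameters and
    per-embryo midline shifts.
    """
    rng = _rng(config, 1)
    profiles: list[EmbryoProfile] = []
    truth = {"params": {}, "midline": {}}
    for genotype, params in config.gradient_truth.items():
        truth["params"][genotype] = dataclasses.asdict(params)
        for e in range(config.n_embryos):
            x = np.sort(rng.uniform(-1.0, 1.0, config.nuclei_per_profile))
            mu = rng.normal(0.0, config.midline_jitter_sd)
            clean = eval_gradient(params, np.clip(x - mu, -1.0, 1.0))
            intensity = _apply_noise(
                rng, clean, config.multiplicative_cv, config.additive_sd
            )
            eid = f"{genotype}_{e:03d}"
            profiles.append(
                EmbryoProfile(x, intensity, {"embryo_id": eid, "genotype": genotype,
                                             "channel": "dl"})
            )
            truth["midline"][eid] = float(mu)
    return profiles, truth


def synth_gene_profiles(config: SynthConfig):
    """Smoothed-pulse mRNA profiles with planted borders.

    sna is a ventral domain [0, border]; sog a lateral stripe [v, d].  The
    clean profile is the logistic-edge canonical template at the planted
    borders; noise as for the gradient profiles.  Returns
    ``(profiles, truth)`` with the planted borders per (gene, genotype).
    """
    rng = _rng(config, 2)
    profiles: list[EmbryoProfile] = []
    truth: dict = {}
    for gene, per_geno in config.gene_truth.items():
        kind = "ventral" if len(next(iter(per_geno.values()))) == 1 else "lateral"
        template = CanonicalProfile(kind=kind, steepness=config.gene_edge_steepness)
        truth[gene] = {g: list(b) for g, b in per_geno.items()}
        for genotype, edges in per_geno.items():
            for e in range(config.n_embryos):
                x = np.sort(rng.uniform(-1.0, 1.0, config.nuclei_per_profile))
                clean = template(x, *edges) + 0.1  # small uniform background
                intensity = _apply_noise(
                    rng, clean, config.multiplicative_cv, config.additive_sd
                )
                profiles.append(
                    EmbryoProfile(
                        x,
                        intensity,
                        {
                            "embryo_id": f"{gene}_{genotype}_{e:03d}",
                            "genotype": genotype,
                            "channel": gene,
                        },
                    )
                )
    return profiles, truth


def _canonical_shape(tau: np.ndarray) -> np.ndarray:
    """Shared nc14 amplitude dynamic: sigmoidal rise, max at end of nc14."""
    s = expit((tau - 0.45) / 0.12)
    return s / expit((1.0 - 0.45) / 0.12)


def synth_amplitude_traces(config: SynthConfig):
    """Live-embryo amplitude time courses with per-genotype planted peaks.

    Each embryo shares the canonical shape, has its own nc14 duration drawn
    from ``t_nc14_range`` (minutes), a genotype peak scaling, and
    multiplicative noise.  Returns ``(traces, truth)``.
    """
    rng = _rng(config, 3)
    traces: list[AmplitudeTrace] = []
    truth = {"peaks": dict(config.peak_truth), "t_nc14": {}}
    for genotype, peak in config.peak_truth.items():
        for e in range(config.n_traces):
            t_nc14 = rng.uniform(*config.t_nc14_range)
            times = np.arange(0.0, t_nc14 + 0.5, 1.0)  # 1-min sampling
            clean = peak * _canonical_shape(times / t_nc14)
            amp = _apply_noise(rng, clean, config.trace_noise_cv, 0.0)
            eid = f"{genotype}_{e:03d}"
            traces.append(
                AmplitudeTrace(
                    times,
                    amp,
                    nc14_start=0,
                    gastrulation=times.size - 1,
                    meta={"embryo_id": eid, "genotype": genotype},
                )
            )
            truth["t_nc14"][eid] = float(t_nc14)
    return traces, truth


def synth_qpcr(config: SynthConfig):
    """Delta-CT table with genotype dose effects and replicate structure.

    delta-CT = -log2(dose) + run offset + biological noise + technical
    noise; invalid-CT dropouts occur at ``dropout_rate``.  Returns
    ``(table, truth)`` where the table has columns genotype, replicate
    (run.bio label), technical, delta_ct.
    """
    rng = _rng(config, 4)
    rows = []
    for run in range(config.n_runs):
        run_offset = rng.normal(0.0, config.run_offset_sd)
        for genotype, dose in config.qpcr_doses.items():
            for bio in range(config.n_bio):
                bio_noise = rng.normal(0.0, config.bio_noise_sd)
                for tech in range(config.n_tech):
                    if rng.uniform() < config.dropout_rate:
                        value = np.nan  # failed CT call
                    else:
                        value = (
                            -np.log2(dose)
                            + run_offset
                            + bio_noise
                            + rng.normal(0.0, config.tech_noise_sd)
                        )
                    rows.append(
                        {
                            "genotype": genotype,
                            "replicate": f"run{run}.bio{bio}",
                            "technical": tech,
                            "delta_ct": value,
                        }
                    )
    truth = {"doses": dict(config.qpcr_doses)}
    return pd.DataFrame(rows), truth
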